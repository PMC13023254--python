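import numpy as np
import pytest
from hypothesis import given, strategies as st

from numtscape.aligner import (EvalueModel, ScoringScheme, SearchParams,
                               build_seed_index, calibrate_evalue, encode,
                               extend_hit, reverse_complement, search,
                               smith_waterman_affine, sw_score_only)
from numtscape.io_formats import SequenceRecord

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestScoringScheme:
    def test_default_gap_costs_follow_open_plus_extend(self):
        s = ScoringScheme()
        assert s.gap_cost(1) == 8
        assert s.gap_cost(3) == 10

    def test_open_includes_first_base_variant(self):
        s = ScoringScheme(open_includes_first_base=True)
        assert s.gap_cost(1) == 7

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=0)


class TestSmithWaterman:
    def test_identical_sequences_score_length(self):
        assert smith_waterman_affine("ACGTACGTAC", "ACGTACGTAC")[0] == 10

    def test_no_homology_scores_zero(self):
        assert smith_waterman_affine("AAAA", "TTTT")[0] == 0

    def test_single_deletion_costs_affine_gap(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:9] + a[10:]
        assert smith_waterman_affine(a, b)[0] == 19 - (7 + 1)

    def test_size_guard(self):
        with pytest.raises(ValueError, match="too large"):
            smith_waterman_affine("A" * 4000, "A" * 4000)

    @given(DNA, DNA)
    def test_vectorized_score_matches_exhaustive_dp(self, a, b):
        s1 = smith_waterman_affine(a, b)[0]
        s2 = sw_score_only(encode(a)[0], encode(b)[0])
        assert s1 == s2


class TestSeedIndex:
    def test_positions_of_repeated_kmer(self):
        assert build_seed_index("ACGTACGT", 4)["ACGT"] == [0, 4]

    def test_masked_positions_excluded_by_default(self):
        idx = build_seed_index("ACgTACGT", 4)
        assert 0 not in idx.get("ACGT", [])
        idx2 = build_seed_index("ACgTACGT", 4, seeds_in_masked=True)
        assert idx2["ACGT"] == [0, 4]

    def test_n_kmers_skipped(self):
        assert build_seed_index("ANGT", 4) == {}


class TestExtendHit:
    def test_exact_implant_recovered_fully(self):
        rng = np.random.default_rng(0)
        frag = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        # flanks chosen to mismatch the query continuation at both ends
        genome = "T" * 200 + frag + "T" * 200
        query = "C" * 50 + frag + "C" * 50
        qc, _ = encode(query)
        tc, _ = encode(genome)
        params = SearchParams()
        cand = extend_hit((50 + 10, 200 + 10), qc, tc, ScoringScheme(),
                          params)
        assert cand is not None
        assert (cand.ta, cand.tb) == (200, 300)
        assert cand.score == 100

    def test_diverged_implant_score_near_oracle(self):
        from numtscape.simulate import mutate_fragment
        rng = np.random.default_rng(3)
        for rep in range(5):
            frag = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
            mut = mutate_fragment(frag, 0.1, 0.002, rng)
            genome = ("".join("ACGT"[i] for i in rng.integers(0, 4, 300))
                      + mut
                      + "".join("ACGT"[i] for i in rng.integers(0, 4, 300)))
            oracle = smith_waterman_affine(frag, mut)[0]
            hits = search(SequenceRecord("q", frag),
                          [SequenceRecord("t", genome)],
                          params=SearchParams(min_score=30))
            got = max(h.score for h in hits if h.strand == "+")
            assert got >= 0.95 * oracle
            assert got <= 1.05 * oracle + 2

    def test_background_seed_dies(self):
        rng = np.random.default_rng(5)
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        t = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        hits = search(SequenceRecord("q", q), [SequenceRecord("t", t)],
                      params=SearchParams())
        assert hits == []


class TestEvalueModel:
    def test_monotone_decreasing_in_score(self):
        m = EvalueModel(lam=1.0, K=0.1, m=100, n=1000)
        assert m.evalue(50) < m.evalue(40)

    def test_doubling_database_doubles_evalue(self):
        m = EvalueModel(lam=1.0, K=0.1, m=100, n=1000)
        assert m.evalue(30, n=2000) == pytest.approx(2 * m.evalue(30))

    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            EvalueModel(lam=-1, K=0.1, m=1, n=1)

    def test_calibration_lambda_near_theory(self, evalue_model):
        # ungapped lambda for +1/-1 uniform composition is ln 3
        assert 0.9 <= evalue_model.lam <= 1.25

    def test_degenerate_fit_rejected(self):
        # a 1-base query forces every max score to equal 1
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_evalue(ScoringScheme(), 1, 50, n_shuffles=30, seed=0)

    def test_self_consistency_expected_hits_at_e1(self, scheme):
        # fraction of null searches reaching the E=1 score should sit
        # within a factor ~3 of 1 - exp(-1)
        model = calibrate_evalue(scheme, 300, 3000, n_shuffles=60, seed=2)
        s1 = model.score_for_evalue(1.0)
        rng = np.random.default_rng(12)
        exceed = 0
        n_rep = 60
        for _ in range(n_rep):
            a = rng.integers(0, 4, 300).astype(np.uint8)
            b = rng.integers(0, 4, 3000).astype(np.uint8)
            if sw_score_only(a, b, scheme) >= s1:
                exceed += 1
        frac = exceed / n_rep
        expected = 1 - np.exp(-1)
        assert expected / 3 <= frac <= min(1.0, expected * 3)


class TestSearch:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            search(SequenceRecord("q", "ACGT"), [])

    def test_reverse_complement_implant_found_on_minus_strand(self):
        rng = np.random.default_rng(21)
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        frag = q[500:1500]
        genome = ("".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
                  + reverse_complement(frag)
                  + "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000)))
        hits = search(SequenceRecord("q", q), [SequenceRecord("t", genome)],
                      params=SearchParams())
        assert len(hits) == 1
        assert hits[0].strand == "-"
        # chance matches in the random flanks may trim/extend by a few bp
        assert abs(hits[0].nstart - 10_000) <= 4
        assert abs(hits[0].nend - 11_000) <= 4

    def test_strand_symmetry(self):
        rng = np.random.default_rng(22)
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        genome = ("".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
                  + q[200:700]
                  + "".join("ACGT"[i] for i in rng.integers(0, 4, 5000)))
        fwd = search(SequenceRecord("q", q), [SequenceRecord("t", genome)],
                     params=SearchParams())
        rev = search(SequenceRecord("q", q),
                     [SequenceRecord("t", reverse_complement(genome))],
                     params=SearchParams())
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)
        assert [h.strand for h in fwd] == ["+"]
        assert [h.strand for h in rev] == ["-"]

    def test_threshold_monotonicity(self, flagship, scheme, evalue_model):
        from numtscape.circular import double_sequence
        q = double_sequence(flagship["mito"])
        genome = flagship["genome"][:1]
        loose = search(q, genome, scheme, SearchParams(min_score=40),
                       evalue_model)
        tight = search(q, genome, scheme, SearchParams(min_score=200),
                       evalue_model)
        stricter_e = search(q, genome, scheme,
                            SearchParams(min_score=40, max_evalue=1e-30),
                            evalue_model)
        assert len(tight) <= len(loose)
        assert len(stricter_e) <= len(loose)
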