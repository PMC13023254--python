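import numpy as np
import pytest
from hypothesis import given, strategies as st

from numtscape.circular import CircularMito
from numtscape.io_formats import GenomicInterval, NumtHit, SequenceRecord
from numtscape.landscape import (annotation_overlap_fraction,
                                 flank_environment, gc_content,
                                 gene_coverage, pearson, window_counts)


def _mito(L=1000, genes=()):
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
    return CircularMito(seq, genes=list(genes))


def _hit(ms, me, wrap=False, chrom="chr1", ns=None, ne=None):
    ns = 10_000 if ns is None else ns
    ne = ns + 100 if ne is None else ne
    return NumtHit("h", chrom, ns, ne, "+", ms, me, 100, 1e-9, 0.9,
                   mstart_folded=ms, mend_folded=me, wrap=wrap,
                   normalized=True)


class TestWindowCounts:
    def test_hit_touches_every_overlapped_window(self):
        wc = window_counts([_hit(0, 250)], _mito(), window_size=100)
        assert wc.counts[:3].tolist() == [1, 1, 1]
        assert wc.counts[3:].sum() == 0

    def test_wrapped_hit_touches_both_ends(self):
        wc = window_counts([_hit(950, 30, wrap=True)], _mito(),
                           window_size=100)
        assert wc.counts[9] == 1 and wc.counts[0] == 1
        assert wc.counts[1:9].sum() == 0

    def test_no_hits_all_zero(self):
        wc = window_counts([], _mito(), window_size=100)
        assert wc.counts.sum() == 0 and wc.mean == 0.0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            window_counts([], _mito(), window_size=0)

    def test_increment_conservation(self):
        # total increments equal the sum over hits of windows overlapped
        hits = [_hit(0, 250), _hit(120, 130), _hit(950, 30, wrap=True)]
        wc = window_counts(hits, _mito(), window_size=100)
        expected = 3 + 1 + 2
        assert wc.counts.sum() == expected


class TestGeneCoverage:
    GENES = (GenomicInterval("mito", 0, 100, label="g1"),
             GenomicInterval("mito", 200, 300, label="g2"))

    def test_half_covered_gene(self):
        df = gene_coverage([_hit(0, 50)], _mito(genes=self.GENES))
        assert df.loc[df.gene == "g1", "covered_fraction"].item() == 0.5

    def test_union_of_overlapping_hits(self):
        df = gene_coverage([_hit(0, 60), _hit(40, 100)],
                           _mito(genes=self.GENES))
        assert df.loc[df.gene == "g1", "covered_fraction"].item() == 1.0

    def test_untouched_gene_zero(self):
        df = gene_coverage([_hit(0, 50)], _mito(genes=self.GENES))
        assert df.loc[df.gene == "g2", "covered_fraction"].item() == 0.0

    def test_matches_brute_force_base_scan(self):
        rng = np.random.default_rng(4)
        genes = [GenomicInterval("mito", a, a + 80, label=f"g{a}")
                 for a in range(0, 900, 120)]
        hits = [_hit(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 800, 12),
                                rng.integers(10, 150, 12))]
        df = gene_coverage(hits, _mito(genes=genes))
        covered = np.zeros(1000, dtype=bool)
        for h in hits:
            covered[h.mstart_folded:h.mend_folded] = True
        for g in genes:
            frac = covered[g.start:g.end].mean()
            assert df.loc[df.gene == g.label,
                          "covered_fraction"].item() == pytest.approx(frac)


class TestAnnotationOverlap:
    def test_contained_is_full_overlap(self):
        a = [GenomicInterval("c", 10, 20)]
        b = [GenomicInterval("c", 0, 100)]
        assert annotation_overlap_fraction(a, b) == (1.0, 1.0)

    def test_disjoint_is_zero(self):
        a = [GenomicInterval("c", 10, 20)]
        b = [GenomicInterval("c", 50, 60)]
        assert annotation_overlap_fraction(a, b) == (0.0, 0.0)

    def test_partial_base_level(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 50, 150)]
        assert annotation_overlap_fraction(a, b) == (1.0, 0.5)

    def test_not_symmetric_in_general(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 50, 150), GenomicInterval("c", 200, 400)]
        ab = annotation_overlap_fraction(a, b)[1]
        ba = annotation_overlap_fraction(b, a)[1]
        assert ab != ba


class TestFlankEnvironment:
    def _genome(self):
        return [SequenceRecord("chr1", "A" * 2000 + "G" * 100 + "T" * 2000)]

    def test_gc_extremes(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("AATT") == 0.0
        assert gc_content("GGNN") == 1.0  # N excluded from denominator

    def test_flank_gc_around_call(self):
        call = _hit(0, 100, ns=2000, ne=2100)
        env = flank_environment([call], self._genome(), flank_size=1000)
        assert env.mean_upstream_gc == 0.0
        assert env.mean_downstream_gc == 0.0

    def test_repeat_counts_by_class(self):
        call = _hit(0, 100, ns=2000, ne=2100)
        ann = [GenomicInterval("chr1", 1500, 1600, label="SINE/tRNA"),
               GenomicInterval("chr1", 1700, 1800, label="SINE/tRNA"),
               GenomicInterval("chr1", 1900, 1950, label="SINE/tRNA"),
               GenomicInterval("chr1", 3000, 3100, label="LINE/L1")]
        env = flank_environment([call], self._genome(), ann, flank_size=1000)
        assert env.repeat_class_counts == {"LINE/L1": 1, "SINE/tRNA": 3}

    def test_truncated_flank_flagged(self):
        call = _hit(0, 100, ns=100, ne=200)
        env = flank_environment([call], self._genome(), flank_size=1000)
        assert bool(env.per_call.truncated.iloc[0])


class TestPearson:
    def test_perfect_linear(self):
        x = [1, 2, 3, 4]
        r, p = pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson([1, 2, 3], [6, 5, 4])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, _ = pearson(x, y)
            # direct product-moment formula
            xm, ym = x - x.mean(), y - y.mean()
            r_oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_hand_computed_example(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        r, p = pearson(x, y)
        assert r == pytest.approx(expected)
        assert 0 < p < 1
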