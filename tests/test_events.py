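import itertools

import numpy as np
import pytest

from numtscape.events import (DupParams, MergeParams, NumtRegion,
                              circular_gap, classify_duplicates,
                              classify_region, count_events,
                              extract_region_flanks, flank_similarity,
                              merge_collinear)
from numtscape.io_formats import GenomicInterval, NumtHit, SequenceRecord

L = 16_600


def _hit(hid, ns, ne, ms, me, chrom="chr1", strand="+", wrap=False):
    return NumtHit(hid, chrom, ns, ne, strand, ms, me, 100, 1e-9, 0.9,
                   mstart_folded=ms, mend_folded=me, wrap=wrap,
                   normalized=True)


class TestMergeCollinear:
    def test_within_thresholds_single_region(self):
        hits = [_hit("a", 0, 1000, 0, 1000),
                _hit("b", 11_000, 12_000, 2000, 3000)]
        regions = merge_collinear(hits, MergeParams(), L)
        assert len(regions) == 1
        assert regions[0].region_class == "single_insertion"
        assert regions[0].junctions[0].nuclear_gap == 10_000
        assert "nuclear_deletion" in regions[0].junctions[0].annotations
        assert "nuclear_insertion" in regions[0].junctions[0].annotations

    def test_large_nuclear_gap_splits(self):
        hits = [_hit("a", 0, 1000, 0, 1000),
                _hit("b", 36_000, 37_000, 1000, 2000)]
        regions = merge_collinear(hits, MergeParams(), L)
        assert [r.region_class for r in regions] == ["singleton", "singleton"]

    def test_transitive_chaining_of_three(self):
        hits = [_hit("a", 0, 1000, 0, 1000),
                _hit("b", 5000, 6000, 1100, 2100),
                _hit("c", 10_000, 11_000, 2200, 3200)]
        # oracle: every adjacent pairing satisfies both gap criteria,
        # so all 2^2 junction outcomes chain into one region
        for a, b in zip(hits, hits[1:]):
            assert b.nstart - a.nend <= 30_000
            assert circular_gap(a, b, L) <= 2_500
        regions = merge_collinear(hits, MergeParams(), L)
        assert len(regions) == 1
        assert regions[0].n_members == 3

    def test_unsorted_input_rejected(self):
        hits = [_hit("a", 5000, 6000, 0, 1000), _hit("b", 0, 1000, 0, 1000)]
        with pytest.raises(ValueError, match="sorted"):
            merge_collinear(hits, MergeParams(), L)

    def test_partition_and_order_invariance(self, flagship):
        hits = sorted(flagship["hits"], key=lambda h: (h.chrom, h.nstart))
        regions = merge_collinear(hits, MergeParams(), flagship["mito"].L)
        member_ids = [h.hit_id for r in regions for h in r.members]
        assert sorted(member_ids) == sorted(h.hit_id for h in hits)
        assert len(member_ids) == len(set(member_ids))

    def test_wider_nuclear_gap_never_more_regions(self, flagship):
        hits = sorted(flagship["hits"], key=lambda h: (h.chrom, h.nstart))
        Lm = flagship["mito"].L
        narrow = merge_collinear(hits, MergeParams(max_nuclear_gap=5_000), Lm)
        wide = merge_collinear(hits, MergeParams(max_nuclear_gap=50_000), Lm)
        assert len(wide) <= len(narrow)


class TestClassifyRegion:
    def test_singleton(self):
        r = NumtRegion("r", "chr1", [_hit("a", 0, 100, 0, 100)])
        assert classify_region(r, MergeParams()) == "singleton"

    def test_large_mito_gap_is_complex(self):
        # smaller arc between [0,1000) and [5000,6000) is 4 kb > 2.5 kb
        hits = [_hit("a", 0, 1000, 0, 1000),
                _hit("b", 21_000, 22_000, 5_000, 6_000)]
        regions = merge_collinear(hits, MergeParams(), L)
        assert len(regions) == 1
        assert regions[0].junctions[0].mito_gap == 4_000
        assert regions[0].region_class == "complex"

    def test_small_mito_gaps_single_insertion(self):
        hits = [_hit("a", 0, 1000, 0, 1000),
                _hit("b", 2000, 3000, 1500, 2500)]
        regions = merge_collinear(hits, MergeParams(), L)
        assert regions[0].region_class == "single_insertion"


class TestCountEvents:
    def test_multi_plus_singletons_identity(self):
        multi = [NumtRegion(f"m{i}", "chr1",
                            [_hit("a", 0, 10, 0, 10), _hit("b", 20, 30, 10, 20)])
                 for i in range(69)]
        single = [NumtRegion(f"s{i}", "chr1", [_hit("a", 0, 10, 0, 10)])
                  for i in range(171)]
        n_events, n_multi, n_single = count_events(multi + single)
        assert (n_events, n_multi, n_single) == (240, 69, 171)

    def test_empty(self):
        assert count_events([]) == (0, 0, 0)


class TestExtractRegionFlanks:
    def test_both_flanks_concatenated(self):
        seq = "".join("ACGT"[i % 4] for i in range(5000))
        genome = {"chr1": seq}
        iv = GenomicInterval("chr1", 1000, 2000)
        out = extract_region_flanks(iv, genome, 200)
        assert out == seq[800:1000] + seq[2000:2200]
        assert len(out) == 400

    def test_upstream_truncated_at_chromosome_start(self):
        seq = "A" * 1000
        out = extract_region_flanks(GenomicInterval("chr1", 50, 500),
                                    {"chr1": seq}, 200)
        assert len(out) == 50 + 200

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError):
            extract_region_flanks(GenomicInterval("chr1", 10, 20),
                                  {"chr1": "A" * 100}, 0)

    def test_region_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_region_flanks(GenomicInterval("chr1", 50, 500),
                                  {"chr1": "A" * 100}, 10)


class TestClassifyDuplicates:
    def test_identical_flanks_flagged(self):
        rng = np.random.default_rng(0)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        core_a = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        core_b = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = flank + core_a + flank + "T" * 40_000 + flank + core_b + flank
        genome = {"chr1": seq}
        ra = NumtRegion("ra", "chr1", [_hit("a", 600, 900, 0, 300)])
        start_b = len(flank) * 3 + 300 + 40_000
        rb = NumtRegion("rb", "chr1",
                        [_hit("b", start_b, start_b + 300, 0, 300)])
        pairs, labels = classify_duplicates([ra, rb], genome)
        assert len(pairs) == 1
        sim, cov = pairs[0][2], pairs[0][3]
        assert sim == pytest.approx(1.0)
        assert cov == pytest.approx(1.0)
        assert labels == {"ra": "duplicated", "rb": "duplicated"}

    def test_unrelated_flanks_not_flagged(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        ra = NumtRegion("ra", "chr1", [_hit("a", 1000, 1500, 0, 500)])
        rb = NumtRegion("rb", "chr1", [_hit("b", 40_000, 40_500, 0, 500)])
        pairs, labels = classify_duplicates([ra, rb], {"chr1": seq})
        assert pairs == []
        assert labels == {"ra": "unique", "rb": "unique"}

    def test_similarity_is_symmetric(self):
        rng = np.random.default_rng(2)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        b = a[:100] + "ACGT" * 5 + a[120:]
        sim_ab, cov_ab = flank_similarity(a, b)
        sim_ba, cov_ba = flank_similarity(b, a)
        assert sim_ab == pytest.approx(sim_ba, abs=0.02)
        assert cov_ab == pytest.approx(cov_ba, abs=0.02)
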