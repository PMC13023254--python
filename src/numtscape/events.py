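"""Reconstruction of insertion events from collinear calls, and
duplication-source classification from flanking sequence.

Neighboring calls on one chromosome whose nuclear gap is at most 30 kb are
chained into one NUMT region, interpreted as a single historical insertion
subsequently broken up by nuclear insertions/deletions; junctions whose
mitochondrial gap stays within 2.5 kb keep the region a plain
single-insertion event, while a larger mitochondrial gap marks the region
complex (rearranged or multiply inserted).  Regions whose 200 bp
concatenated flanks align with similarity and coverage above 0.8 are
classified as post-insertion duplications of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .io_formats import GenomicInterval, NumtHit, SequenceRecord


@dataclass
class MergeParams:
    max_nuclear_gap: int = 30_000
    max_mito_gap: int = 2_500
    complex_mito_span: int = 2_500

    def __post_init__(self) -> None:
        if self.max_nuclear_gap <= 0 or self.max_mito_gap <= 0:
            raise ValueError("gap thresholds must be positive")


@dataclass
class DupParams:
    flank: int = 200
    min_similarity: float = 0.8
    min_coverage: float = 0.8
    kmer_prefilter_k: int = 8
    kmer_prefilter_min: float = 0.2

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        for thr in (self.min_similarity, self.min_coverage):
            if not 0.0 < thr <= 1.0:
                raise ValueError("thresholds must lie in (0,1]")


@dataclass
class Junction:
    nuclear_gap: int
    mito_gap: int
    annotations: tuple[str, ...]   # subset of {nuclear_deletion, nuclear_insertion}


@dataclass
class NumtRegion:
    region_id: str
    chrom: str
    members: list[NumtHit]
    junctions: list[Junction] = field(default_factory=list)
    region_class: str = "singleton"
    mixed_orientation: bool = False

    @property
    def nstart(self) -> int:
        return min(h.nstart for h in self.members)

    @property
    def nend(self) -> int:
        return max(h.nend for h in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)


def circular_gap(a: NumtHit, b: NumtHit, L: int) -> int:
    """Minimal circular gap (smaller arc) between two folded mito
    intervals; 0 when they overlap on the circle."""
    def segments(h: NumtHit) -> list[tuple[int, int]]:
        if h.wrap:
            return [(h.mstart_folded, L), (0, h.mend_folded)]
        return [(h.mstart_folded, h.mend_folded)]

    best = L
    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            if s1 < e2 and s2 < e1:
                return 0
            g = min((s2 - e1) % L, (s1 - e2) % L)
            best = min(best, g)
    return best


def merge_collinear(hits: list[NumtHit], params: MergeParams,
                    L: int) -> list[NumtRegion]:
    """Chain consecutive same-chromosome hits whose nuclear gap is within
    ``max_nuclear_gap``; junction mito gaps annotate the presumed nuclear
    mutation and drive the region class.

    Input must be sorted by (chrom, nstart); chaining is transitive over
    sorted neighbors.
    """
    for a, b in zip(hits, hits[1:]):
        if (a.chrom, a.nstart) > (b.chrom, b.nstart):
            raise ValueError("hits must be sorted by (chrom, nstart)")
    regions: list[NumtRegion] = []
    current: list[NumtHit] = []
    junctions: list[Junction] = []

    def _flush() -> None:
        if not current:
            return
        region = NumtRegion(
            region_id=f"region{len(regions) + 1:04d}",
            chrom=current[0].chrom,
            members=list(current),
            junctions=list(junctions),
            mixed_orientation=len({h.strand for h in current}) > 1,
        )
        region.region_class = classify_region(region, params)
        regions.append(region)

    for h in hits:
        if not current:
            current, junctions = [h], []
            continue
        prev = current[-1]
        nuclear_gap = h.nstart - prev.nend
        if h.chrom == prev.chrom and nuclear_gap <= params.max_nuclear_gap:
            mito_gap = circular_gap(prev, h, L)
            ann = []
            if mito_gap <= params.max_mito_gap:
                ann.append("nuclear_deletion")
                if nuclear_gap > mito_gap:
                    ann.append("nuclear_insertion")
            junctions.append(Junction(nuclear_gap=max(0, nuclear_gap),
                                      mito_gap=mito_gap,
                                      annotations=tuple(ann)))
            current.append(h)
        else:
            _flush()
            current, junctions = [h], []
    _flush()
    return regions


def classify_region(region: NumtRegion, params: MergeParams) -> str:
    """singleton (1 member), complex (any junction mito gap above
    ``complex_mito_span``), else single_insertion."""
    if region.n_members == 1:
        return "singleton"
    if any(j.mito_gap > params.complex_mito_span for j in region.junctions):
        return "complex"
    return "single_insertion"


def count_events(regions: list[NumtRegion]) -> tuple[int, int, int]:
    """(n_insertion_events, n_multi_member_regions, n_singletons); each
    region is one inferred insertion event, so the first equals the sum of
    the other two."""
    n_multi = sum(1 for r in regions if r.n_members >= 2)
    n_single = sum(1 for r in regions if r.n_members == 1)
    n_events = n_multi + n_single
    assert n_events == len(regions)
    return n_events, n_multi, n_single


def extract_region_flanks(region: NumtRegion | GenomicInterval,
                          genome: dict[str, str] | list[SequenceRecord],
                          flank: int = 200) -> str:
    """Concatenate up to ``flank`` bp upstream and downstream of the region
    span (5'->3' on the forward strand, truncated at chromosome ends)."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(genome, list):
        genome = {r.id: r.sequence for r in genome}
    if isinstance(region, GenomicInterval):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region.chrom, region.nstart, region.nend
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise ValueError(f"region outside genome: {chrom}:[{start},{end})")
    up = seq[max(0, start - flank):start]
    down = seq[end:min(len(seq), end + flank)]
    return up + down


_flank_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1,
    open_gap_score=-8, extend_gap_score=-1,
)
# terminal gaps are free: coverage, not completeness, is assessed separately
_flank_aligner.open_end_insertion_score = 0
_flank_aligner.extend_end_insertion_score = 0
_flank_aligner.open_end_deletion_score = 0
_flank_aligner.extend_end_deletion_score = 0


def flank_similarity(a: str, b: str) -> tuple[float, float]:
    """(similarity, coverage) of two concatenated flank sequences.

    A global alignment with free terminal gaps is computed; similarity is
    matching columns over the alignment columns between the first and last
    aligned pair (internal gap columns count as non-matching), coverage is
    the aligned span of the shorter sequence over its length.
    """
    if not a or not b:
        return 0.0, 0.0
    aln = _flank_aligner.align(a.upper(), b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_len = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        aligned_len += e1 - s1
        matches += sum(1 for x, y in zip(a.upper()[s1:e1], b.upper()[s2:e2])
                       if x == y)
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    cols = span_a + span_b - aligned_len
    similarity = matches / cols if cols else 0.0
    shorter_span = span_a if len(a) <= len(b) else span_b
    coverage = shorter_span / min(len(a), len(b))
    return similarity, coverage


def _kmer_set(s: str, k: int) -> set[str]:
    s = s.upper()
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def classify_duplicates(regions: list[NumtRegion],
                        genome: dict[str, str] | list[SequenceRecord],
                        params: DupParams | None = None,
                        ) -> tuple[list[tuple[str, str, float, float]],
                                   dict[str, str]]:
    """All-pairs flank comparison; a pair is flagged duplicated when both
    similarity and coverage strictly exceed their thresholds.

    Returns the flagged pairs ``(id_a, id_b, similarity, coverage)`` and a
    per-region label in {duplicated, unique}.  A cheap shared-k-mer
    prefilter skips clearly unrelated pairs.
    """
    params = params or DupParams()
    if isinstance(genome, list):
        genome = {r.id: r.sequence for r in genome}
    flanks = {
        r.region_id: extract_region_flanks(r, genome, params.flank)
        for r in regions
    }
    kmers = {rid: _kmer_set(s, params.kmer_prefilter_k)
             for rid, s in flanks.items()}
    pairs: list[tuple[str, str, float, float]] = []
    labels = {r.region_id: "unique" for r in regions}
    ids = [r.region_id for r in regions]
    for i, ra in enumerate(ids):
        for rb in ids[i + 1:]:
            ka, kb = kmers[ra], kmers[rb]
            if not ka or not kb:
                continue
            shared = len(ka & kb) / min(len(ka), len(kb))
            if shared < params.kmer_prefilter_min:
                continue
            sim, cov = flank_similarity(flanks[ra], flanks[rb])
            if sim > params.min_similarity and cov > params.min_coverage:
                pairs.append((ra, rb, sim, cov))
                labels[ra] = labels[rb] = "duplicated"
    return pairs, labels
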