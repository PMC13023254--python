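"""Distribution statistics: mitochondrial hotspot windows, per-gene
coverage, nuclear flank environment, and chromosome-length correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circular import CircularMito
from .io_formats import GenomicInterval, NumtHit, SequenceRecord


@dataclass
class WindowCoverage:
    """Per-window hit counts over the circular mitochondrial genome."""

    window_size: int
    counts: np.ndarray
    hotspot_threshold: int

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(self.counts.mean()) if len(self.counts) else 0.0

    @property
    def hotspot_windows(self) -> list[int]:
        return np.nonzero(self.counts > self.hotspot_threshold)[0].tolist()

    @property
    def zscores(self) -> np.ndarray:
        sd = self.counts.std()
        if sd == 0:
            return np.zeros_like(self.counts, dtype=float)
        return (self.counts - self.counts.mean()) / sd


def _hit_segments(h: NumtHit, L: int) -> list[tuple[int, int]]:
    """Folded mito interval of a hit as linear segments on [0, L)."""
    if not h.normalized or h.mstart_folded < 0:
        raise ValueError("hits must be strand-normalized and folded")
    if h.wrap:
        return [(h.mstart_folded, L), (0, h.mend_folded)]
    return [(h.mstart_folded, h.mend_folded)]


def window_counts(hits: list[NumtHit], mito: CircularMito,
                  window_size: int = 100,
                  hotspot_threshold: int = 50) -> WindowCoverage:
    """Each hit increments every window it overlaps by >= 1 bp
    (circular-aware)."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    L = mito.L
    n_win = -(-L // window_size)
    counts = np.zeros(n_win, dtype=np.int64)
    for h in hits:
        touched: set[int] = set()
        for s, e in _hit_segments(h, L):
            touched.update(range(s // window_size, (e - 1) // window_size + 1))
        for w in touched:
            counts[w] += 1
    return WindowCoverage(window_size=window_size, counts=counts,
                          hotspot_threshold=hotspot_threshold)


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _union_len(ivs: list[tuple[int, int]]) -> int:
    return sum(b - a for a, b in _union_intervals(ivs))


def gene_coverage(hits: list[NumtHit], mito: CircularMito) -> pd.DataFrame:
    """Per-gene fraction covered by the merged union of hit intervals, plus
    the raw (unmerged) count of hits overlapping each gene."""
    L = mito.L
    segs = [seg for h in hits for seg in _hit_segments(h, L)]
    merged = _union_intervals(segs)
    rows = []
    for gene in mito.genes:
        if gene.start < gene.end:
            gsegs = [(gene.start, gene.end)]
        else:  # wrapped gene
            gsegs = [(gene.start, L), (0, gene.end)]
        glen = sum(b - a for a, b in gsegs)
        covered = 0
        for ga, gb in gsegs:
            for a, b in merged:
                covered += max(0, min(b, gb) - max(a, ga))
        n_overlap = 0
        for h in hits:
            if any(min(b, gb) > max(a, ga)
                   for a, b in _hit_segments(h, L) for ga, gb in gsegs):
                n_overlap += 1
        rows.append({
            "gene": gene.label, "length": glen,
            "covered_fraction": covered / glen, "hit_count": n_overlap,
        })
    return pd.DataFrame(rows)


def annotation_overlap_fraction(intervals_a: list[GenomicInterval],
                                intervals_b: list[GenomicInterval],
                                ) -> tuple[float, float]:
    """(interval-level, base-level) overlap of set a with set b.

    Interval-level: fraction of a-intervals touching (>= 1 bp) any
    b-interval.  Base-level: |union(a) intersect union(b)| / |union(a)|.
    Not symmetric in general.
    """
    if not intervals_a:
        return 0.0, 0.0
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals_b:
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end))
    n_touch = 0
    for iv in intervals_a:
        if any(iv.start < e and s < iv.end
               for s, e in by_chrom_b.get(iv.chrom, [])):
            n_touch += 1
    # base-level on per-chromosome unions
    by_chrom_a: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals_a:
        by_chrom_a.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total_a = 0
    inter = 0
    for chrom, a_ivs in by_chrom_a.items():
        ua = _union_intervals(a_ivs)
        ub = _union_intervals(by_chrom_b.get(chrom, []))
        total_a += sum(b - a for a, b in ua)
        for a1, b1 in ua:
            for a2, b2 in ub:
                inter += max(0, min(b1, b2) - max(a1, a2))
    return n_touch / len(intervals_a), inter / total_a if total_a else 0.0


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N and other characters excluded from the
    denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    return gc / (gc + at) if gc + at else 0.0


@dataclass
class FlankEnvironment:
    per_call: pd.DataFrame
    mean_upstream_gc: float
    mean_downstream_gc: float
    genome_gc: float
    repeat_class_counts: dict[str, int]
    flank_repeat_base_fraction: float
    genome_repeat_base_fraction: float


def flank_environment(calls: list[NumtHit],
                      genome: list[SequenceRecord],
                      repeat_annotation: list[GenomicInterval] | None = None,
                      flank_size: int = 1000) -> FlankEnvironment:
    """GC content and repeat-element environment of the nuclear flanks.

    Per call: GC of up to ``flank_size`` bp upstream and downstream
    (truncated and flagged at chromosome ends) and per-class counts of
    annotated repeat elements overlapping either flank.  Genome-wide GC and
    repeat base fraction are reported as baselines.
    """
    seqs = {r.id: r.sequence for r in genome}
    ann_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in (repeat_annotation or []):
        ann_by_chrom.setdefault(iv.chrom, []).append(iv)
    rows = []
    class_counts: dict[str, int] = {}
    flank_bases = 0
    flank_repeat_bases = 0
    for h in calls:
        seq = seqs[h.chrom]
        up_a, up_b = max(0, h.nstart - flank_size), h.nstart
        dn_a, dn_b = h.nend, min(len(seq), h.nend + flank_size)
        truncated = (up_b - up_a < flank_size) or (dn_b - dn_a < flank_size)
        up, down = seq[up_a:up_b], seq[dn_a:dn_b]
        counts_here: dict[str, int] = {}
        for fa, fb in ((up_a, up_b), (dn_a, dn_b)):
            flank_bases += fb - fa
            for iv in ann_by_chrom.get(h.chrom, []):
                ov = min(iv.end, fb) - max(iv.start, fa)
                if ov > 0:
                    label = iv.label or "None"
                    counts_here[label] = counts_here.get(label, 0) + 1
                    flank_repeat_bases += ov
        for label, c in counts_here.items():
            class_counts[label] = class_counts.get(label, 0) + c
        rows.append({
            "hit_id": h.hit_id, "chrom": h.chrom,
            "upstream_gc": gc_content(up), "downstream_gc": gc_content(down),
            "repeat_count": sum(counts_here.values()),
            "truncated": truncated,
        })
    per_call = pd.DataFrame(rows)
    genome_seq_gc = gc_content("".join(seqs.values())) if seqs else 0.0
    genome_len = sum(len(s) for s in seqs.values())
    ann_union = 0
    for chrom, ivs in ann_by_chrom.items():
        ann_union += _union_len([(iv.start, iv.end) for iv in ivs])
    return FlankEnvironment(
        per_call=per_call,
        mean_upstream_gc=(float(per_call.upstream_gc.mean())
                          if len(per_call) else 0.0),
        mean_downstream_gc=(float(per_call.downstream_gc.mean())
                            if len(per_call) else 0.0),
        genome_gc=genome_seq_gc,
        repeat_class_counts=dict(sorted(class_counts.items())),
        flank_repeat_base_fraction=(flank_repeat_bases / flank_bases
                                    if flank_bases else 0.0),
        genome_repeat_base_fraction=(ann_union / genome_len
                                     if genome_len else 0.0),
    )


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p-value (t transform,
    n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationReport:
    n_chromosomes: int
    r_length_vs_total_numt_length: float
    p_length_vs_total_numt_length: float
    r_length_vs_numt_count: float
    p_length_vs_numt_count: float


def correlate_with_chromosome_length(per_chromosome: pd.DataFrame,
                                     chrom_lengths: dict[str, int],
                                     ) -> CorrelationReport:
    """Pearson correlations of chromosome length against total NUMT length
    and NUMT count per chromosome.

    Chromosome length normalized by genome length is a pure rescaling of x
    and leaves r unchanged, so only the raw-length correlations are
    reported.
    """
    df = per_chromosome.copy()
    df["chrom_length"] = df["chrom"].map(chrom_lengths)
    r1, p1 = pearson(df["chrom_length"], df["length"])
    r2, p2 = pearson(df["chrom_length"], df["count"])
    return CorrelationReport(
        n_chromosomes=len(df),
        r_length_vs_total_numt_length=r1,
        p_length_vs_total_numt_length=p1,
        r_length_vs_numt_count=r2,
        p_length_vs_numt_count=p2,
    )
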