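"""From raw alignment hits to the final NUMT call set and its summary.

Filtering follows the headline quality rule (score strictly above the
threshold, E-value at or below the cutoff), strand normalization maps
minus-strand mito coordinates onto the forward mitochondrial axis, and the
summary reproduces the standard descriptive statistics: per-chromosome
counts and lengths, genome fraction, the fixed length histogram, and
adjacent-call distances with overlaps logged separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import NumtHit

# fixed length-histogram bins (bp); the first bin starts at the shortest
# reportable call
LENGTH_BINS = [(39, 99), (100, 249), (250, 499), (500, 749), (750, 999),
               (1000, 1999), (2000, 4999), (5000, None)]


def filter_hits(hits: list[NumtHit], min_score: int = 61,
                max_evalue: float = 1e-4) -> list[NumtHit]:
    """Keep hits with ``evalue <= max_evalue`` and ``score > min_score``
    (strictly above, matching a "score > 61" style rule)."""
    return [h for h in hits if h.evalue <= max_evalue and h.score > min_score]


def normalize_strand(hit: NumtHit, query_len: int) -> NumtHit:
    """Convert a minus-strand hit's mito interval from the
    reverse-complemented query axis to forward orientation.  Idempotent;
    the ``strand`` field preserves the original orientation."""
    if hit.strand == "-" and not hit.normalized:
        hit.mstart, hit.mend = query_len - hit.mend, query_len - hit.mstart
        hit.normalized = True
    elif hit.strand == "+":
        hit.normalized = True
    return hit


def merge_mito_overlaps(hits: list[NumtHit],
                        L: int) -> list[tuple[int, int, bool]]:
    """Union of folded mito intervals, circular-aware.

    Returns disjoint ``(start, end, wrap)`` triples sorted by start; a
    wrapped triple has ``start >= end`` and covers ``[start, L) + [0, end)``.
    """
    segments: list[tuple[int, int]] = []
    for h in hits:
        if not h.normalized:
            raise ValueError("merge_mito_overlaps requires normalized hits")
        s, e, wrap = h.mstart_folded, h.mend_folded, h.wrap
        if s < 0:
            raise ValueError("hit lacks folded mito coordinates")
        if wrap:
            segments.extend([(s, L), (0, e)])
        else:
            segments.append((s, e))
    if not segments:
        return []
    segments.sort()
    merged = [list(segments[0])]
    for a, b in segments[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # re-wrap across the origin
    if (len(merged) > 1 and merged[0][0] == 0 and merged[-1][1] == L):
        first = merged.pop(0)
        merged[-1][1] = first[1]
        out = [(a, b, a >= b) for a, b in merged]
    else:
        out = [(a, b, False) for a, b in merged]
    return out


@dataclass
class CallSummary:
    n_hits: int
    total_length: int
    genome_length: int
    per_chromosome: pd.DataFrame
    length_histogram: dict[str, int]
    adjacent_distances: dict[str, list[int]]
    overlap_lengths: list[int]

    @property
    def genome_fraction(self) -> float:
        return self.total_length / self.genome_length

    @property
    def genome_fraction_pct(self) -> str:
        """Genome fraction as a percentage, 3 significant figures."""
        return f"{self.genome_fraction * 100:.3g}%"

    @property
    def max_overlap(self) -> int:
        return max(self.overlap_lengths, default=0)


def _bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo}"


def summarize_calls(hits: list[NumtHit], genome_length: int) -> CallSummary:
    """Descriptive statistics of a filtered call set."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    lengths = [h.nuclear_length for h in hits]
    histogram = {_bin_label(lo, hi): 0 for lo, hi in LENGTH_BINS}
    for ln in lengths:
        for lo, hi in LENGTH_BINS:
            if hi is None or ln <= hi:
                histogram[_bin_label(lo, hi)] += 1
                break
    rows = []
    distances: dict[str, list[int]] = {}
    overlaps: list[int] = []
    by_chrom: dict[str, list[NumtHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    for chrom, hs in sorted(by_chrom.items()):
        hs.sort(key=lambda x: (x.nstart, x.nend))
        rows.append({
            "chrom": chrom,
            "count": len(hs),
            "length": sum(x.nuclear_length for x in hs),
        })
        dlist = []
        for a, b in zip(hs, hs[1:]):
            gap = b.nstart - a.nend
            if gap < 0:
                overlaps.append(-gap)
                gap = 0
            dlist.append(gap)
        distances[chrom] = dlist
    per_chrom = pd.DataFrame(rows, columns=["chrom", "count", "length"])
    return CallSummary(
        n_hits=len(hits),
        total_length=sum(lengths),
        genome_length=genome_length,
        per_chromosome=per_chrom,
        length_histogram=histogram,
        adjacent_distances=distances,
        overlap_lengths=overlaps,
    )
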