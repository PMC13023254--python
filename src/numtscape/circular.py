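"""Circular mitochondrial coordinate handling.

A circular genome broken at an arbitrary origin under-represents homology
spanning the break.  The standard remedy is to search a doubled copy
(sequence + sequence, length 2L) so every origin-spanning locus appears
contiguously, then fold alignment coordinates back onto [0, L) and collapse
the duplicate hits the doubling creates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GenomicInterval, NumtHit, SequenceRecord


@dataclass
class CircularMito:
    """Circular mitochondrial reference with gene-like annotation.

    Gene intervals live on [0, L); a wrapped interval (start >= end) denotes
    one crossing the origin, as the D-loop often does on real mitogenomes.
    """

    sequence: str
    genes: list[GenomicInterval] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("circular sequence must be non-empty")


def double_sequence(mito: CircularMito | SequenceRecord,
                    already_doubled: bool = False) -> SequenceRecord:
    """Concatenate the circular unit with itself (length 2L)."""
    if already_doubled:
        raise ValueError("input flagged as already doubled; refusing to redouble")
    if isinstance(mito, CircularMito):
        seq, name = mito.sequence, "mito"
    else:
        seq, name = mito.sequence, mito.id
    return SequenceRecord(id=f"{name}|doubled", sequence=seq + seq)


def fold_interval(start: int, end: int, L: int) -> tuple[int, int, bool]:
    """Fold a doubled-axis interval [start, end) onto the circle [0, L).

    Returns ``(start', end', wrap)`` with ``start' = start mod L`` and
    ``end' = ((end - 1) mod L) + 1``; ``wrap`` is set when the folded
    interval crosses the origin (then start' >= end').
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if not (0 <= start < end <= 2 * L):
        raise ValueError(f"interval [{start},{end}) outside [0,{2*L}]")
    if end - start > L:
        raise ValueError(
            f"interval length {end - start} exceeds one circular turn ({L})"
        )
    s = start % L
    e = ((end - 1) % L) + 1
    wrap = s >= e
    return s, e, wrap


def circular_length(start: int, end: int, wrap: bool, L: int) -> int:
    """Length of a folded circular interval."""
    if not wrap:
        return end - start
    return (L - start) + end


def fold_hit(hit: NumtHit, L: int) -> NumtHit:
    """Populate the folded mito coordinates of a (normalized) hit."""
    s, e, wrap = fold_interval(hit.mstart, hit.mend, L)
    hit.mstart_folded, hit.mend_folded, hit.wrap = s, e, wrap
    return hit


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _circular_unrolled(s: int, e: int, wrap: bool, L: int) -> tuple[int, int]:
    """Represent a folded interval as a linear interval on [0, 2L)."""
    return (s, e + L) if wrap else (s, e)


def _circular_segments(s: int, e: int, wrap: bool, L: int,
                       ) -> list[tuple[int, int]]:
    if wrap:
        return [(s, L), (0, e)]
    return [(s, e)]


def _circular_coverage(inner: tuple[int, int, bool],
                       outer: tuple[int, int, bool], L: int) -> float:
    """Fraction of the inner folded interval covered by the outer one."""
    inner_segs = _circular_segments(*inner, L)
    outer_segs = _circular_segments(*outer, L)
    total = sum(b - a for a, b in inner_segs)
    if total == 0:
        return 0.0
    cov = 0
    for a1, b1 in inner_segs:
        for a2, b2 in outer_segs:
            cov += max(0, min(b1, b2) - max(a1, a2))
    return cov / total


def dedup_doubled_hits(hits: list[NumtHit], L: int,
                       min_containment: float = 0.95) -> list[NumtHit]:
    """Collapse the duplicate and partial hits the doubled query produces.

    Each genuine locus appears twice on the doubled axis (and, for
    origin-spanning loci, additionally as truncated partial copies at the
    ends of the doubled query).  A hit is dropped when a higher-scoring hit
    on the same chromosome and strand covers at least ``min_containment``
    of it on both the nuclear and the folded circular mito coordinates;
    exact duplicates and trimming-level near-duplicates are special cases.
    """
    folded = [fold_hit(h, L) for h in hits]
    kept: list[NumtHit] = []
    for h in sorted(folded, key=lambda x: -x.score):
        h_n = (h.nstart, h.nend)
        h_m = (h.mstart_folded, h.mend_folded, h.wrap)
        dup = False
        for k in kept:
            if k.chrom != h.chrom or k.strand != h.strand:
                continue
            ov = min(k.nend, h.nend) - max(k.nstart, h.nstart)
            n_cov = ov / (h.nend - h.nstart) if ov > 0 else 0.0
            if n_cov < min_containment:
                continue
            m_cov = _circular_coverage(
                h_m, (k.mstart_folded, k.mend_folded, k.wrap), L)
            if m_cov >= min_containment:
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda x: (x.chrom, x.nstart))
    return kept
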