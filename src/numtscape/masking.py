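"""Low-complexity soft-masking and imported repeat-annotation masking.

Simple repeats inflate apparent homology, so the nuclear genome is masked
before the search.  A DUST-style triplet-entropy score flags low-complexity
windows (built in, self-contained), and externally produced repeat
annotations (e.g. RepeatMasker output) can be applied on top.  Default
semantics are soft (lowercase): masked bases cannot seed alignments but can
be spanned by extensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomicInterval, SequenceRecord
from .aligner import encode


@dataclass
class MaskParams:
    window: int = 64
    dust_threshold: float = 2.0
    merge_gap: int = 5

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.dust_threshold < 0:
            raise ValueError("threshold must be >= 0")


def _merge_intervals(ivs: list[tuple[int, int]],
                     gap: int) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def dust_score(codes: np.ndarray, w: int) -> float:
    """DUST window score: sum_t c_t (c_t - 1) / 2 over triplet counts,
    normalized by (window - 3)."""
    n = len(codes)
    if n < 3:
        return 0.0
    tri = codes[:-2].astype(np.int64) * 16 + codes[1:-1] * 4 + codes[2:]
    tri = tri[np.all(
        np.stack([codes[:-2] < 4, codes[1:-1] < 4, codes[2:] < 4]), axis=0)]
    if len(tri) == 0:
        return 0.0
    counts = np.bincount(tri, minlength=64)
    return float((counts * (counts - 1) // 2).sum()) / max(1, w - 3)


def dust_mask(record: SequenceRecord, params: MaskParams | None = None,
              ) -> tuple[SequenceRecord, list[GenomicInterval]]:
    """Soft-mask low-complexity windows; returns the masked record and the
    merged masked intervals.  Idempotent (case does not affect the score)."""
    params = params or MaskParams()
    codes, _ = encode(record.sequence)
    n = len(codes)
    w = params.window
    step = max(1, w // 2)
    flagged: list[tuple[int, int]] = []
    for start in range(0, max(1, n - 2), step):
        end = min(n, start + w)
        if dust_score(codes[start:end], w) > params.dust_threshold:
            flagged.append((start, end))
        if end == n:
            break
    merged = _merge_intervals(flagged, params.merge_gap)
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy()
    upper = (seq >= ord("A")) & (seq <= ord("Z"))
    for a, b in merged:
        sel = slice(a, b)
        seq[sel] = np.where(upper[sel], seq[sel] + 32, seq[sel])
    masked = SequenceRecord(record.id, seq.tobytes().decode("ascii"))
    return masked, [GenomicInterval(record.id, a, b) for a, b in merged]


def apply_annotation_mask(record: SequenceRecord,
                          intervals: list[GenomicInterval],
                          mode: str = "soft") -> SequenceRecord:
    """Mask annotated intervals: soft = lowercase, hard = N."""
    if mode not in ("soft", "hard"):
        raise ValueError(f"mask mode must be 'soft' or 'hard', got {mode!r}")
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy()
    for iv in intervals:
        if iv.end > len(seq):
            raise ValueError(
                f"annotation {iv.chrom}:[{iv.start},{iv.end}) out of bounds "
                f"for sequence of length {len(seq)}")
        sel = slice(iv.start, iv.end)
        if mode == "soft":
            upper = (seq[sel] >= ord("A")) & (seq[sel] <= ord("Z"))
            seq[sel] = np.where(upper, seq[sel] + 32, seq[sel])
        else:
            seq[sel] = ord("N")
    return SequenceRecord(record.id, seq.tobytes().decode("ascii"))
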