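"""Plurality consensus calling from a multiple alignment of mitogenomes.

Per column the most frequent non-gap base is emitted when its frequency
among non-gap characters reaches the plurality threshold; ties yield the
tie character (N, since the downstream aligner treats any non-ACGT base as
unseedable), and gap-majority columns are dropped by default.  IUPAC
ambiguity codes are deliberately not emitted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN-")


@dataclass
class MultipleAlignment:
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {r.length for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        bad = set("".join(r.sequence.upper() for r in self.records)) - _ALPHABET
        if bad:
            raise ValueError(f"alignment alphabet outside ACGTN-: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return self.records[0].length


@dataclass
class ConsensusParams:
    plurality: float = 0.5
    tie_char: str = "N"
    gap_majority_drops_column: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.plurality <= 1.0:
            raise ValueError("plurality must lie in (0,1]")


def _warn_group_imbalance(records: list[SequenceRecord]) -> None:
    """The consensus is meant for a balanced panel (e.g. equal European and
    Asian pig dosage); warn when labeled groups are uneven."""
    groups = Counter()
    for r in records:
        if "|" in r.id:
            groups[r.id.split("|", 1)[0]] += 1
    if len(groups) > 1 and len(set(groups.values())) > 1:
        logger.warning("unbalanced groups in alignment headers: %s",
                       dict(groups))


def build_consensus(msa: MultipleAlignment,
                    params: ConsensusParams | None = None,
                    record_id: str = "consensus") -> SequenceRecord:
    """Call the plurality consensus of an aligned FASTA."""
    params = params or ConsensusParams()
    _warn_group_imbalance(msa.records)
    mat = np.array([list(r.sequence.upper()) for r in msa.records])
    n = msa.n_sequences
    out: list[str] = []
    for col in mat.T:
        gaps = int((col == "-").sum())
        if params.gap_majority_drops_column and gaps > n / 2:
            continue
        counts = Counter(c for c in col if c != "-")
        if not counts:
            continue
        non_gap = sum(counts.values())
        top = counts.most_common()
        best_count = top[0][1]
        tied = [b for b, c in top if c == best_count]
        if len(tied) > 1:
            out.append(params.tie_char)
        elif best_count / non_gap >= params.plurality:
            out.append(top[0][0])
        else:
            out.append(params.tie_char)
    return SequenceRecord(id=record_id, sequence="".join(out))
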