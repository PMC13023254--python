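"""Decoy-based false-positive assessment.

A completely inverted (character-reversed, NOT complemented) mitochondrial
sequence has no evolutionary route into the nuclear genome, while reverse-
complement homology is genuine biology; alignments of the inverted decoy
therefore estimate the false-positive rate of the search at the working
thresholds.  The decoy search runs on the doubled decoy with bit-identical
parameters to the real search, so both explore the same search space.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .aligner import EvalueModel, ScoringScheme, SearchParams, search
from .circular import CircularMito, double_sequence
from .io_formats import NumtHit, SequenceRecord


def invert_sequence(record: SequenceRecord) -> SequenceRecord:
    """Character-reverse a sequence without complementing it."""
    return SequenceRecord(id=record.id + "|inverted",
                          sequence=record.sequence[::-1])


def config_hash(scheme: ScoringScheme, params: SearchParams) -> str:
    payload = repr(scheme) + repr(params)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class DecoyReport:
    n_decoy_hits: int
    decoy_scores: list[int]
    n_real_hits: int
    config_hash: str
    decoy_hits: list[NumtHit] = field(default_factory=list)

    @property
    def empirical_fdr(self) -> float:
        total = self.n_decoy_hits + self.n_real_hits
        return self.n_decoy_hits / total if total else 0.0


def run_decoy(mito: CircularMito | SequenceRecord,
              genome: list[SequenceRecord],
              scheme: ScoringScheme, params: SearchParams,
              evalue_model: EvalueModel | None = None,
              n_real_hits: int = 0) -> DecoyReport:
    """Search the doubled inverted mitochondrial query against the genome
    with the same parameters as the real search."""
    if isinstance(mito, CircularMito):
        unit = SequenceRecord("mito", mito.sequence)
    else:
        unit = mito
    decoy_query = double_sequence(invert_sequence(unit))
    if not genome or all(r.length == 0 for r in genome):
        hits: list[NumtHit] = []
    else:
        hits = search(decoy_query, genome, scheme, params, evalue_model)
    return DecoyReport(
        n_decoy_hits=len(hits),
        decoy_scores=[h.score for h in hits],
        n_real_hits=n_real_hits,
        config_hash=config_hash(scheme, params),
        decoy_hits=hits,
    )
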