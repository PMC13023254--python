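"""Synthetic genomes with implanted mitochondrial fragments and ground truth.

The generator emulates the data the discovery pipeline assumes: a circular
mitochondrial reference with gene-like annotation, i.i.d.-uniform nuclear
background chromosomes, and implanted mtDNA fragments with controlled
substitution/indel divergence, optional internal fragmentation by a nuclear
insert, origin-spanning source intervals, and post-insertion duplications
that copy the insertion together with its nuclear flanks.

Every event is recorded as a :class:`SimTruth`: the mito source interval
(circular), the nuclear placements of the mito-derived material, and the
full inserted spans (which include internal inserts and copied flanks), so
that removing all inserted spans reconstructs the background exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aligner import reverse_complement
from .circular import CircularMito, fold_interval
from .io_formats import GenomicInterval, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Generator conditions.

    ``substitution_rate`` may be a single per-site rate or a ``(lo, hi)``
    range sampled uniformly per event.  ``min_spacing`` defaults to
    ``min(60 kb, genome_length / (2 * n_events))`` — twice the collinear
    merge threshold where the genome affords it — so implanted events stay
    unambiguous for recall/precision scoring.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 5
    mito_length: int = 16_600
    n_events: int = 30
    fragment_length_range: tuple[int, int] = (300, 3000)
    substitution_rate: float | tuple[float, float] = (0.05, 0.15)
    indel_rate: float = 0.005
    indel_length_geometric_p: float = 0.7
    frac_fragmented: float = 0.0
    internal_insert_range: tuple[int, int] = (200, 1000)
    frac_duplicated: float = 0.0
    dup_flank: int = 300
    frac_junction_spanning: float = 0.0
    frac_reverse: float = 0.5
    min_spacing: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_fragmented, self.frac_duplicated,
                     self.frac_junction_spanning, self.frac_reverse):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        for rng_pair in (self.fragment_length_range,
                         self.internal_insert_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError("ranges must be ordered (min, max)")

    def sub_rate(self, rng: np.random.Generator) -> float:
        if isinstance(self.substitution_rate, (tuple, list)):
            lo, hi = self.substitution_rate
            return float(rng.uniform(lo, hi))
        return float(self.substitution_rate)

    def spacing(self) -> int:
        if self.min_spacing is not None:
            return self.min_spacing
        return min(60_000, self.genome_length // max(1, 2 * self.n_events))


@dataclass
class SimTruth:
    """Ground truth for one implanted insertion event."""

    event_id: str
    mito_start: int          # folded circular coords on [0, L)
    mito_end: int
    wrap: bool
    orientation: str
    divergence: float
    event_class: str         # intact / fragmented / junction-spanning /
    #                          duplicated-parent / duplicated-copy
    placements: list[GenomicInterval] = field(default_factory=list)
    inserted_spans: list[GenomicInterval] = field(default_factory=list)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


# gene-like tiling loosely shaped on a mammalian mitogenome
_GENE_PLAN = [
    ("D-loop", 1100), ("tRNA-Phe", 70), ("12SrRNA", 960), ("tRNA-Val", 70),
    ("16SrRNA", 1570), ("tRNA-Leu", 75), ("ND1", 960), ("tRNA-Ile", 70),
    ("ND2", 1040), ("tRNA-Trp", 70), ("COX1", 1550), ("tRNA-Ser", 70),
    ("COX2", 690), ("tRNA-Lys", 70), ("ATP8", 200), ("ATP6", 680),
    ("COX3", 780), ("tRNA-Gly", 70), ("ND3", 350), ("ND4L", 300),
    ("ND4", 1380), ("tRNA-His", 70), ("ND5", 1820), ("ND6", 530),
    ("tRNA-Glu", 70), ("CYTB", 1140), ("tRNA-Thr", 70), ("tRNA-Pro", 70),
]


def simulate_mito(mito_length: int = 16_600, seed: int = 0) -> CircularMito:
    """Uniform-random circular mitochondrial sequence with a non-overlapping
    tiling of labeled gene-like intervals (includes a D-loop)."""
    if mito_length <= 0:
        raise ValueError("mito_length must be positive")
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, mito_length)
    # scale the gene plan down for short toy mitogenomes so the tiling
    # always yields a full complement of labeled intervals
    plan_span = sum(length for _, length in _GENE_PLAN)
    scale = min(1.0, mito_length * 0.95 / plan_span)
    genes: list[GenomicInterval] = []
    pos = 0
    spacer = max(1, int(5 * scale))
    for name, length in _GENE_PLAN:
        length = max(4, int(length * scale))
        if pos >= mito_length:
            break
        end = min(pos + length, mito_length)
        if end > pos:
            genes.append(GenomicInterval("mito", pos, end, label=name))
        pos = end + spacer
    if len(genes) < 10:
        raise ValueError("mito too short for a gene-like tiling (need >= 10)")
    return CircularMito(sequence=seq, genes=genes)


def mutate_fragment(fragment: str, substitution_rate: float,
                    indel_rate: float, rng: np.random.Generator,
                    indel_length_geometric_p: float = 0.7) -> str:
    """Diverge a fragment: forced-different substitutions plus geometric
    indels; expected identity to the source is ~ 1 - substitution_rate."""
    if not (0 <= substitution_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0,1)")
    if substitution_rate == 0 and indel_rate == 0:
        return fragment
    out: list[str] = []
    p = indel_length_geometric_p
    i = 0
    n = len(fragment)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(p))
            if rng.random() < 0.5:
                out.append(random_dna(rng, length))  # insertion, base kept below
            else:
                i += length  # deletion
                continue
        base = fragment[i]
        if substitution_rate > 0 and rng.random() < substitution_rate:
            choices = [b for b in "ACGT" if b != base.upper()]
            base = choices[int(rng.integers(0, 3))]
        out.append(base)
        i += 1
    return "".join(out)


def _place_positions(rng: np.random.Generator, chrom_lengths: dict[str, int],
                     n: int, spacing: int) -> list[tuple[str, int]]:
    """Random insertion points with a minimum per-chromosome spacing.

    Events are distributed over chromosomes up to each chromosome's
    capacity, then laid out with the sorted-uniform construction (uniform
    slack between consecutive points), which succeeds whenever the genome
    can host them at all.
    """
    chroms = list(chrom_lengths)
    capacity = {
        c: ((chrom_lengths[c] - 2 * spacing) // max(1, spacing) + 1
            if chrom_lengths[c] >= 2 * spacing else 0)
        for c in chroms
    }
    if sum(capacity.values()) < n:
        raise ValueError(
            "genome too small to host all events at the required spacing"
        )
    slots = [c for c in chroms for _ in range(capacity[c])]
    chosen = [slots[i] for i in rng.permutation(len(slots))[:n]]
    out: list[tuple[str, int]] = []
    for c in chroms:
        n_k = chosen.count(c)
        if n_k == 0:
            continue
        usable = chrom_lengths[c] - 2 * spacing
        extra = usable - (n_k - 1) * spacing
        offsets = np.sort(rng.uniform(0, extra, size=n_k))
        for i, off in enumerate(offsets):
            out.append((c, int(spacing + off + i * spacing)))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _place_avoiding(rng: np.random.Generator, chrom_lengths: dict[str, int],
                    n: int, spacing: int,
                    occupied: dict[str, list[tuple[int, int]]],
                    max_tries: int = 10_000) -> list[tuple[str, int]]:
    """Random insertion points at least ``spacing`` away from occupied
    spans and from one another (used for duplication target loci)."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    taken = {c: list(ivs) for c, ivs in occupied.items()}
    out: list[tuple[str, int]] = []
    # the required clearance halves when a spacing level proves infeasible
    # (small genomes), down to a 1 kb floor
    level_spacing = spacing
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            if level_spacing <= 1000:
                raise ValueError(
                    "genome too small to host duplication copies at the "
                    "required spacing")
            level_spacing = max(1000, level_spacing // 2)
            tries = 0
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        hi = chrom_lengths[c] - level_spacing
        if hi <= level_spacing:
            continue
        pos = int(rng.integers(level_spacing, hi))
        if all(pos < a - level_spacing or pos > b + level_spacing
               for a, b in taken.get(c, [])):
            taken.setdefault(c, []).append((pos, pos))
            out.append((c, pos))
    return out


def implant_events(genome: list[SequenceRecord], mito: CircularMito,
                   params: SimParams,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[SequenceRecord], list[SimTruth]]:
    """Insert diverged mito fragments into background chromosomes.

    Returns the mutated genome and one :class:`SimTruth` per event (two for
    duplicated events: parent and copy).
    """
    rng = rng or np.random.default_rng(params.seed)
    L = mito.L
    doubled = mito.sequence + mito.sequence
    chrom_lengths = {r.id: r.length for r in genome}
    n = params.n_events
    spacing = params.spacing()

    idx = np.arange(n)
    n_junction = int(round(params.frac_junction_spanning * n))
    n_frag = int(round(params.frac_fragmented * n))
    n_dup = int(round(params.frac_duplicated * n))
    perm = rng.permutation(idx)
    junction_set = set(perm[:n_junction].tolist())
    frag_set = set(rng.permutation(idx)[:n_frag].tolist())
    dup_set = set(rng.permutation(idx)[:n_dup].tolist())

    positions = _place_positions(rng, chrom_lengths, n, spacing)

    # per-chromosome pending insertions: (bg_pos, block_seq, event, rel_placements)
    pending: dict[str, list[tuple[int, str, SimTruth, list[tuple[int, int]]]]] = {
        r.id: [] for r in genome
    }
    truths: list[SimTruth] = []
    for e in range(n):
        flen = int(rng.integers(params.fragment_length_range[0],
                                params.fragment_length_range[1] + 1))
        flen = min(flen, L)
        if e in junction_set and flen >= 2:
            start = int(rng.integers(max(0, L - flen + 1), L))
        else:
            start = int(rng.integers(0, L - flen + 1))
        source = doubled[start:start + flen]
        sub = params.sub_rate(rng)
        mutated = mutate_fragment(source, sub, params.indel_rate, rng,
                                  params.indel_length_geometric_p)
        orientation = "-" if rng.random() < params.frac_reverse else "+"
        if orientation == "-":
            mutated = reverse_complement(mutated)
        ms, me, wrap = fold_interval(start, start + flen, L)
        if e in frag_set and len(mutated) >= 40:
            cut = int(rng.integers(len(mutated) // 4, 3 * len(mutated) // 4))
            ins_len = int(rng.integers(params.internal_insert_range[0],
                                       params.internal_insert_range[1] + 1))
            insert = random_dna(rng, ins_len)
            block = mutated[:cut] + insert + mutated[cut:]
            rel = [(0, cut), (cut + ins_len, len(block))]
            klass = "fragmented"
        else:
            block = mutated
            rel = [(0, len(block))]
            klass = ("junction-spanning" if e in junction_set and wrap
                     else "intact")
        if e in dup_set:
            klass = "duplicated-parent"
        truth = SimTruth(
            event_id=f"ev{e:03d}", mito_start=ms, mito_end=me, wrap=wrap,
            orientation=orientation, divergence=sub, event_class=klass,
        )
        chrom, pos = positions[e]
        pending[chrom].append((pos, block, truth, rel))
        truths.append(truth)

    # assemble pass 1
    assembled: dict[str, str] = {}
    for rec in genome:
        items = sorted(pending[rec.id], key=lambda x: x[0])
        parts = []
        cursor = 0
        offset = 0
        for pos, block, truth, rel in items:
            parts.append(rec.sequence[cursor:pos])
            block_start = pos + offset
            for a, b in rel:
                truth.placements.append(
                    GenomicInterval(rec.id, block_start + a, block_start + b))
            truth.inserted_spans.append(
                GenomicInterval(rec.id, block_start,
                                block_start + len(block)))
            parts.append(block)
            offset += len(block)
            cursor = pos
        parts.append(rec.sequence[cursor:])
        assembled[rec.id] = "".join(parts)

    # pass 2: duplications copy the NUMT block plus dup_flank bases of
    # flanking genome to a second locus, kept clear of existing events
    dup_parents = [t for t in truths if t.event_class == "duplicated-parent"]
    if dup_parents:
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembled}
        for t in truths:
            for s in t.inserted_spans:
                occupied[s.chrom].append((s.start, s.end))
        dup_positions = _place_avoiding(
            rng, {c: len(s) for c, s in assembled.items()},
            len(dup_parents), spacing, occupied)
        inserts2: dict[str, list[tuple[int, str, SimTruth, int]]] = {
            c: [] for c in assembled
        }
        for truth, (chrom2, pos2) in zip(dup_parents, dup_positions):
            span = truth.inserted_spans[0]
            src = assembled[span.chrom]
            a = max(0, span.start - params.dup_flank)
            b = min(len(src), span.end + params.dup_flank)
            block = src[a:b]
            copy = SimTruth(
                event_id=truth.event_id + "c", mito_start=truth.mito_start,
                mito_end=truth.mito_end, wrap=truth.wrap,
                orientation=truth.orientation, divergence=truth.divergence,
                event_class="duplicated-copy",
            )
            # relative offsets of the mito-derived parts inside the block
            rel_off = span.start - a
            copy._rel = [  # type: ignore[attr-defined]
                (rel_off + (p.start - span.start), rel_off + (p.end - span.start))
                for p in truth.placements
            ]
            inserts2[chrom2].append((pos2, block, copy, rel_off))
            truths.append(copy)
        # apply pass-2 insertions, then shift every pass-1 coordinate
        shifts: dict[str, list[tuple[int, int]]] = {c: [] for c in assembled}
        for chrom in assembled:
            items = sorted(inserts2[chrom], key=lambda x: x[0])
            parts = []
            cursor = 0
            offset = 0
            for pos, block, copy, rel_off in items:
                parts.append(assembled[chrom][cursor:pos])
                block_start = pos + offset
                for a, b in copy._rel:  # type: ignore[attr-defined]
                    copy.placements.append(
                        GenomicInterval(chrom, block_start + a, block_start + b))
                copy.inserted_spans.append(
                    GenomicInterval(chrom, block_start,
                                    block_start + len(block)))
                parts.append(block)
                shifts[chrom].append((pos, len(block)))
                offset += len(block)
                cursor = pos
            parts.append(assembled[chrom][cursor:])
            assembled[chrom] = "".join(parts)

        def _shift(iv: GenomicInterval) -> GenomicInterval:
            d = sum(l for p, l in shifts[iv.chrom] if p <= iv.start)
            return replace(iv, start=iv.start + d, end=iv.end + d)

        for t in truths:
            if t.event_class != "duplicated-copy":
                t.placements = [_shift(p) for p in t.placements]
                t.inserted_spans = [_shift(s) for s in t.inserted_spans]

    out_genome = [SequenceRecord(r.id, assembled[r.id]) for r in genome]
    return out_genome, truths


def simulate_background(params: SimParams,
                        rng: np.random.Generator | None = None,
                        ) -> list[SequenceRecord]:
    """I.i.d.-uniform A/C/G/T chromosomes of near-equal length."""
    rng = rng or np.random.default_rng(params.seed)
    per = params.genome_length // params.n_chromosomes
    return [
        SequenceRecord(f"chr{i + 1}", random_dna(rng, per))
        for i in range(params.n_chromosomes)
    ]


def simulate_dataset(params: SimParams,
                     ) -> tuple[CircularMito, list[SequenceRecord],
                                list[SimTruth]]:
    """Mito + background + implants in one call, all from ``params.seed``.

    Named substreams keep the mito, the background, and the event draws
    statistically independent under one root seed.
    """
    mito = simulate_mito(params.mito_length, seed=params.seed)
    rng_bg = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    rng_ev = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    background = simulate_background(params, rng=rng_bg)
    genome, truths = implant_events(background, mito, params, rng=rng_ev)
    return mito, genome, truths


# --- repeat motif planting (for flank-environment statistics) --------------

_REPEAT_LIBRARY_SPECS = [
    ("SINE/tRNA", 260), ("LINE/L1", 900), ("LTR/ERV1", 420),
    ("Simple_repeat", 120),
]


def repeat_library(seed: int = 99) -> dict[str, str]:
    """Small fixed library of labeled repeat motifs (synthetic)."""
    rng = np.random.default_rng(seed)
    lib = {}
    for name, length in _REPEAT_LIBRARY_SPECS:
        if name == "Simple_repeat":
            lib[name] = "AT" * (length // 2)
        else:
            lib[name] = random_dna(rng, length)
    return lib


def plant_repeat_elements(genome: list[SequenceRecord], n_per_chrom: int,
                          rng: np.random.Generator,
                          ) -> tuple[list[SequenceRecord],
                                     list[GenomicInterval]]:
    """Overwrite background stretches with labeled repeat motifs; returns
    the modified genome and a truth annotation of what was planted."""
    lib = repeat_library()
    names = list(lib)
    out = []
    annotation: list[GenomicInterval] = []
    for rec in genome:
        seq = list(rec.sequence)
        taken: list[tuple[int, int]] = []
        for _ in range(n_per_chrom):
            name = names[int(rng.integers(0, len(names)))]
            motif = lib[name]
            if rec.length <= len(motif):
                continue
            for _try in range(50):
                pos = int(rng.integers(0, rec.length - len(motif)))
                if all(pos + len(motif) <= a or pos >= b for a, b in taken):
                    break
            else:
                continue
            seq[pos:pos + len(motif)] = motif
            taken.append((pos, pos + len(motif)))
            annotation.append(
                GenomicInterval(rec.id, pos, pos + len(motif), label=name))
        out.append(SequenceRecord(rec.id, "".join(seq)))
    annotation.sort(key=lambda iv: (iv.chrom, iv.start))
    return out, annotation


# --- truth IO and scoring ---------------------------------------------------

def truth_to_frame(truths: list[SimTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append({
            "event_id": t.event_id, "mito_start": t.mito_start,
            "mito_end": t.mito_end, "wrap": t.wrap,
            "orientation": t.orientation, "divergence": t.divergence,
            "event_class": t.event_class,
            "placements": ";".join(
                f"{p.chrom}:{p.start}-{p.end}" for p in t.placements),
            "inserted_spans": ";".join(
                f"{s.chrom}:{s.start}-{s.end}" for s in t.inserted_spans),
        })
    return pd.DataFrame(rows)


def score_against_truth(hit_intervals: list[GenomicInterval],
                        truths: list[SimTruth],
                        min_frac: float = 0.5) -> dict:
    """Recall/precision of recovered intervals against implanted truth.

    A truth event counts as recovered when some interval covers at least
    ``min_frac`` of one of its placements; an interval is a true positive
    when at least ``min_frac`` of it lies inside some placement.
    """
    placements = [(p, t.event_id) for t in truths for p in t.placements]
    recovered: set[str] = set()
    tp = 0
    for iv in hit_intervals:
        best_in = 0.0
        for p, _eid in placements:
            if p.chrom != iv.chrom:
                continue
            ov = min(p.end, iv.end) - max(p.start, iv.start)
            if ov > 0:
                best_in = max(best_in, ov / len(iv))
        if best_in >= min_frac:
            tp += 1
    for p, eid in placements:
        for iv in hit_intervals:
            if p.chrom != iv.chrom:
                continue
            ov = min(p.end, iv.end) - max(p.start, iv.start)
            if ov > 0 and ov / len(p) >= min_frac:
                recovered.add(eid)
                break
    event_ids = {t.event_id for t in truths}
    recall = len(recovered) / len(event_ids) if event_ids else 0.0
    precision = tp / len(hit_intervals) if hit_intervals else 1.0
    return {
        "recall": recall, "precision": precision,
        "n_events": len(event_ids), "n_recovered": len(recovered),
        "n_hits": len(hit_intervals), "n_true_hits": tp,
        "recovered_ids": sorted(recovered),
    }
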