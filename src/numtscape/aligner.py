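"""Seed-and-extend local homology search under a distant-homology scoring
scheme, with empirical E-value calibration.

The scoring scheme is the one used for ancient-NUMT detection: match +1,
mismatch -1, affine gaps costing ``gap_open + gap_extend * k`` for a gap of
k bases (LAST convention: a 1-base gap costs 8 by default).  Candidate loci
come from exact k-mer seeds, are extended first ungapped and then with a
banded affine X-drop DP, and are assigned E-values from a Karlin–Altschul /
Gumbel model fitted to maximal local scores of shuffled-sequence searches.

``smith_waterman_affine`` is an exact, exhaustive dynamic program kept as
the testing oracle for the heuristic search path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import NumtHit, SequenceRecord

_NEG = -(10**9)

# base encoding: A,C,G,T -> 0..3 (case-insensitive), anything else -> 4 (N)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, is_masked): codes 0..3 for ACGT, 4 for N/other;
    is_masked marks lowercase (soft-masked) positions."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    is_masked = (raw >= ord("a")) & (raw <= ord("z"))
    return codes, is_masked


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores.

    ``open_includes_first_base=False`` (default) reads "gaps -7, gap
    extensions -1" as a LAST-style cost ``7 + 1*k`` for a k-base gap, i.e. a
    1-base gap costs 8.  Setting it true makes a 1-base gap cost 7.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = 7
    gap_extend: int = 1
    open_includes_first_base: bool = False

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def first_gap_cost(self) -> int:
        """Cost of opening a gap onto its first base."""
        if self.open_includes_first_base:
            return self.gap_open
        return self.gap_open + self.gap_extend

    def gap_cost(self, k: int) -> int:
        return self.first_gap_cost + self.gap_extend * (k - 1)


@dataclass
class SearchParams:
    seed_k: int = 11
    xdrop_ungapped: int = 10
    xdrop_gapped: int = 20
    min_score: int = 61
    max_evalue: float = 1e-4
    seeds_in_masked: bool = False
    gapped_trigger: int = 20
    max_seed_occ: int = 200
    skip_covered_seeds: bool = True

    def __post_init__(self) -> None:
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if self.xdrop_ungapped <= 0 or self.xdrop_gapped <= 0:
            raise ValueError("X-drop thresholds must be positive")


@dataclass
class EvalueModel:
    """Gumbel/Karlin–Altschul model: E(S) = K * m * n * exp(-lambda * S)."""

    lam: float
    K: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def evalue(self, score: float, m: int | None = None,
               n: int | None = None) -> float:
        m = self.m if m is None else m
        n = self.n if n is None else n
        return self.K * m * n * math.exp(-self.lam * score)

    def score_for_evalue(self, evalue: float, m: int | None = None,
                         n: int | None = None) -> float:
        m = self.m if m is None else m
        n = self.n if n is None else n
        return math.log(self.K * m * n / evalue) / self.lam


# ---------------------------------------------------------------------------
# exhaustive oracle


def smith_waterman_affine(a: str, b: str, scheme: ScoringScheme | None = None,
                          max_cells: int = 10**7,
                          ) -> tuple[int, tuple[int, int, int, int]]:
    """Exact optimal local alignment score under affine gaps.

    Returns ``(score, (a_start, a_end, b_start, b_end))`` for one optimal
    alignment (ties broken deterministically: match/mismatch > gap-in-b >
    gap-in-a).  Exhaustive O(|a||b|) DP, guarded for testing scale.
    """
    scheme = scheme or ScoringScheme()
    if len(a) * len(b) > max_cells:
        raise ValueError("input too large for the exhaustive oracle")
    ac, _ = encode(a)
    bc, _ = encode(b)
    m, n = len(ac), len(bc)
    GO, GE = scheme.first_gap_cost, scheme.gap_extend
    Hp = [0] * (n + 1)
    Ep = [_NEG] * (n + 1)
    Fp = [_NEG] * (n + 1)
    best, best_ij = 0, (0, 0)
    H_rows = [list(Hp)]
    for i in range(1, m + 1):
        H = [0] * (n + 1)
        E = [_NEG] * (n + 1)
        F = [_NEG] * (n + 1)
        ai = ac[i - 1]
        for j in range(1, n + 1):
            E[j] = max(E[j - 1] - GE, H[j - 1] - GO)
            F[j] = max(Fp[j] - GE, Hp[j] - GO)
            s = scheme.match if (ai == bc[j - 1] and ai < 4) else scheme.mismatch
            h = Hp[j - 1] + s
            val = max(0, h, F[j], E[j])
            H[j] = val
            if val > best:
                best, best_ij = val, (i, j)
        Hp, Ep, Fp = H, E, F
        H_rows.append(H)
    # recover the start of one optimal alignment by re-running a bounded
    # traceback on the stored score rows
    i, j = best_ij
    a_end, b_end = i, j
    # local traceback using score identities (deterministic preference)
    state = "H"
    while i > 0 and j > 0 and H_rows[i][j] > 0:
        h = H_rows[i][j]
        s = (scheme.match if (ac[i - 1] == bc[j - 1] and ac[i - 1] < 4)
             else scheme.mismatch)
        if H_rows[i - 1][j - 1] + s == h:
            i, j = i - 1, j - 1
            continue
        # gap in b (vertical run)
        moved = False
        for k in range(1, i + 1):
            if H_rows[i - k][j] - scheme.gap_cost(k) == h:
                i -= k
                moved = True
                break
        if moved:
            continue
        for k in range(1, j + 1):
            if H_rows[i][j - k] - scheme.gap_cost(k) == h:
                j -= k
                moved = True
                break
        if not moved:
            break
    return best, (i, a_end, j, b_end)


def sw_score_only(a_codes: np.ndarray, b_codes: np.ndarray,
                  scheme: ScoringScheme | None = None) -> int:
    """Vectorized (row-wise numpy) optimal local score; no traceback.

    Used where only the maximal score of a sequence pair is needed, e.g.
    E-value calibration on shuffled sequences.
    """
    scheme = scheme or ScoringScheme()
    GO, GE = scheme.first_gap_cost, scheme.gap_extend
    m, n = len(a_codes), len(b_codes)
    if m == 0 or n == 0:
        return 0
    Hp = np.zeros(n + 1, dtype=np.int64)
    Fp = np.full(n + 1, _NEG, dtype=np.int64)
    best = 0
    b_col = b_codes.astype(np.int64)
    jidx = np.arange(n, dtype=np.int64) * GE
    for i in range(m):
        ai = a_codes[i]
        s = np.where((b_col == ai) & (b_col < 4), scheme.match, scheme.mismatch)
        diag = Hp[:-1] + s
        F = np.maximum(Fp[1:] - GE, Hp[1:] - GO)
        Ht = np.maximum.reduce([diag, F, np.zeros(n, dtype=np.int64)])
        # E[j] = max_{k<j} (H[k] - GO - GE*(j-1-k)); chained horizontal gaps
        # are dominated, so the prefix max over gap-free row values is exact
        Hfull = np.concatenate(([0], Ht))
        pref = np.maximum.accumulate(Hfull[:-1] + jidx)
        E = pref - GO - jidx
        H = np.maximum(Ht, E)
        best = max(best, int(H.max()))
        Hp = np.concatenate(([0], H))
        Fp = np.concatenate(([_NEG], F))
    return best


# ---------------------------------------------------------------------------
# seed machinery


def _kmer_codes(codes: np.ndarray, masked: np.ndarray, k: int,
                seeds_in_masked: bool) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-mer start positions and their integer codes."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    kc = np.zeros(n, dtype=np.int64)
    for o in range(k):
        kc = kc * 4 + codes[o:o + n].astype(np.int64)
    bad = codes >= 4
    if not seeds_in_masked:
        bad = bad | masked
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    pos = np.nonzero(valid)[0].astype(np.int64)
    return pos, kc[pos]


def build_seed_index(target: str, k: int,
                     seeds_in_masked: bool = False) -> dict[str, list[int]]:
    """Map every valid k-mer of ``target`` to its start positions.

    k-mers containing N, or soft-masked bases when ``seeds_in_masked`` is
    false, are skipped.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    codes, masked = encode(target)
    pos, kc = _kmer_codes(codes, masked, k, seeds_in_masked)
    index: dict[str, list[int]] = {}
    upper = target.upper()
    for p in pos.tolist():
        index.setdefault(upper[p:p + k], []).append(p)
    return index


# ---------------------------------------------------------------------------
# extension


def _extend_ungapped(qc, tc, qs, ts, k, scheme, xdrop):
    """X-drop ungapped extension around an exact seed.

    Returns (score, left_q_ext, right_q_ext): total HSP score including the
    seed's k matches, and extension lengths on each side.
    """
    match, mismatch = scheme.match, scheme.mismatch
    # right
    cur = 0
    best_r, ext_r = 0, 0
    i, j = qs + k, ts + k
    steps = 0
    nq, nt = len(qc), len(tc)
    while i < nq and j < nt:
        cur += match if (qc[i] == tc[j] and qc[i] < 4) else mismatch
        steps += 1
        if cur > best_r:
            best_r, ext_r = cur, steps
        elif best_r - cur > xdrop:
            break
        i += 1
        j += 1
    # left
    cur = 0
    best_l, ext_l = 0, 0
    i, j = qs - 1, ts - 1
    steps = 0
    while i >= 0 and j >= 0:
        cur += match if (qc[i] == tc[j] and qc[i] < 4) else mismatch
        steps += 1
        if cur > best_l:
            best_l, ext_l = cur, steps
        elif best_l - cur > xdrop:
            break
        i -= 1
        j -= 1
    return k * match + best_l + best_r, ext_l, ext_r


def _extend_gapped(qc, tc, scheme, xdrop):
    """Anchored affine-gap X-drop extension from (0, 0) forward.

    ``qc``/``tc`` are code arrays starting at the anchor (pass reversed
    views for leftward extension).  The DP keeps only the window of columns
    within ``xdrop`` of the best score seen so far (adaptive band) and
    records per-cell traceback pointers.

    Returns ``(score, q_ext, t_ext, matches, columns)`` for the best-scoring
    extension end, with matches/columns counted along its traceback.
    """
    GO, GE = scheme.first_gap_cost, scheme.gap_extend
    match, mismatch = scheme.match, scheme.mismatch
    m, n = len(qc), len(tc)
    best, best_ij = 0, (0, 0)

    # pointer byte: bits0-1 H-source (0 origin, 1 diag, 2 E, 3 F);
    # bit2: E came from E (gap extension); bit3: F came from F
    max_j0 = 0
    if GO + 0 * GE <= xdrop:
        max_j0 = min(n, (xdrop - GO) // GE + 1)
    lo = 0
    H = [0] + [-(GO + GE * (j - 1)) for j in range(1, max_j0 + 1)]
    E = [_NEG] + [-(GO + GE * (j - 1)) for j in range(1, max_j0 + 1)]
    F = [_NEG] * (max_j0 + 1)
    ptr0 = bytearray(max_j0 + 1)
    for j in range(1, max_j0 + 1):
        ptr0[j] = 2 | (0 if j == 1 else 4)
    rows = [(0, ptr0)]

    for i in range(1, m + 1):
        qi = qc[i - 1]
        prev_lo, prev_hi = lo, lo + len(H) - 1
        new_lo = prev_lo
        Hn: list[int] = []
        En: list[int] = []
        Fn: list[int] = []
        ptr = bytearray()
        j = new_lo
        first_alive = None
        last_alive = new_lo - 1
        e_cur = _NEG
        h_left = _NEG
        while True:
            if j > n:
                break
            # values from previous row at columns j and j-1
            if prev_lo <= j <= prev_hi:
                hp = H[j - prev_lo]
                fp = F[j - prev_lo]
            else:
                hp, fp = _NEG, _NEG
            if prev_lo <= j - 1 <= prev_hi:
                hd = H[j - 1 - prev_lo]
            else:
                hd = _NEG
            if j == 0:
                # leading gap in the query
                f = -(GO + GE * (i - 1))
                code = 3 | 8
                h = f
                e = _NEG
            else:
                f = max(fp - GE, hp - GO)
                f_ext = fp - GE >= hp - GO
                e = max(e_cur - GE, h_left - GO)
                e_ext = e_cur - GE >= h_left - GO
                tj = tc[j - 1]
                s = match if (qi == tj and qi < 4) else mismatch
                d = hd + s if hd > _NEG // 2 else _NEG
                h = max(d, e, f)
                if h == d:
                    code = 1
                elif h == f:
                    code = 3
                else:
                    code = 2
                code |= (4 if e_ext else 0) | (8 if f_ext else 0)
            if h > best:
                best, best_ij = h, (i, j)
            alive = max(h, e, f) >= best - xdrop
            if alive:
                if first_alive is None:
                    first_alive = j
                last_alive = j
            else:
                h = e = f = _NEG
                code = 0
            if first_alive is not None or j <= prev_hi + 1:
                Hn.append(h)
                En.append(e)
                Fn.append(f)
                ptr.append(code)
            if j > prev_hi and not alive:
                break
            e_cur, h_left = e, h
            j += 1
        if first_alive is None:
            break
        # trim dead leading cells
        trim = first_alive - new_lo
        if trim > 0:
            Hn = Hn[trim:]
            En = En[trim:]
            Fn = Fn[trim:]
            ptr = ptr[trim:]
            new_lo = first_alive
        # trim dead trailing cells
        keep = last_alive - new_lo + 1
        Hn = Hn[:keep]
        En = En[:keep]
        Fn = Fn[:keep]
        ptr = ptr[:keep]
        H, E, F, lo = Hn, En, Fn, new_lo
        rows.append((new_lo, ptr))

    # traceback from best end
    i, j = best_ij
    q_ext, t_ext = i, j
    matches = cols = 0
    state = "H"
    while i > 0 or j > 0:
        row_lo, ptr = rows[i]
        if not (row_lo <= j < row_lo + len(ptr)):
            break
        code = ptr[j - row_lo]
        if state == "H":
            src = code & 3
            if src == 0:
                break
            if src == 1:
                cols += 1
                if qc[i - 1] == tc[j - 1] and qc[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            j -= 1
            state = "E" if (code & 4) else "H"
        else:
            cols += 1
            i -= 1
            state = "F" if (code & 8) else "H"
    return best, q_ext, t_ext, matches, cols


@dataclass
class _Candidate:
    qa: int
    qb: int
    ta: int
    tb: int
    score: int
    matches: int
    cols: int

    @property
    def diag(self) -> int:
        return self.qa - self.ta


def extend_hit(seed: tuple[int, int], query_codes: np.ndarray,
               target_codes: np.ndarray, scheme: ScoringScheme,
               params: SearchParams) -> _Candidate | None:
    """Extend one exact seed: ungapped X-drop first, then gapped X-drop.

    Returns the extended candidate (coordinates on query/target, score,
    match/column counts) or ``None`` when the ungapped stage dies below the
    gapped trigger.
    """
    qs, ts = seed
    k = params.seed_k
    hsp, _, _ = _extend_ungapped(query_codes, target_codes, qs, ts, k,
                                 scheme, params.xdrop_ungapped)
    if hsp < params.gapped_trigger:
        return None
    ls, lq, lt, lm, lc = _extend_gapped(
        query_codes[:qs][::-1], target_codes[:ts][::-1],
        scheme, params.xdrop_gapped)
    rs, rq, rt, rm, rc = _extend_gapped(
        query_codes[qs + k:], target_codes[ts + k:],
        scheme, params.xdrop_gapped)
    score = ls + k * scheme.match + rs
    return _Candidate(
        qa=qs - lq, qb=qs + k + rq, ta=ts - lt, tb=ts + k + rt,
        score=score, matches=lm + k + rm, cols=lc + k + rc,
    )


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate_evalue(scheme: ScoringScheme, query_len: int, db_len: int,
                     n_shuffles: int = 50, seed: int = 0) -> EvalueModel:
    """Fit the Gumbel E-value model on maximal local scores of random
    (shuffled-composition) query/target pairs.

    The maximum local score of a random pair of sizes (m0, n0) follows a
    Gumbel law with location ln(K m0 n0)/lambda and scale 1/lambda under
    the Karlin–Altschul model; ``scipy.stats.gumbel_r`` provides the fit.
    """
    if n_shuffles < 30:
        raise ValueError("need at least 30 shuffles for a stable fit")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_shuffles):
        a = rng.integers(0, 4, size=query_len).astype(np.uint8)
        b = rng.integers(0, 4, size=db_len).astype(np.uint8)
        scores.append(sw_score_only(a, b, scheme))
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate calibration: all shuffle scores equal")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc * lam) / (query_len * db_len)
    return EvalueModel(lam=lam, K=K, m=query_len, n=db_len)


# ---------------------------------------------------------------------------
# full search


def _merge_candidate(cands: list[_Candidate], new: _Candidate) -> None:
    """Keep the best-scoring representative among overlapping candidates."""
    for idx, c in enumerate(cands):
        ov = min(c.tb, new.tb) - max(c.ta, new.ta)
        if ov <= 0:
            continue
        frac = ov / min(c.tb - c.ta, new.tb - new.ta)
        if frac >= 0.5 and abs(c.diag - new.diag) <= 100:
            if new.score > c.score:
                cands[idx] = new
            return
    cands.append(new)


def _covered(cands: list[_Candidate], qs: int, ts: int) -> bool:
    for c in cands:
        if (c.ta <= ts < c.tb and c.qa <= qs < c.qb
                and abs((qs - ts) - c.diag) <= 60):
            return True
    return False


def search(query: SequenceRecord, genome: list[SequenceRecord],
           scheme: ScoringScheme | None = None,
           params: SearchParams | None = None,
           evalue_model: EvalueModel | None = None) -> list[NumtHit]:
    """Search the query (typically the doubled mitochondrial consensus)
    against every genome sequence on both strands.

    Minus-strand hits carry nuclear coordinates on the forward strand and
    mito coordinates on the reverse-complemented query axis (convert with
    :func:`numtscape.calls.normalize_strand`).  Hits scoring below
    ``min_score`` or exceeding ``max_evalue`` are dropped.
    """
    scheme = scheme or ScoringScheme()
    params = params or SearchParams()
    if not genome:
        raise ValueError("empty genome")
    k = params.seed_k
    genome_len = sum(r.length for r in genome)
    queries = {
        "+": query.sequence,
        "-": reverse_complement(query.sequence),
    }
    q_enc = {}
    for strand, qseq in queries.items():
        qc, qm = encode(qseq)
        qpos, qk = _kmer_codes(qc, qm, k, params.seeds_in_masked)
        q_enc[strand] = (qc, qpos, qk)

    hits: list[NumtHit] = []
    nhit = 0
    for rec in genome:
        tc, tm = encode(rec.sequence)
        tpos, tk = _kmer_codes(tc, tm, k, params.seeds_in_masked)
        if len(tpos) == 0:
            continue
        order = np.argsort(tk, kind="stable")
        tk_sorted = tk[order]
        tpos_sorted = tpos[order]
        for strand, (qc, qpos, qk) in q_enc.items():
            if len(qpos) == 0:
                continue
            left = np.searchsorted(tk_sorted, qk, side="left")
            right = np.searchsorted(tk_sorted, qk, side="right")
            counts = right - left
            use = (counts > 0) & (counts <= params.max_seed_occ)
            if not use.any():
                continue
            q_idx = np.nonzero(use)[0]
            pair_q = np.repeat(qpos[q_idx], counts[q_idx])
            pair_t = np.concatenate([
                tpos_sorted[left[i]:right[i]] for i in q_idx
            ])
            by_t = np.argsort(pair_t, kind="stable")
            pair_q = pair_q[by_t]
            pair_t = pair_t[by_t]

            cands: list[_Candidate] = []
            for qs, ts in zip(pair_q.tolist(), pair_t.tolist()):
                if params.skip_covered_seeds and _covered(cands, qs, ts):
                    continue
                cand = extend_hit((qs, ts), qc, tc, scheme, params)
                if cand is None:
                    continue
                _merge_candidate(cands, cand)

            for c in cands:
                if c.score < params.min_score:
                    continue
                ev = (evalue_model.evalue(c.score, m=len(qc), n=genome_len)
                      if evalue_model is not None else float("nan"))
                if evalue_model is not None and ev > params.max_evalue:
                    continue
                nhit += 1
                hits.append(NumtHit(
                    hit_id=f"hit{nhit:05d}", chrom=rec.id,
                    nstart=c.ta, nend=c.tb, strand=strand,
                    mstart=c.qa, mend=c.qb,
                    score=c.score, evalue=ev,
                    identity=c.matches / c.cols if c.cols else 0.0,
                    normalized=(strand == "+"),
                ))
    hits.sort(key=lambda h: (h.chrom, h.nstart))
    return hits
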