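# Methods

This note documents the models and procedures implemented in `numtscape`,
the parameters that matter, the choices made where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## The discovery model

A NUMT is modeled as a local alignment between a mitochondrial reference
(usually a consensus of a haplotype panel) and a nuclear chromosome.
Because insertions may be millions of years old, the scoring scheme is
deliberately shallow: match +1, mismatch −1, and affine gaps costing
`gap_open + gap_extend·k = 7 + k` for a k-base gap. Under this scheme a
1-base gap costs 8; the alternative convention in which the open penalty
includes the first gapped base (1-base gap = 7) is available as
`ScoringScheme(open_includes_first_base=True)`. The default follows the
`a + b·k` cost form used by whole-genome local aligners with these same
printed penalties.

### Circular handling

The mitochondrial genome is circular; linearizing it at an arbitrary
origin hides homology that spans the cut. The query is therefore searched
as `sequence + sequence` (length 2L). Every non-spanning locus then
aligns twice and every origin-spanning locus aligns once in full plus up
to two truncated partials at the ends of the doubled axis.
`fold_interval` maps doubled coordinates back to the circle
(`start mod L`, `((end−1) mod L)+1`, wrap flag), and `dedup_doubled_hits`
removes a hit when a higher-scoring hit on the same chromosome and strand
covers ≥ 95% of it on both the nuclear and folded-mito coordinates. This
containment rule subsumes exact duplicates, trimming-level near-duplicates
(X-drop extension can trim the two copies differently), and the truncated
partials of junction-spanning hits. A single alignment longer than one
circular turn (> L on the mito axis) is an error, not a truncation: no
insertion copies more than the full circle contiguously.

### Seeds and extension

Candidate loci are exact k-mer matches (default k = 11) between the
doubled query and each chromosome, found by sorted integer k-mer codes.
k-mers containing N — or soft-masked bases, unless `seeds_in_masked` is
set — never seed. Each seed is extended ungapped with X-drop 10; seeds
whose ungapped HSP stays below `gapped_trigger` (default 20) are
discarded, which kills essentially all chance seeds cheaply. Survivors are
extended with a banded affine X-drop DP (X = 20) anchored at the seed in
both directions; the band is adaptive (cells within X of the running best
survive) and per-cell pointers give the traceback from which identity
(matches / alignment columns, gaps counting as non-matching) is computed.
Ties in the DP prefer match/mismatch over gap-in-target over gap-in-query,
making results deterministic. N scores as a mismatch even against N;
lowercase bases score as their uppercase identity during extension.

Seeds falling inside an already-extended candidate (same diagonal ± 60)
are skipped for speed; `skip_covered_seeds=False` disables this, and with
exhaustive small-k seeding and unbounded X-drop the search provably
returns the exact Smith–Waterman optimum whenever the optimal alignment
contains an exact k-mer — the property the oracle-equivalence tests
exercise against the standalone `smith_waterman_affine` DP.

Both strands are searched (the reverse-complemented query reports hits
with forward-strand nuclear coordinates); `normalize_strand` maps
minus-strand mito coordinates onto the forward mitochondrial axis while
preserving the original orientation.

### E-values

The aligner the scheme emulates reports E-values, but no closed-form
parameters exist for gapped scoring, so the package calibrates a
Karlin–Altschul/Gumbel model empirically: the maximal local scores of
`n_shuffles` random query/target pairs (default 40 pairs of 400 × 4000 bp)
are fitted with a right Gumbel; then λ = 1/scale and
K = exp(loc·λ)/(m₀·n₀), and `E(S) = K·m·n·e^(−λS)` with m, n the actual
query and database lengths of the search. For the +1/−1 scheme on uniform
composition the ungapped λ is exactly ln 3 ≈ 1.10; calibrated values land
within a few percent of it, a useful sanity anchor. Absolute E-values are
not comparable across tools; the working thresholds (score > 61 strictly,
E ≤ 10⁻⁴) are therefore configuration, and the benchmark judges the
pipeline by ground-truth recovery, not by E-value equality.

### Decoy false-positive control

The decoy is the character-reversed, *non-complemented* mitochondrial
sequence: reverse-complement homology is genuine biology, while plain
reversal has no evolutionary route into the genome, so any decoy alignment
is a false positive. The decoy query is doubled exactly like the real one
and searched with bit-identical parameters (asserted by a config hash in
the report). The report carries the decoy hit count, their scores, and the
implied empirical FDR `decoy / (decoy + real)`.

## Event reconstruction and duplications

Sorted same-chromosome calls chain into one NUMT region when consecutive
nuclear gaps are ≤ 30 kb (transitive over neighbors; long-range
non-adjacent joins are out of scope). The mitochondrial gap at each
junction — computed on the circle as the smaller arc, zero when the
intervals overlap — annotates the junction: ≤ 2.5 kb implies the region
lost intervening mtDNA (nuclear deletion), and a nuclear gap exceeding the
mito gap implies inserted nuclear material; both annotations are recorded
when both are informative. A region is `singleton` (one member),
`complex` (any junction mito gap > 2.5 kb, the operationalization of
"much greater"; configurable as `complex_mito_span`), else
`single_insertion`. Each region counts as one insertion event, so
`events = multi-member regions + singletons` holds by construction and is
asserted.

Duplication classification extracts up to 200 bp upstream plus 200 bp
downstream of each region (truncated at chromosome ends), concatenates
them, and compares all pairs with a global alignment (same scoring, free
terminal gaps). Similarity is matching columns over alignment columns
between the first and last aligned pair; coverage is the aligned span of
the shorter concatenation over its length — the denominator the published
rule leaves unstated, made explicit and configurable here. A pair is
duplicated when both exceed 0.8 strictly. The O(R²) comparison is
prefiltered by shared 8-mer fraction (< 0.2 skips alignment), which keeps
it trivial at the region counts this pipeline produces (hundreds).

## Landscape statistics

Window coverage counts, per 100 bp circular window, the number of calls
overlapping it by ≥ 1 bp; windows covered by more than 50 calls are
hotspots (threshold configurable, z-scores against the window mean also
reported). Gene coverage is the merged-union overlap fraction per
annotated mito gene, with raw per-gene hit counts kept separately for
ranking. Flank environment reports GC of the 1000 bp flanks (N excluded
from the denominator, truncation at chromosome ends flagged) and
per-class counts of annotated repeat elements overlapping each flank —
counts of elements, not bases, with base fractions reported separately.
Correlations are ordinary Pearson product-moment with t-based two-sided
p-values (n−2 df); chromosome length normalized by genome length is a pure
rescaling of x and cannot change r, so only raw-length correlations are
reported.

## The synthetic benchmark

`simulate` generates i.i.d.-uniform A/C/G/T chromosomes — a clean null for
the decoy and for E-value calibration — and implants mitochondrial
fragments drawn from a uniform-random circular mitogenome carrying a
non-overlapping gene-like tiling (28 labeled intervals shaped on a
mammalian mitogenome, including a D-loop; scaled down for toy sizes).
Defaults mirror the reference study conditions exercised by the tests:
2 Mb genome over 5 chromosomes, a 16.6 kb mitogenome (pig-sized), 30
events of 300–3000 bp, per-event substitution rate uniform in 5–15% with
substitutions forced to a different base (so expected identity is
1 − rate), indels at 0.5%/site with geometric lengths (p = 0.7), and
random orientation. Optional knobs produce origin-spanning sources
(`frac_junction_spanning`), internal fragmentation by a nuclear insert
(`frac_fragmented`, insert length configurable), and duplications that
copy the insertion plus 300 bp of flanking genome to a second locus
(`frac_duplicated`; 300 > the 200 bp the duplication classifier reads, so
parent and copy share complete flanks).

Events are spaced at least `min(60 kb, genome/(2·events))` apart — twice
the merge threshold where the genome affords it — via a sorted-uniform
construction that succeeds whenever placement is feasible at all;
duplication copies additionally keep clear of existing events, relaxing
the clearance stepwise (floor 1 kb) only when a small genome cannot honor
it. Ground truth records, per event, the circular source interval, the
nuclear placements of mito-derived material, and the full inserted spans
(internal inserts and copied flanks included), so deleting all inserted
spans reconstructs the background byte-for-byte — a tested invariant. All
randomness flows from one root seed through named substreams (mito,
background, events), making outputs byte-identical under a fixed seed.

What passing on this benchmark does **not** show: performance on real
repeat-rich, GC-structured genomes (the background is uniform; repeat
motifs can be planted, but only from a small synthetic library), realistic
phylogenetic divergence (the mutation model is i.i.d.), or recovery of
NUMTs older/shorter than the scoring scheme and thresholds can separate
from noise on a 2.5 Gb genome. Problem sizes in tests and in the
acceptance script (2 Mb genomes, 16.6 kb mitogenome, tens of events) were
chosen as the smallest at which every mechanism — circular doubling,
fragmentation merging, duplication flanks, decoy nulls — is
unambiguously observable.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; BED-native.
  RepeatMasker import converts its 1-based inclusive query coordinates.
- Consensus: per column the most frequent non-gap base is called when its
  frequency among non-gap characters ≥ plurality (default 0.5); ties give
  N; gap-majority columns are dropped by default. IUPAC ambiguity codes
  are never emitted because any non-ACGT base is unseedable downstream.
  The published pipeline's consensus parameters are unstated; these
  defaults are this package's choice. A warning is logged when labeled
  header groups (e.g. `EUR|…`/`ASN|…`) are unbalanced.
- Masking: the reference workflow builds a custom repeat library; that is
  replaced by a built-in DUST-style masker (window 64, triplet score
  Σc(c−1)/2 normalized by w−3, threshold 2.0, nearby intervals merged
  ≤ 5 bp apart) plus import of any external annotation — soft by default,
  hard (N) available. Masking is idempotent and case-only.
- Call filter: score strictly > 61 ("score > 61" read literally),
  E ≤ 10⁻⁴.
- Adjacent-call distances are per-chromosome gaps between sorted calls;
  negative gaps are reported as distance 0 with the overlap length logged
  separately.
- Length histogram bins are fixed: 39–99, 100–249, 250–499, 500–749,
  750–999, 1000–1999, 2000–4999, > 5000 bp.
- The whole-pipeline runner derives every stage's randomness from one
  root seed, embeds a config hash in every output header, and reuses a
  completed run directory whose manifest matches the config hash
  (whole-run granularity; per-stage caching was judged not worth the
  complexity at these runtimes).
- Plot rendering is deliberately out of scope; every statistic is emitted
  as a TSV from which standard tools plot directly.

## Known limitations

- The heuristic search can in principle miss an optimum whose alignment
  contains no exact k-mer seed; at the default k = 11 this matters only
  for extremely diverged or very short homology near the score threshold.
- The Gumbel calibration assumes uniform base composition; skewed
  genomes would need recalibration on composition-matched shuffles.
- Pairwise duplication comparison is quadratic in regions; fine for
  hundreds, not for hundreds of thousands.
- `smith_waterman_affine` is a testing oracle with an O(m·n) memory
  footprint and a 10⁷-cell guard; it is not the production search path.
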