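"""Estimate the false-positive rate with the inverted-sequence decoy.

A character-reversed (non-complemented) mitochondrial sequence has no
biological homologs, so any decoy alignment is a false positive.  At the
working thresholds (score > 61, E <= 1e-4) the decoy should find nothing;
relaxing the thresholds lets chance alignments through.
"""

from numtscape import (ScoringScheme, SearchParams, SimParams,
                       calibrate_evalue, discover_numts, run_decoy,
                       simulate_dataset)

params = SimParams(genome_length=500_000, n_chromosomes=2, n_events=6,
                   seed=19)
mito, genome, _ = simulate_dataset(params)
scheme = ScoringScheme()
model = calibrate_evalue(scheme, 400, 4000, seed=1)

hits = discover_numts(mito, genome, scheme, SearchParams(), model)
report = run_decoy(mito, genome, scheme, SearchParams(), model,
                   n_real_hits=len(hits))
print(f"real calls       : {len(hits)}")
print(f"decoy hits       : {report.n_decoy_hits}")
print(f"empirical FDR    : {report.empirical_fdr:.3f}")
print(f"search config    : {report.config_hash} (identical to real search)")

relaxed = SearchParams(min_score=14, max_evalue=1e6, gapped_trigger=12,
                       seed_k=8)
loose = run_decoy(mito, genome, scheme, relaxed, model)
print(f"decoy hits at relaxed thresholds (score >= 14): "
      f"{loose.n_decoy_hits}")
# zero decoy hits at working thresholds means the score/E-value cutoffs
# leave no room for chance homology of this query size on this genome
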