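"""Distribution statistics of a call set.

Computes the per-window coverage of the circular mitochondrial genome,
per-gene coverage fractions, the GC environment of the nuclear flanks, and
the chromosome-length correlations.
"""

from numtscape import (ScoringScheme, SearchParams, SimParams,
                       calibrate_evalue, discover_numts, flank_environment,
                       gene_coverage, simulate_dataset, summarize_calls,
                       window_counts)
from numtscape.landscape import correlate_with_chromosome_length

params = SimParams(genome_length=1_000_000, n_chromosomes=5, n_events=20,
                   seed=11)
mito, genome, truths = simulate_dataset(params)
scheme = ScoringScheme()
model = calibrate_evalue(scheme, 400, 4000, seed=1)
hits = discover_numts(mito, genome, scheme, SearchParams(), model)

wc = window_counts(hits, mito, window_size=100)
print(f"mito windows     : {wc.n_windows} x 100 bp, "
      f"mean count {wc.mean:.2f}, hotspots(>50) {wc.hotspot_windows}")

cov = gene_coverage(hits, mito)
top = cov.sort_values("covered_fraction", ascending=False).head(3)
for row in top.itertuples():
    print(f"  top gene {row.gene:10s} covered {row.covered_fraction:.2f} "
          f"by {row.hit_count} calls")

env = flank_environment(hits, genome, flank_size=1000)
print(f"flank GC         : up {env.mean_upstream_gc:.3f} / "
      f"down {env.mean_downstream_gc:.3f} (genome {env.genome_gc:.3f})")

summary = summarize_calls(hits, sum(r.length for r in genome))
corr = correlate_with_chromosome_length(
    summary.per_chromosome, {r.id: r.length for r in genome})
print(f"chrom-length vs NUMT length: r = "
      f"{corr.r_length_vs_total_numt_length:.2f} "
      f"(p = {corr.p_length_vs_total_numt_length:.2f})")
# on a uniform background the flank GC matches the genome (~0.5).  The
# background chromosomes are equal-length, so post-insertion length
# differences are exactly the implanted material: the length correlation
# is ~1 by construction here, unlike on real karyotypes where background
# length variation dominates
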