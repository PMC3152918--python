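"""Full contrast table, significance flags, and distribution summaries.

Builds the per-context table (bias, minimal contrast, binomial p-value of
the minimal-contrast pair, Bonferroni flag), labels the scatter clusters,
and fits the normal approximation to the bulk of minimal contrasts.
"""

from mutcontext import (
    SimulationConfig,
    count_mutation_contexts,
    filter_snps,
    fit_minimal_contrast_normal,
    flank_word_freqs,
    scatter_table,
    simulate,
)
from mutcontext.stats import contrast_table

cfg = SimulationConfig(
    genome_length=5_000_000,
    planted_effects={"C>T|1,CG": 5.0, "T>C|2,ATTG": 3.5},
    seed=1,
)
accepted, _ = filter_snps(simulate(cfg).snps)
counts = count_mutation_contexts(accepted, max_len=4)
freqs = flank_word_freqs(accepted, max_len=4)

table, diagnostics = contrast_table(counts, freqs, min_len=2, max_len=4)
print(f"ranked contexts: {len(table)}   undefined (diagnostics): {len(diagnostics)}")
top = table.sort_values("minimal_contrast", ascending=False).head(6)
cols = ["context", "mutation_bias", "minimal_contrast", "pvalue_min", "significant"]
print(top[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# The planted CG pair tops minimal contrast; the planted ATTG pair and its
# complement separate next, exactly the structure the statistics target.

scatter = scatter_table(table)
print("\ncluster sizes:", scatter.cluster.value_counts().to_dict())

summary = fit_minimal_contrast_normal(table["minimal_contrast"])
print(
    f"normal fit on {summary.fit_range}: mean={summary.mean:.3f} sd={summary.sd:.3f} "
    f"(n={summary.n_fit}); tail chi2={summary.chi2:.1f} p={summary.pvalue:.2g}"
)
# A significant tail p-value flags more high-minimal-contrast contexts than
# the fitted normal bulk predicts — here driven by the planted effects.
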