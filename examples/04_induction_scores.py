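"""Score BGC gene induction under infection from simulated RNA-seq counts.

Plants a 4-fold (log2fc = 2) induction into 20 genes, normalises with
median-of-ratios size factors, applies the log2 variance-flattening transform,
and checks that the per-gene induction scores recover the planted effect.
"""
from gcfkit import (
    BGCGeneSet,
    bgc_induction_scores,
    make_infection_design,
    simulate_counts_matrix,
    size_factors,
    vst_like_transform,
)

samples = make_infection_design(n_per_group=3)
induced = {f"gene{i:05d}" for i in range(20)}
counts = simulate_counts_matrix(500, samples, induced, log2fc=2.0,
                                dispersion=0.05, seed=42)
factors = size_factors(counts)
print(f"size factors span [{factors.min():.3f}, {factors.max():.3f}] "
      "(all near 1: balanced libraries)")

transformed = vst_like_transform(counts, factors)
gene_set = BGCGeneSet("GCF_1", "BGC1", genes=sorted(induced),
                      backbone={"gene00000"})
scores = bgc_induction_scores(transformed, samples, gene_set)
print(f"mean per-gene induction score: {scores['per_gene'].mean():.3f} "
      "(planted log2 fold change was 2.0)")
print(f"per-host scores: "
      + ", ".join(f"{h}={s.mean():.3f}" for h, s in scores["per_host"].items()))
print("Scores near 2 mean the normalisation and transform preserved the "
      "planted infection induction; backbone genes are flagged in exports.")
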