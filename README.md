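# gcfkit

Conservation analysis of fungal **biosynthetic gene clusters (BGCs)** and the
**gene cluster families (GCFs)** they form. Secondary-metabolite clusters —
NRPS, PKS, terpene, RiPP and hybrid systems — are compared by the presence,
order and sequence similarity of their protein domains; families emerge as
connected components of the resulting distance graph; and family-level
questions follow: how are family sizes distributed, how taxonomically
specific are families, and are any families confined to insect-pathogenic
(entomopathogenic) genera? A synthetic-data generator with known ground truth
makes every step testable end to end, and an RNA-seq module scores infection
induction of BGC genes.

The package is a library first: import it from Python, or browse the short
scripts in `examples/`. A thin `gcfkit` CLI wraps the same functions for
shell pipelines.

## The model

**Distance.** Two BGCs of the same metabolite class are compared by

```
d(a, b) = 1 − (w_J · J + w_A · A + w_D · DSS)
```

where `J` is the Jaccard index of their domain-type sets, `A` the Jaccard
index over unordered adjacent domain-type pairs (domain order), and `DSS`
matches copies of each shared domain type one-to-one (exact assignment on
1 − normalised edit distance of their sequences), averaging matched
similarity over matched plus unmatched copies. Default weights
`(w_J, w_A, w_D) = (0.2, 0.05, 0.75)`.

**Families.** At a cutoff `c`, GCFs are the connected components of the graph
with edges where `d ≤ c`. Sweeping `c` over 0.1–0.9 gives family counts,
singleton counts and mean family size per class; a knee heuristic (maximum
perpendicular distance to the chord of the mean-size curve) picks the last
cutoff before families start absorbing dissimilar clusters.

**Family sizes.** Discrete power-law `p(k) = k^−α / ζ(α, xmin)`, discretised
lognormal, and geometric-form exponential models are fitted by bounded MLE on
the tail `k ≥ xmin` and compared with Vuong's likelihood-ratio test for
non-nested models; parameter stability comes from a nonparametric bootstrap.

**Specificity.** Each family is a singleton, genus-specific, or multi-genus;
a Pearson goodness-of-fit chi-square (df = 2) tests the category counts, and
families found in ≥ 3 entomopathogenic genera with no other members are
reported as lifestyle-exclusive.

**Induction.** Counts are normalised by median-of-ratios size factors,
transformed by `log2(normalised + 1)`, and per-gene induction scores are the
mean transformed difference, infection minus saprophytic control.

## Worked example

`python examples/01_simulate_and_cluster.py` simulates 212 BGCs across 48
genomes with planted family structure, sweeps the clustering cutoff and
measures ground-truth recovery:

```
212 BGCs in 48 genomes; largest class NRPS (98)
  cutoff 0.1: 124 GCFs,  93 singletons, mean size 1.71
  cutoff 0.2: 101 GCFs,  67 singletons, mean size 2.10
  cutoff 0.3:  85 GCFs,  50 singletons, mean size 2.49
  cutoff 0.4:  77 GCFs,  41 singletons, mean size 2.75
  ...
knee cutoff 0.4: 77 GCFs; ARI vs ground truth = 1.000
```

The number of families and singletons falls as the cutoff loosens, the mean
family size grows, and at the knee the partition matches the planted families
exactly (adjusted Rand index 1.0). `examples/02_family_size_models.py` fits
the size laws (on 10,000 lognormal draws the Vuong statistic is ≈ 63,
decisively recovering the lognormal over the power law);
`examples/03_specificity.py` classifies specificity and finds
lifestyle-exclusive families; `examples/04_induction_scores.py` recovers a
planted log2 fold change of 2.0 as a mean induction score of 1.95.

The same steps are available from the shell:

```sh
gcfkit simulate --seed 7 --out-dir run/
gcfkit sweep --bgcs run/bgcs.tsv --out-dir run/
gcfkit specificity --bgcs run/bgcs.tsv --cutoff 0.6 --out-dir run/
```

## Layout

- `src/gcfkit/` — `types`, `io`, `summary`, `simulate`, `similarity`,
  `clustering`, `heavytail`, `specificity`, `expression`, `cli`
- `docs/methods.md` — models, assumptions, numerical choices, limitations
- `examples/` — one narrative script per capability
- `tests/` — pytest suite with brute-force oracles for the core algorithms
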