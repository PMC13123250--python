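"""Synthetic BGC inventories, family-size laws, and planted-induction counts."""
import numpy as np
import pytest
from scipy import special, stats

from gcfkit.simulate import (
    LognormalSizes,
    PowerLawSizes,
    SimConfig,
    make_infection_design,
    simulate_counts_matrix,
    simulate_dataset,
    simulate_gcf_sizes,
)
from gcfkit.types import ValidationError


class TestGCFSizes:
    def test_powerlaw_mean_matches_zeta_ratio(self):
        # analytic mean of the zeta law: zeta(alpha-1)/zeta(alpha)
        sizes = simulate_gcf_sizes(PowerLawSizes(2.5), 10000, seed=11)
        analytic = special.zeta(1.5) / special.zeta(2.5)
        assert np.mean(sizes) == pytest.approx(analytic, rel=0.10)

    def test_degenerate_lognormal_all_ones(self):
        sizes = simulate_gcf_sizes(LognormalSizes(0.0, 1e-9), 100, seed=1)
        assert set(sizes) == {1}

    def test_single_draw(self):
        (size,) = simulate_gcf_sizes(PowerLawSizes(2.5), 1, seed=2)
        assert isinstance(size, int) and size >= 1

    def test_alpha_at_most_one_errors(self):
        with pytest.raises(ValidationError, match="alpha"):
            simulate_gcf_sizes(PowerLawSizes(1.0), 10, seed=0)

    def test_histogram_matches_requested_law(self):
        """Chi-square goodness of fit of drawn sizes against the zeta pmf."""
        alpha, n = 2.5, 10000
        sizes = np.array(simulate_gcf_sizes(PowerLawSizes(alpha), n, seed=17))
        kmax = 8
        observed = [np.sum(sizes == k) for k in range(1, kmax + 1)]
        observed.append(np.sum(sizes > kmax))
        pmf = [k ** (-alpha) / special.zeta(alpha) for k in range(1, kmax + 1)]
        expected = [n * p for p in pmf] + [n * (1 - sum(pmf))]
        _, p = stats.chisquare(observed, f_exp=expected)
        assert p > 0.01


class TestDataset:
    def test_zero_noise_members_identical(self):
        cfg = SimConfig(mutation_rate=0.0, indel_rate=0.0, seed=4,
                        n_ancestral_gcfs=8, orphan_rate=0.0, total_bgc_budget=60)
        records, _, truth = simulate_dataset(cfg)
        by_family = {}
        for rec in records:
            by_family.setdefault(truth.true_family[rec.bgc_id], []).append(rec)
        for members in by_family.values():
            archetypes = {tuple((d.domain_type, d.sequence) for d in m.domains)
                          for m in members}
            assert len(archetypes) == 1

    def test_budget_caps_families(self):
        cfg = SimConfig(n_ancestral_gcfs=5, orphan_rate=0.0, seed=9,
                        total_bgc_budget=50)
        records, _, truth = simulate_dataset(cfg)
        assert len(set(truth.true_family.values())) == 5
        assert len(records) <= 50

    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(seed=21, total_bgc_budget=100)
        r1, g1, t1 = simulate_dataset(cfg)
        r2, g2, t2 = simulate_dataset(cfg)
        assert r1 == r2 and g1 == g2
        assert t1.true_family == t2.true_family

    def test_every_bgc_has_truth_label_and_orphans_unique(self):
        cfg = SimConfig(seed=3, orphan_rate=2.0, total_bgc_budget=80)
        records, _, truth = simulate_dataset(cfg)
        assert {r.bgc_id for r in records} == set(truth.true_family)
        orphan_labels = [v for v in truth.true_family.values()
                         if v.startswith("ORPHAN")]
        assert len(orphan_labels) == len(set(orphan_labels))

    def test_infeasible_config_errors(self):
        with pytest.raises(ValidationError):
            SimConfig(n_ancestral_gcfs=0, orphan_rate=0.0)

    def test_genome_meta_counts_match(self):
        records, genomes, _ = simulate_dataset(SimConfig(seed=6, total_bgc_budget=90))
        counted = {}
        for rec in records:
            counted[rec.genome_id] = counted.get(rec.genome_id, 0) + 1
        for g in genomes:
            assert g.n_bgcs == counted.get(g.genome_id, 0)
            assert g.genome_size_mb > 0

    def test_zero_noise_clustering_recovers_truth(self):
        """With no mutation and separated prototypes, any modest cutoff
        recovers the planted families exactly."""
        from sklearn.metrics import adjusted_rand_score

        from gcfkit.clustering import assign_gcfs_all_classes
        from gcfkit.similarity import pairwise_distances

        cfg = SimConfig(mutation_rate=0.0, indel_rate=0.0, seed=13,
                        total_bgc_budget=120)
        records, _, truth = simulate_dataset(cfg)
        edges = pairwise_distances(records)
        assignment = assign_gcfs_all_classes(edges, records, cutoff=0.2)
        ids = sorted(r.bgc_id for r in records)
        ari = adjusted_rand_score(
            truth.labels_for(ids), [assignment.membership[i] for i in ids]
        )
        assert ari == pytest.approx(1.0)


class TestCountsMatrix:
    def test_null_effect_indistinguishable(self):
        samples = make_infection_design(n_per_group=3)
        induced = {f"gene{i:05d}" for i in range(200)}
        counts = simulate_counts_matrix(
            2000, samples, induced, log2fc=0.0, dispersion=0.1, seed=8
        )
        inf_cols = [s.sample_id for s in samples if s.condition == "infection"]
        ctl_cols = [s.sample_id for s in samples if s.condition != "infection"]
        ratio = (counts[inf_cols].mean(axis=1) + 1) / (counts[ctl_cols].mean(axis=1) + 1)
        is_induced = counts.index.isin(list(induced))
        _, p = stats.ks_2samp(ratio[is_induced], ratio[~is_induced])
        assert p > 0.01

    def test_planted_fold_change_in_mean_ratio(self):
        samples = make_infection_design(n_per_group=6)
        induced = {f"gene{i:05d}" for i in range(100)}
        counts = simulate_counts_matrix(
            1000, samples, induced, log2fc=2.0, dispersion=0.01, seed=15
        )
        inf_cols = [s.sample_id for s in samples if s.condition == "infection"]
        ctl_cols = [s.sample_id for s in samples if s.condition != "infection"]
        ratios = counts.loc[sorted(induced), inf_cols].mean(axis=1) / counts.loc[
            sorted(induced), ctl_cols
        ].mean(axis=1)
        assert 3.5 <= ratios.mean() <= 4.5

    def test_zero_baseline_all_zero(self):
        samples = make_infection_design(n_per_group=2)
        counts = simulate_counts_matrix(
            50, samples, set(), log2fc=2.0, dispersion=0.1, seed=1,
            baseline_means=np.zeros(50),
        )
        assert (counts.values == 0).all()

    def test_nonpositive_dispersion_errors(self):
        with pytest.raises(ValidationError, match="dispersion"):
            simulate_counts_matrix(10, make_infection_design(1), set(),
                                   dispersion=0.0, seed=1)

    def test_needs_both_conditions(self):
        from gcfkit.expression import SampleInfo

        only_inf = [SampleInfo("s1", "infection", "Ac", "24h")]
        with pytest.raises(ValidationError):
            simulate_counts_matrix(10, only_inf, set(), seed=1)

    def test_determinism(self):
        samples = make_infection_design(n_per_group=2)
        a = simulate_counts_matrix(100, samples, {"gene00000"}, seed=33)
        b = simulate_counts_matrix(100, samples, {"gene00000"}, seed=33)
        assert a.equals(b)
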