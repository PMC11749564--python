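"""Generator tests: determinism, planted structure, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, spearmanr

from bloomsex.expression import size_factors
from bloomsex.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_annotations,
    simulate_counts,
    simulate_environment,
    simulate_hits,
    simulate_invitro_labels,
)


def test_identical_seed_gives_identical_outputs(default_config):
    cm1, t1 = simulate_counts(default_config)
    cm2, t2 = simulate_counts(default_config)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
    pd.testing.assert_series_equal(t1.assignments, t2.assignments)
    pd.testing.assert_series_equal(t1.size_factors, t2.size_factors)


def test_counts_are_nonnegative_integers_and_truth_consistent(bloom, default_config):
    cm, truth = bloom
    vals = cm.counts.to_numpy()
    assert (vals >= 0).all() and np.issubdtype(vals.dtype, np.integer)
    # background profile exactly zero; markers inside the spike cluster
    assert (truth.profiles.loc[0] == 0).all()
    spike = default_config.spike_cluster
    for gene in truth.marker_genes.values():
        assert truth.assignments[gene] == spike
    sizes = truth.assignments.value_counts()
    for k, expected in enumerate(default_config.cluster_sizes, start=1):
        assert sizes[k] == expected


def test_cluster_sizes_exceeding_n_genes_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_genes=100, cluster_sizes=(50, 30, 30, 10, 10, 10))


def test_poisson_limit_variance_mean_ratio():
    """As dispersion -> 0 the per-cell variance/mean ratio approaches 1."""
    cfg = SimulationConfig(n_genes=1600, dispersion=1e-6, lib_size_log_sd=0.0, seed=3)
    cm, truth = simulate_counts(cfg)
    background = truth.assignments.index[truth.assignments == 0]
    x = cm.counts.loc[background].to_numpy(float)
    # replicate pairs within a day share the same mean
    a, b = x[:, 0::2], x[:, 1::2]
    mean = (a + b) / 2
    var = (a - mean) ** 2 + (b - mean) ** 2  # 1-df within-pair variance
    ratio = var.sum() / mean.sum()
    assert abs(ratio - 1.0) < 0.05


def test_spike_mean_ratio_matches_planted_log2fc():
    """Spike-day over other-day empirical mean ratio ~ 2**spike_log2fc."""
    cfg = SimulationConfig(seed=4, spike_log2fc=8.0)
    ratios = []
    for rep in range(3):  # >=50 spike genes per draw; average over redraws
        cm, truth = simulate_counts(SimulationConfig(seed=4 + rep))
        spike_genes = truth.assignments.index[truth.assignments == cfg.spike_cluster]
        x = cm.counts.loc[spike_genes].div(truth.size_factors, axis=1)
        sheet = cm.samples
        on = sheet.index[sheet["day"] == truth.spike_day]
        off = sheet.index[sheet["day"] != truth.spike_day]
        ratios.append(x[on].mean(axis=1).mean() / x[off].mean(axis=1).mean())
    # off-days include the gene baseline only, so ratio estimates 2**8
    assert np.mean(ratios) == pytest.approx(2**8.0, rel=0.2)


def test_background_genes_have_no_day_effect(bloom):
    cm, truth = bloom
    background = truth.assignments.index[truth.assignments == 0][:300]
    x = cm.counts.loc[background].div(truth.size_factors, axis=1)
    day_means = x.T.groupby(cm.samples["day"]).mean().T
    lfc = np.log2(day_means.div(day_means.mean(axis=1), axis=0))
    assert np.abs(lfc.mean(axis=0)).max() < 0.2


def test_size_factor_recovery(bloom):
    cm, truth = bloom
    rho = spearmanr(size_factors(cm.counts), truth.size_factors).statistic
    assert rho > 0.9


class TestSimulateHits:
    def test_profile_recovery_within_binomial_ci(self, default_config):
        hits, _ = simulate_hits(
            default_config,
            {"A": 0.7, "B": 0.3},
            n_reads=10000,
            ambiguous_fraction=0.1,
            seed=5,
            above_threshold_fraction=0.0,
        )
        from bloomsex.taxonomy import TaxonomyMap, assign_reads

        _, taxmap = simulate_hits(default_config, {"A": 0.7, "B": 0.3}, 10, 0.0, seed=5)
        asg = assign_reads(hits, TaxonomyMap(taxmap), "class", 1e-70)
        assigned = asg[asg != "unassigned"]
        n_a = int((assigned == "A").sum())
        ci = binomtest(n_a, len(assigned), 0.7).proportion_ci(confidence_level=0.99)
        assert ci.low <= 0.7 <= ci.high

    def test_fully_ambiguous_reads_never_assigned(self, default_config):
        hits, taxmap = simulate_hits(
            default_config, {"A": 0.5, "B": 0.5}, n_reads=500, ambiguous_fraction=1.0, seed=6
        )
        from bloomsex.taxonomy import TaxonomyMap, assign_reads

        asg = assign_reads(hits, TaxonomyMap(taxmap), "class", 1e-70)
        assert (asg == "unassigned").all()

    def test_empty_profile_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            simulate_hits(default_config, {}, 10, 0.0, seed=1)


class TestSimulateAnnotations:
    def test_full_nesting_produces_subset_pair(self, bloom, default_config):
        _, truth = bloom
        ann = simulate_annotations(default_config, truth, nesting=1.0, seed=7)
        sets = {go: set(sub["gene"]) for go, sub in ann.groupby("go_id")}
        sub, sup = truth.go_truth["nested_pairs"][0]
        assert sets[sub] < sets[sup]

    def test_requires_at_least_two_terms(self, bloom, default_config):
        _, truth = bloom
        with pytest.raises(ConfigurationError):
            simulate_annotations(default_config, truth, n_go=1)


class TestSimulateInvitroLabels:
    def test_zero_coverage_gives_empty_panel(self, bloom, default_config):
        _, truth = bloom
        panel = simulate_invitro_labels(default_config, truth, homolog_coverage=0.0, seed=8)
        assert panel.is_empty()
        from bloomsex.crossref import NoMappedGenesError, cross_enrich

        with pytest.raises(NoMappedGenesError, match="no mapped genes"):
            cross_enrich({"g00001"}, panel, "T1", "up")

    def test_nonpositive_target_or_rejected(self, bloom, default_config):
        _, truth = bloom
        with pytest.raises(ConfigurationError, match="unattainable"):
            simulate_invitro_labels(
                default_config, truth, target_or={(6, "T1", "up"): 0.0}, seed=8
            )

    def test_cross_columns_identical_by_default(self, bloom, default_config):
        _, truth = bloom
        panel = simulate_invitro_labels(default_config, truth, seed=9)
        assert (panel.labels["vs_plus_log2fc"] == panel.labels["vs_minus_log2fc"]).all()


def test_environment_has_default_covariates(default_config):
    env = simulate_environment(default_config)
    from bloomsex.ordination import DEFAULT_COVARIATES

    assert set(DEFAULT_COVARIATES) <= set(env.columns)
    assert len(env) == default_config.n_days * default_config.replicates_per_day
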