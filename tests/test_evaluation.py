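"""Logistic GRS fits, replicate aggregation, and Tukey method contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from grseval import (
    CaseControlDataset,
    GRSWeightSet,
    fit_grs_model,
    pairwise_method_contrasts,
    run_study,
    simulate_liability_dataset,
)
from grseval.errors import ConfigurationError
from grseval.scores import weighted_score


def brute_force_c_statistic(case_scores, control_scores):
    """Concordance by enumerating all case-control pairs (ties half credit)."""
    wins = ties = 0
    for cs, ct in itertools.product(case_scores, control_scores):
        if cs > ct:
            wins += 1
        elif cs == ct:
            ties += 1
    return (wins + 0.5 * ties) / (len(case_scores) * len(control_scores))


class TestFit:
    def test_c_statistic_small_fixture(self):
        status = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([1.0, 2.0, 3.0, 0.0, 1.0, 2.0])
        fit = fit_grs_model(status, scores)
        # 6 concordant pairs and 2 ties among the 9 case-control pairs
        expected = brute_force_c_statistic([1, 2, 3], [0, 1, 2])
        assert expected == pytest.approx(7.0 / 9)
        assert fit.c_statistic == pytest.approx(expected)

    def test_constant_scores_collapse_to_null(self):
        status = np.array([1, 0] * 20)
        fit = fit_grs_model(status, np.full(40, 3.0))
        assert fit.c_statistic == 0.5
        assert fit.lrt_statistic == 0.0
        assert fit.lrt_pvalue == 1.0

    def test_perfect_separation_has_c_one(self):
        status = np.array([1] * 15 + [0] * 15)
        scores = np.concatenate([np.full(15, 5.0), np.full(15, 1.0)])
        fit = fit_grs_model(status, scores)
        assert fit.c_statistic == 1.0
        assert fit.lrt_pvalue < 0.01

    def test_aic_identity(self, common_equal_spec):
        ds = simulate_liability_dataset(common_equal_spec, 0)
        fit = fit_grs_model(ds, ds.genotypes.sum(axis=1))
        assert fit.aic == pytest.approx(4 - 2 * fit.log_likelihood, abs=1e-9)
        assert fit.lrt_statistic >= 0

    def test_misaligned_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_grs_model(np.array([0, 1, 0]), np.array([1.0, 2.0]))
        with pytest.raises(ConfigurationError):
            fit_grs_model(np.array([1, 1, 1]), np.array([1.0, 2.0, 3.0]))


def _forced_dataset(significant: bool, r: int) -> CaseControlDataset:
    """Perfect separation forces p ~ 0; all-heterozygous forces p = 1."""
    n = 20
    status = np.array([1] * n + [0] * n)
    if significant:
        g = np.vstack([np.full((n, 2), 2), np.zeros((n, 2))])
    else:
        g = np.ones((2 * n, 2))
    return CaseControlDataset(genotypes=g, status=status, replicate_index=r)


class TestRunStudy:
    def test_power_counting_oracle(self):
        datasets = [_forced_dataset(r < 40, r) for r in range(100)]
        res = run_study(datasets, methods=("SC",))
        assert res.rejection_rate("SC") == pytest.approx(0.40)

    def test_equal_weights_collapse_identical_pvalues(self, common_equal_spec):
        datasets = [simulate_liability_dataset(common_equal_spec, r) for r in range(5)]
        loci = [l.locus_id for l in common_equal_spec.loci]
        weight_sets = {
            "OR": GRSWeightSet(method="OR", loci=loci, weights=np.full(4, 0.7)),
            "EV": GRSWeightSet(method="EV", loci=loci, weights=np.full(4, 0.3)),
        }
        res = run_study(datasets, methods=("SC", "OR", "EV"), weight_sets=weight_sets)
        wide = res.per_replicate.pivot(index="replicate", columns="method", values="lrt_pvalue")
        np.testing.assert_allclose(wide["OR"], wide["SC"], rtol=1e-9)
        np.testing.assert_allclose(wide["EV"], wide["SC"], rtol=1e-9)

    def test_affine_invariance_of_rescaling(self, common_equal_spec):
        ds = simulate_liability_dataset(common_equal_spec, 1)
        ws = GRSWeightSet(
            method="OR", loci=ds.locus_ids, weights=np.array([0.1, 0.5, 0.3, 0.2])
        )
        raw = fit_grs_model(ds, weighted_score(ds.genotypes, ws, rescale=False).values)
        scaled = fit_grs_model(ds, weighted_score(ds.genotypes, ws, rescale=True).values)
        assert raw.lrt_pvalue == pytest.approx(scaled.lrt_pvalue, rel=1e-7, abs=1e-12)
        assert raw.c_statistic == pytest.approx(scaled.c_statistic, abs=1e-12)
        assert raw.aic == pytest.approx(scaled.aic, rel=1e-9)

    def test_missing_weight_set_rejected(self, common_equal_spec):
        ds = simulate_liability_dataset(common_equal_spec, 0)
        with pytest.raises(ConfigurationError):
            run_study([ds], methods=("OR",))
        with pytest.raises(ConfigurationError):
            run_study([], methods=("SC",))

    def test_summary_columns_and_ci(self, common_equal_spec):
        datasets = [simulate_liability_dataset(common_equal_spec, r) for r in range(10)]
        res = run_study(datasets, methods=("SC",), scenario="demo")
        row = res.summary.iloc[0]
        assert set(res.summary.columns) >= {
            "method", "rejection_rate", "ci_low", "ci_high", "mean_c", "mean_aic", "n_replicates"
        }
        assert 0 <= row["ci_low"] <= row["rejection_rate"] <= row["ci_high"] <= 1
        assert row["n_replicates"] == 10


def _metric_frame(shift_or=0.0, n=30, scenarios=("s1", "s2")):
    rng = np.random.default_rng(2)
    rows = []
    for scen in scenarios:
        base = rng.normal(50, 5, size=n)
        for method in ("SC", "OR", "EV"):
            vals = base + (shift_or if method == "OR" else 0.0)
            rows += [{"scenario": scen, "method": method, "power": v} for v in vals]
    return pd.DataFrame(rows)


class TestContrasts:
    def test_identical_metrics_no_winners(self):
        tab = pairwise_method_contrasts(_metric_frame(0.0), "power")
        assert (tab["winner"] == "").all()

    def test_forced_ordering_declares_winner(self):
        tab = pairwise_method_contrasts(_metric_frame(10.0), "power", larger_is_better=True)
        row = tab.set_index("pair").loc["SC-OR"]
        assert row["winner"] == "OR" and row["adjusted_p"] < 0.05
        assert tab.set_index("pair").loc["SC-EV", "winner"] == ""

    def test_smaller_is_better_flips_winner(self):
        tab = pairwise_method_contrasts(_metric_frame(10.0), "power", larger_is_better=False)
        assert tab.set_index("pair").loc["SC-OR", "winner"] == "SC"

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(3)
        df = _metric_frame(1.5)
        df["power"] += rng.normal(0, 3, size=len(df))
        tab = pairwise_method_contrasts(df, "power")
        assert (tab["adjusted_p"] >= tab["unadjusted_p"] - 1e-12).all()

    def test_matches_statsmodels_tukey_single_scenario(self):
        # one scenario reduces the two-way model to one-way ANOVA, where
        # statsmodels' Tukey HSD is the independent reference
        df = _metric_frame(2.0, scenarios=("only",))
        rng = np.random.default_rng(4)
        df["power"] += rng.normal(0, 4, size=len(df))
        ours = pairwise_method_contrasts(df, "power").set_index("pair")
        ref = pairwise_tukeyhsd(df["power"], df["method"])
        ref_p = {
            f"{g1}-{g2}": p
            for (g1, g2), p in zip(
                itertools.combinations(ref.groupsunique, 2), ref.pvalues
            )
        }
        for pair, p in ref_p.items():
            a, b = pair.split("-")
            key = pair if pair in ours.index else f"{b}-{a}"
            assert ours.loc[key, "adjusted_p"] == pytest.approx(p, abs=1e-6)

    def test_too_few_methods_rejected(self):
        df = _metric_frame(0.0)
        with pytest.raises(ConfigurationError):
            pairwise_method_contrasts(df[df["method"] == "SC"], "power")
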