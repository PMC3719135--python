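"""Analytic heritability decomposition vs closed forms and a Monte-Carlo oracle."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from grseval import (
    InteractionTerm,
    LiabilityModelSpec,
    LiabilityPopulation,
    LocusSpec,
    decompose,
    h2_curves,
)
from grseval.errors import CapacityError, ConfigurationError
from grseval.heritability import (
    analytic_penetrances,
    h2_interaction,
    h2_pair,
    h2_single,
    mc_penetrances,
    population_threshold,
)
from tests.conftest import make_liability_spec


class TestThreshold:
    def test_null_model_threshold_is_intercept(self, null_spec):
        assert population_threshold(null_spec) == pytest.approx(20.0, abs=1e-9)

    def test_symmetric_model_threshold_is_mean(self):
        # maf 0.5 and equal effects: the genotype mixture is symmetric about
        # its mean b0 + sum b_i * 1
        spec = LiabilityModelSpec(
            loci=(LocusSpec("a", 0.5), LocusSpec("b", 0.5)),
            main_effects=(0.3, 0.3),
        )
        assert population_threshold(spec) == pytest.approx(20.6, abs=1e-9)

    def test_threshold_matches_empirical_median(self, common_equal_spec):
        from grseval.liability import linear_predictor, sample_genotypes_hwe

        rng = np.random.default_rng(5)
        n = 2_000_000
        g = sample_genotypes_hwe(common_equal_spec.loci, n, rng)
        y = linear_predictor(common_equal_spec, g) + rng.normal(
            0, common_equal_spec.noise_sd, n
        )
        t = population_threshold(common_equal_spec)
        # MC error of a quantile estimate: ~1/(2 f(t) sqrt(n))
        assert t == pytest.approx(np.median(y), abs=0.01)

    def test_capacity_cap(self):
        spec = make_liability_spec((0.4,) * 4, (0.2,) * 4)
        nine = LiabilityModelSpec(
            loci=tuple(LocusSpec(f"S{i}", 0.4) for i in range(9)),
            main_effects=(0.1,) * 9,
        )
        LiabilityPopulation(spec)  # fine
        with pytest.raises(CapacityError):
            LiabilityPopulation(nine)


class TestPenetrances:
    def test_null_model_all_half(self, null_spec):
        pens = analytic_penetrances(null_spec)
        assert all(abs(p - 0.5) < 1e-12 for p in pens.values())

    def test_mixture_mean_is_prevalence_half(self, common_equal_spec):
        pop = LiabilityPopulation(common_equal_spec)
        assert pop.prevalence == pytest.approx(0.5, abs=1e-10)

    def test_agreement_with_mc_oracle(self, common_equal_spec):
        rng = np.random.default_rng(17)
        n = 1_000_000
        combos, freq, pen = mc_penetrances(common_equal_spec, n, rng)
        pop = LiabilityPopulation(common_equal_spec)
        counts = freq * n
        se = np.sqrt(pop.penetrances * (1 - pop.penetrances) / np.maximum(counts, 1))
        ok = counts > 200  # skip near-empty cells
        assert (np.abs(pen[ok] - pop.penetrances[ok]) < 3.5 * se[ok]).all()


class TestComponents:
    def test_null_locus_has_zero_marginal(self):
        spec = make_liability_spec((0.4,) * 4, (0.0, 0.2, 0.2, 0.2))
        assert h2_single(spec, 0) == pytest.approx(0.0, abs=1e-14)

    def test_small_effect_closed_form(self, common_equal_spec):
        # H2 -> (2 p q beta^2 / Var Y) * (2 / pi) for small effects at 50%
        # prevalence
        var_y = 10.0 + 4 * 2 * 0.4 * 0.6 * 0.04
        approx = (2 * 0.4 * 0.6 * 0.04 / var_y) * (2 / np.pi)
        exact = h2_single(common_equal_spec, 2)
        assert exact == pytest.approx(approx, rel=0.02)

    def test_risk_allele_relabelling_invariance(self):
        # coding the major allele as the risk allele (G -> 2 - G) with the
        # negated effect describes the same phenotype distribution
        base = LiabilityModelSpec(
            loci=(LocusSpec("a", 0.3), LocusSpec("b", 0.4)),
            main_effects=(0.4, 0.2),
        )
        flipped = LiabilityModelSpec(
            loci=(LocusSpec("a", 0.3, risk_allele_is_minor=False), LocusSpec("b", 0.4)),
            main_effects=(-0.4, 0.2),
        )
        assert h2_single(flipped, 0) == pytest.approx(h2_single(base, 0), rel=1e-9)

    def test_pair_total_bounds_and_identity(self, common_equal_spec):
        pop = LiabilityPopulation(common_equal_spec)
        pair = (2, 3)
        total = h2_pair(pop, pair)
        m3, m4 = h2_single(pop, 2), h2_single(pop, 3)
        assert total >= max(m3, m4)
        assert h2_interaction(pop, pair) == pytest.approx(total - m3 - m4, abs=1e-12)

    def test_zero_coefficient_interaction_is_negligible(self):
        spec = make_liability_spec((0.05,) * 4, (0.8,) * 4, beta34=0.0)
        assert abs(h2_interaction(spec, (2, 3))) < 5e-4

    def test_positive_interaction_increases_pair_total(self):
        totals = []
        for coef in (0.0, 0.2, 0.5):
            spec = make_liability_spec((0.4,) * 4, (0.1,) * 4, beta34=coef)
            totals.append(h2_pair(spec, (2, 3)))
        assert totals[0] < totals[1] < totals[2]


class TestDecompose:
    def test_ladder_lowest_rung(self, common_equal_spec):
        dec = decompose(common_equal_spec)
        assert 100 * dec.group_totals["G3G4"] == pytest.approx(0.24, abs=0.02)
        assert 100 * dec.overall_total == pytest.approx(0.49, abs=0.03)
        assert dec.prevalence == pytest.approx(0.5, abs=1e-10)

    def test_grouping_convention(self):
        spec = make_liability_spec((0.4,) * 4, (0.2,) * 4, beta34=0.2)
        dec = decompose(spec)
        # main-effect group is the sum of its marginals
        ids = [l.locus_id for l in spec.loci]
        assert dec.group_totals["G1G2"] == pytest.approx(
            dec.per_locus_marginal[ids[0]] + dec.per_locus_marginal[ids[1]], abs=1e-12
        )
        # interacting group adds the pairwise remainder
        assert dec.group_totals["G3G4"] == pytest.approx(
            dec.per_locus_marginal[ids[2]] + dec.per_locus_marginal[ids[3]]
            + dec.pairwise_interaction["G3G4"],
            abs=1e-12,
        )
        assert dec.overall_total == pytest.approx(
            dec.group_totals["G1G2"] + dec.group_totals["G3G4"], abs=1e-12
        )

    def test_three_way_group_assembly(self):
        spec = LiabilityModelSpec(
            loci=tuple(LocusSpec(f"S{i}", 0.4) for i in range(4)),
            main_effects=(0.2,) * 4,
            interactions=(InteractionTerm(loci=(1, 2, 3), coefficient=0.2),),
        )
        dec = decompose(spec)
        assert "G2G3G4" in dec.group_totals and "G2G3G4" in dec.higher_order_interaction
        pop = LiabilityPopulation(spec)
        assert dec.group_totals["G2G3G4"] == pytest.approx(pop.h2((1, 2, 3)), abs=1e-12)

    def test_unknown_grouping_rejected(self, common_equal_spec):
        with pytest.raises(ConfigurationError):
            decompose(common_equal_spec, grouping=[(0, 9)])

    def test_mc_oracle_decomposition(self):
        # recompute the group total from empirical penetrances of a large draw
        spec = make_liability_spec((0.4,) * 4, (0.2, 0.2, 0.2, 0.5))
        rng = np.random.default_rng(23)
        n = 2_000_000
        combos, freq, pen = mc_penetrances(spec, n, rng)
        prev = float(freq @ pen)
        # marginalize onto loci 3,4
        key34 = combos[:, 2] * 3 + combos[:, 3]
        p34 = np.zeros(9)
        pen34 = np.zeros(9)
        for cell in range(9):
            m = key34 == cell
            p34[cell] = freq[m].sum()
            pen34[cell] = freq[m] @ pen[m] / p34[cell]
        h2_emp = p34 @ (pen34 - prev) ** 2 / (prev * (1 - prev))
        pop = LiabilityPopulation(spec)
        assert h2_emp == pytest.approx(pop.h2((2, 3)), abs=3 * 2e-4)


class TestCurves:
    def test_maf_sweep_monotone(self, common_equal_spec):
        grid = np.linspace(0.02, 0.5, 8)
        tab = h2_curves("MAF", grid, common_equal_spec, pair=(2, 3))
        assert (np.diff(tab["h2_marginal_2"]) > 0).all()

    def test_raf_sweep_endpoints_zero(self, common_equal_spec):
        tab = h2_curves("RAF", np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
                        common_equal_spec, pair=(2, 3))
        assert tab["h2_marginal_2"].iloc[0] == 0.0
        assert tab["h2_marginal_2"].iloc[-1] == 0.0
        assert tab["h2_marginal_2"].iloc[2] == tab["h2_marginal_2"].max()

    def test_ev_weight_tracks_heritability_along_raf(self):
        # single-locus effect 0.5 used directly as the log OR
        spec = LiabilityModelSpec(
            loci=(LocusSpec("a", 0.4), LocusSpec("b", 0.4)),
            main_effects=(0.0, 0.5),
        )
        grid = np.linspace(0.02, 0.98, 25)
        tab = h2_curves("RAF", grid, spec, pair=(0, 1))
        rho = spearmanr(tab["ev_weight"], tab["h2_marginal_2"]).statistic
        assert rho > 0.99

    def test_interaction_sweep_touches_pair_total(self, common_equal_spec):
        tab = h2_curves("interaction", np.array([0.0, 0.3]), common_equal_spec, pair=(2, 3))
        assert tab["h2_total_pair"].iloc[1] > tab["h2_total_pair"].iloc[0]

    def test_unknown_axis(self, common_equal_spec):
        with pytest.raises(ConfigurationError):
            h2_curves("banana", np.array([0.1]), common_equal_spec)
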