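"""Analytic heritability decomposition for binary traits under the
liability-threshold model.

For a disease defined by thresholding a genotype-dependent Gaussian liability
at its population median, the penetrance of every genotype combination is
available in closed form, and broad-sense heritability on the observed
(disease) scale is the variance of penetrance across genotypes divided by
P(D)(1 - P(D)):

    H2_S = sum_{g in S} P(g) (P(D|g) - P(D))^2 / [P(D) (1 - P(D))]

evaluated over any locus subset S after marginalising the joint penetrance.
The interaction component of a pair is the pair total minus both single-locus
marginals; the three-way remainder subtracts all marginals and all pairwise
interactions.  Everything is computed by exact enumeration over the 3^L
genotype table (capped at L = 8), with a Monte-Carlo oracle provided for
cross-checking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .datasets import hwe_genotype_probs
from .errors import CapacityError, ConfigurationError
from .liability import LiabilityModelSpec, linear_predictor
from .scores import ev_weight

__all__ = [
    "LiabilityPopulation",
    "HeritabilityDecomposition",
    "population_threshold",
    "analytic_penetrances",
    "h2_single",
    "h2_pair",
    "h2_marginal",
    "h2_interaction",
    "decompose",
    "h2_curves",
    "mc_penetrances",
]

ENUMERATION_CAP = 8  # 3^8 = 6561 genotype cells


def _enumerate(n_loci: int) -> np.ndarray:
    if n_loci > ENUMERATION_CAP:
        raise CapacityError(
            f"exact enumeration supports up to {ENUMERATION_CAP} loci, got {n_loci}"
        )
    return np.array(list(itertools.product((0, 1, 2), repeat=n_loci)), dtype=np.int8)


class LiabilityPopulation:
    """Exact (infinite-population) view of a liability-threshold model.

    Enumerates all genotype combinations with their HWE probabilities and the
    genetic value mu_G of each; the threshold, penetrances and every
    heritability component derive from these three arrays.
    """

    def __init__(self, spec: LiabilityModelSpec):
        self.spec = spec
        self.combos = _enumerate(spec.n_loci)
        probs_per_locus = [locus.genotype_probs() for locus in spec.loci]
        self.probs = np.ones(len(self.combos))
        for j, p in enumerate(probs_per_locus):
            self.probs *= p[self.combos[:, j]]
        self.mu = linear_predictor(spec, self.combos)
        self.sigma = spec.noise_sd
        self._threshold: float | None = None
        self._penetrances: np.ndarray | None = None

    @property
    def threshold(self) -> float:
        """Population median of Y: the t with sum_G P(G) Phi((t - mu_G)/sigma) = 1/2."""
        if self._threshold is None:
            def cdf_minus_half(t: float) -> float:
                return float(self.probs @ norm.cdf((t - self.mu) / self.sigma) - 0.5)

            lo = float(self.mu.min() - 12.0 * self.sigma)
            hi = float(self.mu.max() + 12.0 * self.sigma)
            t = brentq(cdf_minus_half, lo, hi, xtol=1e-13, rtol=8.9e-16)
            if abs(cdf_minus_half(t)) > 1e-12:
                raise RuntimeError("threshold root-finding did not reach tolerance")
            self._threshold = float(t)
        return self._threshold

    @property
    def penetrances(self) -> np.ndarray:
        """P(D | G) = 1 - Phi((t - mu_G)/sigma) for every genotype combination."""
        if self._penetrances is None:
            self._penetrances = norm.sf((self.threshold - self.mu) / self.sigma)
        return self._penetrances

    @property
    def prevalence(self) -> float:
        return float(self.probs @ self.penetrances)

    def marginal(self, subset: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        """Joint genotype probabilities and penetrances over a locus subset."""
        subset = tuple(subset)
        if any(j < 0 or j >= self.spec.n_loci for j in subset):
            raise ConfigurationError(f"subset {subset} references unknown loci")
        cells = _enumerate(len(subset))
        probs = np.zeros(len(cells))
        pens = np.zeros(len(cells))
        keys = self.combos[:, subset]
        for i, cell in enumerate(cells):
            mask = (keys == cell).all(axis=1)
            probs[i] = self.probs[mask].sum()
            if probs[i] > 0:
                pens[i] = self.probs[mask] @ self.penetrances[mask] / probs[i]
        return probs, pens

    def h2(self, subset: tuple[int, ...]) -> float:
        """Heritability attributable to a locus subset (total for that subset)."""
        pd_ = self.prevalence
        if pd_ <= 0.0 or pd_ >= 1.0:
            raise ConfigurationError("degenerate prevalence; heritability undefined")
        probs, pens = self.marginal(subset)
        return float(probs @ (pens - pd_) ** 2 / (pd_ * (1.0 - pd_)))

    def h2_interaction(self, group: tuple[int, ...]) -> float:
        """Interaction remainder: group total minus all lower-order components."""
        group = tuple(group)
        if len(group) == 2:
            return self.h2(group) - sum(self.h2((j,)) for j in group)
        if len(group) == 3:
            total = self.h2(group)
            total -= sum(self.h2((j,)) for j in group)
            total -= sum(self.h2_interaction(p) for p in itertools.combinations(group, 2))
            return total
        raise ConfigurationError("interaction components defined for pairs and triples")


@dataclass
class HeritabilityDecomposition:
    """All heritability components of one model, as dimensionless proportions."""

    prevalence: float
    threshold: float
    per_locus_marginal: dict = field(default_factory=dict)  # locus_id -> H2_M
    group_totals: dict = field(default_factory=dict)  # "G3G4" -> H2 group total
    pairwise_interaction: dict = field(default_factory=dict)  # "G3G4" -> H2_I
    higher_order_interaction: dict = field(default_factory=dict)
    overall_total: float = 0.0

    def as_frame(self, percent: bool = True) -> pd.DataFrame:
        """Tidy table of components; values in percent by default."""
        scale = 100.0 if percent else 1.0
        rows = [("prevalence", "", self.prevalence)]
        rows += [("marginal", k, v * scale) for k, v in self.per_locus_marginal.items()]
        rows += [("group_total", k, v * scale) for k, v in self.group_totals.items()]
        rows += [("interaction", k, v * scale) for k, v in self.pairwise_interaction.items()]
        rows += [("higher_order", k, v * scale) for k, v in self.higher_order_interaction.items()]
        rows.append(("total", "H2_Total", self.overall_total * scale))
        return pd.DataFrame(rows, columns=["component", "loci", "value"])


# ---------------------------------------------------------------------------
# functional surface


def population_threshold(spec: LiabilityModelSpec) -> float:
    return LiabilityPopulation(spec).threshold


def analytic_penetrances(spec: LiabilityModelSpec, threshold: float | None = None):
    """Map genotype combination -> P(D|G); mixture-weighted mean is 1/2."""
    pop = LiabilityPopulation(spec)
    if threshold is not None:
        pop._threshold = float(threshold)
    return {tuple(int(x) for x in c): float(p) for c, p in zip(pop.combos, pop.penetrances)}


def h2_single(spec_or_pop, locus: int) -> float:
    pop = spec_or_pop if isinstance(spec_or_pop, LiabilityPopulation) else LiabilityPopulation(spec_or_pop)
    return pop.h2((locus,))


def h2_pair(spec_or_pop, pair: tuple[int, int]) -> float:
    pop = spec_or_pop if isinstance(spec_or_pop, LiabilityPopulation) else LiabilityPopulation(spec_or_pop)
    return pop.h2(tuple(pair))


# marginal heritability of one locus within a pair coincides with the
# single-locus expression after marginalisation
h2_marginal = h2_single


def h2_interaction(spec_or_pop, group: tuple[int, ...]) -> float:
    pop = spec_or_pop if isinstance(spec_or_pop, LiabilityPopulation) else LiabilityPopulation(spec_or_pop)
    return pop.h2_interaction(tuple(group))


def _default_grouping(spec: LiabilityModelSpec) -> list[tuple[int, ...]]:
    """Interacting loci grouped by the interaction terms that join them
    (connected components of the interaction graph, via union-find); remaining
    loci pooled into one main-effect group.  An interaction term with
    coefficient 0 still designates its loci as an interacting group."""
    parent = list(range(spec.n_loci))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for term in spec.interactions:
        for a, b in itertools.combinations(term.loci, 2):
            parent[find(a)] = find(b)
    comps: dict[int, list[int]] = {}
    for j in range(spec.n_loci):
        comps.setdefault(find(j), []).append(j)
    groups = []
    mains: list[int] = []
    for comp in comps.values():
        if len(comp) > 1:
            groups.append(tuple(sorted(comp)))
        else:
            mains.extend(comp)
    groups.sort()
    if mains:
        groups.insert(0, tuple(sorted(mains)))
    return groups


def _group_label(spec: LiabilityModelSpec, group: tuple[int, ...]) -> str:
    return "".join(f"G{j + 1}" for j in group)


def decompose(
    spec: LiabilityModelSpec,
    grouping: list[tuple[int, ...]] | None = None,
) -> HeritabilityDecomposition:
    """Assemble the full decomposition under the study's grouping convention.

    A group whose loci share an interaction term contributes its marginals plus
    the pairwise (and, for triples, three-way) interaction remainders; a
    main-effects-only group contributes the sum of its marginals.  Declaring an
    interaction term with coefficient 0 is the way to say "this pair belongs
    together as an interacting unit, currently at zero strength": its (tiny,
    threshold-nonlinearity) interaction remainder is then reported and included
    in the group total.
    """
    pop = LiabilityPopulation(spec)
    if grouping is None:
        grouping = _default_grouping(spec)
    interacting = set()
    for term in spec.interactions:
        interacting.add(tuple(sorted(term.loci)))

    out = HeritabilityDecomposition(prevalence=pop.prevalence, threshold=pop.threshold)
    for j, locus in enumerate(spec.loci):
        out.per_locus_marginal[locus.locus_id] = pop.h2((j,))

    for group in grouping:
        group = tuple(sorted(group))
        if any(j < 0 or j >= spec.n_loci for j in group):
            raise ConfigurationError(f"grouping references unknown loci: {group}")
        label = _group_label(spec, group)
        has_interaction = any(
            set(term.loci) <= set(group) for term in spec.interactions
        )
        marg_sum = sum(pop.h2((j,)) for j in group)
        if has_interaction and len(group) in (2, 3):
            total = marg_sum
            for pair in itertools.combinations(group, 2):
                hi = pop.h2_interaction(pair)
                out.pairwise_interaction[_group_label(spec, pair)] = hi
                total += hi
            if len(group) == 3:
                h3 = pop.h2_interaction(group)
                out.higher_order_interaction[label] = h3
                total += h3
            out.group_totals[label] = total
        else:
            out.group_totals[label] = marg_sum

    out.overall_total = float(sum(out.group_totals.values()))
    return out


def mc_penetrances(
    spec: LiabilityModelSpec, n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo oracle: empirical genotype frequencies and penetrances.

    Draws genotypes and liabilities, dichotomises at the *empirical* median of
    the draw, and tabulates P(D|G) per genotype cell.  Returns (combos, freq,
    penetrance) aligned with :class:`LiabilityPopulation` ordering.
    """
    from .liability import sample_genotypes_hwe

    g = sample_genotypes_hwe(spec.loci, n_draws, rng)
    y = linear_predictor(spec, g) + rng.normal(0.0, spec.noise_sd, size=n_draws)
    d = y > np.median(y)
    combos = _enumerate(spec.n_loci)
    key = np.zeros(n_draws, dtype=np.int64)
    for j in range(spec.n_loci):
        key = key * 3 + g[:, j]
    cell_idx = np.array([int("".join(map(str, c)), 3) for c in combos])
    counts = np.bincount(key, minlength=3 ** spec.n_loci)[cell_idx]
    cases = np.bincount(key, weights=d.astype(float), minlength=3 ** spec.n_loci)[cell_idx]
    freq = counts / n_draws
    with np.errstate(invalid="ignore", divide="ignore"):
        pen = np.where(counts > 0, cases / np.maximum(counts, 1), 0.0)
    return combos, freq, pen


def _sweep_spec(base: LiabilityModelSpec, **overrides) -> LiabilityModelSpec:
    from dataclasses import replace

    return replace(base, **overrides)


def h2_curves(
    axis: str,
    grid: np.ndarray,
    base_spec: LiabilityModelSpec,
    pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Heritability components along a one-dimensional parameter sweep.

    ``axis`` selects what the grid varies for the second locus of ``pair``:

    * ``"ES"`` — its main effect;
    * ``"MAF"`` — its minor-allele frequency (risk allele = minor);
    * ``"RAF"`` — its risk-allele frequency in (0, 1), folding through the
      ``risk_allele_is_minor`` flag above 0.5;
    * ``"interaction"`` — the coefficient of the pair's interaction term.

    For the RAF sweep the table also carries the explained-variance weight
    with the effect size used directly as the log odds ratio, enabling the
    weight-vs-heritability comparison.
    """
    from dataclasses import replace as _replace

    from .liability import InteractionTerm

    a, b = pair
    rows = []
    for value in np.asarray(grid, dtype=float):
        spec = base_spec
        if axis == "RAF" and (value <= 0.0 or value >= 1.0):
            # monomorphic limits: the locus carries no genotypic variance, so
            # its marginal and the pair interaction vanish and the pair total
            # collapses onto the other locus (a fixed genotype only shifts the
            # intercept, which the median threshold absorbs)
            live_terms = tuple(t for t in base_spec.interactions if t.coefficient != 0.0)
            if any(b in t.loci for t in live_terms):
                raise ConfigurationError(
                    "monomorphic RAF endpoints unsupported for interacting loci"
                )
            fixed = 2 if value >= 1.0 else 0
            loci = tuple(l for j, l in enumerate(base_spec.loci) if j != b)
            me = tuple(m for j, m in enumerate(base_spec.main_effects) if j != b)
            reduced = _sweep_spec(
                base_spec,
                loci=loci,
                main_effects=me,
                intercept=base_spec.intercept + fixed * base_spec.main_effects[b],
                interactions=tuple(
                    type(t)(loci=tuple(i - (i > b) for i in t.loci), coefficient=t.coefficient)
                    for t in live_terms
                ),
            )
            pop = LiabilityPopulation(reduced)
            h_a = pop.h2((a - (a > b),))
            rows.append({
                axis: value, "h2_total_pair": h_a, "h2_marginal_1": h_a,
                "h2_marginal_2": 0.0, "h2_interaction": 0.0, "ev_weight": 0.0,
            })
            continue
        if axis == "ES":
            me = list(spec.main_effects)
            me[b] = value
            spec = _sweep_spec(spec, main_effects=tuple(me))
        elif axis in ("MAF", "RAF"):
            loci = list(spec.loci)
            old = loci[b]
            if axis == "MAF":
                maf, minor = value, True
            else:  # RAF in (0,1): fold frequencies above 0.5
                maf = value if value <= 0.5 else 1.0 - value
                minor = value <= 0.5
            loci[b] = type(old)(locus_id=old.locus_id, maf=maf, risk_allele_is_minor=minor)
            spec = _sweep_spec(spec, loci=tuple(loci))
        elif axis == "interaction":
            others = tuple(t for t in spec.interactions if set(t.loci) != {a, b})
            spec = _sweep_spec(
                spec, interactions=others + (InteractionTerm(loci=(a, b), coefficient=value),)
            )
        else:
            raise ConfigurationError(f"unknown sweep axis {axis!r}")
        pop = LiabilityPopulation(spec)
        h_a, h_b = pop.h2((a,)), pop.h2((b,))
        h_ab = pop.h2((a, b))
        row = {
            axis: value,
            "h2_total_pair": h_ab,
            "h2_marginal_1": h_a,
            "h2_marginal_2": h_b,
            "h2_interaction": h_ab - h_a - h_b,
        }
        if axis == "RAF":
            es = spec.main_effects[b]
            maf_b = spec.loci[b].maf
            row["ev_weight"] = ev_weight(float(np.exp(es)), maf_b) if es != 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
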