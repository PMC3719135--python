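"""Two-locus additive-penetrance simulator with a linked non-causal marker.

Disease risk comes from two causal loci acting additively on penetrance:
with baseline penetrance ``k`` and per-locus relative risks ``theta_a``,
``theta_b`` (homozygous risk vs homozygous non-risk), the penetrance of a
genotype pair (g_a, g_b) with g in {0,1,2} risk-allele counts is

    P(D | g_a, g_b) = k + (theta_a - 1) k g_a / 2 + (theta_b - 1) k g_b / 2

so heterozygotes sit exactly halfway between the homozygotes at each locus
(additive mode).  A third marker never enters the penetrance; it is drawn
from a genotype-conditional table given the second causal locus — identical
rows mean no linkage disequilibrium (weak mode), concentrated rows mean
strong LD.  Balanced case-control samples are collected by rejection
sampling from the probabilistic disease model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import CaseControlDataset, hwe_genotype_probs
from .errors import ConfigurationError, SimulationError

__all__ = [
    "PenetranceModelSpec",
    "LDStructure",
    "additive_penetrance_table",
    "sample_linked_genotypes",
    "simulate_ld_case_control",
    "make_train_test_study",
]


def additive_penetrance_table(k: float, theta_a: float, theta_b: float) -> np.ndarray:
    """3x3 penetrance matrix P[g_a][g_b] under the additive two-locus mode.

    Corner cells are ``k`` (no risk alleles), ``theta_a k``, ``theta_b k``
    (single-locus homozygotes) and ``(theta_a + theta_b - 1) k`` (double
    homozygote); interior cells interpolate linearly in each allele count.
    """
    if not 0.0 < k < 1.0:
        raise ConfigurationError(f"baseline penetrance must be in (0, 1), got {k}")
    g = np.arange(3, dtype=float)
    # cell-by-cell table form ...
    table = np.array([
        [k, (theta_b + 1.0) * k / 2.0, theta_b * k],
        [(theta_a + 1.0) * k / 2.0, (theta_a + theta_b) * k / 2.0, (theta_a + 2.0 * theta_b - 1.0) * k / 2.0],
        [theta_a * k, (2.0 * theta_a + theta_b - 1.0) * k / 2.0, (theta_a + theta_b - 1.0) * k],
    ])
    # ... and the equivalent per-locus additive-increment form; they must agree.
    additive = k + np.add.outer((theta_a - 1.0) * k * g / 2.0, (theta_b - 1.0) * k * g / 2.0)
    assert np.allclose(table, additive, atol=1e-12), "penetrance table forms disagree"
    if table.min() < 0.0 or table.max() > 1.0:
        raise ConfigurationError(
            f"penetrance table leaves [0, 1] (k={k}, theta_a={theta_a}, theta_b={theta_b}); "
            f"requires (theta_a + theta_b - 1) * k <= 1"
        )
    return table


@dataclass(frozen=True)
class PenetranceModelSpec:
    """Two causal loci + one marker; defaults follow the standard design:
    k = 0.1, relative risks in {1.25, 1.5, 1.75}, 200 cases / 200 controls."""

    baseline_penetrance: float = 0.1
    relative_risks: tuple[float, float] = (1.5, 1.5)
    mafs: tuple[float, float, float] = (0.4, 0.4, 0.4)  # loci 1, 2, marker 3
    n_cases: int = 200
    n_controls: int = 200
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        ta, tb = self.relative_risks
        if ta < 1.0 or tb < 1.0:
            raise ConfigurationError("relative risks must be >= 1")
        # validates every cell in [0, 1]
        additive_penetrance_table(self.baseline_penetrance, ta, tb)
        for p in self.mafs:
            if not 0.0 < p <= 0.5:
                raise ConfigurationError(f"MAF must be in (0, 0.5], got {p}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("case/control counts must be positive")

    @property
    def penetrance_table(self) -> np.ndarray:
        return additive_penetrance_table(self.baseline_penetrance, *self.relative_risks)

    def with_seed(self, seed: int) -> "PenetranceModelSpec":
        return replace(self, seed=seed)

    def population_prevalence(self) -> float:
        """P(D) by enumeration over the 9-cell joint genotype table (loci 1, 2)."""
        pa = hwe_genotype_probs(self.mafs[0])
        pb = hwe_genotype_probs(self.mafs[1])
        return float(pa @ self.penetrance_table @ pb)


@dataclass(frozen=True)
class LDStructure:
    """Conditional genotype table P(G3 = j | G2 = i), row-stochastic 3x3."""

    conditional: tuple  # 3x3, rows indexed by G2
    mode: str = "strong"  # "strong" | "weak"

    def __post_init__(self) -> None:
        c = np.asarray(self.conditional, dtype=float)
        if c.shape != (3, 3):
            raise ConfigurationError("conditional table must be 3x3")
        if (c < 0).any() or not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("conditional rows must be non-negative and sum to 1")
        object.__setattr__(self, "conditional", tuple(map(tuple, c)))
        if self.mode == "weak" and not np.allclose(c, c[0], atol=1e-12):
            raise ConfigurationError("weak mode requires identical rows (independence)")

    @property
    def table(self) -> np.ndarray:
        return np.asarray(self.conditional, dtype=float)

    @classmethod
    def weak(cls, marker_maf: float) -> "LDStructure":
        """Marker independent of the causal locus: every row is HWE at the marker MAF."""
        row = hwe_genotype_probs(marker_maf)
        return cls(conditional=tuple(map(tuple, np.tile(row, (3, 1)))), mode="weak")

    @classmethod
    def strong(cls, marker_maf: float, self_mass: float = 0.8) -> "LDStructure":
        """Marker tracks the causal genotype: mass ``self_mass`` on G3 = G2 and the
        remainder spread proportionally to the marker's HWE frequencies."""
        if not 0.0 < self_mass < 1.0:
            raise ConfigurationError("self_mass must be in (0, 1)")
        hwe = hwe_genotype_probs(marker_maf)
        c = np.tile((1.0 - self_mass) * hwe, (3, 1))
        c[np.arange(3), np.arange(3)] += self_mass
        c /= c.sum(axis=1, keepdims=True)
        return cls(conditional=tuple(map(tuple, c)), mode="strong")

    def to_dict(self) -> dict:
        return {"conditional": [list(r) for r in self.conditional], "mode": self.mode}

    @classmethod
    def from_dict(cls, d: dict) -> "LDStructure":
        return cls(conditional=tuple(map(tuple, d["conditional"])), mode=d.get("mode", "strong"))


def sample_linked_genotypes(
    mafs: tuple[float, float, float],
    ld: LDStructure,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Loci 1 and 2 independent HWE; marker 3 drawn conditionally on locus 2."""
    g1 = rng.choice(3, size=n, p=hwe_genotype_probs(mafs[0]))
    g2 = rng.choice(3, size=n, p=hwe_genotype_probs(mafs[1]))
    cond = ld.table
    g3 = np.empty(n, dtype=np.int8)
    # inverse-CDF draw per subject, indexed by the subject's G2 row
    u = rng.random(n)
    cum = cond.cumsum(axis=1)
    for i in range(3):
        mask = g2 == i
        g3[mask] = np.searchsorted(cum[i], u[mask], side="right")
    np.clip(g3, 0, 2, out=g3)
    return np.column_stack([g1, g2, g3]).astype(np.int8)


def simulate_ld_case_control(
    spec: PenetranceModelSpec,
    ld: LDStructure,
    replicate_index: int = 0,
    stream: int = 1,
    max_draws: int = 2_000_000,
) -> CaseControlDataset:
    """Rejection-sample subjects until the case and control quotas are filled.

    Disease status is Bernoulli in the penetrance of causal loci 1 and 2 only;
    the marker never enters disease generation.  ``stream`` separates training
    (0) from test (1) seed streams.  Exceeding ``max_draws`` raises
    :class:`SimulationError` with a diagnostic — never silent truncation.
    """
    rng = np.random.default_rng([spec.seed, stream, replicate_index])
    table = spec.penetrance_table
    need_cases, need_controls = spec.n_cases, spec.n_controls
    kept_g, kept_d = [], []
    drawn = 0
    prev = spec.population_prevalence()
    while need_cases > 0 or need_controls > 0:
        deficit = need_cases + need_controls
        batch = int(min(max(4 * deficit / max(min(prev, 1 - prev), 1e-6), 200), 200_000))
        if drawn + batch > max_draws:
            batch = max_draws - drawn
            if batch <= 0:
                raise SimulationError(
                    f"case/control quota unreachable within {max_draws} draws "
                    f"(still need {need_cases} cases, {need_controls} controls; "
                    f"population prevalence {prev:.4f})"
                )
        g = sample_linked_genotypes(spec.mafs, ld, batch, rng)
        pen = table[g[:, 0], g[:, 1]]
        d = (rng.random(batch) < pen).astype(np.int8)
        drawn += batch
        for label, need in ((1, need_cases), (0, need_controls)):
            idx = np.flatnonzero(d == label)[:need]
            if idx.size:
                kept_g.append(g[idx])
                kept_d.append(d[idx])
        need_cases -= min(need_cases, int((d == 1).sum()))
        need_controls -= min(need_controls, int((d == 0).sum()))
    genotypes = np.vstack(kept_g)
    status = np.concatenate(kept_d)
    order = rng.permutation(status.shape[0])
    return CaseControlDataset(
        genotypes=genotypes[order],
        status=status[order],
        replicate_index=replicate_index,
        seed_used=(spec.seed, stream, replicate_index),
        generator="penetrance",
        locus_ids=["SNP1", "SNP2", "SNP3"],
    )


def make_train_test_study(
    spec: PenetranceModelSpec,
    ld: LDStructure,
    n_train: int | None = None,
    n_test: int | None = None,
) -> tuple[list[CaseControlDataset], list[CaseControlDataset]]:
    """Disjoint training and test replicate collections from separated streams.

    Training replicates feed external weight estimation; test replicates feed
    the evaluation harness.  Defaults: ``n_replicates`` of each (the standard
    design uses 100 + 100).
    """
    n_train = spec.n_replicates if n_train is None else n_train
    n_test = spec.n_replicates if n_test is None else n_test
    train = [simulate_ld_case_control(spec, ld, r, stream=0) for r in range(n_train)]
    test = [simulate_ld_case_control(spec, ld, r, stream=1) for r in range(n_test)]
    return train, test
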