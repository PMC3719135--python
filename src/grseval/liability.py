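"""Liability-threshold simulator with product-term epistasis.

A continuous latent trait is generated from genotypes by a linear model

    Y = b0 + sum_i b_i G_i + sum_T c_T prod_{i in T} G_i + e,   e ~ N(0, s^2)

with genotypes drawn independently under Hardy-Weinberg equilibrium, and a
subject is a case iff Y exceeds the replicate's empirical median — giving
exactly 50% prevalence for an even subject count.  Interaction terms are
arbitrary products over locus subsets, covering two-way (c_{34} G3 G4) and
higher-order (c_{345} G3 G4 G5) epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import CaseControlDataset, LocusSpec
from .errors import ConfigurationError

__all__ = [
    "InteractionTerm",
    "LiabilityModelSpec",
    "sample_genotypes_hwe",
    "linear_predictor",
    "simulate_liability_dataset",
]


@dataclass(frozen=True)
class InteractionTerm:
    """A product-interaction term over a set of loci (0-based indices)."""

    loci: tuple[int, ...]
    coefficient: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if len(self.loci) < 2:
            raise ConfigurationError("interaction terms need at least two loci")
        if len(set(self.loci)) != len(self.loci):
            raise ConfigurationError(f"duplicate loci in interaction term {self.loci}")
        if not np.isfinite(self.coefficient):
            raise ConfigurationError("interaction coefficient must be finite")


@dataclass(frozen=True)
class LiabilityModelSpec:
    """Full generative model for one simulation scenario.

    Defaults follow the standard study design: intercept 20, noise variance
    10, balanced 250 cases / 250 controls, 100 replicates.
    """

    loci: tuple[LocusSpec, ...]
    main_effects: tuple[float, ...]
    interactions: tuple[InteractionTerm, ...] = ()
    intercept: float = 20.0
    noise_variance: float = 10.0
    n_cases: int = 250
    n_controls: int = 250
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "main_effects", tuple(float(b) for b in self.main_effects))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        if len(self.main_effects) != len(self.loci):
            raise ConfigurationError("one main effect per locus required")
        if self.noise_variance <= 0:
            raise ConfigurationError("noise variance must be positive")
        if self.n_cases < 1 or self.n_controls < 1 or self.n_replicates < 1:
            raise ConfigurationError("sample and replicate counts must be positive")
        for term in self.interactions:
            if any(i < 0 or i >= len(self.loci) for i in term.loci):
                raise ConfigurationError(f"interaction term {term.loci} references unknown loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def noise_sd(self) -> float:
        return float(np.sqrt(self.noise_variance))

    def with_seed(self, seed: int) -> "LiabilityModelSpec":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "loci": [
                {"locus_id": l.locus_id, "maf": l.maf, "risk_allele_is_minor": l.risk_allele_is_minor}
                for l in self.loci
            ],
            "main_effects": list(self.main_effects),
            "interactions": [
                {"loci": list(t.loci), "coef": t.coefficient} for t in self.interactions
            ],
            "intercept": self.intercept,
            "noise_variance": self.noise_variance,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LiabilityModelSpec":
        loci = tuple(
            LocusSpec(
                locus_id=l.get("locus_id", f"SNP{i + 1}"),
                maf=l["maf"],
                risk_allele_is_minor=l.get("risk_allele_is_minor", True),
            )
            for i, l in enumerate(d["loci"])
        )
        interactions = tuple(
            InteractionTerm(loci=tuple(t["loci"]), coefficient=t["coef"])
            for t in d.get("interactions", [])
        )
        return cls(
            loci=loci,
            main_effects=tuple(d["main_effects"]),
            interactions=interactions,
            intercept=d.get("intercept", 20.0),
            noise_variance=d.get("noise_variance", 10.0),
            n_cases=d.get("n_cases", 250),
            n_controls=d.get("n_controls", 250),
            n_replicates=d.get("n_replicates", 100),
            seed=d.get("seed", 0),
        )


def sample_genotypes_hwe(
    loci: tuple[LocusSpec, ...], n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent HWE genotypes (risk-allele counts) for each locus."""
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be at least 1")
    cols = []
    for locus in loci:
        probs = locus.genotype_probs()
        cols.append(rng.choice(3, size=n_subjects, p=probs))
    return np.column_stack(cols).astype(np.int8)


def linear_predictor(spec: LiabilityModelSpec, genotypes: np.ndarray) -> np.ndarray:
    """Genetic value mu_G = b0 + sum b_i G_i + sum c_T prod G_T (no noise)."""
    g = np.asarray(genotypes, dtype=float)
    mu = spec.intercept + g @ np.asarray(spec.main_effects)
    for term in spec.interactions:
        mu = mu + term.coefficient * g[:, term.loci].prod(axis=1)
    return mu


def simulate_liability_dataset(
    spec: LiabilityModelSpec, replicate_index: int = 0
) -> CaseControlDataset:
    """Draw one replicate and dichotomise at the empirical median.

    Case iff Y strictly exceeds median(Y); ties (measure zero under Gaussian
    noise) break toward control.  Replicate r uses the deterministic child
    stream seeded by (root seed, r), so any replicate is reproducible alone.
    """
    rng = np.random.default_rng([spec.seed, replicate_index])
    n = spec.n_subjects
    g = sample_genotypes_hwe(spec.loci, n, rng)
    y = linear_predictor(spec, g) + rng.normal(0.0, spec.noise_sd, size=n)
    d = (y > np.median(y)).astype(np.int8)
    return CaseControlDataset(
        genotypes=g,
        status=d,
        replicate_index=replicate_index,
        seed_used=(spec.seed, replicate_index),
        generator="liability",
        locus_ids=[l.locus_id for l in spec.loci],
    )


def simulate_study(spec: LiabilityModelSpec) -> list[CaseControlDataset]:
    """All replicates of the scenario, each from its own child stream."""
    return [simulate_liability_dataset(spec, r) for r in range(spec.n_replicates)]
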