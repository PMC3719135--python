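"""Core domain containers shared by the simulators and the scoring code.

Genotypes are always coded as risk-allele counts 0/1/2, one column per locus,
one row per subject.  Disease status ``D`` is 0 (control) / 1 (case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CodingError, ConfigurationError

__all__ = ["LocusSpec", "CaseControlDataset", "hwe_genotype_probs"]


def hwe_genotype_probs(risk_allele_freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for counts (0, 1, 2) of the risk allele."""
    p = float(risk_allele_freq)
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"allele frequency must be in [0, 1], got {p}")
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


@dataclass(frozen=True)
class LocusSpec:
    """One biallelic variant.

    ``maf`` is the minor-allele frequency; genotypes count *risk* alleles, and
    ``risk_allele_is_minor`` records which allele that is.  With the default
    convention (risk = minor) the risk-allele frequency equals the MAF; setting
    the flag to False models risk alleles that are the major allele (risk-allele
    frequency 1 - MAF), which matters for risk-allele-frequency sweeps.
    """

    locus_id: str
    maf: float
    risk_allele_is_minor: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigurationError(
                f"locus {self.locus_id!r}: MAF must be in (0, 0.5], got {self.maf}"
            )

    @property
    def risk_allele_frequency(self) -> float:
        return self.maf if self.risk_allele_is_minor else 1.0 - self.maf

    def genotype_probs(self) -> np.ndarray:
        return hwe_genotype_probs(self.risk_allele_frequency)


def _validate_genotypes(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise CodingError(f"genotype matrix must be 2-D (subjects x loci), got shape {g.shape}")
    if not np.isin(g, (0, 1, 2)).all():
        bad = np.unique(g[~np.isin(g, (0, 1, 2))])
        raise CodingError(f"genotype values outside {{0,1,2}}: {bad.tolist()}")
    return g.astype(np.int8, copy=False)


@dataclass
class CaseControlDataset:
    """Genotypes plus binary affection status for one simulated replicate."""

    genotypes: np.ndarray  # (n_subjects, n_loci) risk-allele counts
    status: np.ndarray  # (n_subjects,) 0 control / 1 case
    replicate_index: int = 0
    seed_used: tuple = ()
    generator: str = "unknown"  # "liability" | "penetrance" | "external"
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = _validate_genotypes(self.genotypes)
        d = np.asarray(self.status)
        if not np.isin(d, (0, 1)).all():
            raise CodingError("status values must be 0 or 1")
        self.status = d.astype(np.int8, copy=False)
        if self.status.shape[0] != self.genotypes.shape[0]:
            raise ConfigurationError("status length does not match genotype rows")
        if not self.locus_ids:
            self.locus_ids = [f"SNP{i + 1}" for i in range(self.genotypes.shape[1])]
        elif len(self.locus_ids) != self.genotypes.shape[1]:
            raise ConfigurationError("locus_ids length does not match genotype columns")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_subjects - self.status.sum())
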