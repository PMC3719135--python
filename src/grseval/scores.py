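"""Genetic risk score construction: simple-count, odds-ratio- and
explained-variance-weighted scores.

Three scores are supported, each summarising a subject's genotype vector
``G = (G_1, ..., G_I)`` of risk-allele counts into one scalar:

* **SC** (simple count): ``sum_i G_i`` — every risk allele counts once.
* **OR** (odds-ratio weighted): ``sum_i log(OR_i) G_i`` — alleles weighted by
  their per-allele log odds ratio, so protective variants (OR < 1) get
  negative weight.
* **EV** (explained-variance weighted): ``sum_i (log OR_i)^2 2 MAF_i (1-MAF_i) G_i``
  — the weight is the per-locus contribution to explained variance on the
  log-odds scale (the classical 2pq beta^2 variance of an additive allelic
  effect), so it grows with both effect size and allele frequency and is
  never negative.

Weighted scores are conventionally *rescaled* by ``I / sum_i w_i`` so that
their magnitude is comparable to the simple count; rescaling is a positive
affine map and therefore leaves logistic-regression inference (LRT p-value,
C-statistic, AIC) unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import CaseControlDataset, LocusSpec, _validate_genotypes
from .errors import ConfigurationError, EstimationError, RescalingError

__all__ = [
    "GRSWeightSet",
    "ScoreVector",
    "simple_count_score",
    "or_weight",
    "ev_weight",
    "weighted_score",
    "estimate_weights_from_training",
]

METHODS = ("SC", "OR", "EV")


@dataclass
class GRSWeightSet:
    """Per-locus weights for one scoring method.

    ``or_estimates`` / ``maf_estimates`` keep the raw ingredients of the
    weights (absent where the method does not use them) so a weight set is
    self-documenting and serialisable.
    """

    method: str
    loci: list[str]
    weights: np.ndarray
    or_estimates: np.ndarray | None = None
    maf_estimates: np.ndarray | None = None
    rescaled: bool = False
    estimation_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}, got {self.method!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.loci) != self.weights.shape[0]:
            raise ConfigurationError("loci and weights length mismatch")
        if self.method == "SC" and not np.all(self.weights == 1.0):
            raise ConfigurationError("SC weight sets must have all weights equal to 1")
        if self.method == "EV" and np.any(self.weights < 0):
            raise ConfigurationError("EV weights cannot be negative")

    @classmethod
    def simple_count(cls, loci: Sequence[str]) -> "GRSWeightSet":
        return cls(method="SC", loci=list(loci), weights=np.ones(len(loci)))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "loci": list(self.loci),
            "weights": self.weights.tolist(),
            "or_estimates": None if self.or_estimates is None else np.asarray(self.or_estimates).tolist(),
            "maf_estimates": None if self.maf_estimates is None else np.asarray(self.maf_estimates).tolist(),
            "rescaled": self.rescaled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRSWeightSet":
        return cls(
            method=d["method"],
            loci=list(d["loci"]),
            weights=np.asarray(d["weights"], dtype=float),
            or_estimates=None if d.get("or_estimates") is None else np.asarray(d["or_estimates"], dtype=float),
            maf_estimates=None if d.get("maf_estimates") is None else np.asarray(d["maf_estimates"], dtype=float),
            rescaled=bool(d.get("rescaled", False)),
        )


@dataclass
class ScoreVector:
    """Per-subject GRS values with provenance."""

    values: np.ndarray
    method: str
    weight_set_id: str | None = None
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def simple_count_score(genotypes: np.ndarray, loci: Sequence | None = None) -> ScoreVector:
    """Sum of risk-allele counts over all loci (integer-valued, in [0, 2I])."""
    g = _validate_genotypes(genotypes)
    if loci is not None:
        if len(loci) == 0:
            raise ConfigurationError("empty locus list")
        if len(loci) != g.shape[1]:
            raise ConfigurationError("locus list length does not match genotype columns")
    elif g.shape[1] == 0:
        raise ConfigurationError("genotype matrix has no loci")
    return ScoreVector(values=g.sum(axis=1).astype(float), method="SC")


def or_weight(odds_ratio: float) -> float:
    """Log-odds-ratio weight; negative for protective variants (OR < 1)."""
    if not odds_ratio > 0:
        raise ConfigurationError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def ev_weight(odds_ratio: float, maf: float) -> float:
    """Explained-variance weight ``(log OR)^2 * 2 * maf * (1 - maf)``.

    Non-negative; zero iff OR = 1; invariant to OR <-> 1/OR inversion and to
    maf <-> 1-maf relabelling.
    """
    if not odds_ratio > 0:
        raise ConfigurationError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 < maf < 1.0:
        raise ConfigurationError(f"maf must be in (0, 1), got {maf}")
    return math.log(odds_ratio) ** 2 * 2.0 * maf * (1.0 - maf)


def weighted_score(
    genotypes: np.ndarray, weight_set: GRSWeightSet, rescale: bool = True
) -> ScoreVector:
    """Weighted allele count ``sum_i w_i G_i``, optionally rescaled by ``I / sum_i w_i``.

    Rescaling makes the score's range comparable to the simple count; because
    it is a positive scalar multiple, it never changes downstream inference.
    """
    g = _validate_genotypes(genotypes)
    w = weight_set.weights
    if g.shape[1] != w.shape[0]:
        raise ConfigurationError(
            f"weight set covers {w.shape[0]} loci but genotypes have {g.shape[1]} columns"
        )
    raw = g @ w
    if not rescale:
        return ScoreVector(values=raw, method=weight_set.method)
    wsum = float(w.sum())
    if wsum <= 0:
        raise RescalingError(
            f"cannot rescale {weight_set.method} score: weight sum {wsum} is not positive"
        )
    return ScoreVector(values=len(w) * raw / wsum, method=weight_set.method)


def _pool_training(training: CaseControlDataset | Iterable[CaseControlDataset]):
    if isinstance(training, CaseControlDataset):
        training = [training]
    training = list(training)
    if not training:
        raise ConfigurationError("no training datasets supplied")
    locus_ids = training[0].locus_ids
    for ds in training[1:]:
        if ds.locus_ids != locus_ids:
            raise ConfigurationError("training datasets have inconsistent loci")
    g = np.vstack([ds.genotypes for ds in training])
    d = np.concatenate([ds.status for ds in training])
    return g, d, locus_ids


def estimate_weights_from_training(
    training: CaseControlDataset | Iterable[CaseControlDataset],
    method: str,
) -> GRSWeightSet:
    """Estimate OR or EV weights from pooled training replicates.

    Each locus gets a univariate logistic regression of disease status on its
    0/1/2 allele count (per-allele odds ratio), fitted on all training
    replicates pooled together.  MAF is the pooled allele frequency, folded to
    the minor allele.  Monomorphic loci cannot be weighted and raise
    :class:`EstimationError`; non-convergent fits are flagged in
    ``estimation_report`` (never silently dropped).
    """
    if method not in ("OR", "EV"):
        raise ConfigurationError(f"weight estimation is for OR or EV, got {method!r}")
    g, d, locus_ids = _pool_training(training)
    if d.min() == d.max():
        raise ConfigurationError("training data must contain both cases and controls")

    log_ors = np.empty(g.shape[1])
    report: dict = {"n_subjects": int(g.shape[0]), "failures": {}}
    monomorphic = [locus_ids[j] for j in range(g.shape[1]) if g[:, j].min() == g[:, j].max()]
    if monomorphic:
        raise EstimationError(
            f"monomorphic loci in training data: {monomorphic}", failed_loci=monomorphic
        )
    for j in range(g.shape[1]):
        x = sm.add_constant(g[:, j].astype(float))
        try:
            res = sm.Logit(d, x).fit(disp=0, maxiter=200)
            log_ors[j] = res.params[1]
            if not res.mle_retvals.get("converged", True):
                report["failures"][locus_ids[j]] = "non-convergence"
        except Exception as exc:  # perfect separation raises in statsmodels
            raise EstimationError(
                f"logistic fit failed at locus {locus_ids[j]}: {exc}",
                failed_loci=[locus_ids[j]],
            ) from exc

    risk_freq = g.mean(axis=0) / 2.0
    maf = np.minimum(risk_freq, 1.0 - risk_freq)
    ors = np.exp(log_ors)
    if method == "OR":
        weights = log_ors
        return GRSWeightSet(
            method="OR", loci=list(locus_ids), weights=weights,
            or_estimates=ors, estimation_report=report,
        )
    weights = np.array([ev_weight(o, m) for o, m in zip(ors, maf)])
    return GRSWeightSet(
        method="EV", loci=list(locus_ids), weights=weights,
        or_estimates=ors, maf_estimates=maf, estimation_report=report,
    )


def score_dataset(
    dataset: CaseControlDataset,
    method: str,
    weight_set: GRSWeightSet | None = None,
    rescale: bool = True,
) -> ScoreVector:
    """Score one dataset with the requested method (SC needs no weight set)."""
    if method == "SC":
        return simple_count_score(dataset.genotypes, dataset.locus_ids)
    if weight_set is None:
        raise ConfigurationError(f"method {method} requires a weight set")
    if weight_set.method != method:
        raise ConfigurationError(
            f"weight set is for {weight_set.method}, requested {method}"
        )
    if weight_set.loci != dataset.locus_ids:
        raise ConfigurationError("weight set loci do not match dataset loci")
    return weighted_score(dataset.genotypes, weight_set, rescale=rescale)


def scores_frame(datasets: Iterable[CaseControlDataset], method: str, **kw) -> pd.DataFrame:
    """Convenience: long-format frame of per-subject scores over replicates."""
    rows = []
    for ds in datasets:
        sv = score_dataset(ds, method, **kw)
        rows.append(pd.DataFrame({
            "replicate": ds.replicate_index,
            "D": ds.status,
            "score": sv.values,
        }))
    return pd.concat(rows, ignore_index=True)
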