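"""Replicate-based evaluation of GRS methods.

Each replicate is analysed with a logistic regression of disease status on a
single GRS predictor, ``logit P(D=1) = alpha + beta * GRS``.  The global fit
is judged by the likelihood-ratio test against the intercept-only null (1 df
chi-square); discrimination by the C-statistic (concordance probability, ties
half-credited, equal to the area under the ROC curve); parsimony by AIC with
k = 2 parameters.  Power (non-null scenarios) or type-I error (null
scenarios) is the fraction of replicates with LRT p below the nominal alpha.
Method differences are assessed with a two-way linear model (method +
scenario) and Tukey's studentized-range adjustment for the three pairwise
method contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import chi2, studentized_range, t as t_dist
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .datasets import CaseControlDataset
from .errors import ConfigurationError
from .scores import GRSWeightSet, score_dataset

__all__ = [
    "GRSFit",
    "EvaluationSummary",
    "fit_grs_model",
    "run_study",
    "pairwise_method_contrasts",
]


@dataclass
class GRSFit:
    """Results of one logistic fit of D on a single GRS."""

    intercept_hat: float
    slope_hat: float
    log_likelihood: float
    null_log_likelihood: float
    lrt_statistic: float
    lrt_pvalue: float
    c_statistic: float
    aic: float
    converged: bool = True


def _null_loglik(status: np.ndarray) -> float:
    n = status.shape[0]
    p = status.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def fit_grs_model(dataset_or_status, scores) -> GRSFit:
    """Maximum-likelihood logistic fit of disease status on one GRS.

    Accepts a :class:`CaseControlDataset` or a raw 0/1 status vector.  A
    constant score is a degenerate but legal input: the model collapses onto
    the null (LRT 0, C-statistic 1/2).  Non-convergence is flagged on the
    returned fit, never silently ignored.
    """
    if isinstance(dataset_or_status, CaseControlDataset):
        status = dataset_or_status.status
    else:
        status = np.asarray(dataset_or_status)
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != status.shape[0]:
        raise ConfigurationError("scores are not aligned with subjects")
    if status.min() == status.max():
        raise ConfigurationError("dataset must contain both cases and controls")

    ll0 = _null_loglik(status)
    c_stat = float(roc_auc_score(status, s)) if np.ptp(s) > 0 else 0.5

    if np.ptp(s) == 0:
        # uninformative predictor: slope pinned at 0, model equals the null
        return GRSFit(
            intercept_hat=float(np.log(status.mean() / (1 - status.mean()))),
            slope_hat=0.0,
            log_likelihood=ll0,
            null_log_likelihood=ll0,
            lrt_statistic=0.0,
            lrt_pvalue=1.0,
            c_statistic=0.5,
            aic=2 * 2 - 2 * ll0,
        )

    x = sm.add_constant(s)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(status, x).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            llf = float(res.llf)
            params = res.params
        except Exception:
            # perfect separation makes the Newton Hessian singular; BFGS still
            # walks the profile deviance to its supremum (llf -> 0), so the
            # replicate is reported with its LRT, flagged as non-converged
            res = sm.Logit(status, x).fit(disp=0, method="bfgs", maxiter=500)
            llf = float(res.llf)
            params = res.params
            converged = False
    lrt = max(0.0, 2.0 * (llf - ll0))
    return GRSFit(
        intercept_hat=float(params[0]),
        slope_hat=float(params[1]),
        log_likelihood=llf,
        null_log_likelihood=ll0,
        lrt_statistic=lrt,
        lrt_pvalue=float(chi2.sf(lrt, df=1)),
        c_statistic=c_stat,
        aic=2 * 2 - 2 * llf,
        converged=converged,
    )


@dataclass
class EvaluationSummary:
    """Aggregated per-method performance over a replicate collection."""

    summary: pd.DataFrame  # one row per method
    per_replicate: pd.DataFrame  # one row per (method, replicate)
    alpha: float = 0.05
    n_replicates: int = 0
    n_failed: dict = field(default_factory=dict)

    def rejection_rate(self, method: str) -> float:
        row = self.summary.set_index("method").loc[method]
        return float(row["rejection_rate"])


def run_study(
    test_replicates: Sequence[CaseControlDataset],
    methods: Iterable[str] = ("SC", "OR", "EV"),
    weight_sets: dict[str, GRSWeightSet] | None = None,
    alpha: float = 0.05,
    scenario: str = "",
) -> EvaluationSummary:
    """Score and fit every test replicate with every method and aggregate.

    ``weight_sets`` maps method name to a prepared weight set (required for OR
    and EV; SC needs none).  Returns rejection rates with 95% Wilson intervals
    plus mean C-statistic and mean AIC per method.
    """
    test_replicates = list(test_replicates)
    if not test_replicates:
        raise ConfigurationError("empty replicate list")
    weight_sets = weight_sets or {}
    rows = []
    n_failed: dict[str, int] = {}
    for method in methods:
        ws = weight_sets.get(method)
        if method != "SC" and ws is None:
            raise ConfigurationError(f"method {method} requires a trained weight set")
        for ds in test_replicates:
            sv = score_dataset(ds, method, weight_set=ws)
            fit = fit_grs_model(ds, sv.values)
            if not fit.converged:
                n_failed[method] = n_failed.get(method, 0) + 1
            rows.append({
                "scenario": scenario,
                "method": method,
                "replicate": ds.replicate_index,
                "lrt_pvalue": fit.lrt_pvalue,
                "c_statistic": fit.c_statistic,
                "aic": fit.aic,
                "converged": fit.converged,
            })
    per_rep = pd.DataFrame(rows)
    summary_rows = []
    for method, sub in per_rep.groupby("method", sort=False):
        k = int((sub["lrt_pvalue"] < alpha).sum())
        n = len(sub)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        summary_rows.append({
            "scenario": scenario,
            "method": method,
            "rejection_rate": k / n,
            "ci_low": lo,
            "ci_high": hi,
            "mean_c": sub["c_statistic"].mean(),
            "mean_aic": sub["aic"].mean(),
            "n_replicates": n,
        })
    return EvaluationSummary(
        summary=pd.DataFrame(summary_rows),
        per_replicate=per_rep,
        alpha=alpha,
        n_replicates=len(test_replicates),
        n_failed=n_failed,
    )


def pairwise_method_contrasts(
    per_replicate: pd.DataFrame,
    metric: str,
    larger_is_better: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-adjusted pairwise method contrasts from a two-way linear model.

    Fits ``metric ~ C(method) + C(scenario)`` by OLS and compares method means
    with the studentized-range distribution on the model's residual scale.
    Returns one row per method pair with the mean difference, adjusted and
    unadjusted p-values, and the winning method (empty when the adjusted p is
    above ``alpha``), the winner being the larger or smaller mean according to
    ``larger_is_better``.
    """
    df = per_replicate.copy()
    required = {"method", metric}
    if not required <= set(df.columns):
        raise ConfigurationError(f"per-replicate frame needs columns {sorted(required)}")
    if "scenario" not in df.columns:
        df["scenario"] = ""
    methods = list(pd.unique(df["method"]))
    if len(methods) < 2:
        raise ConfigurationError("need at least two methods to contrast")
    counts = df.groupby(["method", "scenario"]).size()
    if counts.groupby("scenario").size().nunique() > 1 or counts.nunique() > 1:
        warnings.warn("unbalanced method x scenario cells; contrasts use the pooled residual scale")

    df = df.rename(columns={metric: "_y"})
    multi_scenario = df["scenario"].nunique() > 1
    formula = "_y ~ C(method) + C(scenario)" if multi_scenario else "_y ~ C(method)"
    model = smf.ols(formula, data=df).fit()
    mse = model.mse_resid
    dfr = model.df_resid
    k = len(methods)
    means = df.groupby("method")["_y"].mean()
    ns = df.groupby("method")["_y"].size()

    rows = []
    for m1, m2 in itertools.combinations(methods, 2):
        diff = means[m1] - means[m2]
        se2 = mse * (1.0 / ns[m1] + 1.0 / ns[m2])
        if se2 <= 0 or dfr <= 0:
            q = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
            p_unadj = p_adj
        else:
            q = abs(diff) / np.sqrt(se2 / 2.0)
            p_adj = float(studentized_range.sf(q, k, dfr))
            tval = abs(diff) / np.sqrt(se2)
            p_unadj = float(2.0 * t_dist.sf(tval, dfr))
        winner = ""
        if p_adj < alpha:
            better_is_m1 = (diff > 0) == larger_is_better
            winner = m1 if better_is_m1 else m2
        rows.append({
            "pair": f"{m1}-{m2}",
            "metric": metric,
            "mean_diff": diff,
            "adjusted_p": p_adj,
            "unadjusted_p": p_unadj,
            "winner": winner,
        })
    return pd.DataFrame(rows)
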