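"""Moment estimation, Rubin's-rules pooling, and simulation outcome metrics.

Estimates are pooled on a transform scale chosen per estimand so the
back-transformed confidence intervals respect the parameter space:
correlations are pooled as Fisher z (CI stays inside (−1, 1)), variances on
the log scale (CI stays positive), means and covariances untransformed.
Degrees of freedom follow the Barnard–Rubin small-sample adjustment with
complete-data df n − 1.

The three outcome measures of the Monte Carlo evaluation are the absolute
percent relative bias (PRB), the average 95% confidence-interval width
(CIW), and the confidence-interval coverage (CIC) of the true value, where
"truth" is the mean of the full-data estimates across replications.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParamEstimate",
    "PooledResult",
    "estimate_moments",
    "pool_rubin",
    "evaluate",
    "PRB_FLAG",
    "CIC_FLAG",
]

PRB_FLAG = 10.0  # PRB above this is considered problematic bias
CIC_FLAG = 0.90  # coverage below this is considered problematic


@dataclass
class ParamEstimate:
    """One moment estimate with its SE on the pooling (transform) scale."""

    estimand: str  # mean | variance | covariance | correlation
    columns: tuple[str, ...]
    estimate: float  # natural scale
    transform: str  # identity | log | fisher-z
    est_t: float  # transform scale
    se_t: float  # SE on the transform scale
    n: int

    @property
    def key(self) -> tuple:
        return (self.estimand, self.columns)


@dataclass
class PooledResult:
    """Rubin's rules output for one estimand across m imputations."""

    estimand: str
    columns: tuple[str, ...]
    qbar: float  # pooled point estimate, natural scale
    qbar_t: float  # pooled point estimate, transform scale
    ubar: float  # within-imputation variance (transform scale)
    b: float  # between-imputation variance
    t: float  # total variance
    df: float  # Barnard-Rubin degrees of freedom
    ci_lower: float  # natural scale
    ci_upper: float
    m: int
    transform: str


_BACK = {
    "identity": lambda x: x,
    "log": np.exp,
    "fisher-z": np.tanh,
}


def estimate_moments(
    dataset: pd.DataFrame, targets: Sequence[str]
) -> list[ParamEstimate]:
    """Means, variances, covariances and correlations of the target columns,
    each with a normal-theory SE on its pooling scale.

    mean: identity, se = s/√n; variance: log scale, se = √(2/(n−1));
    covariance: identity, se = √((s_x² s_y² + s_xy²)/(n−1)); correlation:
    Fisher z, se = 1/√(n−3).
    """
    if dataset[list(targets)].isna().any().any():
        raise ValueError("dataset must be complete")
    n = dataset.shape[0]
    if n < 4:
        raise ValueError("need at least 4 rows")
    out: list[ParamEstimate] = []
    x = dataset[list(targets)].to_numpy(dtype=float)
    means = x.mean(axis=0)
    cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    sds = np.sqrt(np.diag(cov))
    if (sds <= 0).any():
        raise ValueError("zero-variance target column")
    for i, col in enumerate(targets):
        out.append(
            ParamEstimate(
                "mean", (col,), means[i], "identity", means[i],
                sds[i] / np.sqrt(n), n,
            )
        )
    for i, col in enumerate(targets):
        v = cov[i, i]
        out.append(
            ParamEstimate(
                "variance", (col,), v, "log", float(np.log(v)),
                float(np.sqrt(2.0 / (n - 1))), n,
            )
        )
    for i, j in combinations(range(len(targets)), 2):
        cols = (targets[i], targets[j])
        c = cov[i, j]
        se = np.sqrt((cov[i, i] * cov[j, j] + c**2) / (n - 1))
        out.append(ParamEstimate("covariance", cols, c, "identity", c, float(se), n))
    for i, j in combinations(range(len(targets)), 2):
        cols = (targets[i], targets[j])
        r = cov[i, j] / (sds[i] * sds[j])
        out.append(
            ParamEstimate(
                "correlation", cols, float(r), "fisher-z", float(np.arctanh(r)),
                float(1.0 / np.sqrt(n - 3)), n,
            )
        )
    return out


def pool_rubin(per_imp: Sequence[ParamEstimate], level: float = 0.95) -> PooledResult:
    """Pool m estimates of one estimand across imputations.

    On the transform scale: q̄ = mean, Ū = mean(se²), B = sample variance of
    the estimates, T = Ū + (1 + 1/m) B; Barnard–Rubin df with complete-data
    df n − 1; the CI bounds are back-transformed to the natural scale.
    """
    m = len(per_imp)
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    keys = {e.key for e in per_imp}
    if len(keys) != 1 or len({e.transform for e in per_imp}) != 1:
        raise ValueError("all estimates must share estimand and transform")
    first = per_imp[0]
    q = np.array([e.est_t for e in per_imp])
    u = np.array([e.se_t**2 for e in per_imp])
    qbar_t = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t = ubar + (1.0 + 1.0 / m) * b

    nu_com = first.n - 1
    if b > 0:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        df_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com * (1.0 - lam)
        df = df_old * df_obs / (df_old + df_obs)
    else:
        df = float(nu_com)
    half = stats.t.ppf(0.5 + level / 2, df) * np.sqrt(t)
    back = _BACK[first.transform]
    return PooledResult(
        estimand=first.estimand,
        columns=first.columns,
        qbar=float(back(qbar_t)),
        qbar_t=qbar_t,
        ubar=ubar,
        b=b,
        t=t,
        df=float(df),
        ci_lower=float(back(qbar_t - half)),
        ci_upper=float(back(qbar_t + half)),
        m=m,
        transform=first.transform,
    )


def evaluate(
    pooled: Sequence[Sequence[PooledResult]],
    full_data_estimates: Sequence[Sequence[ParamEstimate]],
) -> pd.DataFrame:
    """Compute PRB, CIW and CIC per estimand across S replications.

    ``pooled[s]`` holds the pooled results of replication s; the truth for
    each estimand is the mean of its full-data estimates across the S
    replications.  Returns a long-format table with the problematic-bias
    (PRB > 10) and under-coverage (CIC < 0.9) flags.
    """
    S = len(pooled)
    if S < 1 or len(full_data_estimates) != S:
        raise ValueError("pooled and full-data estimates must align, S >= 1")
    keys = [p.key if isinstance(p, ParamEstimate) else (p.estimand, p.columns)
            for p in pooled[0]]
    rows = []
    for key in keys:
        est, ci_lo, ci_hi, truth_s = [], [], [], []
        for s in range(S):
            pr = next(p for p in pooled[s] if (p.estimand, p.columns) == key)
            fu = next(e for e in full_data_estimates[s] if e.key == key)
            est.append(pr.qbar)
            ci_lo.append(pr.ci_lower)
            ci_hi.append(pr.ci_upper)
            truth_s.append(fu.estimate)
        truth = float(np.mean(truth_s))
        mean_est = float(np.mean(est))
        if truth == 0:
            prb = np.nan
            bias_abs = abs(mean_est)
        else:
            prb = abs(mean_est - truth) / abs(truth) * 100.0
            bias_abs = abs(mean_est - truth)
        ciw = float(np.mean(np.array(ci_hi) - np.array(ci_lo)))
        covered = (np.array(ci_lo) <= truth) & (truth <= np.array(ci_hi))
        cic = float(covered.mean())
        rows.append(
            {
                "estimand": key[0],
                "param": ":".join(key[1]),
                "truth": truth,
                "estimate": mean_est,
                "prb": prb,
                "bias_abs": bias_abs,
                "ciw": ciw,
                "cic": cic,
                "S": S,
                "prb_flag": bool(prb > PRB_FLAG) if np.isfinite(prb) else True,
                "cic_flag": cic < CIC_FLAG,
            }
        )
    return pd.DataFrame(rows)
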