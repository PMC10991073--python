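"""Comparator predictor-selection strategies and non-graphical rules for
choosing how many principal components to retain.

``quickpred_select`` mirrors the correlation-thresholding strategy of the R
mice package's quickpred: a column qualifies as predictor when it correlates
with the target *or* with the target's missingness indicator above a
threshold.  ``oracle_select`` encodes the idealized imputer who knows the
missingness mechanism.  ``select_npc`` implements four retention rules from
the eigenvalue scree of a Pearson correlation matrix: the Kaiser criterion
(kc), Horn's parallel analysis (pa), the optimal coordinates index (oc) and
the acceleration factor (af).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasim import DataMatrix, IncompleteData

__all__ = [
    "PredictorSet",
    "EigenProfile",
    "quickpred_select",
    "oracle_select",
    "eigen_profile",
    "select_npc",
]

RULES = ("oc", "af", "kc", "pa")


@dataclass
class PredictorSet:
    target: str
    predictors: list[str]
    rule: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.target in self.predictors:
            raise ValueError("target cannot be its own predictor")


@dataclass
class EigenProfile:
    """Descending eigenvalues of a Pearson correlation matrix, with the row
    count they were computed from (needed by parallel analysis)."""

    eigenvalues: np.ndarray
    n: int
    source: str

    @property
    def p(self) -> int:
        return len(self.eigenvalues)


def _pairwise_corr(a: pd.Series, b: pd.Series) -> float:
    both = a.notna() & b.notna()
    if both.sum() < 3:
        return 0.0
    x, y = a[both], b[both]
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def quickpred_select(
    data: IncompleteData, target: str, threshold: float
) -> PredictorSet:
    """Keep column v iff max(|cor(target, v)|, |cor(δ_target, v)|) ≥
    threshold, on pairwise-complete cases; constant columns are excluded."""
    df = data.values
    if target not in df.columns:
        raise ValueError(f"unknown target {target!r}")
    y = df[target]
    if y.notna().sum() == 0:
        raise ValueError(f"target {target!r} has no observed values")
    delta = y.isna().astype(float)
    chosen = []
    for col in df.columns:
        if col == target:
            continue
        v = df[col]
        if v.dropna().nunique() <= 1:
            continue
        r_y = abs(_pairwise_corr(y, v))
        r_d = abs(_pairwise_corr(delta, v)) if 0 < delta.sum() < len(delta) else 0.0
        if max(r_y, r_d) >= threshold:
            chosen.append(col)
    return PredictorSet(target=target, predictors=chosen, rule="quickpred",
                        threshold=threshold)


def oracle_select(
    target: str, analysis_cols: list[str], mar_predictor_cols: list[str]
) -> PredictorSet:
    """The oracle imputer: remaining analysis-model variables plus the true
    missingness predictors, independent of the data realization."""
    if target not in analysis_cols:
        raise ValueError("target must be one of the analysis columns")
    preds = [c for c in analysis_cols if c != target]
    preds += [c for c in mar_predictor_cols if c not in preds and c != target]
    return PredictorSet(target=target, predictors=preds, rule="oracle")


def eigen_profile(
    data: DataMatrix | IncompleteData | pd.DataFrame,
    source: str = "fully-observed",
) -> EigenProfile:
    """Eigendecompose the Pearson correlation matrix of either the full data
    or its complete cases (rows with zero NAs across all columns)."""
    if source not in ("fully-observed", "complete-cases"):
        raise ValueError(f"unknown source {source!r}")
    df = data if isinstance(data, pd.DataFrame) else data.values
    if source == "complete-cases":
        df = df.dropna(axis=0, how="any")
        p = df.shape[1]
        if df.shape[0] < p + 2:
            raise ValueError(
                f"only {df.shape[0]} complete cases for {p} variables; "
                f"need at least {p + 2}"
            )
    elif df.isna().any().any():
        raise ValueError("fully-observed source requires complete data")
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("constant column in the correlation matrix")
    corr = np.corrcoef(x, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return EigenProfile(eigenvalues=np.clip(evals, 0.0, None), n=x.shape[0],
                        source=source)


def _optimal_coordinates(eig: np.ndarray, baseline: np.ndarray | None = None) -> int:
    # Raiche et al.'s non-graphical formulation: the predicted ("optimal
    # coordinate") eigenvalue at position i is extrapolated from the line
    # through the scree coordinates (i+1, eig[i+1]) and (p, eig[p]); retain
    # the count of positions whose observed eigenvalue meets both its
    # prediction and a baseline (Kaiser's 1 by default, as in nFactors).
    p = len(eig)
    if baseline is None:
        baseline = np.ones(p)
    kept = 0
    for i in range(p - 2):  # 0-based position i; 1-based position i+1
        x1, y1 = i + 2, eig[i + 1]
        x2, y2 = p, eig[p - 1]
        slope = (y2 - y1) / (x2 - x1)
        pred = y1 + slope * ((i + 1) - x1)
        if eig[i] >= pred and eig[i] >= baseline[i]:
            kept += 1
    return max(kept, 1)


def _acceleration_factor(eig: np.ndarray) -> int:
    # second differences of the scree; the elbow precedes the sharpest
    # acceleration, i.e. the maximizer of eig[i-1] - 2 eig[i] + eig[i+1]
    if len(eig) < 3:
        return 1
    accel = eig[:-2] - 2 * eig[1:-1] + eig[2:]  # value at positions 2..p-1
    return max(int(np.argmax(accel)) + 2 - 1, 1)


def select_npc(
    profile: EigenProfile,
    rule: str,
    reps: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    percentile: float | None = None,
) -> int:
    """Number of components to retain according to one of the four rules.

    kc counts eigenvalues above 1; pa counts observed eigenvalues above the
    mean (or a percentile, if given) of eigenvalues from ``reps`` simulated
    independent-normal data sets of the same shape; oc and af are the
    non-graphical scree rules.  All rules return at least 1.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    eig = np.asarray(profile.eigenvalues, dtype=float)
    if rule == "kc":
        return max(int((eig > 1.0).sum()), 1)
    if rule == "af":
        return _acceleration_factor(eig)
    if rule == "oc":
        return _optimal_coordinates(eig)
    # parallel analysis
    rng = np.random.default_rng(seed)
    n, p = profile.n, profile.p
    ref = np.zeros(p)
    for _ in range(reps):
        sim = rng.standard_normal((n, p))
        ref += np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
    ref /= reps
    if percentile is not None:
        # percentile mode recomputes the reference per position
        sims = np.empty((reps, p))
        rng = np.random.default_rng(seed)
        for r in range(reps):
            sim = rng.standard_normal((n, p))
            sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False)))[::-1]
        ref = np.percentile(sims, percentile, axis=0)
    # retain the leading run of eigenvalues above the reference spectrum
    below = eig <= ref
    return max(int(np.argmax(below)) if below.any() else len(eig), 1)
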