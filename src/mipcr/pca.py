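"""Correlation-scale PCA and the three ways of splicing principal-component
scores into the chained-equations engine.

All PCAs here are computed on the Pearson correlation scale (columns are
z-scored before extraction), even for coarsened ordinal items, which are
treated as numeric.  The three strategies differ in *which* variables are
summarized and *when* the basis is (re)fitted:

* ``impute_mi_pcr_aux`` — one fixed basis on the auxiliary variables,
  extracted before MICE; analysis-model variables enter the designs raw.
* ``impute_mi_pcr_all`` — one fixed basis on all variables of a
  singly-imputed completed matrix; the scores are the only predictors, and
  since they are complete a single sweep suffices.
* ``impute_mi_pcr_vbv`` — the basis is refitted on all other columns of the
  current completed matrix at every (chain, iteration, target), so the
  component scores track the evolving imputations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasim import DataMatrix, IncompleteData
from .engine import (
    DEFAULT_RIDGE,
    ImputationResult,
    UnivariateModelSpec,
    raw_builder,
    run_mice,
)

__all__ = [
    "PCABasis",
    "PCScores",
    "fit_pca",
    "project",
    "single_impute_pretreat",
    "impute_mi_pcr_aux",
    "impute_mi_pcr_all",
    "impute_mi_pcr_vbv",
    "resolve_npc",
]

logger = logging.getLogger(__name__)


@dataclass
class PCABasis:
    """Standardization constants plus the weight matrix W (p × q) and the
    full set of eigenvalues of the correlation matrix (descending)."""

    center: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    eigenvalues: np.ndarray

    @property
    def q(self) -> int:
        return self.weights.shape[1]


@dataclass
class PCScores:
    """Component scores Z = standardized(X) W."""

    scores: np.ndarray

    @property
    def q(self) -> int:
        return self.scores.shape[1]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (X - center) / scale, center, scale


def fit_pca(X: np.ndarray, q: int | str = "max") -> tuple[PCABasis, PCScores]:
    """Extract the top-q principal components of the Pearson correlation
    matrix of ``X`` (complete, n × p).

    ``q = "max"`` resolves to min(n − 1, p).  The sign of each weight vector
    is fixed so its largest-magnitude entry is positive, making the output
    deterministic across eigensolver backends.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires complete data")
    n, p = X.shape
    qmax = min(n - 1, p)
    q = qmax if q == "max" else int(q)
    if not 1 <= q <= qmax:
        raise ValueError(f"q must be in [1, {qmax}], got {q}")
    Z, center, scale = _standardize(X)
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    W = evecs[:, order[:q]]
    # deterministic sign: largest-|entry| of each component positive
    flips = np.sign(W[np.abs(W).argmax(axis=0), np.arange(q)])
    flips[flips == 0] = 1.0
    W = W * flips
    basis = PCABasis(center=center, scale=scale, weights=W, eigenvalues=evals)
    return basis, PCScores(scores=Z @ W)


def project(basis: PCABasis, Xnew: np.ndarray) -> PCScores:
    """Project new rows onto a fitted basis (apply stored center/scale,
    multiply by W)."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.shape[1] != basis.weights.shape[0]:
        raise ValueError(
            f"expected {basis.weights.shape[0]} columns, got {Xnew.shape[1]}"
        )
    return PCScores(scores=((Xnew - basis.center) / basis.scale) @ basis.weights)


def resolve_npc(npc: int | str, method: str, p: int, n: int | None = None) -> int:
    """Resolve the requested component count, with ``"max"`` depending on
    the strategy: all auxiliaries (aux), all p variables (all), or the p − 1
    predictors available per target (vbv)."""
    caps = {"aux": p, "all": p, "vbv": p - 1}
    cap = caps[method]
    if n is not None:
        cap = min(cap, n - 1)
    if npc == "max":
        return cap
    npc = int(npc)
    if not 1 <= npc <= cap:
        raise ValueError(f"npc must be in [1, {cap}] for method {method!r}")
    return npc


def _quickpred_specs(
    data: IncompleteData, threshold: float, method: str, ridge: float
) -> list[UnivariateModelSpec]:
    from .selection import quickpred_select  # local import avoids a cycle

    cols = list(data.values.columns)
    col_ix = {c: i for i, c in enumerate(cols)}
    specs = []
    for target in cols:
        if not data.values[target].isna().any():
            continue
        chosen = quickpred_select(data, target, threshold).predictors
        if not chosen:
            logger.warning(
                "no predictor passed threshold %.2f for %r; intercept-only model",
                threshold,
                target,
            )
        specs.append(
            UnivariateModelSpec(
                target=target,
                builder=raw_builder([col_ix[c] for c in chosen]),
                method=method,
                ridge=ridge,
                strategy="quickpred",
            )
        )
    return specs


def single_impute_pretreat(
    data: IncompleteData,
    threshold: float = 0.3,
    maxit: int = 20,
    method: str = "bayes-norm",
    seed: int | np.random.SeedSequence | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> pd.DataFrame:
    """Single imputation used only to enable PC extraction (never for
    inference): one chain, predictors chosen by correlation thresholding."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if not data.values.isna().any().any():
        return data.values.copy()
    specs = _quickpred_specs(data, threshold, method, ridge)
    res = run_mice(data, specs, m=1, maxit=maxit, seed=seed)
    return res.completed[0]


def _incomplete_target_specs(data: IncompleteData) -> list[str]:
    return [c for c in data.values.columns if data.values[c].isna().any()]


def impute_mi_pcr_aux(
    data: IncompleteData,
    analysis_cols: list[str],
    npc: int | str,
    m: int = 5,
    maxit: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    method: str = "bayes-norm",
    ridge: float = DEFAULT_RIDGE,
    pretreat_threshold: float = 0.3,
    pretreat_maxit: int = 20,
) -> ImputationResult:
    """MI-PCR-AUX: each target is imputed from the raw remaining analysis
    columns plus the first npc component scores of the auxiliary variables.

    Any NA among the auxiliaries is first resolved by a single imputation;
    the auxiliary basis is then fitted once and never refitted (auxiliary
    scores are fixed throughout MICE).
    """
    cols = list(data.values.columns)
    missing_analysis = set(analysis_cols) - set(cols)
    if missing_analysis:
        raise ValueError(f"unknown analysis columns: {sorted(missing_analysis)}")
    aux_cols = [c for c in cols if c not in set(analysis_cols)]
    if not aux_cols:
        raise ValueError("no auxiliary columns left after removing analysis columns")
    npc = resolve_npc(npc, "aux", len(aux_cols), data.values.shape[0])
    # feasibility cap: each target's design (raw analysis cols + scores +
    # intercept) must stay smaller than its observed-row count
    n_obs_min = int(data.values.notna().sum().min())
    cap = n_obs_min - (len(analysis_cols) - 1) - 2
    if npc > cap:
        logger.warning("npc %d exceeds feasible cap %d; capping", npc, cap)
        npc = max(cap, 1)

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        seed if seed is not None else None
    )
    pre_seed, mice_seed = root.spawn(2)

    aux = data.values[aux_cols]
    if aux.isna().any().any():
        aux_incomplete = IncompleteData(
            data=DataMatrix(
                values=aux.copy(),
                roles={"T": [], "M": [], "A": aux_cols},
                ncat=data.data.ncat,
                design=data.data.design,
            ),
            response=data.response[aux_cols],
            spec=data.spec,
        )
        aux_filled = single_impute_pretreat(
            aux_incomplete, pretreat_threshold, pretreat_maxit, seed=pre_seed
        )
    else:
        aux_filled = aux
    _, scores = fit_pca(aux_filled.to_numpy(dtype=float), q=npc)
    z_aux = scores.scores

    col_ix = {c: i for i, c in enumerate(cols)}
    specs = []
    for target in _incomplete_target_specs(data):
        raw_ix = [col_ix[c] for c in analysis_cols if c != target]

        def build(filled: np.ndarray, j: int, _raw=tuple(raw_ix)) -> np.ndarray:
            return np.column_stack([filled[:, list(_raw)], z_aux])

        specs.append(
            UnivariateModelSpec(
                target=target, builder=build, method=method, ridge=ridge,
                strategy="pcr-aux",
            )
        )
    return run_mice(data, specs, m=m, maxit=maxit, seed=mice_seed)


def impute_mi_pcr_all(
    data: IncompleteData,
    npc: int | str,
    m: int = 5,
    seed: int | np.random.SeedSequence | None = None,
    method: str = "bayes-norm",
    ridge: float = DEFAULT_RIDGE,
    pretreat_threshold: float = 0.3,
    pretreat_maxit: int = 20,
    pretreat_method: str = "bayes-norm",
    share_pretreat: bool = True,
    maxit: int = 1,
) -> ImputationResult:
    """MI-PCR-ALL: one basis on *all* variables of a singly-imputed matrix;
    the first npc scores are the only predictors of every target.

    The scores are complete by construction, so each of the m imputations
    needs just one sweep (maxit defaults to 1).  By default the m
    imputations share one pretreat fill; set ``share_pretreat=False`` for an
    independent fill per imputation.
    """
    p = data.values.shape[1]
    npc = resolve_npc(npc, "all", p, data.values.shape[0])
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        seed if seed is not None else None
    )
    pre_seed, mice_seed = root.spawn(2)

    def _specs_from_fill(filled: pd.DataFrame) -> list[UnivariateModelSpec]:
        _, scores = fit_pca(filled.to_numpy(dtype=float), q=npc)
        z = scores.scores
        return [
            UnivariateModelSpec(
                target=t,
                builder=lambda filled_, j, _z=z: _z,
                method=method,
                ridge=ridge,
                strategy="pcr-all",
            )
            for t in _incomplete_target_specs(data)
        ]

    if share_pretreat:
        filled = single_impute_pretreat(
            data, pretreat_threshold, pretreat_maxit, pretreat_method, seed=pre_seed
        )
        return run_mice(data, _specs_from_fill(filled), m=m, maxit=maxit, seed=mice_seed)

    completed, traces = [], []
    for i, (ps, ms) in enumerate(zip(pre_seed.spawn(m), mice_seed.spawn(m))):
        filled = single_impute_pretreat(
            data, pretreat_threshold, pretreat_maxit, pretreat_method, seed=ps
        )
        res = run_mice(data, _specs_from_fill(filled), m=1, maxit=maxit, seed=ms)
        completed.append(res.completed[0])
        tr = res.traces.copy()
        tr["chain"] = i
        traces.append(tr)
    return ImputationResult(
        completed=completed, traces=pd.concat(traces, ignore_index=True),
        m=m, maxit=maxit,
    )


def impute_mi_pcr_vbv(
    data: IncompleteData,
    npc: int | str,
    m: int = 5,
    maxit: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> ImputationResult:
    """MI-PCR-VBV: refit the PCA on all other columns of the current
    completed matrix at every (chain, iteration, target) and use the first
    npc scores as the sole predictors of the Bayesian normal sampler.

    Standardization constants are recomputed at every refit, since the
    imputations change the column moments.
    """
    p = data.values.shape[1]
    npc = resolve_npc(npc, "vbv", p, data.values.shape[0])

    def build(filled: np.ndarray, j: int) -> np.ndarray:
        others = np.delete(filled, j, axis=1)
        _, scores = fit_pca(others, q=npc)
        return scores.scores

    specs = [
        UnivariateModelSpec(
            target=t, builder=build, method="bayes-norm", ridge=ridge,
            strategy="pcr-vbv",
        )
        for t in _incomplete_target_specs(data)
    ]
    return run_mice(data, specs, m=m, maxit=maxit, seed=seed)
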