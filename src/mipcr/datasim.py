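"""Synthetic questionnaire data with a confirmatory-factor structure, and
calibrated right-tail MAR amputation.

The generator emulates multi-scale social-survey data: ``n`` respondents
answer items loading on seven latent traits.  The first scale contributes
four analysis items (``T``, which later receive missing values) and four
missingness predictors (``M``); the remaining six scales contribute the
auxiliary pool (``A``).  Missing values are imposed on ``T`` by a logistic
model on the (continuous) ``M`` items whose intercept is root-found so that
each column loses a fixed proportion of cells, concentrated in the right
tail of the predictor score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "LatentDesign",
    "DataMatrix",
    "MissingnessSpec",
    "IncompleteData",
    "build_design",
    "generate_data",
    "discretize_column",
    "solve_mar_intercept",
    "impose_mar",
]

#: permitted noise-variable proportions (share of auxiliary factors whose
#: correlation with the first factor is weak)
PN_LEVELS = (0.0, 0.33, 0.67, 1.0)

#: permitted coarseness levels; ``inf`` keeps items continuous
NCAT_LEVELS = (float("inf"), 7, 5, 3, 2)

N_FACTORS = 7
LOW_CORR = 0.1
HIGH_CORR = 0.7
LOADING = 0.85
TARGET_MEAN = 5.0
TARGET_VAR = 6.5


@dataclass(frozen=True)
class LatentDesign:
    """The factor model generating one simulated questionnaire.

    ``psi`` is the latent correlation matrix (unit diagonal), ``loading``
    the common standardized loading λ, and ``error_var`` the per-item
    uniqueness 1 − λ².  ``items_per_factor[i]`` gives the number of items
    indicating factor ``i``.
    """

    n_factors: int
    items_per_factor: tuple[int, ...]
    loading: float
    psi: np.ndarray
    error_var: float
    target_mean: float = TARGET_MEAN
    target_var: float = TARGET_VAR
    study: int = 1
    pn: float = 0.0

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.shape != (self.n_factors, self.n_factors):
            raise ValueError("psi must be n_factors x n_factors")
        if not np.allclose(psi, psi.T):
            raise ValueError("psi must be symmetric")
        if not np.allclose(np.diag(psi), 1.0):
            raise ValueError("psi must have a unit diagonal")
        if np.linalg.eigvalsh(psi).min() <= 0:
            raise ValueError("psi must be positive definite")
        if not 0 < self.error_var:
            raise ValueError("error variance must be positive")

    @property
    def n_items(self) -> int:
        return int(sum(self.items_per_factor))

    @property
    def lambda_matrix(self) -> np.ndarray:
        """The p × n_factors simple-structure loading matrix Λ."""
        lam = np.zeros((self.n_items, self.n_factors))
        row = 0
        for j, k in enumerate(self.items_per_factor):
            lam[row : row + k, j] = self.loading
            row += k
        return lam

    def population_correlation(self) -> np.ndarray:
        """Closed-form item correlation matrix: λ² Ψ_{f(i) f(j)} off the
        diagonal (within a scale Ψ = 1, hence λ²)."""
        lam = self.lambda_matrix
        rho = lam @ self.psi @ lam.T
        np.fill_diagonal(rho, 1.0)
        return rho


@dataclass
class DataMatrix:
    """A fully observed simulated data set.

    ``values`` holds the (possibly coarsened) items; ``m_continuous`` keeps
    the uncoarsened missingness predictors so the amputation model stays
    equally strong across coarseness levels.
    """

    values: pd.DataFrame
    roles: dict[str, list[str]]
    ncat: float
    design: LatentDesign
    m_continuous: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MissingnessSpec:
    """Right-tail MAR: logit Pr(δ=1) = β0 + Mβ with β0 calibrated."""

    target_prop: float = 0.3
    slopes: tuple[float, ...] | None = None
    mechanism: str = "right-tail MAR"

    def __post_init__(self) -> None:
        if not 0 < self.target_prop < 1:
            raise ValueError("target_prop must lie in (0, 1)")


@dataclass
class IncompleteData:
    """A DataMatrix with NA cells in the analysis items plus the response
    indicator δ (1 = missing) and the amputation spec used."""

    data: DataMatrix
    response: pd.DataFrame
    spec: MissingnessSpec
    intercepts: dict[str, float] = field(default_factory=dict)

    @property
    def values(self) -> pd.DataFrame:
        return self.data.values


def _column_names(items_per_factor: tuple[int, ...]) -> list[str]:
    return [f"x{i + 1}" for i in range(sum(items_per_factor))]


def build_design(pn: float, study: int = 1) -> LatentDesign:
    """Construct the latent design for one simulation-study cell.

    ``pn`` sets the proportion of noise variables in the auxiliary pool:
    round(pn × 6) of the six auxiliary factors correlate 0.1 (instead of
    0.7) with the first factor and with each other.
    """
    if not any(np.isclose(pn, lvl) for lvl in PN_LEVELS):
        raise ValueError(f"pn must be one of {PN_LEVELS}, got {pn!r}")
    if study not in (1, 2):
        raise ValueError(f"study must be 1 or 2, got {study!r}")

    items = (8,) + (8,) * 6 if study == 1 else (8,) + (39,) * 6
    n_noise = int(round(pn * 6))
    # factors 1..6 after the first; the last n_noise are the noise factors
    noisy = np.zeros(N_FACTORS, dtype=bool)
    if n_noise:
        noisy[N_FACTORS - n_noise :] = True
    psi = np.empty((N_FACTORS, N_FACTORS))
    for j in range(N_FACTORS):
        for k in range(N_FACTORS):
            if j == k:
                psi[j, k] = 1.0
            elif noisy[j] or noisy[k]:
                psi[j, k] = LOW_CORR
            else:
                psi[j, k] = HIGH_CORR
    return LatentDesign(
        n_factors=N_FACTORS,
        items_per_factor=items,
        loading=LOADING,
        psi=psi,
        error_var=1.0 - LOADING**2,
        study=study,
        pn=float(pn),
    )


def discretize_column(values: np.ndarray, ncat: float) -> np.ndarray:
    """Coarsen a continuous item into ``ncat`` equal-probability ordinal
    levels 1..ncat (sample-quantile cut points); ``ncat = inf`` is the
    identity."""
    values = np.asarray(values, dtype=float)
    if np.isinf(ncat):
        return values
    ncat = int(ncat)
    if ncat < 2:
        raise ValueError("ncat must be at least 2")
    if len(np.unique(values)) <= ncat:
        raise ValueError("ncat must be smaller than the number of distinct values")
    probs = np.arange(1, ncat) / ncat
    cuts = np.quantile(values, probs)
    return (np.searchsorted(cuts, values, side="left") + 1).astype(float)


def generate_data(
    design: LatentDesign,
    n: int = 500,
    ncat: float = float("inf"),
    seed: int | np.random.SeedSequence | None = None,
) -> DataMatrix:
    """Draw one fully observed data set X = FΛ' + E and rescale every column
    to (approximately) mean 5 and variance 6.5.

    F ~ MVN(0, Ψ), E ~ MVN(0, (1 − λ²) I).  After rescaling, the M and A
    columns are coarsened to ``ncat`` levels; the four T columns always stay
    continuous.  The continuous (pre-coarsening) M columns are retained for
    the amputation model.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (np.isinf(ncat) or int(ncat) in (7, 5, 3, 2)):
        raise ValueError(f"ncat must be one of {NCAT_LEVELS}, got {ncat!r}")
    rng = np.random.default_rng(seed)
    p = design.n_items
    chol = np.linalg.cholesky(design.psi)
    factors = rng.standard_normal((n, design.n_factors)) @ chol.T
    errors = rng.standard_normal((n, p)) * np.sqrt(design.error_var)
    x = factors @ design.lambda_matrix.T + errors
    # per-column sample-moment rescale to the target mean/variance
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    x = x * np.sqrt(design.target_var) + design.target_mean

    cols = _column_names(design.items_per_factor)
    roles = {"T": cols[:4], "M": cols[4:8], "A": cols[8:]}
    m_cont = x[:, 4:8].copy()
    if not np.isinf(ncat):
        for j in range(4, p):
            x[:, j] = discretize_column(x[:, j], ncat)
    return DataMatrix(
        values=pd.DataFrame(x, columns=cols),
        roles=roles,
        ncat=ncat,
        design=design,
        m_continuous=m_cont,
    )


def solve_mar_intercept(linear_predictor: np.ndarray, target_prop: float) -> float:
    """Root-find the logistic intercept β0 so that the mean response
    probability mean(expit(β0 + η)) equals ``target_prop``.

    The bracket is expanded around −mean(η) until it straddles the root;
    tolerance 1e-6 on the achieved proportion.
    """
    eta = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor contains non-finite values")
    if not 0 < target_prop < 1:
        raise ValueError("target_prop must lie in (0, 1)")

    def gap(b0: float) -> float:
        return expit(b0 + eta).mean() - target_prop

    center = -float(eta.mean()) + float(logit(target_prop))
    half = 1.0
    while gap(center - half) > 0 or gap(center + half) < 0:
        half *= 2.0
        if half > 1e6:  # pragma: no cover - degenerate eta
            raise RuntimeError("failed to bracket the MAR intercept")
    return float(brentq(gap, center - half, center + half, xtol=1e-10, rtol=1e-12))


def impose_mar(
    data: DataMatrix,
    spec: MissingnessSpec | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> IncompleteData:
    """Blank cells of the T columns under calibrated right-tail MAR.

    Each T column gets an independent indicator δ ~ Bernoulli(expit(β0 + Mβ))
    with all slopes 1 on the *continuous* M items and β0 freshly calibrated,
    so missingness concentrates where the M scale score is high.
    """
    spec = spec or MissingnessSpec()
    rng = np.random.default_rng(seed)
    m_cols = data.roles["M"]
    m_cont = data.m_continuous
    if m_cont is None:
        m_cont = data.values[m_cols].to_numpy(dtype=float)
    if np.isnan(m_cont).any() or data.values[m_cols].isna().any().any():
        raise ValueError("M columns must be fully observed before amputation")
    slopes = np.asarray(
        spec.slopes if spec.slopes is not None else np.ones(m_cont.shape[1]), float
    )
    if slopes.shape[0] != m_cont.shape[1]:
        raise ValueError("slopes length must match the number of M columns")

    eta = m_cont @ slopes
    values = data.values.copy()
    response = pd.DataFrame(
        np.zeros(values.shape, dtype=int), columns=values.columns, index=values.index
    )
    intercepts: dict[str, float] = {}
    for col in data.roles["T"]:
        b0 = solve_mar_intercept(eta, spec.target_prop)
        delta = rng.random(data.n) < expit(b0 + eta)
        values.loc[delta, col] = np.nan
        response[col] = delta.astype(int)
        intercepts[col] = b0
    out = DataMatrix(
        values=values,
        roles=data.roles,
        ncat=data.ncat,
        design=data.design,
        m_continuous=m_cont,
    )
    return IncompleteData(data=out, response=response, spec=spec, intercepts=intercepts)
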