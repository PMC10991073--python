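"""Orchestration of the factorial Monte Carlo studies.

A study crosses the coarseness of the auxiliary items (nCat ∈ {∞,7,5,3,2})
with the proportion of noise variables (pn ∈ {0, .33, .67, 1}); for each of
S replications of each cell, complete data are generated, amputated, imputed
with every configured (method, npc) pair, analyzed (means, variances,
covariances, correlations of the four incomplete items), pooled by Rubin's
rules, and summarized into PRB/CIW/CIC.  Each (replication, cell) owns an
independent, reproducible seed stream, so results are invariant to execution
order and worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasim, pca, pooling, selection
from .engine import UnivariateModelSpec, raw_builder, run_mice

__all__ = [
    "StudyConfig",
    "ResultStore",
    "impute_with_method",
    "run_study",
    "run_npc_table",
    "run_dataset",
]

logger = logging.getLogger(__name__)

#: methods that take an npc grid
PCR_METHODS = ("vbv", "all", "aux")
RAW_METHODS = ("qp", "oracle")


@dataclass
class StudyConfig:
    study: int = 1
    S: int = 100
    n: int = 500
    ncat_levels: tuple[float, ...] = (float("inf"),)
    pn_levels: tuple[float, ...] = (0.0,)
    methods: dict = field(default_factory=lambda: {"vbv": [8], "qp": None, "oracle": None})
    m: int = 5
    maxit: int = 20
    target_prop: float = 0.3
    quickpred_threshold: float = 0.1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be at least 1")
        for nc in self.ncat_levels:
            if not (np.isinf(nc) or int(nc) in (7, 5, 3, 2)):
                raise ValueError(f"invalid nCat level {nc!r}")
        for pn in self.pn_levels:
            if not any(np.isclose(pn, lvl) for lvl in datasim.PN_LEVELS):
                raise ValueError(f"invalid pn level {pn!r}")
        for meth in self.methods:
            if meth not in PCR_METHODS + RAW_METHODS:
                raise ValueError(f"unknown method {meth!r}")

    def cells(self) -> list[tuple[float, float]]:
        return [(nc, pn) for nc in self.ncat_levels for pn in self.pn_levels]

    def method_grid(self) -> list[tuple[str, int | str | None]]:
        grid: list[tuple[str, int | str | None]] = []
        for meth, npcs in self.methods.items():
            if meth in RAW_METHODS:
                grid.append((meth, None))
            else:
                for npc in npcs or []:
                    grid.append((meth, npc))
        return grid


@dataclass
class ResultStore:
    """Per-replication pooled results and full-data estimates plus run
    metadata, keyed by (cell, rep, method, npc)."""

    config: StudyConfig
    pooled: dict = field(default_factory=dict)  # key -> list[PooledResult]
    full_estimates: dict = field(default_factory=dict)  # (cell, rep) -> list
    errors: list = field(default_factory=list)

    def metrics(self) -> pd.DataFrame:
        """Aggregate PRB/CIW/CIC per (cell, method, npc, estimand)."""
        combos = sorted({k[:2] + k[3:] for k in self.pooled})  # drop rep
        frames = []
        for (ncat, pn, method, npc) in combos:
            reps = sorted(
                r for (nc, p, r, me, q) in self.pooled
                if (nc, p, me, q) == (ncat, pn, method, npc)
            )
            pooled = [self.pooled[(ncat, pn, r, method, npc)] for r in reps]
            full = [self.full_estimates[(ncat, pn, r)] for r in reps]
            tab = pooling.evaluate(pooled, full)
            tab.insert(0, "npc", npc if npc is not None else "")
            tab.insert(0, "method", method)
            tab.insert(0, "pn", pn)
            tab.insert(0, "ncat", ncat)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)


def impute_with_method(
    incomplete: datasim.IncompleteData,
    method: str,
    npc: int | str | None,
    m: int,
    maxit: int,
    seed,
    quickpred_threshold: float = 0.1,
    sampler: str = "bayes-norm",
):
    """Dispatch one imputation run; returns an ImputationResult."""
    roles = incomplete.data.roles
    analysis_cols = roles["T"]
    if method == "vbv":
        return pca.impute_mi_pcr_vbv(incomplete, npc, m=m, maxit=maxit, seed=seed)
    if method == "all":
        return pca.impute_mi_pcr_all(incomplete, npc, m=m, seed=seed)
    if method == "aux":
        return pca.impute_mi_pcr_aux(
            incomplete, analysis_cols, npc, m=m, maxit=maxit, seed=seed
        )
    cols = list(incomplete.values.columns)
    col_ix = {c: i for i, c in enumerate(cols)}
    specs = []
    for target in analysis_cols:
        if not incomplete.values[target].isna().any():
            continue
        if method == "qp":
            chosen = selection.quickpred_select(
                incomplete, target, quickpred_threshold
            ).predictors
        elif method == "oracle":
            chosen = selection.oracle_select(target, analysis_cols, roles["M"]).predictors
        else:
            raise ValueError(f"unknown method {method!r}")
        specs.append(
            UnivariateModelSpec(
                target=target,
                builder=raw_builder([col_ix[c] for c in chosen]),
                method=sampler,
                strategy=method,
            )
        )
    return run_mice(incomplete, specs, m=m, maxit=maxit, seed=seed)


def _cell_seed(base_seed: int, cell_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([base_seed, cell_idx, rep])


def run_study(config: StudyConfig, progress: bool = False) -> ResultStore:
    """Run the full factorial: generate → ampute → impute → pool, per
    replication and cell.  A failing (method, npc) run is recorded in
    ``store.errors`` rather than aborting the study."""
    store = ResultStore(config=config)
    grid = config.method_grid()
    for cell_idx, (ncat, pn) in enumerate(config.cells()):
        design = datasim.build_design(pn, config.study)
        for rep in range(config.S):
            root = _cell_seed(config.base_seed, cell_idx, rep)
            gen_seed, amp_seed, *meth_seeds = root.spawn(2 + len(grid))
            full = datasim.generate_data(design, config.n, ncat, seed=gen_seed)
            targets = full.roles["T"]
            store.full_estimates[(ncat, pn, rep)] = pooling.estimate_moments(
                full.values, targets
            )
            incomplete = datasim.impose_mar(
                full, datasim.MissingnessSpec(config.target_prop), seed=amp_seed
            )
            for (method, npc), ms in zip(grid, meth_seeds):
                try:
                    res = impute_with_method(
                        incomplete, method, npc, config.m, config.maxit, ms,
                        config.quickpred_threshold,
                    )
                    per_imp = [
                        pooling.estimate_moments(c, targets) for c in res.completed
                    ]
                    pooled = [
                        pooling.pool_rubin([est[i] for est in per_imp])
                        for i in range(len(per_imp[0]))
                    ]
                    store.pooled[(ncat, pn, rep, method, npc)] = pooled
                except Exception as exc:  # robustness across hundreds of reps
                    logger.warning(
                        "cell (ncat=%s, pn=%s) rep %d method %s npc %s failed: %s",
                        ncat, pn, rep, method, npc, exc,
                    )
                    store.errors.append(
                        {"ncat": ncat, "pn": pn, "rep": rep, "method": method,
                         "npc": npc, "error": str(exc)}
                    )
            if progress and (rep + 1) % 10 == 0:
                logger.info("cell (ncat=%s, pn=%s): %d/%d reps", ncat, pn,
                            rep + 1, config.S)
    return store


def run_npc_table(
    study: int = 1,
    S: int = 100,
    n: int = 500,
    ncat_levels: Sequence[float] = (float("inf"),),
    pn_levels: Sequence[float] = (0.0,),
    rules: Sequence[str] = ("oc", "af", "kc", "pa"),
    sources: Sequence[str] = ("fully-observed", "complete-cases"),
    target_prop: float = 0.3,
    pa_reps: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Apply the component-retention decision rules to S generated data sets
    per cell and summarize min/median/max of the selected counts, in the
    shape of the retention-rule summary table (long format)."""
    for rule in rules:
        if rule not in selection.RULES:
            raise ValueError(f"unknown rule {rule!r}")
    counts: dict[tuple, list[int]] = {}
    unavailable: set[tuple] = set()
    for cell_idx, (ncat, pn) in enumerate(
        (nc, p) for nc in ncat_levels for p in pn_levels
    ):
        design = datasim.build_design(pn, study)
        for rep in range(S):
            root = _cell_seed(base_seed, cell_idx, rep)
            gen_seed, amp_seed, pa_seed = root.spawn(3)
            full = datasim.generate_data(design, n, ncat, seed=gen_seed)
            incomplete = datasim.impose_mar(
                full, datasim.MissingnessSpec(target_prop), seed=amp_seed
            )
            for source in sources:
                key_src = incomplete if source == "complete-cases" else full
                try:
                    prof = selection.eigen_profile(key_src, source)
                except ValueError:
                    unavailable.add((ncat, pn, source))
                    continue
                for rule in rules:
                    cnt = selection.select_npc(prof, rule, reps=pa_reps, seed=pa_seed)
                    counts.setdefault((ncat, pn, rule, source), []).append(cnt)
    rows = []
    for (ncat, pn, rule, source), vals in sorted(
        counts.items(), key=lambda kv: str(kv[0])
    ):
        arr = np.array(vals)
        rows.append(
            {"P": datasim.build_design(pn, study).n_items, "ncat": ncat, "pn": pn,
             "rule": rule, "source": source, "min": int(arr.min()),
             "median": float(np.median(arr)), "max": int(arr.max()),
             "S": len(vals)}
        )
    for (ncat, pn, source) in sorted(unavailable, key=str):
        rows.append(
            {"P": None, "ncat": ncat, "pn": pn, "rule": "all", "source": source,
             "min": None, "median": None, "max": None, "S": 0}
        )
    return pd.DataFrame(rows)


def run_dataset(
    df: pd.DataFrame,
    method: str = "vbv",
    npc: int | str = "max",
    analysis_cols: Sequence[str] | None = None,
    m: int = 5,
    maxit: int = 20,
    seed: int = 0,
    n_seeds: int = 1,
    quickpred_threshold: float = 0.1,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Generic run-on-your-table mode.

    Imputes ``df`` with the chosen method and returns (completed data sets
    of the last seed, traces of the last seed, pooled report of the analysis
    columns' means across ``n_seeds`` independent seeds).
    """
    analysis_cols = list(analysis_cols or [c for c in df.columns if df[c].isna().any()])
    missing = set(analysis_cols) - set(df.columns)
    if missing:
        raise ValueError(f"unknown analysis columns: {sorted(missing)}")
    for c in df.columns:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} has no observed values")
    dm = datasim.DataMatrix(
        values=df.copy(),
        roles={"T": analysis_cols, "M": [], "A": [c for c in df.columns
                                                  if c not in analysis_cols]},
        ncat=float("inf"),
        design=None,
    )
    incomplete = datasim.IncompleteData(
        data=dm,
        response=df.isna().astype(int),
        spec=datasim.MissingnessSpec(),
    )
    report_rows = []
    completed: list[pd.DataFrame] = []
    traces = pd.DataFrame()
    pool_targets = [c for c in analysis_cols if df[c].isna().any()] or analysis_cols
    for k in range(n_seeds):
        run_seed = np.random.SeedSequence([seed, k])
        if method in ("vbv", "all", "aux"):
            res = impute_with_method(incomplete, method, npc, m, maxit, run_seed)
        else:
            res = impute_with_method(
                incomplete, method, None, m, maxit, run_seed, quickpred_threshold
            )
        completed, traces = res.completed, res.traces
        per_imp = [pooling.estimate_moments(c, pool_targets) for c in res.completed]
        for i, est in enumerate(per_imp[0]):
            if est.estimand != "mean":
                continue
            pooled = pooling.pool_rubin([e[i] for e in per_imp])
            report_rows.append(
                {"seed": k, "column": pooled.columns[0], "mean": pooled.qbar,
                 "ci_lower": pooled.ci_lower, "ci_upper": pooled.ci_upper}
            )
    return completed, traces, pd.DataFrame(report_rows)
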