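import numpy as np
import pandas as pd
import pytest

from mipcr import (
    IncompleteData,
    DataMatrix,
    MissingnessSpec,
    build_design,
    generate_data,
    impose_mar,
)


@pytest.fixture(scope="session")
def design_pn0():
    return build_design(0.0, 1)


@pytest.fixture(scope="session")
def study1_full(design_pn0):
    """One fully observed study-1 data set (n=500, continuous)."""
    return generate_data(design_pn0, 500, float("inf"), seed=11)


@pytest.fixture(scope="session")
def study1_incomplete(study1_full):
    return impose_mar(study1_full, MissingnessSpec(0.3), seed=12)


def make_small_incomplete(n=80, p=5, miss_cols=(0,), prop=0.3, seed=0):
    """A small correlated table with MCAR holes — cheap engine fodder."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 1))
    x = 0.8 * f + 0.6 * rng.standard_normal((n, p))
    cols = [f"v{i + 1}" for i in range(p)]
    df = pd.DataFrame(x, columns=cols)
    for j in miss_cols:
        holes = rng.random(n) < prop
        holes[:3] = False  # keep a few observed rows, always
        df.iloc[holes, j] = np.nan
    dm = DataMatrix(
        values=df,
        roles={"T": [cols[j] for j in miss_cols], "M": [],
               "A": [c for i, c in enumerate(cols) if i not in miss_cols]},
        ncat=float("inf"),
        design=None,
    )
    return IncompleteData(data=dm, response=df.isna().astype(int),
                          spec=MissingnessSpec(prop))


@pytest.fixture
def small_incomplete():
    return make_small_incomplete()
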