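"""QSPR stage: simple linear regression of graph energy on descriptors.

Each framework family is regressed separately: graph energy E_pi (the
response Y) against one descriptor column X over the family's tabulated
reference dimensions, Y = aX + b by ordinary least squares.  Models are
ranked by F statistic (higher is better) with residual standard error as
the tie-break.  Prediction optionally rounds the fitted coefficients to a
fixed number of decimals first, replicating how published regression
equations are quoted and applied at printed precision.

The shipped property table pairs the tabulated descriptor values with the
tabulated energies; recomputed descriptor values differ from the tables
for three of the four families (see :mod:`moftopo.families`), and the
reference regressions demonstrably used the tables, so the tables are the
default input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up
from .descriptors import DESCRIPTOR_NAMES, normalize_descriptor_name
from .families import normalize_family_name

__all__ = [
    "RegressionFit",
    "fit_linear",
    "predict",
    "select_optimal",
    "property_table",
    "family_fits",
    "regression_report",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    n_points: int
    r: float
    r2: float
    adj_r2: float
    se: float  # residual standard error, sqrt(SSE / (n - 2))
    f_stat: float  # inf for an exact fit (flagged, not an error)

    @property
    def exact(self) -> bool:
        return math.isinf(self.f_stat)


def fit_linear(xs: Sequence[float], ys: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x with the full statistic set.

    Requires n >= 3 and non-degenerate x.  A perfect fit yields se = 0 and
    f_stat = inf (flagged via :attr:`RegressionFit.exact`).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.all(x == x[0]):
        raise ValueError("degenerate predictor: all x values equal")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    se = math.sqrt(sse / (n - 2))
    ssr = sst - sse
    f_stat = math.inf if sse == 0.0 else ssr / (sse / (n - 2))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=n,
        r=float(res.rvalue),
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        se=se,
        f_stat=f_stat,
    )


def predict(
    fit: RegressionFit, x: float, round_coefficients_to: Optional[int] = None
) -> float:
    """a*x + b, optionally with a and b first rounded half-up.

    Coefficient rounding replicates predictions made from regression
    equations quoted at fixed printed precision.
    """
    a, b = fit.slope, fit.intercept
    if round_coefficients_to is not None:
        a = round_half_up(a, round_coefficients_to)
        b = round_half_up(b, round_coefficients_to)
    return a * x + b


def select_optimal(
    fits: Sequence[Tuple[str, int, RegressionFit]],
) -> Tuple[str, int, RegressionFit]:
    """Pick the fit with maximal F; ties broken by minimal se, then by
    descriptor enumeration order.  Deterministic."""
    if not fits:
        raise ValueError("no fits to select from")
    order = {name: i for i, name in enumerate(DESCRIPTOR_NAMES)}

    def key(item):
        name, k, fit = item
        return (-fit.f_stat, fit.se, order.get(name, len(order)), k)

    return min(fits, key=key)


def property_table(
    descriptor_csv: Optional[str] = None, energy_csv: Optional[str] = None
) -> pd.DataFrame:
    """Tabulated descriptor values joined with tabulated graph energies.

    Columns: family, m, n, k, descriptor, value, energy — one row per
    (family, dimension, k, descriptor).  Defaults to the reference tables
    shipped with the package; pass CSV paths to use other data.
    """
    if descriptor_csv is None:
        src = resources.files("moftopo.data").joinpath("descriptor_values.csv")
        with resources.as_file(src) as p:
            desc = pd.read_csv(p)
    else:
        desc = pd.read_csv(descriptor_csv)
    if energy_csv is None:
        src = resources.files("moftopo.data").joinpath("graph_energies.csv")
        with resources.as_file(src) as p:
            ener = pd.read_csv(p)
    else:
        ener = pd.read_csv(energy_csv)
    return desc.merge(ener, on=["family", "m", "n"], how="inner")


def family_fits(
    table: pd.DataFrame, family: str, k: int
) -> Dict[str, RegressionFit]:
    """Fit energy ~ descriptor for every descriptor column of one family."""
    family = normalize_family_name(family)
    sub = table[(table["family"] == family) & (table["k"] == k)]
    if sub[["m", "n"]].drop_duplicates().shape[0] < 3:
        raise ValueError(f"fewer than 3 dimensions for {family} at k={k}")
    fits = {}
    for name in DESCRIPTOR_NAMES:
        block = sub[sub["descriptor"] == name].sort_values(["m", "n"])
        if block.empty:
            continue
        fits[name] = fit_linear(block["value"].to_numpy(),
                                block["energy"].to_numpy())
    return fits


def regression_report(table: pd.DataFrame, family: str, k: int) -> pd.DataFrame:
    """Per-descriptor fit summary with display rounding.

    Slope/intercept and the r family at 3 decimals, se at 3, F at 2;
    full-precision fits are available from :func:`family_fits`.
    """
    fits = family_fits(table, family, k)
    rows = []
    for name, fit in fits.items():
        rows.append(
            {
                "descriptor": name,
                "slope": round_half_up(fit.slope, 3),
                "intercept": round_half_up(fit.intercept, 3),
                "r": round_half_up(fit.r, 3),
                "r2": round_half_up(fit.r2, 3),
                "adj_r2": round_half_up(fit.adj_r2, 3),
                "se": round_half_up(fit.se, 3),
                "f_stat": math.inf if fit.exact else round_half_up(fit.f_stat, 2),
            }
        )
    return pd.DataFrame(rows).set_index("descriptor")
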