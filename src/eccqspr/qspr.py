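"""QSPR regression of physicochemical properties on eccentric indices.

Quantitative structure-property relationship (QSPR) modelling regresses a
measured property Y of each drug on a topological descriptor EI of its
molecular graph.  Two model forms are fitted by ordinary least squares:

    linear      Y = alpha + beta * EI
    quadratic   Y = alpha + beta * EI + gamma * EI^2

Model quality is summarised by the multiple correlation coefficient
r = sqrt(R^2), the coefficient of determination R^2 = 1 - SSE/SST, the
overall F statistic

    F = (R^2 / k) / ((1 - R^2) / (n - k - 1)),      k = #predictors,

and its upper-tail p-value under F(k, n-k-1).  A fit is flagged significant
when p <= 0.05, F > 2.5 and r > 0.7 simultaneously (the screening rule used
with these descriptors).

Note that r is reported non-negative even for a negative slope — it is the
multiple correlation of the fitted model, not the signed Pearson r; the sign
of the relationship lives in ``beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import INDEX_COLUMNS

__all__ = [
    "PROPERTY_COLUMNS",
    "RegressionFit",
    "fit_linear",
    "fit_quadratic",
    "f_statistic",
    "p_from_f",
    "significance",
    "correlation_table",
    "fit_all",
]

#: property columns of the drug table: boiling point (degC), melting point
#: (degC), enthalpy of vaporisation (kJ/mol), flash point (degC), molar
#: refractivity (cm^3), structural complexity (unitless), molecular weight
#: (g/mol), refractive index (as printed in the source table).
PROPERTY_COLUMNS = ("BP", "MP", "E", "FP", "MR", "C", "MW", "R")

# R^2 this close to 1 means an exact fit; F would overflow.
_EXACT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class RegressionFit:
    """One fitted property ~ index model and its summary statistics."""

    kind: str                      # "linear" | "quadratic"
    alpha: float                   # intercept
    beta: float                    # linear coefficient
    gamma: float | None            # quadratic coefficient (None for linear)
    r: float                       # multiple correlation, sqrt(r2) >= 0
    r2: float                      # coefficient of determination
    f: float                       # overall F statistic (inf for exact fits)
    p: float                       # upper-tail F-test p-value
    n: int                         # sample size
    flags: dict = field(default_factory=dict)

    def as_record(self) -> dict:
        rec = {"model": self.kind, "alpha": self.alpha, "beta": self.beta,
               "gamma": self.gamma, "r": self.r, "r2": self.r2,
               "f": self.f, "p": self.p, "n": self.n}
        rec.update({k: bool(v) for k, v in self.flags.items()})
        return rec


def f_statistic(r2: float, n: int, k: int) -> float:
    """Overall-regression F from R^2: (R^2/k) / ((1-R^2)/(n-k-1))."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must lie in [0, 1); got {r2} (exact fits have no finite F)")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 residual degrees of freedom (n={n}, k={k})")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def p_from_f(f: float, k: int, d: int) -> float:
    """Upper-tail probability of the F(k, d) distribution at ``f``."""
    if f < 0:
        raise ValueError("F statistic cannot be negative")
    if k < 1 or d < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.sf(f, k, d))


def _ols(design: np.ndarray, y: np.ndarray, kind: str) -> RegressionFit:
    n, p = design.shape
    k = p - 1
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError(
            f"rank-deficient design for {kind} fit (rank {rank} < {p}); "
            "the predictor is constant or has too few distinct values")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("response is constant; R^2 undefined")
    r2 = 1.0 - sse / sst
    r2 = min(max(r2, 0.0), 1.0)
    if 1.0 - r2 < _EXACT_FIT_TOL:
        r2 = 1.0
        f_val, p_val = math.inf, 0.0
    else:
        f_val = f_statistic(r2, n, k)
        p_val = p_from_f(f_val, k, n - k - 1)
    fit = RegressionFit(
        kind=kind,
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=float(coef[2]) if p == 3 else None,
        r=math.sqrt(r2),
        r2=r2,
        f=f_val,
        p=p_val,
        n=n,
    )
    return RegressionFit(**{**fit.__dict__, "flags": significance(fit)})


def _as_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors; got {x.shape} and {y.shape}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def fit_linear(x, y) -> RegressionFit:
    """OLS fit of y = alpha + beta*x with r, R^2, F and p."""
    x, y = _as_xy(x, y, min_n=3)
    return _ols(np.column_stack([np.ones_like(x), x]), y, "linear")


def fit_quadratic(x, y) -> RegressionFit:
    """OLS fit of y = alpha + beta*x + gamma*x^2 with r, R^2, F and p."""
    x, y = _as_xy(x, y, min_n=4)
    if len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    return _ols(np.column_stack([np.ones_like(x), x, x * x]), y, "quadratic")


def significance(fit: RegressionFit) -> dict:
    """Screening flags: p <= 0.05, F > 2.5 (strict), r > 0.7 (strict)."""
    p_ok = fit.p <= 0.05
    f_ok = fit.f > 2.5
    r_ok = fit.r > 0.7
    return {"p_ok": p_ok, "f_ok": f_ok, "r_ok": r_ok,
            "overall": p_ok and f_ok and r_ok}


_FITTERS = {"linear": fit_linear, "quadratic": fit_quadratic}


def fit_all(indices: pd.DataFrame, props: pd.DataFrame,
            models: tuple[str, ...] = ("linear", "quadratic")) -> list[dict]:
    """Fit every property ~ index pair for the requested model kinds.

    Both frames are indexed by drug id; rows are aligned on the shared ids
    and a mismatch is an error.  A constant index column is reported as a
    degenerate record (``error`` field) rather than aborting the batch.
    """
    missing = set(indices.index).symmetric_difference(props.index)
    if missing:
        raise ValueError(f"drug ids do not match between tables: {sorted(missing)}")
    props = props.loc[indices.index]
    records = []
    for model in models:
        if model not in _FITTERS:
            raise ValueError(f"unknown model kind {model!r}")
        for idx_name in INDEX_COLUMNS:
            x = indices[idx_name].to_numpy(dtype=float)
            for prop_name in PROPERTY_COLUMNS:
                y = props[prop_name].to_numpy(dtype=float)
                rec = {"property": prop_name, "index": idx_name}
                try:
                    rec.update(_FITTERS[model](x, y).as_record())
                except ValueError as exc:
                    rec.update({"model": model, "error": str(exc)})
                records.append(rec)
    return records


def correlation_table(indices: pd.DataFrame, props: pd.DataFrame,
                      model: str = "linear", ndigits: int | None = 4) -> pd.DataFrame:
    """8x8 table of correlation coefficients r, indices as rows, properties
    as columns (the layout of the published comparison tables)."""
    recs = fit_all(indices, props, models=(model,))
    table = pd.DataFrame(index=list(INDEX_COLUMNS), columns=list(PROPERTY_COLUMNS),
                         dtype=float)
    for rec in recs:
        if "error" in rec:
            continue
        table.loc[rec["index"], rec["property"]] = rec["r"]
    if ndigits is not None:
        table = table.round(ndigits)
    return table
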