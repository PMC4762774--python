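"""Two-descriptor QSPR regression with leave-one-out validation.

The model family is fixed: an ordinary least-squares fit of one
thermodynamic property on the two eigenvalue descriptors,

    P = a1 + a2 * XP1 + a3 * XP2.

``XPRegression`` is the model object (built from arrays or a DataFrame);
``fit()`` returns an ``XPRegressionResults`` carrying the coefficients,
their standard errors and the usual QSPR quality statistics: the multiple
correlation coefficient R = sqrt(1 - SSE/SST), its adjusted form, the
standard error of estimate S, the Fisher F statistic, and leave-one-out
cross-validation results (PRESS, q2 = 1 - PRESS/SST and the square-root
form r_cv = sqrt(q2), which is the scale on which cross-validated
correlation coefficients are conventionally quoted alongside R).

LOO predictions use the hat-matrix identity e_(-i) = e_i / (1 - h_ii);
rows with leverage one fall back to an explicit refit without that row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary."""

    y_pred: np.ndarray  # out-of-sample prediction per row
    press: float        # sum of squared out-of-sample residuals
    q2: float           # 1 - PRESS/SST
    r_cv: float         # sqrt(max(0, q2))
    ss: float           # sqrt(sum (y - y_pred)^2 / (n - 1))
    ds: float           # sqrt(sum (y - y_mean)^2 / (n - 1))

    def to_dict(self) -> dict:
        return {"press": self.press, "q2": self.q2, "r_cv": self.r_cv,
                "ss": self.ss, "ds": self.ds}


@dataclass
class AREResult:
    """Average relative error (%) with the zero-denominator exclusion count."""

    value: float
    n_used: int
    n_excluded: int


class XPRegression:
    """OLS model of a property on descriptor columns.

    Parameters
    ----------
    y
        Observed property values (length n).
    X
        Descriptor matrix, shape (n, p), without intercept column.
    ids, property_name, descriptor_names
        Labels used in summaries and serialized output.
    """

    def __init__(self, y, X, ids=None, property_name: str = "y",
                 descriptor_names: tuple[str, ...] = ("xp1", "xp2")):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("y and X row counts differ")
        self.n, self.p = self.X.shape
        if self.n < self.p + 2:
            raise ValueError(f"need at least {self.p + 2} rows, got {self.n}")
        self.ids = list(ids) if ids is not None else list(range(self.n))
        self.property_name = property_name
        self.descriptor_names = tuple(descriptor_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, property_col: str,
                       descriptor_cols: tuple[str, ...] = ("xp1", "xp2"),
                       id_col: str | None = None) -> "XPRegression":
        """Build a model from a table, dropping rows with a missing property."""
        cols = [*descriptor_cols, property_col]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        sub = df.dropna(subset=[property_col])
        if sub[list(descriptor_cols)].isna().any().any():
            raise ValueError("missing descriptor values in retained rows")
        ids = sub[id_col] if id_col else sub.index
        return cls(sub[property_col].to_numpy(), sub[list(descriptor_cols)].to_numpy(),
                   ids=list(ids), property_name=property_col,
                   descriptor_names=tuple(descriptor_cols))

    def fit(self) -> "XPRegressionResults":
        exog = sm.add_constant(self.X, has_constant="add")
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            raise ValueError("descriptor columns are collinear (rank-deficient design)")
        res = sm.OLS(self.y, exog).fit()
        return XPRegressionResults(self, res)


class XPRegressionResults:
    """Fitted-model container; all statistics derive from the OLS fit."""

    def __init__(self, model: XPRegression, sm_results):
        self.model = model
        self._sm = sm_results
        self.params = np.asarray(sm_results.params)   # (a1, a2, ..., a_{p+1})
        self.bse = np.asarray(sm_results.bse)
        self.n = model.n
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.resid = np.asarray(sm_results.resid)
        self.sse = float(sm_results.ssr)
        self.sst = float(sm_results.centered_tss)
        self.r = float(np.sqrt(max(0.0, sm_results.rsquared)))
        self.r_adj = float(np.sqrt(max(0.0, sm_results.rsquared_adj)))
        self.s_err = float(np.sqrt(sm_results.mse_resid))
        self.f_stat = float(sm_results.fvalue)
        self._cv: CVReport | None = None

    # -- prediction ------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Apply a1 + sum_k a_k x_k to new descriptor rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.p:
            raise ValueError(f"expected {self.model.p} descriptors, got {X.shape[1]}")
        return self.params[0] + X @ self.params[1:]

    # -- leave-one-out ---------------------------------------------------
    def loo(self) -> CVReport:
        """Leave-one-out CV via the hat-matrix shortcut (refit fallback)."""
        if self._cv is not None:
            return self._cv
        y = self.model.y
        h = OLSInfluence(self._sm).hat_matrix_diag
        e_loo = np.empty(self.n)
        ok = 1.0 - h > 1e-10
        e_loo[ok] = self.resid[ok] / (1.0 - h[ok])
        for i in np.flatnonzero(~ok):
            mask = np.ones(self.n, bool)
            mask[i] = False
            exog = sm.add_constant(self.model.X[mask], has_constant="add")
            beta = np.linalg.lstsq(exog, y[mask], rcond=None)[0]
            e_loo[i] = y[i] - (beta[0] + self.model.X[i] @ beta[1:])
        y_pred = y - e_loo
        press = float(e_loo @ e_loo)
        q2 = 1.0 - press / self.sst
        self._cv = CVReport(
            y_pred=y_pred, press=press, q2=q2, r_cv=float(np.sqrt(max(0.0, q2))),
            ss=float(np.sqrt(press / (self.n - 1))),
            ds=float(np.sqrt(self.sst / (self.n - 1))))
        return self._cv

    @property
    def press(self) -> float:
        return self.loo().press

    @property
    def r_cv(self) -> float:
        return self.loo().r_cv

    # -- reporting -------------------------------------------------------
    def to_dict(self) -> dict:
        cv = self.loo()
        return {
            "property": self.model.property_name,
            "descriptors": list(self.model.descriptor_names),
            "n": self.n,
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "R": self.r,
            "R_adj": self.r_adj,
            "S": self.s_err,
            "F": self.f_stat,
            "PRESS": cv.press,
            "q2": cv.q2,
            "r_cv": cv.r_cv,
            "Ss": cv.ss,
            "Ds": cv.ds,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable fit summary (6 significant digits)."""
        names = ("intercept", *self.model.descriptor_names)
        cv = self.loo()
        lines = [
            f"QSPR model: {self.model.property_name} ~ "
            + " + ".join(self.model.descriptor_names),
            f"  n = {self.n}",
        ]
        for name, a, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:<10s} {a: #.6g} +/- {se:#.6g}")
        lines += [
            f"  R = {self.r:#.6g}   R_adj = {self.r_adj:#.6g}   r_cv = {cv.r_cv:#.6g}",
            f"  S = {self.s_err:#.6g}   F = {self.f_stat:#.6g}   PRESS = {cv.press:#.6g}",
        ]
        return "\n".join(lines)


def average_relative_error(y_cal, y_pre, eps: float = 1e-6) -> AREResult:
    """Mean of 100 |y_pre - y_cal| / |y_cal| over rows with |y_cal| >= eps."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pre = np.asarray(y_pre, dtype=float).ravel()
    if y_cal.shape != y_pre.shape:
        raise ValueError("y_cal and y_pre lengths differ")
    keep = np.abs(y_cal) >= eps
    if not keep.any():
        raise ValueError("all rows excluded by the zero-denominator guard")
    are = 100.0 * np.mean(np.abs(y_pre[keep] - y_cal[keep]) / np.abs(y_cal[keep]))
    return AREResult(value=float(are), n_used=int(keep.sum()),
                     n_excluded=int((~keep).sum()))


def relative_property(df: pd.DataFrame, value_col: str, group_col: str,
                      out_col: str | None = None) -> pd.DataFrame:
    """Within-group relative values: y - min(y) per group.

    Groups of size one get a missing value (no isomer to compare against),
    mirroring the undefined relative-Gibbs entries for the parent compound
    and the fully substituted congener.
    """
    if group_col not in df.columns:
        raise KeyError(f"missing group column {group_col!r}")
    out_col = out_col or f"{value_col}_rel"
    out = df.copy()
    grouped = out.groupby(group_col)[value_col]
    rel = out[value_col] - grouped.transform("min")
    rel[grouped.transform("size") == 1] = np.nan
    out[out_col] = rel
    return out


def read_property_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited property table with a header row."""
    return pd.read_csv(path, sep=sep)


def write_property_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
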