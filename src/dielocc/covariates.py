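"""Covariate transformation, standardization, and collinearity screening.

Non-categorical site covariates are (optionally) log-transformed toward
normality and then standardized to mean 0, sd 1 before entering the
occurrence and detection models; binary covariates are left untouched.
Screening computes pairwise Spearman rank correlations and per-covariate
variance inflation factors and reports — but does not drop — covariates
violating the configured thresholds (|r| and VIF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformRecord",
    "standardize",
    "inverse_standardize",
    "standardize_table",
    "spearman_matrix",
    "vif",
    "screen",
    "ScreeningReport",
    "DEFAULT_R_MAX",
    "DEFAULT_VIF_MAX",
]

# thresholds the study covariates satisfied
DEFAULT_R_MAX = 0.62
DEFAULT_VIF_MAX = 3.1

#: covariates log-transformed by default (strictly positive / right-skewed
#: landscape quantities); the set is configurable per analysis
DEFAULT_LOG_SET = frozenset({"Elv", "Prk", "Rd250", "Rd500", "Pch250", "Pch500"})

#: covariates never transformed or standardized (binary indicators)
BINARY_COVARIATES = frozenset({"NF.plot"})


@dataclass(frozen=True)
class TransformRecord:
    """Enough information to invert a standardization exactly."""

    name: str
    log_transform: bool
    shift: float  # applied inside the log: log(x + shift)
    mean: float
    sd: float


def standardize(
    column: np.ndarray, log_transform: bool = False, name: str = ""
) -> tuple[np.ndarray, TransformRecord]:
    """Standardize one numeric column to mean 0, sd 1.

    With ``log_transform`` the column first passes through ``log(x + s)``
    where the shift ``s`` is 0 for strictly positive columns and half the
    smallest positive value when zeros are present (road density can be
    exactly zero).
    """
    x = np.asarray(column, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"column {name or '<unnamed>'} is constant")
    shift = 0.0
    if log_transform:
        if (x < 0).any():
            raise ValueError(f"column {name or '<unnamed>'}: negative values under log")
        if (x == 0).any():
            positive = x[x > 0]
            if positive.size == 0:
                raise ValueError(f"column {name or '<unnamed>'} is all zeros")
            shift = 0.5 * float(positive.min())
        x = np.log(x + shift)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    z = (x - mean) / sd
    return z, TransformRecord(name=name, log_transform=log_transform, shift=shift,
                              mean=mean, sd=sd)


def inverse_standardize(z: np.ndarray, record: TransformRecord) -> np.ndarray:
    x = np.asarray(z, dtype=float) * record.sd + record.mean
    if record.log_transform:
        x = np.exp(x) - record.shift
    return x


def standardize_table(
    table: pd.DataFrame,
    columns: list[str],
    log_set: frozenset[str] | set[str] = DEFAULT_LOG_SET,
) -> tuple[pd.DataFrame, dict[str, TransformRecord]]:
    """Standardize the named columns of a site table; binaries pass through."""
    out = table[columns].copy().astype(float)
    records: dict[str, TransformRecord] = {}
    for col in columns:
        if col in BINARY_COVARIATES:
            continue
        z, rec = standardize(out[col].to_numpy(), col in log_set, name=col)
        out[col] = z
        records[col] = rec
    return out, records


def spearman_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of the covariate columns."""
    if len(X) < 3:
        raise ValueError("need at least 3 sites for rank correlations")
    rho = stats.spearmanr(X.to_numpy(float), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=X.columns, columns=X.columns)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 − R²) from
    regressing each column on all the others.

    Exactly collinear columns are reported as ``inf``; the caller gets the
    culprit names from the returned index.
    """
    Z = X.to_numpy(float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    n, p = Z.shape
    values = np.empty(p)
    for c in range(p):
        target = Z[:, c]
        others = np.delete(Z, c, axis=1)
        if others.shape[1] == 0:
            values[c] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(target @ target)
        if ss_res / ss_tot < 1e-12:
            values[c] = np.inf
        else:
            values[c] = ss_tot / ss_res
    return pd.Series(values, index=X.columns, name="VIF")


@dataclass(frozen=True)
class ScreeningReport:
    correlations: pd.DataFrame
    vifs: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    flagged_vifs: list[tuple[str, float]]
    r_max: float
    vif_max: float

    @property
    def passed(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vifs

    def to_frame(self) -> pd.DataFrame:
        """Upper-triangle correlations with VIFs appended as the last row."""
        out = self.correlations.where(
            np.triu(np.ones_like(self.correlations, dtype=bool), k=1)
        )
        out.loc["VIF"] = self.vifs
        return out


def screen(
    X: pd.DataFrame, r_max: float = DEFAULT_R_MAX, vif_max: float = DEFAULT_VIF_MAX
) -> ScreeningReport:
    """Collinearity screen: flag covariate pairs with |Spearman r| ≥ r_max
    and covariates with VIF ≥ vif_max.  Advisory — nothing is dropped."""
    if r_max <= 0 or vif_max <= 0:
        raise ValueError("screening thresholds must be positive")
    corr = spearman_matrix(X)
    vifs = vif(X)
    cols = list(X.columns)
    pairs = [
        (cols[a], cols[b], float(corr.iloc[a, b]))
        for a in range(len(cols))
        for b in range(a + 1, len(cols))
        if abs(corr.iloc[a, b]) >= r_max
    ]
    # an infinite threshold disables the VIF check entirely
    flagged_v = [
        (c, float(v)) for c, v in vifs.items()
        if np.isfinite(vif_max) and v >= vif_max
    ]
    return ScreeningReport(corr, vifs, pairs, flagged_v, r_max, vif_max)
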