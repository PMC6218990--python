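"""Survival dataset container and delimited-file input.

The model works on right-censored survival outcomes ``(T_i, delta_i)``
together with a high-dimensional marker matrix ``X`` (genotypes, expression,
methylation, ...) and a low-dimensional clinical covariate matrix ``Z``
whose first column is the intercept.  Marker columns are standardised
(mean 0, unit sample SD) once at construction; the scaling constants are
kept so effects can be mapped back to the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "read_survival_table", "read_marker_matrix"]


class DataError(ValueError):
    """Invalid survival/marker input."""


@dataclass
class SurvivalDataset:
    """Right-censored survival data with markers and clinical covariates.

    Parameters
    ----------
    times
        Observed times ``T_i = min(t_i, c_i)``, strictly positive.
    events
        Event indicators ``delta_i`` (1 = event observed, 0 = right-censored).
    X
        ``(n, p)`` marker matrix.  Standardised in place unless
        ``standardize=False`` (pass pre-scaled columns in that case).
    Z
        ``(n, q)`` clinical covariate matrix *without* intercept, or None.
        An all-ones intercept column is always prepended.
    """

    times: np.ndarray
    events: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None = None
    marker_names: list[str] | None = None
    standardize: bool = True
    x_center: np.ndarray = field(init=False)
    x_scale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        self.events = np.asarray(self.events, dtype=np.float64).ravel()
        self.X = np.array(self.X, dtype=np.float64, order="F", copy=True)
        n = self.times.shape[0]
        if self.events.shape[0] != n or self.X.shape[0] != n:
            raise DataError("times, events and X must have matching row counts")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise DataError("all survival times must be finite and > 0")
        if not np.isin(self.events, (0.0, 1.0)).all():
            raise DataError("event indicators must be coded 0/1")
        if self.Z is None:
            Z = np.ones((n, 1))
        else:
            Zc = np.asarray(self.Z, dtype=np.float64)
            if Zc.ndim == 1:
                Zc = Zc[:, None]
            if Zc.shape[0] != n:
                raise DataError("Z row count must match n")
            Z = np.column_stack([np.ones(n), Zc])
        self.Z = Z
        if self.marker_names is None:
            self.marker_names = [f"m{j}" for j in range(self.X.shape[1])]
        if self.standardize:
            self.x_center = self.X.mean(axis=0)
            self.x_scale = self.X.std(axis=0, ddof=1)
            if np.any(self.x_scale == 0):
                bad = [self.marker_names[j] for j in np.flatnonzero(self.x_scale == 0)]
                raise DataError(f"constant marker columns cannot be scaled: {bad}")
            self.X -= self.x_center
            self.X /= self.x_scale
        else:
            p = self.X.shape[1]
            self.x_center = np.zeros(p)
            self.x_scale = np.ones(p)
        self.log_times = np.log(self.times)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        """Number of clinical covariates (intercept excluded)."""
        return self.Z.shape[1] - 1

    def unscale_beta(self, beta: np.ndarray) -> np.ndarray:
        """Map marker effects from the standardised to the original scale."""
        return np.asarray(beta) / self.x_scale


def _read_delimited(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_survival_table(
    path: str,
    time_col: str = "time",
    event_col: str = "event",
    covar_cols: list[str] | None = None,
) -> dict:
    """Read time / event / clinical covariates from a delimited table.

    Rows with missing time, event or covariate values are rejected (the row
    indices are named); zero or negative survival times are rejected, the
    same validation applied when cleaning real cohorts.  Returns a dict with
    keys ``times``, ``events``, ``Z`` (or None) and ``ids``.
    """
    df = _read_delimited(path)
    for col in [time_col, event_col] + list(covar_cols or []):
        if col not in df.columns:
            raise DataError(f"column {col!r} not found in {path}")
    t = pd.to_numeric(df[time_col], errors="coerce")
    e = pd.to_numeric(df[event_col], errors="coerce")
    bad = df.index[t.isna() | e.isna()].tolist()
    if bad:
        raise DataError(f"missing/non-numeric time or event in rows {bad}")
    bad = df.index[t <= 0].tolist()
    if bad:
        raise DataError(f"zero or negative survival time in rows {bad}")
    if not e.isin([0, 1]).all():
        raise DataError(f"event column {event_col!r} must be coded 0/1")
    Z = None
    if covar_cols:
        Zdf = df[covar_cols].apply(pd.to_numeric, errors="coerce")
        bad = df.index[Zdf.isna().any(axis=1)].tolist()
        if bad:
            raise DataError(f"missing covariate values in rows {bad}")
        Z = Zdf.to_numpy(dtype=float)
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return {"times": t.to_numpy(float), "events": e.to_numpy(float), "Z": Z, "ids": ids}


def read_marker_matrix(
    path: str,
    ids: np.ndarray | None = None,
    id_col: str | None = None,
    impute_mean: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Read an n x p numeric marker matrix from a delimited file.

    If ``id_col`` is given, rows are realigned to match ``ids`` from the
    survival table (error if the ID sets differ).  Constant columns are
    dropped with a warning naming them.  Missing values are an error unless
    ``impute_mean`` is set, in which case they are replaced by the column
    mean (the usual handling for sporadically missing genotypes).
    """
    df = _read_delimited(path)
    if id_col is None and len(df.columns) and str(df.columns[0]).lower() == "id":
        id_col = df.columns[0]
    if id_col is not None:
        if id_col not in df.columns:
            raise DataError(f"id column {id_col!r} not found")
        df = df.set_index(id_col)
        if ids is not None:
            if set(df.index) != set(np.asarray(ids).tolist()):
                raise DataError("marker matrix IDs do not match survival table IDs")
            df = df.loc[np.asarray(ids)]
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        if impute_mean:
            mat = mat.fillna(mat.mean())
        else:
            cols = mat.columns[mat.isna().any()].tolist()
            raise DataError(f"missing marker values in columns {cols}")
    if ids is not None and len(mat) != len(ids):
        raise DataError("marker matrix row count does not match survival table")
    sd = mat.std(ddof=1)
    const = sd.index[sd == 0].tolist()
    if const:
        warnings.warn(f"dropping constant marker columns: {const}")
        mat = mat.drop(columns=const)
    return mat.to_numpy(dtype=float), [str(c) for c in mat.columns]
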