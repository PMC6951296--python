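"""Paired allometric observations and coordinate mappings.

An allometric dataset is a set of paired positive measurements (x, y):
a size covariate x (leaf area, body mass, DBH, ...) and a trait response
y (biomass, chela mass, ...). Zero-intercept allometry works in two
coordinate systems:

* arithmetical space -- the original (x, y) scales;
* geometrical space -- the log-transformed plane (u, v) = (ln x, ln y).

Both views are cached on the dataset; natural logarithms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AllometricDataset", "load_dataset", "to_geometric", "write_fitted_table"]


@dataclass(frozen=True)
class AllometricDataset:
    """Paired positive (x, y) observations with cached log transforms.

    Attributes
    ----------
    x, y : ndarray
        Arithmetic-scale covariate and response; strictly positive.
    u, v : ndarray
        Natural logarithms of ``x`` and ``y``.
    labels : tuple of str
        Column labels carried through from the source file. Units are
        opaque: they are whatever the labels say.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray = field(default=None)  # type: ignore[assignment]
    v: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: tuple = ("x", "y")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("need at least two observations")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in dataset")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError(
                "zero-intercept allometry requires strictly positive x and y"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "u", np.log(x))
        object.__setattr__(self, "v", np.log(y))

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n


def load_dataset(
    path,
    x_column: str | None = None,
    y_column: str | None = None,
    delimiter: str | None = None,
    strict: bool = False,
) -> AllometricDataset:
    """Read a two-column delimited text file into an :class:`AllometricDataset`.

    Column order defaults to (x, y); ``x_column``/``y_column`` headers
    override. Rows with missing or non-positive values are dropped with a
    logged warning (``strict=True`` raises instead), because field data
    sheets routinely contain zeros and blanks.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns")
    if x_column is None:
        x_column = df.columns[0]
    if y_column is None:
        y_column = df.columns[1]
    for col in (x_column, y_column):
        if col not in df.columns:
            raise KeyError(f"{path}: column {col!r} not found")
    xy = df[[x_column, y_column]].apply(pd.to_numeric, errors="coerce")
    ok = xy.notna().all(axis=1) & (xy > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        msg = f"{path}: dropped {n_dropped} rows with missing or non-positive values"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    xy = xy[ok]
    if len(xy) < 2:
        raise ValueError(f"{path}: fewer than two valid rows remain")
    return AllometricDataset(
        x=xy[x_column].to_numpy(),
        y=xy[y_column].to_numpy(),
        labels=(str(x_column), str(y_column)),
    )


def to_geometric(ds: AllometricDataset) -> tuple[np.ndarray, np.ndarray]:
    """Return the geometric-space coordinates (u, v) = (ln x, ln y)."""
    return ds.u, ds.v


def write_fitted_table(path, ds: AllometricDataset, v_hat: np.ndarray) -> None:
    """Write a TSV of observations, fitted values and residuals.

    ``v_hat`` is the geometric-space fitted mean; the arithmetic-scale
    fitted value column is its plain exponential (no correction factor).
    """
    v_hat = np.asarray(v_hat, dtype=float)
    pd.DataFrame(
        {
            "x": ds.x,
            "y": ds.y,
            "y_hat": np.exp(v_hat),
            "u": ds.u,
            "v": ds.v,
            "v_hat": v_hat,
            "residual": ds.v - v_hat,
        }
    ).to_csv(path, sep="\t", index=False)
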