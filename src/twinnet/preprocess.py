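"""Skewness screening and nonparanormal Gaussianization.

Gaussian graphical model estimation assumes roughly normal margins.  To
preserve the original data where possible, only columns whose absolute
sample skewness exceeds a threshold (default 1.0) are transformed; the
transform is the rank-based nonparanormal map (inverse normal CDF of a
Winsorized empirical CDF), which preserves ranks exactly and therefore
leaves rank correlations untouched.  Transformation is applied within the
analysis group whose network is being estimated, not on pooled samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fast

logger = logging.getLogger("twinnet")


@dataclass
class PreprocessReport:
    """Per-column record of the screening decisions actually taken."""

    columns: list[str]
    raw_skewness: np.ndarray
    transformed: np.ndarray
    post_skewness: np.ndarray
    n_used: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.columns,
            "raw_skewness": self.raw_skewness,
            "transformed": self.transformed,
            "post_skewness": self.post_skewness,
        })

    def to_json(self, path) -> None:
        payload = {
            "n_used": int(self.n_used),
            "threshold": float(self.threshold),
            "variables": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def sample_skewness(column) -> float:
    """Unadjusted Fisher-Pearson skewness g1 = m3 / m2^{3/2}."""
    x = np.asarray(column, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("skewness needs at least 3 observations")
    value = _fast.skewness_g1(x)
    if np.isnan(value):
        raise ValueError("constant column: skewness undefined")
    return float(value)


def nonparanormal_transform(column) -> np.ndarray:
    """Rank-Gaussianize one column (Winsorized-ECDF nonparanormal).

    Output is Phi^{-1} of the truncated empirical CDF, with truncation
    constant delta_n = 1/(4 n^{1/4} sqrt(pi log n)), standardized to mean 0
    and unit sample variance.  Ties share a value; ranks are preserved
    exactly, so the map is idempotent.
    """
    x = np.asarray(column, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("nonparanormal transform needs n >= 10")
    if np.all(x == x[0]):
        raise ValueError("constant column: cannot transform")
    return _fast.npn_transform(x)


def preprocess_matrix(table, threshold: float = 1.0,
                      missing: str = "complete"
                      ) -> tuple[np.ndarray, PreprocessReport]:
    """Screen and transform a full individuals-by-variables matrix.

    Columns with |g1| <= threshold are standardized but otherwise left
    alone; the rest are nonparanormal-transformed.  Rows with missing
    values are dropped by default (``missing="complete"``); with
    ``missing="pairwise"`` each column is screened and transformed on its
    own observed entries and NaNs are kept in place for a downstream
    pairwise-complete correlation (logged, since the resulting
    correlation matrix is not guaranteed positive semidefinite).
    ``n_used`` records the complete-case count either way.  Raises on
    constant columns, warns when n < p (the network stays estimable
    thanks to regularization).
    """
    if isinstance(table, pd.DataFrame):
        columns = [str(c) for c in table.columns]
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        columns = [f"col{j}" for j in range(X.shape[1])]
    if X.ndim != 2:
        raise ValueError("expected a 2-D table")
    if missing not in ("complete", "pairwise"):
        raise ValueError("missing must be 'complete' or 'pairwise'")
    complete = ~np.isnan(X).any(axis=1)
    n_dropped = int((~complete).sum())
    pairwise = missing == "pairwise" and n_dropped > 0
    if n_dropped and not pairwise:
        logger.info("preprocess: dropped %d incomplete rows", n_dropped)
        X = X[complete]
    n, p = X.shape
    if (n if not pairwise else int(complete.sum())) < 3:
        raise ValueError("need at least 3 complete rows")
    if n < p:
        warnings.warn(f"n={n} < p={p}: correlations are rank-deficient; "
                      "regularized estimation remains possible")
    if pairwise:
        logger.warning("preprocess: pairwise-complete mode; %d rows have "
                       "missing values and are used where observed",
                       n_dropped)
        Z = np.full_like(X, np.nan)
        flags = np.zeros(p, dtype=bool)
        raw_skew = np.empty(p)
        post_skew = np.empty(p)
        for j in range(p):
            obs = ~np.isnan(X[:, j])
            col = np.ascontiguousarray(X[obs, j][:, None])
            zj, fj, rj, pj = _fast.preprocess_core(col, float(threshold))
            Z[obs, j] = zj[:, 0]
            flags[j], raw_skew[j], post_skew[j] = fj[0], rj[0], pj[0]
    else:
        Z, flags, raw_skew, post_skew = _fast.preprocess_core(
            np.ascontiguousarray(X), float(threshold))
    if np.isnan(raw_skew).any():
        bad = [columns[j] for j in np.flatnonzero(np.isnan(raw_skew))]
        raise ValueError(f"constant column(s): {bad}")
    n = int(complete.sum()) if pairwise else n
    for j in np.flatnonzero(flags):
        logger.info("preprocess: nonparanormal transform applied to %s "
                    "(skew %.2f -> %.2f)", columns[j], raw_skew[j],
                    post_skew[j])
    report = PreprocessReport(columns=columns, raw_skewness=raw_skew,
                              transformed=flags, post_skewness=post_skew,
                              n_used=n, threshold=float(threshold))
    return Z, report
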