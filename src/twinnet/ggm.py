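"""Sparse Gaussian graphical model estimation (EBIC-selected glasso).

The estimator maximizes the penalized log-likelihood

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |theta_ij|

over positive definite precision matrices Theta, where S is the sample
correlation matrix of the (preprocessed) data.  A log-spaced grid of 100
penalties from lambda_max (the smallest penalty yielding an empty graph)
down to lambda_max * 0.01 is fitted by blockwise coordinate descent with
warm starts, and the model with the lowest Extended Bayesian Information
Criterion,

    EBIC = -2 ll + E log(n) + 4 E gamma log(p),

is selected (E = number of nonzero upper-triangle entries, gamma = 0.5 by
default to guard against spurious edges).  Edge weights are the partial
correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from ._fast import EDGE_EPS

logger = logging.getLogger("twinnet")

DEFAULT_GAMMA = 0.5
DEFAULT_N_LAMBDAS = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01
GLASSO_TOL = 1e-8
GLASSO_MAX_ITER = 500


class GlassoConvergenceError(RuntimeError):
    pass


@dataclass
class NetworkModel:
    """A selected sparse partial-correlation network."""

    node_labels: list[str]
    W: np.ndarray              # partial correlations, zero diagonal
    Theta: np.ndarray          # selected precision matrix
    lambda_selected: float
    ebic_value: float
    gamma: float
    n: int

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int((np.abs(np.triu(self.Theta, 1)) > EDGE_EPS).sum())

    def edge_list(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.p, 1)
        mask = np.abs(self.W[i, j]) > EDGE_EPS
        return pd.DataFrame({
            "node_i": [self.node_labels[a] for a in i[mask]],
            "node_j": [self.node_labels[b] for b in j[mask]],
            "weight": self.W[i, j][mask],
        })


@dataclass
class PenaltyPath:
    """Per-penalty fits along the glasso path."""

    lambdas: np.ndarray
    edge_counts: np.ndarray
    logliks: np.ndarray
    ebics: np.ndarray
    selected_index: int
    thetas: np.ndarray | None = field(default=None, repr=False)


def _validate_cov(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    return np.ascontiguousarray(0.5 * (S + S.T))


def glasso_fit(S, lam: float, tol: float = GLASSO_TOL,
               max_iter: int = GLASSO_MAX_ITER) -> np.ndarray:
    """Solve one graphical-lasso problem; diagonal entries are unpenalized.

    Raises :class:`GlassoConvergenceError` if the coordinate-descent sweeps
    do not stabilize within ``max_iter``.
    """
    S = _validate_cov(S)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    W = S.copy()
    Beta = np.zeros_like(S)
    theta, sweeps, converged = _fast.glasso_core(S, float(lam), W, Beta,
                                                 tol, max_iter)
    if not converged:
        raise GlassoConvergenceError(
            f"glasso did not converge in {sweeps} sweeps "
            f"(lambda={lam:.4g}, p={S.shape[0]}, tol={tol:.1e})")
    return theta


def precision_to_partial(theta) -> np.ndarray:
    """w_ij = -theta_ij / sqrt(theta_ii * theta_jj), zero diagonal."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.diag(theta) <= 0):
        raise ValueError("invalid precision matrix: non-positive diagonal")
    return _fast.partial_from_precision(np.ascontiguousarray(theta))


def ebic(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC; gamma = 0 reduces to the ordinary BIC."""
    if n_edges < 0:
        raise ValueError("edge count must be >= 0")
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    return (-2.0 * loglik + n_edges * np.log(n)
            + 4.0 * n_edges * gamma * np.log(p))


def kkt_residual(S, theta, lam: float) -> float:
    """Worst violation of the glasso stationarity conditions.

    For off-diagonal entries: |[Theta^{-1} - S]_ij| <= lam where theta_ij=0
    and [Theta^{-1} - S]_ij = lam * sign(theta_ij) elsewhere; the diagonal
    (unpenalized) must satisfy [Theta^{-1}]_ii = S_ii.
    """
    S = np.asarray(S, dtype=float)
    theta = np.asarray(theta, dtype=float)
    R = np.linalg.inv(theta) - S
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    zero = off & (np.abs(theta) <= EDGE_EPS)
    nonzero = off & ~zero
    worst = np.abs(np.diag(R)).max()
    if zero.any():
        worst = max(worst, float(np.maximum(np.abs(R[zero]) - lam, 0).max()))
    if nonzero.any():
        worst = max(worst, float(np.abs(R[nonzero]
                                        - lam * np.sign(theta[nonzero])).max()))
    return float(worst)


def estimate_network(data, gamma: float = DEFAULT_GAMMA,
                     n_lambdas: int = DEFAULT_N_LAMBDAS,
                     lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                     node_labels: list[str] | None = None,
                     store_path_models: bool = False,
                     edge_threshold: bool = True,
                     missing: str = "complete",
                     ) -> tuple[NetworkModel, PenaltyPath]:
    """Fit the full penalty path on ``data`` and select the EBIC minimizer.

    ``data`` is an individuals-by-variables matrix, assumed already
    preprocessed (see :mod:`twinnet.preprocess`); estimation operates on
    its Pearson correlation matrix, so column scaling is irrelevant.  Ties
    in EBIC break toward the larger penalty (sparser model).

    With ``edge_threshold`` (the default), edges of the selected model
    whose partial correlation falls below log(p(p-1)/2)/sqrt(n) are set to
    zero.  Penalized-likelihood EBIC selection admits spurious edges of
    tiny magnitude when the sample is large; this consistency bound (the
    rule behind qgraph's ``threshold`` option) removes them while leaving
    genuine edges intact.  Path fits in :class:`PenaltyPath` stay raw so
    their optimality conditions remain checkable.
    """
    if isinstance(data, pd.DataFrame):
        if node_labels is None:
            node_labels = [str(c) for c in data.columns]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    n, p = X.shape
    if node_labels is None:
        node_labels = [f"V{j + 1}" for j in range(p)]
    if np.isnan(X).any():
        if missing != "pairwise":
            raise ValueError("data contain NaN; preprocess with "
                             "complete-case deletion or pass "
                             "missing='pairwise'")
        frame = pd.DataFrame(X)
        counts = frame.notna().astype(int)
        pair_n = (counts.T @ counts).to_numpy()
        n = int(np.median(pair_n[np.triu_indices(p, 1)]))
        logger.warning("estimate_network: pairwise-complete correlations; "
                       "using median pairwise n=%d for the EBIC", n)
        C = frame.corr(min_periods=3).to_numpy()
        if np.isnan(C).any():
            raise ValueError("pairwise correlations undefined for some "
                             "variable pairs")
    else:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [node_labels[j] for j in np.flatnonzero(sds == 0)]
            raise ValueError(f"degenerate (constant) column(s): {bad}")
        C = np.corrcoef(X, rowvar=False)
    if n <= 10:
        raise ValueError("need n > 10 observations")
    C = np.ascontiguousarray(0.5 * (C + C.T))
    np.fill_diagonal(C, 1.0)
    lambdas = _fast.lambda_grid(C, int(n_lambdas), float(lambda_min_ratio))
    if lambdas[0] <= 0:
        # perfectly diagonal correlation matrix: empty network
        theta = np.eye(p)
        model = NetworkModel(node_labels, np.zeros((p, p)), theta, 0.0,
                             float(ebic(0.5 * n * 0.0, 0, n, p, gamma)),
                             gamma, n)
        path = PenaltyPath(lambdas, np.zeros(n_lambdas, dtype=int),
                           np.zeros(n_lambdas), np.zeros(n_lambdas), 0)
        return model, path
    thetas_out = (np.empty((n_lambdas, p, p))
                  if store_path_models else np.empty((0, p, p)))
    theta_best, idx, edge_counts, logliks, ebics, ok = _fast.ebic_path_core(
        C, n, float(gamma), lambdas, GLASSO_TOL, GLASSO_MAX_ITER,
        thetas_out, bool(store_path_models))
    if not ok:
        raise GlassoConvergenceError("positive definiteness lost along the "
                                     "penalty path")
    W = precision_to_partial(theta_best)
    if edge_threshold:
        tau = _fast.edge_threshold_value(n, p)
        theta_best = theta_best.copy()
        removed = (np.abs(W) < tau) & ~np.eye(p, dtype=bool)
        W[removed] = 0.0
        theta_best[removed] = 0.0
    model = NetworkModel(node_labels=list(node_labels), W=W,
                         Theta=theta_best,
                         lambda_selected=float(lambdas[idx]),
                         ebic_value=float(ebics[idx]), gamma=float(gamma),
                         n=int(n))
    path = PenaltyPath(lambdas=lambdas, edge_counts=edge_counts,
                       logliks=logliks, ebics=ebics, selected_index=int(idx),
                       thetas=thetas_out if store_path_models else None)
    return model, path
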