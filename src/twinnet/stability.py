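"""Bootstrap diagnostics for estimated networks.

Three related procedures, all of which re-run the full estimation pipeline
(skew screening, nonparanormal transform, EBIC-glasso) on each resample:

* case-dropping bootstrap and the correlation-stability (CS) coefficient —
  the largest proportion of cases that can be dropped such that, with 95%
  probability, the subsample node centralities still correlate at least
  0.7 with the full-sample centralities.  Values above 0.25 indicate a
  stable network; above 0.5 is preferable.  The drop grid runs from 0.05
  to 0.75 in steps of 0.05, so 0.75 is the largest reportable value.
* nonparametric bootstrap confidence intervals for edge weights
  (percentile intervals; narrower intervals mean a more reliable network),
* bootstrapped difference tests for pairs of edges or of node
  centralities (a pair differs when the percentile interval of the
  bootstrap difference distribution excludes zero).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .ggm import (DEFAULT_GAMMA, DEFAULT_LAMBDA_MIN_RATIO, DEFAULT_N_LAMBDAS,
                  GLASSO_MAX_ITER, GLASSO_TOL)

logger = logging.getLogger("twinnet")

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
MIN_SUBSAMPLE = 10


def _pipeline_args(gamma, n_lambdas, lambda_min_ratio, skew_threshold,
                   edge_threshold):
    return (float(skew_threshold), float(gamma), int(n_lambdas),
            float(lambda_min_ratio), GLASSO_TOL, GLASSO_MAX_ITER,
            bool(edge_threshold))


def _coerce_matrix(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return np.ascontiguousarray(data.to_numpy(dtype=float))
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    return np.ascontiguousarray(X)


def _centrality(W_stack: np.ndarray, measure: str) -> np.ndarray:
    if measure == "strength":
        return np.abs(W_stack).sum(axis=-1)
    if measure == "expected_influence":
        return W_stack.sum(axis=-1)
    raise ValueError("measure must be 'strength' or 'expected_influence'")


@dataclass
class CaseDropResult:
    """Per-proportion record of the case-dropping bootstrap."""

    drop_grid: np.ndarray
    correlations: list[np.ndarray]       # per proportion, per subsample
    prop_retained: np.ndarray            # fraction of corr >= threshold
    cs_coefficient: float
    measure: str
    threshold_corr: float
    quantile: float
    n_failed: int = 0


def case_dropping_bootstrap(data, measure: str = "strength",
                            n_boot: int = 1000,
                            threshold_corr: float = 0.7,
                            quantile: float = 0.95,
                            drop_grid=DEFAULT_DROP_GRID, seed=None,
                            gamma: float = DEFAULT_GAMMA,
                            n_lambdas: int = DEFAULT_N_LAMBDAS,
                            lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                            skew_threshold: float = 1.0,
                            edge_threshold: bool = True) -> CaseDropResult:
    """Drop-proportion profile of centrality stability.

    For each proportion q in the grid, ``n_boot`` subsamples of
    round(n (1-q)) cases are drawn without replacement, the network is
    re-estimated, and the Pearson correlation between subsample and
    full-sample centralities recorded.  The CS coefficient is the largest
    q whose correlations reach ``threshold_corr`` with probability
    ``quantile``.
    """
    X = _coerce_matrix(data)
    n = X.shape[0]
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: CS estimates will be noisy")
    args = _pipeline_args(gamma, n_lambdas, lambda_min_ratio, skew_threshold,
                          edge_threshold)
    W_full, ok = _fast.fit_weights_core(X, *args)
    if not ok:
        raise RuntimeError("full-sample network estimation failed")
    cent_full = _centrality(W_full[None], measure)[0]
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(drop_grid), dtype=float)
    correlations, props = [], []
    n_failed = 0
    for q in grid:
        m = int(round(n * (1.0 - q)))
        if m < MIN_SUBSAMPLE:
            warnings.warn(f"drop proportion {q:.2f} leaves {m} cases; "
                          "skipped")
            correlations.append(np.empty(0))
            props.append(np.nan)
            continue
        idx = np.empty((n_boot, m), dtype=np.int64)
        for b in range(n_boot):
            idx[b] = rng.choice(n, size=m, replace=False)
        W_stack, failed = _fast.subsample_weights_core(X, idx, *args)
        n_failed += int(failed.sum())
        cents = _centrality(W_stack[~failed], measure)
        with np.errstate(invalid="ignore"):
            corrs = np.array([_safe_corr(c, cent_full) for c in cents])
        correlations.append(corrs)
        props.append(float((corrs >= threshold_corr).mean())
                     if corrs.size else np.nan)
    props = np.asarray(props)
    cs = 0.0
    for q, pr in zip(grid, props):
        if np.isfinite(pr) and pr >= quantile:
            cs = max(cs, float(q))
    return CaseDropResult(drop_grid=grid, correlations=correlations,
                          prop_retained=props, cs_coefficient=cs,
                          measure=measure, threshold_corr=threshold_corr,
                          quantile=quantile, n_failed=n_failed)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # constant centrality vectors (e.g. an empty subsample network) cannot
    # retain the ranking: count them as correlation 0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cs_coefficient(data, measure: str = "strength", n_boot: int = 1000,
                   threshold_corr: float = 0.7, quantile: float = 0.95,
                   seed=None, **kwargs) -> float:
    """Correlation-stability coefficient (see module docstring)."""
    return case_dropping_bootstrap(
        data, measure=measure, n_boot=n_boot, threshold_corr=threshold_corr,
        quantile=quantile, seed=seed, **kwargs).cs_coefficient


def _bootstrap_weights(X, n_boot, rng, args):
    n = X.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n)).astype(np.int64)
    W_stack, failed = _fast.subsample_weights_core(X, idx, *args)
    if failed.any():
        logger.warning("bootstrap: %d/%d resample estimations failed",
                       int(failed.sum()), n_boot)
    return W_stack[~failed], int(failed.sum())


def edge_ci_bootstrap(data, n_boot: int = 1000, level: float = 0.95,
                      seed=None, node_labels=None,
                      gamma: float = DEFAULT_GAMMA,
                      n_lambdas: int = DEFAULT_N_LAMBDAS,
                      lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                      skew_threshold: float = 1.0,
                      edge_threshold: bool = True) -> pd.DataFrame:
    """Percentile bootstrap confidence interval per edge.

    Each case-resample re-runs the full pipeline including EBIC selection.
    Returns a long-format frame (node_i, node_j, estimate, lower, upper,
    boot_mean).
    """
    X = _coerce_matrix(data)
    if isinstance(data, pd.DataFrame) and node_labels is None:
        node_labels = [str(c) for c in data.columns]
    p = X.shape[1]
    if node_labels is None:
        node_labels = [f"V{j + 1}" for j in range(p)]
    if n_boot == 1:
        warnings.warn("n_boot=1: degenerate interval equal to the single "
                      "resample estimate")
    args = _pipeline_args(gamma, n_lambdas, lambda_min_ratio, skew_threshold,
                          edge_threshold)
    W_full, ok = _fast.fit_weights_core(X, *args)
    if not ok:
        raise RuntimeError("full-sample network estimation failed")
    rng = np.random.default_rng(seed)
    W_stack, _ = _bootstrap_weights(X, n_boot, rng, args)
    iu, ju = np.triu_indices(p, 1)
    draws = W_stack[:, iu, ju]
    alpha = 1.0 - level
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return pd.DataFrame({
        "node_i": [node_labels[a] for a in iu],
        "node_j": [node_labels[b] for b in ju],
        "estimate": W_full[iu, ju],
        "lower": lo,
        "upper": hi,
        "boot_mean": draws.mean(axis=0),
    })


def bootstrap_difference_test(data, n_boot: int = 1000,
                              what: str = "edges", level: float = 0.95,
                              seed=None, node_labels=None,
                              measure: str = "strength",
                              gamma: float = DEFAULT_GAMMA,
                              n_lambdas: int = DEFAULT_N_LAMBDAS,
                              lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
                              skew_threshold: float = 1.0,
                              edge_threshold: bool = True):
    """Pairwise bootstrapped difference tests.

    For every pair of edges (``what='edges'``) or of nodes
    (``what='centrality'``), the bootstrap distribution of their
    difference is formed from the same resamples; the pair differs
    significantly when the percentile interval excludes zero.  Returns
    (boolean significance matrix, item labels).
    """
    X = _coerce_matrix(data)
    if isinstance(data, pd.DataFrame) and node_labels is None:
        node_labels = [str(c) for c in data.columns]
    p = X.shape[1]
    if node_labels is None:
        node_labels = [f"V{j + 1}" for j in range(p)]
    args = _pipeline_args(gamma, n_lambdas, lambda_min_ratio, skew_threshold,
                          edge_threshold)
    rng = np.random.default_rng(seed)
    W_stack, _ = _bootstrap_weights(X, n_boot, rng, args)
    if what == "edges":
        iu, ju = np.triu_indices(p, 1)
        draws = W_stack[:, iu, ju]
        labels = [f"{node_labels[a]}--{node_labels[b]}"
                  for a, b in zip(iu, ju)]
    elif what == "centrality":
        draws = _centrality(W_stack, measure)
        labels = list(node_labels)
    else:
        raise ValueError("what must be 'edges' or 'centrality'")
    m = draws.shape[1]
    alpha = 1.0 - level
    significant = np.zeros((m, m), dtype=bool)
    for a in range(m):
        diffs = draws[:, a][:, None] - draws[:, a + 1:]
        if diffs.size == 0:
            continue
        lo = np.quantile(diffs, alpha / 2, axis=0)
        hi = np.quantile(diffs, 1 - alpha / 2, axis=0)
        sig = (lo > 0) | (hi < 0)
        significant[a, a + 1:] = sig
        significant[a + 1:, a] = sig
    return significant, labels


@dataclass
class StabilityReport:
    """Aggregate stability diagnostics for one analysis sample."""

    cs_strength: float
    cs_expected_influence: float
    case_drop: CaseDropResult = field(repr=False)
    edge_cis: pd.DataFrame = field(repr=False)
    edge_diff_significant: np.ndarray = field(repr=False)
    edge_diff_labels: list[str] = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "cs_strength": self.cs_strength,
            "cs_expected_influence": self.cs_expected_influence,
            "drop_grid": self.case_drop.drop_grid.tolist(),
            "prop_retained": [None if not np.isfinite(v) else float(v)
                              for v in self.case_drop.prop_retained],
            "edge_cis": self.edge_cis.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def stability_report(data, n_boot: int = 1000, seed=None,
                     node_labels=None, drop_grid=DEFAULT_DROP_GRID,
                     **kwargs) -> StabilityReport:
    """Run the three bootstrap diagnostics with a shared seed stream."""
    ss = np.random.SeedSequence(seed)
    s_drop, s_drop_ei, s_ci, s_diff = ss.spawn(4)
    drop = case_dropping_bootstrap(data, measure="strength", n_boot=n_boot,
                                   seed=s_drop, drop_grid=drop_grid,
                                   **kwargs)
    drop_ei = case_dropping_bootstrap(data, measure="expected_influence",
                                      n_boot=n_boot, seed=s_drop_ei,
                                      drop_grid=drop_grid, **kwargs)
    cis = edge_ci_bootstrap(data, n_boot=n_boot, seed=s_ci,
                            node_labels=node_labels, **kwargs)
    sig, labels = bootstrap_difference_test(data, n_boot=n_boot, seed=s_diff,
                                            node_labels=node_labels, **kwargs)
    return StabilityReport(cs_strength=drop.cs_coefficient,
                           cs_expected_influence=drop_ei.cs_coefficient,
                           case_drop=drop, edge_cis=cis,
                           edge_diff_significant=sig,
                           edge_diff_labels=labels)
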