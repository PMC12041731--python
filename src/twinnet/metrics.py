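"""Node centrality (strength, expected influence) and global strength.

Strength of a node is the sum of absolute weights of its edges; expected
influence is the signed sum (one-step), so the two coincide on networks
with no negative edges.  Centralities are reported raw and z-standardized
across the nodes of one network (sample SD, n-1 denominator).  The global
strength of a network is the sum of absolute weights over unique edges,
which feeds the S statistic of the network comparison test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _as_weight_matrix(W) -> np.ndarray:
    if hasattr(W, "W"):  # NetworkModel
        W = W.W
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if np.abs(np.diag(W)).max(initial=0.0) > 1e-10:
        raise ValueError("weight matrix must have zero diagonal")
    return W


def strength(W, node: int | None = None):
    """Sum of absolute edge weights per node (or one node)."""
    W = _as_weight_matrix(W)
    values = np.abs(W).sum(axis=1)
    return values if node is None else float(values[node])


def expected_influence(W, node: int | None = None):
    """Signed sum of edge weights per node (one-step EI)."""
    W = _as_weight_matrix(W)
    values = W.sum(axis=1)
    return values if node is None else float(values[node])


def global_strength(W) -> float:
    """Sum of absolute weights over unique (upper-triangle) edges."""
    W = _as_weight_matrix(W)
    return float(np.abs(W[np.triu_indices_from(W, 1)]).sum())


def z_standardize(values) -> np.ndarray:
    """(x - mean) / SD with the sample SD (n-1).  Constant input returns
    zeros with a warning."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant centrality values: z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(model_or_W, node_labels: list[str] | None = None,
                     categories: dict[str, str] | None = None
                     ) -> pd.DataFrame:
    """Raw and z-standardized strength and expected influence per node.

    Covariate nodes are included in the ranking but flagged when a
    category map is provided, since substantive interpretation usually
    focuses on the non-covariate battery.
    """
    if hasattr(model_or_W, "W") and node_labels is None:
        node_labels = list(model_or_W.node_labels)
    W = _as_weight_matrix(model_or_W)
    p = W.shape[0]
    if node_labels is None:
        node_labels = [f"V{j + 1}" for j in range(p)]
    s = strength(W)
    ei = expected_influence(W)
    out = pd.DataFrame({
        "node": node_labels,
        "strength": s,
        "expected_influence": ei,
        "strength_z": z_standardize(s) if p > 1 else np.zeros(p),
        "expected_influence_z": z_standardize(ei) if p > 1 else np.zeros(p),
    })
    if categories is not None:
        out["category"] = [categories.get(n, "unknown") for n in node_labels]
        out["is_covariate"] = out["category"] == "covariate"
    return out
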