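"""Reading and writing tables, networks, and run configurations.

Twin tables travel as CSV/TSV with four metadata columns (pair_id,
twin_index, zygosity, gender) followed by the variables in registry order.
Networks export as weighted edge lists (TSV), square weight matrices
(CSV, full precision) or GraphML with node category attributes, the
latter for Cytoscape-style visualization.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .synth import VariableRegistry

logger = logging.getLogger("twinnet")

META_COLUMNS = ["pair_id", "twin_index", "zygosity", "gender"]

_ZYGOSITY_CODES = {"MZ": "MZ", "DZ": "DZ", "MONOZYGOTIC": "MZ",
                   "DIZYGOTIC": "DZ"}
_GENDER_CODES = {"F": "F", "M": "M", "FEMALE": "F", "MALE": "M",
                 "W": "F", "WOMAN": "F", "MAN": "M"}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_twin_table(path, registry: VariableRegistry | None = None
                    ) -> pd.DataFrame:
    """Load and validate a twin-pair table.

    Checks metadata columns, canonicalizes zygosity and gender codes,
    verifies that every pair occurs exactly twice (one row per twin index)
    with shared zygosity and gender, and — when a registry is supplied —
    reorders the variable columns to registry order.
    """
    table = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    table["pair_id"] = table["pair_id"].astype(str)

    zyg = table["zygosity"].astype(str).str.upper().map(_ZYGOSITY_CODES)
    if zyg.isna().any():
        bad = sorted(table.loc[zyg.isna(), "zygosity"].astype(str).unique())
        raise ValueError(f"unknown zygosity codes: {bad}")
    table["zygosity"] = zyg
    gen = table["gender"].astype(str).str.upper().map(_GENDER_CODES)
    if gen.isna().any():
        bad = sorted(table.loc[gen.isna(), "gender"].astype(str).unique())
        raise ValueError(f"unknown gender codes: {bad}")
    table["gender"] = gen
    if not table["twin_index"].isin([1, 2]).all():
        raise ValueError("twin_index must be 1 or 2")

    dup = table.duplicated(subset=["pair_id", "twin_index"])
    if dup.any():
        raise ValueError(f"duplicated pair/twin rows: "
                         f"{sorted(table.loc[dup, 'pair_id'].unique())[:5]}")
    by_pair = table.groupby("pair_id")
    counts = by_pair["twin_index"].agg(["count", "sum"])
    incomplete = counts[(counts["count"] != 2) | (counts["sum"] != 3)]
    if len(incomplete):
        raise ValueError("pairs missing a co-twin: "
                         f"{sorted(incomplete.index)[:10]}")
    mixed = by_pair[["zygosity", "gender"]].nunique()
    bad = mixed[(mixed > 1).any(axis=1)]
    if len(bad):
        raise ValueError(f"pairs with inconsistent zygosity/gender: "
                         f"{sorted(bad.index)[:10]}")

    if registry is not None:
        variables = [c for c in table.columns if c not in META_COLUMNS]
        missing_vars = [v for v in registry.names if v not in variables]
        if missing_vars:
            raise ValueError(f"registry variables absent from table: "
                             f"{missing_vars[:10]}")
        if variables != registry.names:
            logger.info("reordering %d variable columns to registry order",
                        len(registry.names))
        table = table[META_COLUMNS + registry.names]
    return table.reset_index(drop=True)


def write_twin_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_network(model, path, fmt: str = "edges",
                  categories: dict[str, str] | None = None) -> None:
    """Write a NetworkModel (or weight matrix) to disk.

    ``fmt`` is one of ``edges`` (weighted edge-list TSV), ``matrix``
    (square CSV at full precision) or ``graphml``.
    """
    labels = getattr(model, "node_labels", None)
    W = model.W if hasattr(model, "W") else np.asarray(model, dtype=float)
    if labels is None:
        labels = [f"V{j + 1}" for j in range(W.shape[0])]
    path = Path(path)
    if fmt == "matrix":
        frame = pd.DataFrame(W, index=labels, columns=labels)
        frame.to_csv(path, float_format="%.17g")
    elif fmt == "edges":
        iu, ju = np.triu_indices(W.shape[0], 1)
        mask = W[iu, ju] != 0
        frame = pd.DataFrame({
            "node_i": [labels[a] for a in iu[mask]],
            "node_j": [labels[b] for b in ju[mask]],
            "weight": W[iu, ju][mask],
        })
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "graphml":
        graph = nx.Graph()
        for name in labels:
            attrs = {}
            if categories is not None:
                attrs["category"] = categories.get(name, "unknown")
            graph.add_node(name, **attrs)
        iu, ju = np.triu_indices(W.shape[0], 1)
        for a, b in zip(iu, ju):
            if W[a, b] != 0:
                graph.add_edge(labels[a], labels[b], weight=float(W[a, b]),
                               sign="positive" if W[a, b] > 0 else "negative")
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a square weight-matrix CSV back as (W, node labels)."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return frame.to_numpy(dtype=float), [str(c) for c in frame.columns]


def write_matrix_csv(matrix: np.ndarray, path,
                     labels: list[str] | None = None) -> None:
    """Square CSV export (e.g. ground-truth precision matrices)."""
    matrix = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"V{j + 1}" for j in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=labels,
                 columns=labels).to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated analysis parameters; defaults follow the reference
    settings (gamma 0.5, 100 penalties, 1000 permutations, 1000
    reassignments, skew threshold 1.0, 95% intervals)."""

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    skew_threshold: float = 1.0
    n_boot: int = 1000
    n_permutations: int = 1000
    n_reassignments: int = 1000
    inner_permutations: int = 1000
    alpha: float = 0.05
    ci_level: float = 0.95
    multiplicity: str = "holm"
    block_by_pair: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not 0 <= self.gamma:
            raise ValueError("gamma must be >= 0")
        for name in ("n_lambdas", "n_boot", "n_permutations",
                     "n_reassignments", "inner_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.lambda_min_ratio <= 1:
            raise ValueError("lambda_min_ratio must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.multiplicity not in ("holm", "none"):
            raise ValueError("multiplicity must be 'holm' or 'none'")
        if self.skew_threshold < 0:
            raise ValueError("skew_threshold must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path, config: RunConfig, extra: dict | None = None
                   ) -> None:
    """Provenance record sufficient to reproduce a run byte-identically."""
    import twinnet
    payload = {
        "twinnet_version": twinnet.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "numpy_version": np.__version__,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
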