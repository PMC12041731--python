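"""Synthetic like-sex twin-pair data with known network ground truth.

The generator emulates the structure of a middle-aged twin-registry survey:
one row per individual, pairs sharing zygosity and gender, a 39-variable
battery (9 depressive symptoms, 6 cognitive scores, 8 intellectual, 6
physical and 8 social leisure-activity frequencies, plus age and alcohol
consumption as covariates), zygosity-dependent cross-twin correlation and
gender-specific sparse partial-correlation structure.  Because the true
precision matrices are inputs, every downstream estimator can be validated
against a known graph.

Cross-twin dependence follows an equicorrelated ACE-style simplification:
with additive-genetic proportion h2 and shared-environment proportion c2,
the cross-twin covariance is rho_z * Sigma with rho_MZ = h2 + c2 and
rho_DZ = h2/2 + c2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("twinnet")

CATEGORIES = ("depressive", "cognitive", "intellectual", "physical",
              "social", "covariate")
SCALES = ("continuous", "count-like", "frequency-ordinal")
ZYGOSITIES = ("MZ", "DZ")
GENDERS = ("F", "M")
#: fixed stratum order used everywhere (generation, orchestration, reports)
STRATA = (("F", "MZ"), ("F", "DZ"), ("M", "MZ"), ("M", "DZ"))

# Shape parameter of the lognormal skewing map exp(x / (s * sd(x))):
# s = 1.5 gives marginal skewness ~2.7, comfortably beyond the |skew| > 1
# screening threshold at realistic sample sizes.
SKEW_SHAPE = 1.5


@dataclass(frozen=True)
class Variable:
    name: str
    category: str
    scale: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass(frozen=True)
class VariableRegistry:
    """Ordered node battery; the order defines matrix row/column order."""

    entries: tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.entries]

    @property
    def p(self) -> int:
        return len(self.entries)

    def categories(self) -> dict[str, str]:
        return {v.name: v.category for v in self.entries}

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for v in self.entries:
            counts[v.category] += 1
        return counts

    def names_in_category(self, category: str) -> list[str]:
        return [v.name for v in self.entries if v.category == category]

    @classmethod
    def default(cls) -> "VariableRegistry":
        """The 39-node battery: 9 + 6 + 8 + 6 + 8 + 2 variables."""
        def block(names, category, scale):
            return [Variable(n, category, scale) for n in names]

        entries = (
            block(["Sad", "HappyNow", "Lonely", "WorthNothing", "Tense",
                   "Outlook", "Tired", "Sleep", "Appetite"],
                  "depressive", "frequency-ordinal")
            + block(["Learning", "DelayedRecall", "WorkingMemory",
                     "AuditAtt", "Fluency", "Associations"],
                    "cognitive", "continuous")
            + block(["Museum", "Library", "Courses", "Reading", "WriteStory",
                     "Crossword", "Concert", "Lecture"],
                    "intellectual", "frequency-ordinal")
            + block(["Exercised", "Yoga", "Sport", "Biking", "Walking",
                     "HardWork"], "physical", "frequency-ordinal")
            + block(["MeetTwin", "PhoneTwin", "Dinner", "FriendsDinner",
                     "PhoneFamily", "VisitFamily", "Club", "Volunteer"],
                    "social", "frequency-ordinal")
            + [Variable("Age", "covariate", "continuous"),
               Variable("Alcohol", "covariate", "count-like")]
        )
        return cls(tuple(entries))

    @classmethod
    def generic(cls, p: int) -> "VariableRegistry":
        """A p-variable continuous registry for simulation studies."""
        width = len(str(p))
        return cls(tuple(Variable(f"V{i + 1:0{width}d}", "cognitive",
                                  "continuous") for i in range(p)))


def make_chain_precision(p: int, edge_weight: float,
                         boost: float = 1.0) -> np.ndarray:
    """Chain-graph precision matrix with unit diagonal.

    The first off-diagonal is set to ``-edge_weight * boost`` so the implied
    partial correlation of each chain edge equals ``edge_weight * boost``.
    ``boost > 1`` produces a uniformly stronger network from the same
    skeleton (the "denser female network" condition).

    Raises ``ValueError`` if the construction is not positive definite.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    theta = np.eye(p)
    w = edge_weight * boost
    idx = np.arange(p - 1)
    theta[idx, idx + 1] = -w
    theta[idx + 1, idx] = -w
    smallest = np.linalg.eigvalsh(theta)[0]
    if smallest <= 0:
        raise ValueError(
            f"chain precision not positive definite (min eigenvalue "
            f"{smallest:.3g}); reduce edge_weight*boost={w:.3g}")
    return theta


def _check_spd(name: str, theta: np.ndarray) -> None:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError(f"{name}: precision matrix must be square")
    if not np.allclose(theta, theta.T, atol=1e-10):
        raise ValueError(f"{name}: precision matrix must be symmetric")
    smallest = np.linalg.eigvalsh(theta)[0]
    if smallest <= 0:
        raise ValueError(f"{name}: precision matrix not positive definite "
                         f"(min eigenvalue {smallest:.3g})")


def _default_n_pairs() -> dict[tuple[str, str], int]:
    # registry-like strata at quarter scale (pairs, not individuals)
    return {("F", "MZ"): 115, ("F", "DZ"): 140,
            ("M", "MZ"): 91, ("M", "DZ"): 123}


@dataclass
class GeneratorConfig:
    """Everything the twin-pair generator needs, with validated defaults.

    ``true_precision_by_gender`` maps "F"/"M" to p x p symmetric positive
    definite precision matrices; by default women get a chain graph with
    partial correlations 0.45 (boost 1.8 over the base 0.25) and men the
    base chain, so gendered network differences exist by construction.
    """

    n_pairs: dict[tuple[str, str], int] = field(default_factory=_default_n_pairs)
    p: int = 39
    true_precision_by_gender: dict[str, np.ndarray] | None = None
    h2: float = 0.6
    c2: float = 0.2
    skew_columns: tuple[str, ...] | None = None
    seed: int = 0

    @property
    def rho_mz(self) -> float:
        return self.h2 + self.c2

    @property
    def rho_dz(self) -> float:
        return 0.5 * self.h2 + self.c2

    def resolved_precisions(self) -> dict[str, np.ndarray]:
        if self.true_precision_by_gender is not None:
            return {g: np.asarray(m, dtype=float)
                    for g, m in self.true_precision_by_gender.items()}
        return {"F": make_chain_precision(self.p, 0.25, boost=1.8),
                "M": make_chain_precision(self.p, 0.25, boost=1.0)}

    def resolved_skew_columns(self, registry: VariableRegistry) -> list[str]:
        if self.skew_columns is not None:
            missing = set(self.skew_columns) - set(registry.names)
            if missing:
                raise ValueError(f"skew_columns not in registry: "
                                 f"{sorted(missing)}")
            return list(self.skew_columns)
        defaults = ["Alcohol", "Yoga", "Volunteer", "Crossword"]
        return [n for n in defaults if n in registry.names]

    def to_yaml(self, path, precision_paths: dict[str, str] | None = None
                ) -> None:
        """Write the configuration as key/value text.

        Precision matrices are not inlined; pass ``precision_paths``
        mapping gender to a square-CSV path (see
        :func:`twinnet.io.write_matrix_csv`) to reference them, otherwise
        the chain-graph defaults are assumed on reload.
        """
        import yaml
        payload = {
            "p": self.p,
            "h2": self.h2,
            "c2": self.c2,
            "seed": self.seed,
            "n_pairs": {f"{g}-{z}": int(n)
                        for (g, z), n in self.n_pairs.items()},
            "skew_columns": (list(self.skew_columns)
                             if self.skew_columns is not None else None),
        }
        if precision_paths is not None:
            payload["precision_csv"] = dict(precision_paths)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml
        from .io import read_network_matrix
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"p", "h2", "c2", "seed", "n_pairs", "skew_columns",
                 "precision_csv"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: raw[k] for k in ("p", "h2", "c2", "seed") if k in raw}
        if "n_pairs" in raw:
            kwargs["n_pairs"] = {tuple(k.split("-")): int(v)
                                 for k, v in raw["n_pairs"].items()}
        if raw.get("skew_columns") is not None:
            kwargs["skew_columns"] = tuple(raw["skew_columns"])
        if "precision_csv" in raw:
            kwargs["true_precision_by_gender"] = {
                g: read_network_matrix(p)[0]
                for g, p in raw["precision_csv"].items()}
        return cls(**kwargs)

    def validate(self, registry: VariableRegistry) -> None:
        if registry.p != self.p:
            raise ValueError(f"registry has {registry.p} variables, "
                             f"config expects p={self.p}")
        for key, n in self.n_pairs.items():
            if key not in STRATA:
                raise ValueError(f"unknown stratum {key}")
            if n < 1:
                raise ValueError(f"n_pairs for {key} must be positive")
        if not (0.0 <= self.h2 <= 1.0 and 0.0 <= self.c2 <= 1.0):
            raise ValueError("h2 and c2 must lie in [0, 1]")
        if self.h2 + self.c2 > 1.0:
            raise ValueError(f"h2 + c2 = {self.h2 + self.c2:.3g} exceeds 1")
        precisions = self.resolved_precisions()
        for g in GENDERS:
            if g not in precisions:
                raise ValueError(f"missing precision matrix for gender {g}")
            _check_spd(f"gender {g}", precisions[g])
            if precisions[g].shape[0] != self.p:
                raise ValueError(f"gender {g}: precision is "
                                 f"{precisions[g].shape[0]}x, expected {self.p}")
        self.resolved_skew_columns(registry)


def _skew_map(x: np.ndarray, sd: float) -> np.ndarray:
    """Monotone skewing map x -> exp(x / (s*sd)), restandardized.

    Standardization uses the exact lognormal moments of the map applied to
    a centred Gaussian with standard deviation ``sd``, so the output has
    population mean 0 and variance 1 while remaining a strictly increasing
    function of the input (hence invertible by a rank-based transform).
    """
    sigma = 1.0 / SKEW_SHAPE
    y = np.exp(x / (SKEW_SHAPE * sd))
    mean = np.exp(0.5 * sigma ** 2)
    var = (np.exp(sigma ** 2) - 1.0) * np.exp(sigma ** 2)
    return (y - mean) / np.sqrt(var)


def generate_pairs(config: GeneratorConfig,
                   registry: VariableRegistry | None = None) -> pd.DataFrame:
    """Draw a complete twin-pair table under the configured ground truth.

    Each pair is one draw from a 2p-dimensional Gaussian with within-twin
    covariance Sigma_g = Theta_g^{-1} and cross-twin covariance
    rho_z * Sigma_g; skew-designated columns then pass through the monotone
    lognormal map.  Identical seeds give bit-identical tables.
    """
    if registry is None:
        registry = (VariableRegistry.default() if config.p == 39
                    else VariableRegistry.generic(config.p))
    config.validate(registry)
    precisions = config.resolved_precisions()
    skew_cols = config.resolved_skew_columns(registry)
    p = config.p
    rng = np.random.default_rng(config.seed)
    frames = []
    for gender, zygosity in STRATA:
        n_pairs = config.n_pairs.get((gender, zygosity), 0)
        if n_pairs == 0:
            continue
        sigma = np.linalg.inv(precisions[gender])
        rho = config.rho_mz if zygosity == "MZ" else config.rho_dz
        if rho >= 1.0:
            raise ValueError(f"cross-twin correlation {rho} >= 1: pair "
                             "covariance not positive definite")
        pair_cov = np.block([[sigma, rho * sigma], [rho * sigma, sigma]])
        chol = np.linalg.cholesky(pair_cov)
        draws = rng.standard_normal((n_pairs, 2 * p)) @ chol.T
        twin1, twin2 = draws[:, :p], draws[:, p:]
        sds = np.sqrt(np.diag(sigma))
        for name in skew_cols:
            j = registry.names.index(name)
            twin1[:, j] = _skew_map(twin1[:, j], sds[j])
            twin2[:, j] = _skew_map(twin2[:, j], sds[j])
        pair_ids = [f"{gender}-{zygosity}-{i + 1:05d}" for i in range(n_pairs)]
        for twin_index, block in ((1, twin1), (2, twin2)):
            frame = pd.DataFrame(block, columns=registry.names)
            frame.insert(0, "pair_id", pair_ids)
            frame.insert(1, "twin_index", twin_index)
            frame.insert(2, "zygosity", zygosity)
            frame.insert(3, "gender", gender)
            frames.append(frame)
    if not frames:
        raise ValueError("no strata with positive n_pairs")
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["pair_id", "twin_index"], kind="stable")
    return table.reset_index(drop=True)


def discretize_quantile(table: pd.DataFrame, columns: list[str],
                        n_levels: int = 5) -> pd.DataFrame:
    """Quantile-bin columns to 1..n_levels, a stress test for the pipeline
    on ordinal-looking data (the estimators treat them numerically)."""
    out = table.copy()
    for name in columns:
        ranks = out[name].rank(method="average", pct=True)
        out[name] = np.ceil(ranks * n_levels).clip(1, n_levels).astype(float)
    return out
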