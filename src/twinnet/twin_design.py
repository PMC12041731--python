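"""Three-level twin comparison design.

Level 1 compares co-twins within each gender-by-zygosity stratum.  Because
labelling pair members "twin 1" and "twin 2" is arbitrary, each stratum is
randomly reassigned many times (default 1000): every iteration flips a
fair coin per pair to split the stratum into two datasets, runs the
network comparison test between them, and accumulates the two estimated
networks into running elementwise means ("averaged co-twin networks").
The distribution of per-iteration p-values summarizes the level-1
evidence; a stratum is flagged when the fraction of iterations significant
at alpha clearly exceeds what chance allows (alpha plus two binomial
standard errors).

Level 2 pools both co-twins and compares MZ to DZ individuals within each
gender; level 3 pools zygosity and compares women to men.  The gates of
the sequential design (pool only after the previous level found no
difference) are recorded but advisory: all levels are always computed and
inconsistencies flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nct import NCTResult, nct
from .synth import STRATA

logger = logging.getLogger("twinnet")

META_COLUMNS = ["pair_id", "twin_index", "zygosity", "gender"]


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _variable_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _split_cotwins(stratum: pd.DataFrame):
    """Return (twin1 matrix, twin2 matrix, pair_ids, variable names)."""
    missing = [c for c in META_COLUMNS if c not in stratum.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    if stratum["zygosity"].nunique() != 1 or stratum["gender"].nunique() != 1:
        raise ValueError("stratum must be homogeneous in zygosity and gender")
    counts = stratum.groupby("pair_id")["twin_index"].agg(["count", "sum"])
    bad = counts[(counts["count"] != 2) | (counts["sum"] != 3)]
    if len(bad):
        raise ValueError(f"incomplete or duplicated pairs: "
                         f"{list(bad.index[:5])}")
    ordered = stratum.sort_values(["pair_id", "twin_index"], kind="stable")
    variables = _variable_columns(stratum)
    values = ordered[variables].to_numpy(dtype=float)
    t1 = values[0::2]
    t2 = values[1::2]
    pair_ids = ordered["pair_id"].to_numpy()[0::2]
    return t1, t2, pair_ids, variables


@dataclass
class ReassignmentResult:
    """Co-twin reassignment analysis of one stratum."""

    stratum: tuple[str, str]
    n_reassignments: int
    s_values: np.ndarray
    m_values: np.ndarray
    s_pvalues: np.ndarray
    m_pvalues: np.ndarray
    averaged_network_a: np.ndarray = field(repr=False)
    averaged_network_b: np.ndarray = field(repr=False)
    node_labels: list[str] = field(default_factory=list)
    alpha: float = 0.05
    assignments: np.ndarray | None = field(default=None, repr=False)

    def decision_threshold(self) -> float:
        r = self.n_reassignments
        return self.alpha + 2.0 * np.sqrt(self.alpha * (1 - self.alpha) / r)

    def summary(self) -> dict:
        thr = self.decision_threshold()
        out = {"n_reassignments": self.n_reassignments, "alpha": self.alpha,
               "decision_threshold": thr}
        for name, pvals in (("s", self.s_pvalues), ("m", self.m_pvalues)):
            prop = float((pvals < self.alpha).mean())
            out[f"{name}_pvalue_min"] = float(pvals.min())
            out[f"{name}_pvalue_q05"] = float(np.quantile(pvals, 0.05))
            out[f"{name}_prop_significant"] = prop
            out[f"{name}_significant"] = bool(prop > thr)
        out["significant"] = bool(out["s_significant"] or out["m_significant"])
        return out


def reassign_cotwins(stratum: pd.DataFrame, n_reassignments: int = 1000,
                     inner_permutations: int = 1000, seed=None,
                     alpha: float = 0.05, keep_assignments: bool = False,
                     **nct_kwargs) -> ReassignmentResult:
    """Compare co-twins under repeated random pair-member assignment.

    Every iteration assigns each pair's two members to datasets A and B by
    an independent fair coin, runs the NCT between A and B, and adds both
    estimated networks into elementwise running means.  Deterministic
    under ``seed``.
    """
    if n_reassignments < 1:
        raise ValueError("n_reassignments must be >= 1")
    t1, t2, _, variables = _split_cotwins(stratum)
    n_pairs, p = t1.shape
    stratum_key = (str(stratum["gender"].iloc[0]),
                   str(stratum["zygosity"].iloc[0]))
    ss = _as_seed_sequence(seed)
    coin_rng = np.random.default_rng(ss.spawn(1)[0])
    inner_seeds = ss.spawn(n_reassignments)
    s_vals = np.empty(n_reassignments)
    m_vals = np.empty(n_reassignments)
    s_pvals = np.empty(n_reassignments)
    m_pvals = np.empty(n_reassignments)
    mean_a = np.zeros((p, p))
    mean_b = np.zeros((p, p))
    assignments = (np.empty((n_reassignments, n_pairs), dtype=bool)
                   if keep_assignments else None)
    for r in range(n_reassignments):
        coins = coin_rng.integers(0, 2, size=n_pairs).astype(bool)
        if assignments is not None:
            assignments[r] = coins
        a = np.where(coins[:, None], t1, t2)
        b = np.where(coins[:, None], t2, t1)
        res = nct(a, b, n_permutations=inner_permutations,
                  seed=inner_seeds[r], compute_edge_tests=False,
                  **nct_kwargs)
        s_vals[r], m_vals[r] = res.s_observed, res.m_observed
        s_pvals[r], m_pvals[r] = res.s_pvalue, res.m_pvalue
        mean_a += (res.w1 - mean_a) / (r + 1)
        mean_b += (res.w2 - mean_b) / (r + 1)
    return ReassignmentResult(stratum=stratum_key,
                              n_reassignments=n_reassignments,
                              s_values=s_vals, m_values=m_vals,
                              s_pvalues=s_pvals, m_pvalues=m_pvals,
                              averaged_network_a=mean_a,
                              averaged_network_b=mean_b,
                              node_labels=variables, alpha=alpha,
                              assignments=assignments)


def run_level2(stratum_mz: pd.DataFrame, stratum_dz: pd.DataFrame,
               n_permutations: int = 1000, seed=None,
               block_by_pair: bool = False, **nct_kwargs) -> NCTResult:
    """NCT between pooled MZ and pooled DZ individuals of one gender."""
    for df, zyg in ((stratum_mz, "MZ"), (stratum_dz, "DZ")):
        if len(df) == 0:
            raise ValueError(f"empty {zyg} stratum")
    g_mz = set(stratum_mz["gender"].unique())
    g_dz = set(stratum_dz["gender"].unique())
    if g_mz != g_dz or len(g_mz) != 1:
        raise ValueError(f"gender mismatch between strata: {g_mz} vs {g_dz}")
    variables = _variable_columns(stratum_mz)
    pair_ids = None
    if block_by_pair:
        pair_ids = np.concatenate([stratum_mz["pair_id"].to_numpy(),
                                   stratum_dz["pair_id"].to_numpy()])
    return nct(stratum_mz[variables], stratum_dz[variables],
               n_permutations=n_permutations, seed=seed, pair_ids=pair_ids,
               **nct_kwargs)


def run_level3(women: pd.DataFrame, men: pd.DataFrame,
               n_permutations: int = 1000, seed=None,
               block_by_pair: bool = False,
               restrict_edges_to: list[str] | None = None,
               **nct_kwargs) -> NCTResult:
    """NCT between all women and all men (zygosity pooled).

    ``restrict_edges_to`` limits the per-edge tests (and their correction)
    to edges incident to the listed nodes, e.g. the depressive symptoms.
    """
    variables = _variable_columns(women)
    if variables != _variable_columns(men):
        raise ValueError("variable mismatch between gender tables")
    edge_subset = None
    if restrict_edges_to is not None:
        wanted = {variables.index(v) for v in restrict_edges_to}
        p = len(variables)
        edge_subset = [(i, j) for i in range(p) for j in range(i + 1, p)
                       if i in wanted or j in wanted]
    pair_ids = None
    if block_by_pair:
        pair_ids = np.concatenate([women["pair_id"].to_numpy(),
                                   men["pair_id"].to_numpy()])
    return nct(women[variables], men[variables],
               n_permutations=n_permutations, seed=seed, pair_ids=pair_ids,
               edge_subset=edge_subset, **nct_kwargs)


@dataclass
class StudyReport:
    """Results and gate decisions of the full three-level design."""

    level1: dict[tuple[str, str], ReassignmentResult]
    level2: dict[str, NCTResult]
    level3: NCTResult
    gates: dict
    alpha: float
    seed: int | None
    sample_sizes: dict

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "seed": self.seed,
            "sample_sizes": {f"{g}-{z}": n for (g, z), n
                             in self.sample_sizes.items()},
            "gates": self.gates,
            "level1": {f"{g}-{z}": res.summary()
                       for (g, z), res in self.level1.items()},
            "level2": {g: res.summary() for g, res in self.level2.items()},
            "level3": self.level3.summary(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_study(table: pd.DataFrame, n_reassignments: int = 1000,
              inner_permutations: int = 1000, n_permutations: int = 1000,
              seed=None, alpha: float = 0.05, block_by_pair: bool = True,
              restrict_edges_to: list[str] | None = None,
              **nct_kwargs) -> StudyReport:
    """Execute levels 1-3 with the sequential gating logic.

    Level 2 pools co-twins within zygosity (justified when level 1 found
    no co-twin differences); level 3 pools zygosity within gender
    (justified when level 2 found none).  Gates are recorded but never
    block execution; a violated gate is flagged in the report.

    Levels 2 and 3 default to pair-blocked permutations: the pooled
    samples contain both members of each pair, and reassigning whole
    pairs keeps the within-pair dependence intact under the null
    (individual-level permutation is mildly anticonservative there).
    """
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    present = {(g, z) for g, z in
               table[["gender", "zygosity"]].drop_duplicates().itertuples(
                   index=False)}
    missing = [s for s in STRATA if s not in present]
    if missing:
        raise ValueError(f"missing strata: {missing}")
    ss = _as_seed_sequence(seed)
    l1_seeds = ss.spawn(len(STRATA))
    l2_seeds = ss.spawn(2)
    l3_seed = ss.spawn(1)[0]

    level1 = {}
    sample_sizes = {}
    for (gender, zygosity), child in zip(STRATA, l1_seeds):
        stratum = table[(table["gender"] == gender)
                        & (table["zygosity"] == zygosity)]
        sample_sizes[(gender, zygosity)] = int(len(stratum))
        logger.info("level 1: stratum %s-%s (%d individuals)", gender,
                    zygosity, len(stratum))
        level1[(gender, zygosity)] = reassign_cotwins(
            stratum, n_reassignments=n_reassignments,
            inner_permutations=inner_permutations, seed=child, alpha=alpha,
            **nct_kwargs)
    gate1 = not any(res.summary()["significant"] for res in level1.values())

    # Each gate is one pooling decision informed by several index tests
    # (2 genders x {S, M} at level 2; {S, M} at level 3), so the decision
    # controls the family-wise error at alpha via Bonferroni.

    level2 = {}
    for gender, child in zip(("F", "M"), l2_seeds):
        mz = table[(table["gender"] == gender) & (table["zygosity"] == "MZ")]
        dz = table[(table["gender"] == gender) & (table["zygosity"] == "DZ")]
        logger.info("level 2: %s MZ (%d) vs DZ (%d)", gender, len(mz),
                    len(dz))
        level2[gender] = run_level2(mz, dz, n_permutations=n_permutations,
                                    seed=child, block_by_pair=block_by_pair,
                                    **nct_kwargs)
    level2_pvalues = [p for res in level2.values()
                      for p in (res.s_pvalue, res.m_pvalue)]
    gate2 = min(level2_pvalues) >= alpha / len(level2_pvalues)

    women = table[table["gender"] == "F"]
    men = table[table["gender"] == "M"]
    logger.info("level 3: women (%d) vs men (%d)", len(women), len(men))
    level3 = run_level3(women, men, n_permutations=n_permutations,
                        seed=l3_seed, block_by_pair=block_by_pair,
                        restrict_edges_to=restrict_edges_to, **nct_kwargs)

    gates = {
        "level1_no_cotwin_difference": bool(gate1),
        "level2_no_zygosity_difference": bool(gate2),
        "level2_pooling_supported": bool(gate1),
        "level3_pooling_supported": bool(gate2),
        "level3_significant": bool(min(level3.s_pvalue, level3.m_pvalue)
                                   < alpha / 2),
    }
    if not gate1:
        logger.warning("gate violation: co-twin differences detected at "
                       "level 1; level-2 pooling is flagged")
    if not gate2:
        logger.warning("gate violation: zygosity differences detected at "
                       "level 2; level-3 pooling is flagged")
    return StudyReport(level1=level1, level2=level2, level3=level3,
                       gates=gates, alpha=alpha,
                       seed=seed if isinstance(seed, int) else None,
                       sample_sizes=sample_sizes)
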