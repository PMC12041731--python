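import numpy as np
import pandas as pd
import pytest

from twinnet import (GeneratorConfig, generate_pairs, reassign_cotwins,
                     run_level2, run_level3, run_study)


def stratum_of(table, gender, zygosity):
    return table[(table["gender"] == gender)
                 & (table["zygosity"] == zygosity)]


@pytest.fixture(scope="module")
def table8():
    config = GeneratorConfig(
        p=8,
        n_pairs={("F", "MZ"): 40, ("F", "DZ"): 40,
                 ("M", "MZ"): 40, ("M", "DZ"): 40},
        h2=0.6, c2=0.2, seed=11)
    return generate_pairs(config)


class TestReassignCotwins:
    def test_identical_cotwins_limit(self, table8):
        # duplicate twin 1 as twin 2: every reassignment yields two
        # identical datasets, so S = M = 0 and p = 1 exactly
        strat = stratum_of(table8, "F", "MZ").copy()
        strat = strat.sort_values(["pair_id", "twin_index"])
        variables = strat.columns[4:]
        vals = strat[variables].to_numpy()
        vals[1::2] = vals[0::2]
        strat[variables] = vals
        res = reassign_cotwins(strat, n_reassignments=5,
                               inner_permutations=20, seed=0)
        assert np.array_equal(res.s_values, np.zeros(5))
        assert np.array_equal(res.m_values, np.zeros(5))
        assert np.array_equal(res.s_pvalues, np.ones(5))
        assert np.array_equal(res.m_pvalues, np.ones(5))

    def test_partition_correctness(self, table8):
        strat = stratum_of(table8, "M", "DZ")
        res = reassign_cotwins(strat, n_reassignments=4,
                               inner_permutations=10, seed=1,
                               keep_assignments=True)
        n_pairs = len(strat) // 2
        assert res.assignments.shape == (4, n_pairs)
        # each pair contributes exactly one member per dataset by
        # construction; coin flips should vary across iterations
        assert len({a.tobytes() for a in res.assignments}) > 1

    def test_averaged_networks_symmetric_zero_diagonal(self, table8):
        strat = stratum_of(table8, "F", "DZ")
        res = reassign_cotwins(strat, n_reassignments=3,
                               inner_permutations=10, seed=2)
        for W in (res.averaged_network_a, res.averaged_network_b):
            assert np.allclose(W, W.T)
            assert np.all(np.diag(W) == 0)

    def test_summary_decision_rule(self, table8):
        strat = stratum_of(table8, "F", "MZ")
        res = reassign_cotwins(strat, n_reassignments=4,
                               inner_permutations=10, seed=3)
        summary = res.summary()
        expected_thr = 0.05 + 2 * np.sqrt(0.05 * 0.95 / 4)
        assert summary["decision_threshold"] == pytest.approx(expected_thr)
        assert summary["s_significant"] == (
            summary["s_prop_significant"] > expected_thr)

    def test_mixed_stratum_rejected(self, table8):
        mixed = table8[table8["gender"] == "F"]
        with pytest.raises(ValueError, match="homogeneous"):
            reassign_cotwins(mixed, n_reassignments=2, inner_permutations=5)

    def test_incomplete_pair_rejected(self, table8):
        strat = stratum_of(table8, "F", "MZ").iloc[1:]
        with pytest.raises(ValueError, match="pairs"):
            reassign_cotwins(strat, n_reassignments=2, inner_permutations=5)

    def test_zero_reassignments_rejected(self, table8):
        strat = stratum_of(table8, "F", "MZ")
        with pytest.raises(ValueError, match="n_reassignments"):
            reassign_cotwins(strat, n_reassignments=0, inner_permutations=5)


class TestLevel2And3:
    def test_level2_gender_mismatch_rejected(self, table8):
        with pytest.raises(ValueError, match="gender"):
            run_level2(stratum_of(table8, "F", "MZ"),
                       stratum_of(table8, "M", "DZ"), n_permutations=5)

    def test_level2_empty_stratum_rejected(self, table8):
        with pytest.raises(ValueError, match="empty"):
            run_level2(stratum_of(table8, "F", "MZ").iloc[:0],
                       stratum_of(table8, "F", "DZ"), n_permutations=5)

    def test_level2_runs_blocked(self, table8):
        res = run_level2(stratum_of(table8, "F", "MZ"),
                         stratum_of(table8, "F", "DZ"),
                         n_permutations=20, seed=4, block_by_pair=True)
        assert 0 < res.s_pvalue <= 1

    def test_level3_variable_mismatch_rejected(self, table8):
        women = table8[table8["gender"] == "F"]
        men = table8[table8["gender"] == "M"].rename(columns={"V1": "X1"})
        with pytest.raises(ValueError, match="mismatch"):
            run_level3(women, men, n_permutations=5)

    def test_level3_edge_restriction(self, table8):
        women = table8[table8["gender"] == "F"]
        men = table8[table8["gender"] == "M"]
        res = run_level3(women, men, n_permutations=15, seed=5,
                         block_by_pair=True, restrict_edges_to=["V1", "V2"])
        # edges incident to V1 or V2: 7 + 7 - 1 = 13 of the 28 pairs
        assert len(res.edge_tests) == 13


class TestRunStudy:
    def test_missing_stratum_rejected(self, table8):
        partial = table8[~((table8["gender"] == "M")
                           & (table8["zygosity"] == "DZ"))]
        with pytest.raises(ValueError, match="missing strata"):
            run_study(partial, n_reassignments=2, inner_permutations=5,
                      n_permutations=5)

    def test_report_structure_and_reproducibility(self, table8, tmp_path):
        kwargs = dict(n_reassignments=2, inner_permutations=10,
                      n_permutations=15, seed=42)
        rep_a = run_study(table8, **kwargs)
        rep_b = run_study(table8, **kwargs)
        assert set(rep_a.level1) == {("F", "MZ"), ("F", "DZ"),
                                     ("M", "MZ"), ("M", "DZ")}
        assert set(rep_a.level2) == {"F", "M"}
        assert rep_a.level3.s_pvalue == rep_b.level3.s_pvalue
        for key in rep_a.level1:
            assert np.array_equal(rep_a.level1[key].s_pvalues,
                                  rep_b.level1[key].s_pvalues)
        path_a, path_b = tmp_path / "a.json", tmp_path / "b.json"
        rep_a.to_json(path_a)
        rep_b.to_json(path_b)
        assert path_a.read_bytes() == path_b.read_bytes()

    def test_gate_semantics_match_pvalues(self, table8):
        rep = run_study(table8, n_reassignments=2, inner_permutations=10,
                        n_permutations=15, seed=7)
        pvals = [p for res in rep.level2.values()
                 for p in (res.s_pvalue, res.m_pvalue)]
        assert rep.gates["level2_no_zygosity_difference"] == (
            min(pvals) >= rep.alpha / 4)
        assert rep.gates["level3_significant"] == (
            min(rep.level3.s_pvalue, rep.level3.m_pvalue) < rep.alpha / 2)
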