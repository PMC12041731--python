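import numpy as np
import pandas as pd
import pytest

from twinnet import (GeneratorConfig, VariableRegistry, discretize_quantile,
                     generate_pairs, make_chain_precision)
from twinnet.synth import STRATA, Variable


class TestRegistry:
    def test_default_battery_composition(self):
        reg = VariableRegistry.default()
        assert reg.p == 39
        assert reg.category_counts() == {
            "depressive": 9, "cognitive": 6, "intellectual": 8,
            "physical": 6, "social": 8, "covariate": 2}
        assert len(set(reg.names)) == 39

    def test_duplicate_names_rejected(self):
        v = Variable("A", "cognitive", "continuous")
        with pytest.raises(ValueError, match="unique"):
            VariableRegistry((v, v))

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            Variable("A", "nonsense", "continuous")


class TestChainPrecision:
    def test_zero_weight_gives_identity(self):
        assert np.array_equal(make_chain_precision(3, 0.0), np.eye(3))

    def test_implied_partial_correlation(self):
        # pr = -theta12 / sqrt(theta11 * theta22)
        theta = make_chain_precision(2, 0.4)
        pr = -theta[0, 1] / np.sqrt(theta[0, 0] * theta[1, 1])
        assert pr == pytest.approx(0.4)

    def test_boosted_chain_positive_definite(self):
        theta = make_chain_precision(10, 0.3, boost=1.5)
        assert np.linalg.eigvalsh(theta)[0] > 0

    def test_non_pd_construction_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            make_chain_precision(10, 0.6, boost=1.0)


class TestGeneratorConfig:
    def test_rho_derivation(self):
        cfg = GeneratorConfig(h2=0.6, c2=0.2)
        assert cfg.rho_mz == pytest.approx(0.8)
        assert cfg.rho_dz == pytest.approx(0.5)
        assert cfg.rho_mz >= cfg.rho_dz >= 0

    def test_heritability_budget_enforced(self):
        cfg = GeneratorConfig(p=4, h2=0.7, c2=0.5)
        with pytest.raises(ValueError, match="exceeds 1"):
            cfg.validate(VariableRegistry.generic(4))

    def test_non_spd_precision_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 1.5
        cfg = GeneratorConfig(p=4, true_precision_by_gender={"F": bad,
                                                             "M": np.eye(4)})
        with pytest.raises(ValueError, match="positive definite"):
            cfg.validate(VariableRegistry.generic(4))


def small_config(seed=3, **kwargs):
    defaults = dict(
        p=5,
        n_pairs={("F", "MZ"): 50, ("F", "DZ"): 50,
                 ("M", "MZ"): 50, ("M", "DZ"): 50},
        h2=0.6, c2=0.2, seed=seed)
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


class TestGeneratePairs:
    def test_pair_structure_and_like_sex(self):
        table = generate_pairs(small_config())
        counts = table.groupby("pair_id")["twin_index"].agg(["count", "sum"])
        assert (counts["count"] == 2).all()
        assert (counts["sum"] == 3).all()  # twin_index 1 and 2 once each
        homo = table.groupby("pair_id")[["zygosity", "gender"]].nunique()
        assert (homo == 1).all().all()
        assert set(map(tuple, table[["gender", "zygosity"]]
                       .drop_duplicates().to_numpy())) == set(STRATA)

    def test_deterministic_under_seed(self):
        a = generate_pairs(small_config(seed=9))
        b = generate_pairs(small_config(seed=9))
        pd.testing.assert_frame_equal(a, b)
        c = generate_pairs(small_config(seed=10))
        assert not a[a.columns[4:]].equals(c[c.columns[4:]])

    def test_twin_exchangeability_of_pooled_moments(self):
        # swapping twin labels within every pair leaves pooled summary
        # statistics untouched (same rows, reordered)
        table = generate_pairs(small_config())
        variables = table.columns[4:]
        swapped = table.copy()
        swapped["twin_index"] = 3 - swapped["twin_index"]
        a = table[variables].to_numpy()
        b = swapped.sort_values(["pair_id", "twin_index"])[variables].to_numpy()
        assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0))
        assert np.allclose(np.cov(a.T), np.cov(b.T))

    def test_cross_twin_correlation_matches_rho(self):
        # MC oracle: with h2=0.6, c2=0.2 the constructed pair covariance
        # gives cross-twin correlation 0.8 (MZ) and 0.5 (DZ)
        cfg = small_config(
            seed=21, p=4,
            n_pairs={("F", "MZ"): 5000, ("F", "DZ"): 5000,
                     ("M", "MZ"): 2, ("M", "DZ"): 2},
            skew_columns=())
        table = generate_pairs(cfg)
        for zyg, rho in (("MZ", 0.8), ("DZ", 0.5)):
            strat = table[(table.gender == "F") & (table.zygosity == zyg)]
            strat = strat.sort_values(["pair_id", "twin_index"])
            vals = strat[strat.columns[4:]].to_numpy()
            t1, t2 = vals[0::2], vals[1::2]
            for j in range(4):
                r = np.corrcoef(t1[:, j], t2[:, j])[0, 1]
                assert r == pytest.approx(rho, abs=0.03)

    def test_independent_cotwins_when_h2_c2_zero(self):
        cfg = small_config(seed=33, p=3, h2=0.0, c2=0.0,
                           n_pairs={("F", "MZ"): 2000, ("F", "DZ"): 2,
                                    ("M", "MZ"): 2, ("M", "DZ"): 2},
                           skew_columns=())
        table = generate_pairs(cfg)
        strat = table[(table.gender == "F") & (table.zygosity == "MZ")]
        vals = strat.sort_values(["pair_id", "twin_index"]).iloc[:, 4:]
        t1, t2 = vals.to_numpy()[0::2], vals.to_numpy()[1::2]
        for j in range(3):
            assert abs(np.corrcoef(t1[:, j], t2[:, j])[0, 1]) < 0.05

    def test_skew_columns_exceed_threshold(self):
        from twinnet import sample_skewness
        cfg = small_config(
            seed=5,
            n_pairs={("F", "MZ"): 600, ("F", "DZ"): 2,
                     ("M", "MZ"): 2, ("M", "DZ"): 2},
            skew_columns=("V2", "V4"))
        table = generate_pairs(cfg)
        assert abs(sample_skewness(table["V2"])) > 1.0
        assert abs(sample_skewness(table["V4"])) > 1.0
        assert abs(sample_skewness(table["V1"])) < 1.0

    def test_default_quarter_scale_strata(self):
        cfg = GeneratorConfig()
        assert cfg.n_pairs == {("F", "MZ"): 115, ("F", "DZ"): 140,
                               ("M", "MZ"): 91, ("M", "DZ"): 123}

    def test_config_yaml_roundtrip_with_precisions(self, tmp_path):
        from twinnet import read_network_matrix, write_matrix_csv
        theta_f = make_chain_precision(5, 0.3, boost=1.5)
        theta_m = make_chain_precision(5, 0.3)
        pf, pm = tmp_path / "f.csv", tmp_path / "m.csv"
        write_matrix_csv(theta_f, pf)
        write_matrix_csv(theta_m, pm)
        cfg = small_config(seed=4, skew_columns=("V2",),
                           true_precision_by_gender={"F": theta_f,
                                                     "M": theta_m})
        path = tmp_path / "gen.yaml"
        cfg.to_yaml(path, precision_paths={"F": str(pf), "M": str(pm)})
        loaded = GeneratorConfig.from_yaml(path)
        assert loaded.n_pairs == cfg.n_pairs
        assert loaded.h2 == cfg.h2 and loaded.seed == cfg.seed
        assert loaded.skew_columns == ("V2",)
        assert np.array_equal(loaded.true_precision_by_gender["F"], theta_f)
        pd.testing.assert_frame_equal(generate_pairs(loaded),
                                      generate_pairs(cfg))

    def test_fitted_network_recovers_generator_truth(self):
        # pooled individuals from one stratum (twin dependence included)
        # still identify the ground-truth chain at large n
        from twinnet import estimate_network
        cfg = small_config(
            seed=77, p=8,
            n_pairs={("F", "MZ"): 2500, ("F", "DZ"): 2,
                     ("M", "MZ"): 2, ("M", "DZ"): 2},
            skew_columns=())
        table = generate_pairs(cfg)
        strat = table[(table.gender == "F") & (table.zygosity == "MZ")]
        model, _ = estimate_network(strat[strat.columns[4:]])
        theta_true = cfg.resolved_precisions()["F"]
        true_edges = np.abs(np.triu(theta_true, 1)) > 0
        found = np.abs(np.triu(model.W, 1)) > 0
        sensitivity = (found & true_edges).sum() / true_edges.sum()
        fpr = (found & ~true_edges).sum() / (~true_edges & np.triu(
            np.ones((8, 8), dtype=bool), 1)).sum()
        assert sensitivity >= 0.9
        assert fpr <= 0.05

    def test_discretize_quantile_levels(self):
        table = generate_pairs(small_config())
        out = discretize_quantile(table, ["V1"], n_levels=4)
        assert set(out["V1"].unique()) <= {1.0, 2.0, 3.0, 4.0}
        # monotone: rank order preserved between raw and binned values
        raw = table["V1"].to_numpy()
        binned = out["V1"].to_numpy()
        order = np.argsort(raw)
        assert (np.diff(binned[order]) >= 0).all()
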