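"""Generators: trees, lambda-Brownian traits, sex-group summaries, masking."""

import numpy as np
import pandas as pd
import pytest

from phylosel import (
    SimulationConfig,
    apply_missingness,
    read_newick,
    simulate_dataset,
    simulate_sex_groups,
    simulate_traits,
    simulate_tree,
)
from phylosel.pgls import pgls
from phylosel.pipeline import derive_indices


class TestSimulateTree:
    @pytest.mark.parametrize("model", ["pure_birth", "coalescent"])
    def test_shape_and_positivity(self, model):
        t = simulate_tree(16, model, 1.0, seed=5)
        assert t.n_tips == 16
        assert len(set(t.tip_labels)) == 16
        for node in t.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0

    def test_three_tips_forced_topology(self):
        t = simulate_tree(3, "pure_birth", 1.0, seed=1)
        assert t.n_tips == 3
        edges = [nd for nd in t.tree.preorder_node_iter() if nd.parent_node]
        assert len(edges) == 4
        depths = list(t.depths().values())
        assert max(depths) - min(depths) < 1e-9

    def test_64_tip_ultrametric(self):
        t = simulate_tree(64, "pure_birth", 1.0, seed=7)
        depths = np.array(list(t.depths().values()))
        assert np.ptp(depths) < 1e-9

    def test_deterministic_newick(self):
        a = simulate_tree(20, "pure_birth", 1.0, seed=42).to_newick()
        b = simulate_tree(20, "pure_birth", 1.0, seed=42).to_newick()
        assert a == b

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2, "pure_birth", 1.0, seed=1)


class TestSimulateTraits:
    def test_zero_covariance_gives_root_means(self, tree12):
        df = simulate_traits(tree12, np.zeros((2, 2)), 1.0, [3.0, -1.0], seed=1)
        assert (df["trait0"] == 3.0).all() and (df["trait1"] == -1.0).all()

    def test_lambda_zero_sister_independence(self):
        # mean correlation between a sister pair across replicates ~ 0
        tree = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        xs = np.array([
            simulate_traits(tree, np.eye(1), 0.0, [0.0], seed=s).loc[["A", "B"], "trait0"]
            for s in range(500)
        ])
        r = np.corrcoef(xs[:, 0], xs[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_two_tip_brownian_variance(self):
        # lambda=1, sigma^2=1, depth T=2: Var(tip) across replicates ~ 2
        tree = read_newick("(A:2,B:2);")
        vals = np.array([
            simulate_traits(tree, np.eye(1), 1.0, [0.0], seed=s).loc["A", "trait0"]
            for s in range(1000)
        ])
        assert np.var(vals) == pytest.approx(2.0, rel=0.15)

    def test_lambda_interpolates_sister_covariance(self):
        # shared-history covariance at lambda=0.5 is ~half that at lambda=1
        tree = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")

        def sister_cov(lam):
            xs = np.array([
                simulate_traits(tree, np.eye(1), lam, [0.0], seed=1000 * int(lam * 2) + s)
                .loc[["A", "B"], "trait0"]
                for s in range(1000)
            ])
            return np.cov(xs[:, 0], xs[:, 1])[0, 1]

        ratio = sister_cov(0.5) / sister_cov(1.0)
        assert 0.35 <= ratio <= 0.65

    def test_variance_scales_linearly_with_depth(self):
        # replicate tip variance regressed on tree depth: slope ~ sigma^2
        depths = [1.0, 2.0, 3.0]
        variances = []
        for d in depths:
            tree = read_newick(f"(A:{d},B:{d});")
            vals = [
                simulate_traits(tree, np.eye(1), 1.0, [0.0],
                                seed=10_000 + int(d * 1000) + s).loc["A", "trait0"]
                for s in range(1000)
            ]
            variances.append(np.var(vals))
        slope = np.polyfit(depths, variances, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.10)

    def test_deterministic(self, tree12):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        a = simulate_traits(tree12, R, 0.7, [0, 0], seed=9)
        b = simulate_traits(tree12, R, 0.7, [0, 0], seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_rejected(self, tree12):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_traits(tree12, bad, 1.0, [0, 0], seed=1)


class TestSimulateSexGroups:
    def test_symmetric_construction_gives_zero_deltas(self, tree12):
        g = simulate_sex_groups(tree12, 0.0, seed=3, noise_sd=0.0)
        d = derive_indices(_groups_to_raw(g))
        assert np.allclose(d["delta_I"].abs() - _correction(g), 0.0, atol=1e-12)
        assert np.allclose(d["delta_beta_ss"], 0.0, atol=1e-12)

    def test_null_effect_uncorrelated_with_care(self):
        tree = simulate_tree(24, seed=1)
        rs = []
        for s in range(500):
            g = simulate_sex_groups(tree, 0.0, seed=s)
            implied = np.log(
                (g["rs_sd_m"] / g["rs_mean_m"]) / (g["rs_sd_f"] / g["rs_mean_f"])
            )
            rs.append(np.corrcoef(g["care_frac"], implied)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_negative_effect_recovers_negative_slope(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            ds = simulate_dataset(n_species=64, seed=500 + rep)
            derived = derive_indices(ds.table)
            sub = derived[derived["has_care"]]
            fit = pgls("care_score ~ delta_I", sub, ds.tree)
            hits += fit.params[1] < 0
        assert hits / n_rep > 0.9


def _groups_to_raw(groups: pd.DataFrame) -> pd.DataFrame:
    raw = groups.copy()
    raw["male_mass_g"] = 1.0
    raw["female_mass_g"] = 1.0
    return raw


def _correction(groups: pd.DataFrame) -> np.ndarray:
    return np.abs(
        1.0 / (2 * (groups["rs_n_m"] - 1)) - 1.0 / (2 * (groups["rs_n_f"] - 1))
    ).to_numpy()


class TestApplyMissingness:
    def test_exact_counts(self, rng):
        tree = simulate_tree(100, seed=2)
        tab = simulate_traits(tree, np.eye(1), 1.0, [0.0], seed=2,
                              trait_names=["testis_mass_g"])
        masked = apply_missingness(tab, {"testis_mass_g": 0.48}, seed=4)
        assert int(masked.mask["testis_mass_g"].sum()) == 48
        assert int(masked.data["testis_mass_g"].isna().sum()) == 48

    def test_zero_rate_noop(self, tree12):
        tab = simulate_traits(tree12, np.eye(2), 1.0, [0, 0], seed=5)
        masked = apply_missingness(tab, {"trait0": 0.0, "trait1": 0.0}, seed=1)
        assert not masked.mask.any().any()
        pd.testing.assert_frame_equal(masked.data, tab)

    def test_deterministic_masks(self, tree12):
        tab = simulate_traits(tree12, np.eye(2), 1.0, [0, 0], seed=5)
        m1 = apply_missingness(tab, {"trait0": 0.4}, seed=9)
        m2 = apply_missingness(tab, {"trait0": 0.4}, seed=9)
        pd.testing.assert_frame_equal(m1.mask, m2.mask)

    def test_truth_retains_originals(self, tree12):
        tab = simulate_traits(tree12, np.eye(2), 1.0, [0, 0], seed=5)
        masked = apply_missingness(tab, {"trait0": 0.5}, seed=9)
        pd.testing.assert_frame_equal(masked.truth, tab)

    def test_rate_one_rejected(self, tree12):
        tab = simulate_traits(tree12, np.eye(1), 1.0, [0.0], seed=5)
        with pytest.raises(ValueError):
            apply_missingness(tab, {"trait0": 1.0}, seed=1)

    def test_care_columns_protected(self, tree12):
        tab = simulate_traits(tree12, np.eye(1), 1.0, [0.0], seed=5)
        tab["percent_male_care"] = 50.0
        with pytest.raises(ValueError, match="may not be masked"):
            apply_missingness(tab, {"percent_male_care": 0.2}, seed=1)


class TestSimulateDataset:
    def test_deterministic_end_to_end(self):
        a = simulate_dataset(n_species=20, seed=3)
        b = simulate_dataset(n_species=20, seed=3)
        assert a.tree.to_newick() == b.tree.to_newick()
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_masking_fractions_match_config(self):
        ds = simulate_dataset(n_species=64, seed=1)
        for col, rate in ds.config.missing_rates.items():
            expected = int(np.floor(rate * 64 + 0.5))
            assert int(ds.mask[col].sum()) == expected

    def test_care_never_missing_for_care_species(self):
        ds = simulate_dataset(n_species=64, seed=2)
        care = ds.table["has_care"].astype(bool)
        assert ds.table.loc[care, "percent_male_care"].notna().all()

    def test_auxiliary_species_partially_observed(self):
        ds = simulate_dataset(n_species=20, n_auxiliary=6, seed=4)
        aux = ds.table[ds.table["is_auxiliary"]]
        assert len(aux) == 6
        assert aux["male_mass_g"].notna().all()
        assert aux["delta_I"].isna().all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_species=2)
        with pytest.raises(ValueError):
            SimulationConfig(lambda_true=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(missing_rates={"delta_I": 1.2})
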