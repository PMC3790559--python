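"""Synthetic study generator: trees, traits, outlines, isotopes."""

import numpy as np
import pandas as pd
import pytest

from opermorph import (SyntheticConfig, eigenshape, generate_dataset,
                       generate_isotopes, generate_outlines, generate_tree,
                       pgls, resample_equidistant, simulate_traits,
                       write_dataset, zahn_roskies)


class TestGenerateTree:
    def test_two_taxa_cherry(self):
        tree = generate_tree(2, 1.0, seed=0)
        assert tree.n_tips == 2
        np.testing.assert_allclose(tree.blen[:2], 1.0, atol=1e-12)

    def test_ultrametric_with_right_node_count(self):
        tree = generate_tree(25, 23.0, seed=1)
        assert tree.n_nodes - tree.n_tips == 24
        tip_t = tree.node_times[:25]
        assert tip_t.max() - tip_t.min() < 1e-9 * 23.0
        assert tree.depth == pytest.approx(23.0)

    def test_tip_labels_and_determinism(self):
        t1 = generate_tree(10, 5.0, seed=7)
        t2 = generate_tree(10, 5.0, seed=7)
        assert t1.tip_labels[0] == "sp001"
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(1, 1.0, seed=0)

    def test_lineage_growth_matches_pure_birth_expectation(self):
        # conditioned on n tips at depth 1, lineages grow like 2*exp(rt)
        # with effective rate r = log(n/2); check the fitted log-LTT slope
        n, depth = 50, 1.0
        grid = np.linspace(0.05, 0.95, 10)
        counts = np.zeros_like(grid)
        n_seeds = 100
        for seed in range(1, n_seeds + 1):
            tree = generate_tree(n, depth, seed=seed)
            times = np.sort(tree.node_times[tree.n_tips:])
            for k, t in enumerate(grid):
                counts[k] += 1 + np.searchsorted(times, t, side="right")
        mean_lineages = counts / n_seeds
        slope = np.polyfit(grid, np.log(mean_lineages), 1)[0]
        expected = np.log(n / 2) / depth
        assert slope == pytest.approx(expected, rel=0.2)


class TestSimulateTraits:
    def test_zero_rate_bm_constant_at_root_state(self, small_tree):
        out = simulate_traits(small_tree, "BM", {"sigma2": 0.0, "z0": 2.5},
                              seed=0)
        np.testing.assert_allclose(out["trait1"], 2.5)

    def test_cherry_contrast_variance(self):
        from opermorph import Phylogeny

        tree = Phylogeny([2, 2, -1], [1.0, 1.0, 0.0], ["a", "b"])
        diffs = []
        for seed in range(100):
            x = simulate_traits(tree, "BM", {"sigma2": 1.0}, n_traits=100,
                                seed=seed)
            diffs.append(x.loc["a"].to_numpy() - x.loc["b"].to_numpy())
        var = np.var(np.concatenate(diffs))
        assert var == pytest.approx(2.0, rel=0.05)

    def test_bm_tip_covariance_matches_shared_paths(self):
        tree = generate_tree(8, 2.0, seed=5)
        X = np.stack([
            simulate_traits(tree, "BM", {"sigma2": 1.5}, n_traits=125,
                            seed=s).to_numpy() for s in range(80)
        ])  # (80, 8, 125) -> 10000 replicates
        X = np.moveaxis(X, 1, 2).reshape(-1, 8)
        emp = np.cov(X.T)
        np.testing.assert_allclose(emp, 1.5 * tree.vcv(), atol=0.15)

    def test_strong_ou_decorrelates_root_sisters(self):
        # two tips diverging at the root, alpha*T = 5
        from opermorph import Phylogeny

        tree = Phylogeny([2, 2, -1], [1.0, 1.0, 0.0], ["a", "b"])
        x = simulate_traits(tree, "OU", {"sigma2": 1.0, "alpha": 5.0},
                            n_traits=10_000, seed=3)
        a, b = x.loc["a"].to_numpy(), x.loc["b"].to_numpy()
        cov = np.cov(a, b)
        assert abs(cov[0, 1]) < 0.01 * cov[0, 0]

    def test_eb_matches_bm_on_transformed_tree(self, small_tree):
        from opermorph import eb_transform

        a = -0.1
        x1 = simulate_traits(small_tree, "EB", {"sigma2": 1.0, "a": a}, seed=9)
        x2 = simulate_traits(eb_transform(small_tree, a), "BM",
                             {"sigma2": 1.0}, seed=9)
        pd.testing.assert_frame_equal(x1, x2)

    def test_unknown_model_rejected(self, small_tree):
        with pytest.raises(ValueError, match="unknown model"):
            simulate_traits(small_tree, "ACDC", {"sigma2": 1.0}, seed=0)


class TestGenerateOutlines:
    def test_no_signal_no_noise_identical(self):
        cfg = SyntheticConfig(n_species=4, n_clades=2, clade_effect_size=0.0,
                              outline_noise_sd=0.0, seed=1,
                              specimens_per_species=(2, 2))
        vals = pd.Series([1.0, -1.0, 0.5, 0.0],
                         index=[f"sp{i:03d}" for i in range(1, 5)])
        outlines, table = generate_outlines(cfg, vals, seed=2)
        ref = zahn_roskies(resample_equidistant(outlines[0], 100)).phi_star
        for o in outlines[1:]:
            sf = zahn_roskies(resample_equidistant(o, 100))
            np.testing.assert_allclose(sf.phi_star, ref, atol=1e-8)

    def test_opposite_values_on_opposite_es1_sides(self):
        cfg = SyntheticConfig(n_species=2, n_clades=1, outline_noise_sd=0.0,
                              seed=1, specimens_per_species=(3, 3))
        vals = pd.Series([-1.0, 1.0], index=["sp001", "sp002"])
        outlines, table = generate_outlines(cfg, vals, seed=2)
        sfs = [zahn_roskies(resample_equidistant(o, 100)) for o in outlines]
        es = eigenshape(sfs)
        scores = es.scores_frame()["ES1"]
        sp = table.set_index("specimen_id")["species"]
        means = scores.groupby(sp).mean()
        assert means.loc["sp001"] * means.loc["sp002"] < 0

    def test_outlines_counter_clockwise_with_start_zero(self):
        cfg = SyntheticConfig(seed=5)
        vals = pd.Series(np.linspace(-1, 1, 25),
                         index=[f"sp{i:03d}" for i in range(1, 26)])
        outlines, _ = generate_outlines(cfg, vals, seed=5)
        assert all(o.signed_area() > 0 for o in outlines)
        assert all(o.start_index == 0 for o in outlines)
        assert all(o.p == 100 for o in outlines)


class TestGenerateIsotopes:
    def test_zero_coupling_zero_noise_constant(self):
        vals = pd.Series([1.0, -2.0, 0.3], index=list("abc"))
        iso = generate_isotopes(vals, coupling=0.0, noise_sd=0.0, seed=0)
        assert iso["d15N"].nunique() == 1
        assert iso["d13C"].nunique() == 1

    def test_unit_coupling_perfect_correlation(self):
        vals = pd.Series(np.linspace(-2, 2, 9),
                         index=[f"s{i}" for i in range(9)])
        iso = generate_isotopes(vals, coupling=1.0, noise_sd=0.0, seed=0)
        assert np.corrcoef(iso["d15N"], vals)[0, 1] == pytest.approx(1.0)

    def test_pgls_recovers_coupling(self):
        # generator as truth, pgls as estimator
        tree = generate_tree(21, 1.0, seed=4)
        slopes = []
        for seed in range(300):
            vals = simulate_traits(tree, "BM", {"sigma2": 1.0},
                                   seed=seed)["trait1"]
            iso = generate_isotopes(vals, coupling=0.5, noise_sd=0.5,
                                    seed=20_000 + seed)
            res = pgls(tree, iso["d15N"], vals.to_frame("ES1"),
                       correlation=np.eye(21))
            slopes.append(res.coefficients.loc["ES1", "coef"])
        assert np.mean(slopes) == pytest.approx(0.5, rel=0.1)


class TestDataset:
    def test_default_scale_matches_study_design(self):
        ds = generate_dataset(SyntheticConfig(seed=11))
        assert ds.tree.n_tips == 25
        assert ds.specimens["clade"].nunique() == 4
        per_species = ds.specimens.groupby("species").size()
        assert per_species.min() >= 1 and per_species.max() <= 12
        assert set(ds.isotopes.columns) == {"d13C", "d15N"}

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        for sub in ("x", "y"):
            write_dataset(generate_dataset(SyntheticConfig(seed=7)),
                          tmp_path / sub)
        for name in ("outlines.tps", "tree.nwk", "specimens.csv",
                     "isotopes.csv"):
            assert (tmp_path / "x" / name).read_bytes() == \
                (tmp_path / "y" / name).read_bytes()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_species=3, n_clades=5)
        with pytest.raises(ValueError):
            SyntheticConfig(p_points=4)
        with pytest.raises(ValueError):
            SyntheticConfig(outline_noise_sd=-0.1)
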