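import numpy as np
import pandas as pd
import pytest

from anatidiv.config import substream
from anatidiv.env_drivers import ndvi_summaries, vif_screen
from anatidiv.synthetic import (
    AssemblyScenario,
    assemble_communities,
    default_trait_schema,
    simulate_bd_lineage_count,
    simulate_environment,
    simulate_traits,
    simulate_tree_ensemble,
    two_hemisphere_demo,
)
from anatidiv.trait_space import gower_similarity, to_dissimilarity


class TestTreeSimulation:
    def test_yule_five_tips_structure(self):
        ens = simulate_tree_ensemble(5, 2, seed=1)
        t = ens[0]
        assert t.n_tips == 5
        assert t.n_nodes == 9  # 4 internal bifurcations + root path
        depths = [t.branch_sum([sp]) for sp in t.tip_labels]
        assert max(depths) - min(depths) < 1e-9  # ultrametric

    def test_same_seed_same_ensemble(self):
        a = simulate_tree_ensemble(8, 3, seed=2)
        b = simulate_tree_ensemble(8, 3, seed=2)
        for ta, tb in zip(a, b):
            assert ta.to_newick() == tb.to_newick()

    def test_death_rate_must_be_below_birth(self):
        with pytest.raises(ValueError, match="death"):
            simulate_tree_ensemble(5, 1, model="birth-death", birth=1.0, death=1.2)

    def test_unconditioned_tip_count_matches_closed_form_mean(self):
        # E[N(t)] = exp((birth - death) t)
        birth, death, t = 1.0, 0.3, 1.2
        rng = np.random.default_rng(3)
        counts = [simulate_bd_lineage_count(birth, death, t, rng) for _ in range(500)]
        expected = np.exp((birth - death) * t)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05


class TestTraitSimulation:
    def test_percentage_groups_sum_to_100_exactly(self):
        ens = simulate_tree_ensemble(12, 1, seed=4)
        tt = simulate_traits(ens[0], seed=4)
        schema = default_trait_schema()
        for cols in schema.percentage_groups.values():
            sums = tt.data[cols].sum(axis=1)
            assert np.abs(sums - 100.0).max() < 1e-9

    def test_zero_rate_trait_is_constant(self):
        ens = simulate_tree_ensemble(10, 1, seed=5)
        tt = simulate_traits(ens[0], seed=5, rate={"body_mass": 0.0})
        assert tt.data["body_mass"].nunique() == 1

    def test_brownian_tip_variance_matches_rate_times_depth(self):
        # a tip's variance across replicate simulations is rate x root-to-tip depth
        ens = simulate_tree_ensemble(6, 1, seed=6)
        tree = ens[0]
        depth = tree.branch_sum([tree.tip_labels[0]])
        rate = 2.0
        vals = [
            simulate_traits(tree, seed=1000 + k, rate=rate).data["body_mass"].iloc[0]
            for k in range(400)
        ]
        var = np.var(vals, ddof=1)
        expected = rate * depth
        # chi-square spread of a sample variance at n=400: ~14% SE
        assert abs(var - expected) / expected < 0.5


class TestEnvironmentSimulation:
    def test_seasonality_tracks_latitude_in_the_north(self):
        env = simulate_environment(n_lat=14, n_lon=10, seed=7)
        north = env.cells["lat"] >= 0
        corr = np.corrcoef(
            env.truth["season_field"][north], np.abs(env.cells["lat"][north])
        )[0, 1]
        assert corr > 0.8

    def test_summary_operators_recover_generating_fields(self):
        env = simulate_environment(n_lat=8, n_lon=6, seed=8)
        season_hat = []
        peak_hat = []
        for i in range(len(env.cells.index)):
            s = ndvi_summaries(env.ndvi.cell(i))
            season_hat.append(s["season"])
            peak_hat.append(s["mn"])
        assert np.corrcoef(season_hat, env.truth["season_field"])[0, 1] > 0.9
        assert np.corrcoef(peak_hat, env.truth["peak_field"])[0, 1] > 0.9

    def test_planted_collinear_predictors_are_caught_by_vif(self):
        env = simulate_environment(n_lat=10, n_lon=8, seed=9)
        cols, trace = vif_screen(env.env.data, threshold=10.0)
        dropped = set(trace["dropped"])
        assert set(env.truth["planted_collinear"]) <= dropped | (set(env.env.data.columns) - set(cols))
        for name in env.truth["planted_collinear"]:
            assert name not in cols

    def test_reproducible_under_seed(self):
        a = simulate_environment(n_lat=5, n_lon=5, seed=10)
        b = simulate_environment(n_lat=5, n_lon=5, seed=10)
        pd.testing.assert_frame_equal(a.env.data, b.env.data)
        assert np.array_equal(a.ndvi.data, b.ndvi.data)


class TestAssembly:
    @pytest.fixture(scope="class")
    def pool(self):
        trees = simulate_tree_ensemble(40, 1, seed=11)
        traits = simulate_traits(trees[0], seed=11)
        env = simulate_environment(n_lat=6, n_lon=6, seed=11)
        return trees, traits, env

    def test_neutral_with_fixed_richness(self, pool):
        _, traits, env = pool
        r = pd.Series(7, index=env.cells.index)
        grid, flags = assemble_communities(
            traits, env.cells, AssemblyScenario(mode="neutral", seed=12), richness=r
        )
        assert (grid.richness() == 7).all()
        assert not flags.any()

    def test_filtering_sigma_to_zero_selects_nearest_trait_values(self, pool):
        _, traits, env = pool
        sc = AssemblyScenario(mode="filtering", sigma=1e-3, richness_mean=3, seed=13)
        r = pd.Series(3, index=env.cells.index)
        grid, _ = assemble_communities(
            traits, env.cells, sc,
            env_values=env.truth["season_field"], richness=r,
        )
        z = traits.data["body_mass"]
        zs = (z - z.mean()) / z.std()
        e = env.truth["season_field"]
        es = (e - e.mean()) / e.std()
        for cid in list(env.cells.index)[:10]:
            sp = grid.species_in(cid)
            got = sorted(np.abs(zs[sp] - es[cid]))
            best = sorted(np.abs(zs - es[cid]))[:3]
            assert np.allclose(got, best, atol=1e-12)

    def test_limiting_similarity_overdisperses_relative_to_neutral(self, pool):
        _, traits, env = pool
        D = to_dissimilarity(gower_similarity(traits)).to_numpy()
        labels = list(traits.species)
        sc = AssemblyScenario(mode="limiting-similarity", delta=0.25, seed=14)
        r = pd.Series(6, index=env.cells.index)
        grid, _ = assemble_communities(
            traits, env.cells, sc,
            gower_distance=to_dissimilarity(gower_similarity(traits)), richness=r,
        )
        pos = {s: i for i, s in enumerate(labels)}

        def mean_pairwise(sp):
            idx = [pos[s] for s in sp]
            sub = D[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), 1)
            return sub[iu].mean()

        n_cells = len(grid.cell_ids)
        obs = np.mean([mean_pairwise(grid.species_in(c)) for c in grid.cell_ids])
        rng = np.random.default_rng(15)
        null = [
            np.mean([
                mean_pairwise(list(rng.choice(labels, 6, replace=False)))
                for _ in range(n_cells)
            ])
            for _ in range(300)
        ]
        assert obs > np.quantile(null, 0.99)

    def test_exhaustion_is_flagged(self, pool):
        _, traits, env = pool
        sc = AssemblyScenario(mode="limiting-similarity", delta=0.9, seed=16)
        r = pd.Series(30, index=env.cells.index[:4])
        grid, flags = assemble_communities(
            traits, env.cells.iloc[:4], sc,
            gower_distance=to_dissimilarity(gower_similarity(traits)), richness=r,
        )
        assert flags.any()
        assert (grid.richness() <= 30).all()

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            AssemblyScenario(mode="chaos")
        with pytest.raises(ValueError):
            AssemblyScenario(mode="filtering", sigma=0.0)
        with pytest.raises(ValueError):
            AssemblyScenario(mode="limiting-similarity", delta=1.5)


def test_demo_is_bit_reproducible():
    a = two_hemisphere_demo(seed=17, n_species=20, n_trees=2, n_lat=6, n_lon=4)
    b = two_hemisphere_demo(seed=17, n_species=20, n_trees=2, n_lat=6, n_lon=4)
    pd.testing.assert_frame_equal(a.grid.presence, b.grid.presence)
    assert a.trees[0].to_newick() == b.trees[0].to_newick()
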