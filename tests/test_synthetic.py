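import numpy as np
import pandas as pd
import pytest

import forestbeta as fb
from forestbeta.data_io import ValidationError
from forestbeta.phylo_signal import _KEngine, phylo_vcv
from forestbeta.synthetic import _habitat_surface, plot_layout
from forestbeta.trait_space import pca_scores, standardize_traits


class TestTree:
    def test_three_tips_unit_depth(self):
        phy = fb.simulate_tree(3, seed=1)
        assert len(phy.tip_labels) == 3
        assert phy.depth == pytest.approx(1.0, abs=1e-9)
        assert phy.is_ultrametric

    def test_determinism(self):
        a = fb.simulate_tree(40, seed=7).as_newick()
        b = fb.simulate_tree(40, seed=7).as_newick()
        assert a == b

    def test_mean_cophenetic_bounded_by_twice_depth(self):
        phy = fb.simulate_tree(64, seed=9)
        dm = fb.phylo_cophenetic_distance(phy)
        off = dm.values[np.triu_indices(dm.n, 1)]
        assert 0 < off.mean() <= 2.0 + 1e-9

    def test_too_few_species(self):
        with pytest.raises(ValidationError):
            fb.simulate_tree(2, seed=1)


class TestTraits:
    def test_determinism(self, yule8):
        t1 = fb.simulate_traits(yule8, 0.5, seed=3)
        t2 = fb.simulate_traits(yule8, 0.5, seed=3)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_positive_and_named(self, traits8):
        assert (traits8.data.to_numpy() > 0).all()
        assert list(traits8.data.columns) == list(fb.data_io.TRAIT_NAMES)

    def test_signal_weight_controls_blomberg_k(self, yule64):
        """w=1 gives K near 1 on average; w=0 pushes K far below 1."""
        labels, V = phylo_vcv(yule64)
        eng = _KEngine(V)
        k_bm, k_noise = [], []
        for s in range(25):
            bm = fb.simulate_traits(yule64, 1.0, seed=s)
            noise = fb.simulate_traits(yule64, 0.0, seed=s)
            # log undoes the lognormal map, K is affine-invariant
            k_bm.append(eng.k(np.log(bm.data["SLA"]).reindex(labels).to_numpy()))
            k_noise.append(eng.k(np.log(noise.data["SLA"]).reindex(labels).to_numpy()))
        assert 0.75 < np.mean(k_bm) < 1.25
        assert np.median(k_noise) < 0.5

    def test_weight_domain(self, yule8):
        with pytest.raises(ValidationError):
            fb.simulate_traits(yule8, 1.5, seed=1)


class TestHabitat:
    def test_aspect_domain_and_coverage(self):
        h = fb.simulate_habitat(n_plots=2, grains=(10, 20), seed=1,
                                regime_heterogeneity=(1.0,), plot_regimes=[1, 1])
        asp = h.data["aspect"]
        assert ((asp >= 0) & (asp < 360)).all()
        assert len(h.data) == 2 * (100 + 25)

    def test_base_elevation_span(self):
        h = fb.simulate_habitat(n_plots=9, grains=(20,), seed=2)
        by_plot = h.data.groupby("plot_id")["mean_elevation"].mean()
        assert by_plot.between(300, 850).all()

    def test_heterogeneity_orders_within_plot_habitat_variance(self):
        """Regime multipliers (0.2, 0.6, 1.0) must order the within-plot
        elevation spread monotonically across regimes (averaged over
        replicates)."""
        spreads = {1: [], 2: [], 3: []}
        for s in range(6):
            h = fb.simulate_habitat(
                n_plots=6, grains=(20,), seed=s,
                regime_heterogeneity=(0.2, 0.6, 1.0),
                plot_regimes=[1, 1, 2, 2, 3, 3],
            )
            df = h.data
            df = df.assign(regime=df["plot_id"].map({1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}))
            for reg, sub in df.groupby("regime"):
                spreads[reg].append(sub.groupby("plot_id")["mean_elevation"].std().mean())
        m = {r: np.mean(v) for r, v in spreads.items()}
        assert m[1] < m[2] < m[3]

    def test_bad_grain_rejected(self):
        with pytest.raises(ValidationError, match="grain"):
            fb.simulate_habitat(n_plots=1, grains=(7,), seed=0)


class TestCensus:
    def test_neutral_conservation_and_richness(self):
        sc = fb.AssemblyScenario(mode="neutral", n_species=30, n_regimes=1,
                                 n_plots_per_regime=2, stems_per_plot=500, seed=1)
        ds = fb.simulate_dataset(sc, grains=(20,))
        counts = ds.stems.data.groupby("plot_id").size()
        assert len(counts) == 2
        # Poisson(500) per plot: stay within 5 sd of the mean
        assert counts.between(500 - 5 * np.sqrt(500), 500 + 5 * np.sqrt(500)).all()
        assert ds.stems.data.groupby("plot_id")["species"].nunique().gt(1).all()
        assert (ds.stems.data["dbh"].between(1.0, 80.0)).all()

    def test_dataset_is_pure_function_of_scenario(self):
        sc = fb.AssemblyScenario(mode="priority", n_species=25, n_regimes=1,
                                 n_plots_per_regime=2, stems_per_plot=300,
                                 priority_fraction=0.6, seed=77)
        d1 = fb.simulate_dataset(sc, grains=(20,))
        d2 = fb.simulate_dataset(sc, grains=(20,))
        pd.testing.assert_frame_equal(d1.stems.data, d2.stems.data)
        assert d1.phylogeny.as_newick() == d2.phylogeny.as_newick()
        pd.testing.assert_frame_equal(d1.habitat.data, d2.habitat.data)

    def test_extreme_filtering_sorts_species_onto_habitat(self):
        """With near-zero filter width each subplot should be dominated by a
        species whose trait is unusually close to the local habitat value."""
        sc = fb.AssemblyScenario(mode="filtering", n_species=30, n_regimes=1,
                                 n_plots_per_regime=2, stems_per_plot=2000,
                                 trait_signal_w=1.0, filter_strength_sigma=0.05,
                                 regime_heterogeneity=(1.0,), seed=11)
        ds = fb.simulate_dataset(sc, grains=(10,))
        z = standardize_traits(ds.traits)
        pc1 = pca_scores(z).iloc[:, 0]
        pc1 = (pc1 - pc1.mean()) / pc1.std(ddof=1)
        cm = fb.grid_stems(ds.stems, 10).nonempty()
        ok = 0
        total = 0
        for plot_id, sub in cm.meta.groupby("plot_id"):
            surf, grain = _habitat_surface(ds.habitat, plot_id)
            for sid, row in sub.iterrows():
                counts = cm.counts.loc[sid]
                if counts.sum() < 5:
                    continue
                top = counts.idxmax()
                h = surf[int(row["cy"] // grain), int(row["cx"] // grain)]
                dist_top = abs(pc1[top] - h)
                dist_med = np.median(np.abs(pc1 - h))
                total += 1
                ok += dist_top < dist_med
        assert total > 50
        assert ok / total >= 0.9

    def test_priority_effect_raises_conspecific_concentration(self):
        """Cloned recruitment must make subplots more monodominant than the
        matched neutral run."""

        def mean_simpson(ds):
            cm = fb.grid_stems(ds.stems, 20).nonempty()
            f = cm.relative_abundances().to_numpy()
            return float((f**2).sum(axis=1).mean())

        base = dict(n_species=30, n_regimes=1, n_plots_per_regime=2,
                    stems_per_plot=1000, seed=21)
        neutral = fb.simulate_dataset(fb.AssemblyScenario(mode="neutral", **base), grains=(20,))
        prio = fb.simulate_dataset(
            fb.AssemblyScenario(mode="priority", priority_fraction=0.9, **base), grains=(20,)
        )
        assert mean_simpson(prio) > mean_simpson(neutral)

    def test_species_mismatch_rejected(self, yule8, traits8):
        sc = fb.AssemblyScenario(mode="neutral", n_species=30)
        habitat = fb.simulate_habitat(n_plots=9, grains=(20,), seed=1)
        with pytest.raises(ValidationError, match="species"):
            fb.assemble_census(sc, yule8, traits8, habitat)

    def test_layout_regimes(self):
        pl = plot_layout(3, 3, seed=1)
        assert list(pl.data["regime"]) == [1, 1, 1, 2, 2, 2, 3, 3, 3]
        assert pl.data["plot_id"].is_unique

    def test_write_roundtrip(self, tmp_path, reduced_neutral):
        reduced_neutral.write(tmp_path / "ds")
        from forestbeta import data_io

        stems = data_io.read_stem_table(tmp_path / "ds" / "stems.tsv")
        phy = data_io.read_phylogeny(tmp_path / "ds" / "phylogeny.nwk")
        traits = data_io.read_trait_table(tmp_path / "ds" / "traits.tsv")
        assert len(stems) == len(reduced_neutral.stems)
        stems.check_cross_references(phy, traits)
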