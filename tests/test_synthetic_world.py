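"""Generator-level checks: determinism, injected structure, and
Monte-Carlo agreement with closed-form expectations."""

import numpy as np
import pytest

from arborclim.raster import VARIABLE_CODES
from arborclim.rrpp_models import phylo_covariance
from arborclim.synthetic_world import (
    ARBOREAL,
    BASELINE_MEANS,
    N_VARS,
    SamplingError,
    TERRESTRIAL,
    World,
    WorldConfig,
    WorldConfigError,
    assign_microhabitats,
    build_world,
    evolve_niche_centers,
    generate_climate_raster,
    sample_occurrences,
    simulate_chronogram,
    tree_height,
)


class TestWorldConfig:
    def test_non_psd_correlation_rejected(self):
        bad = np.eye(N_VARS)
        bad[0, 1] = bad[1, 0] = 1.5  # breaks PSD while staying symmetric
        with pytest.raises(WorldConfigError, match="positive semi-definite"):
            WorldConfig(layer_correlation=bad)

    def test_nonpositive_breadth_rejected(self):
        with pytest.raises(WorldConfigError, match="niche_breadth"):
            WorldConfig(niche_breadth=np.zeros(N_VARS))


class TestClimateRaster:
    def test_seeded_determinism(self):
        cfg = WorldConfig(grid_rows=20, grid_cols=20, seed=3)
        r1 = generate_climate_raster(cfg)
        r2 = generate_climate_raster(cfg)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_identity_correlation_gives_independent_layers(self):
        cfg = WorldConfig(
            grid_rows=100,
            grid_cols=100,
            smoothing_radius=0.0,
            layer_correlation=np.eye(N_VARS),
            temp_lat_gradient=0.0,
            seed=5,
        )
        raster = generate_climate_raster(cfg)
        flat = raster.values.reshape(N_VARS, -1)
        corr = np.corrcoef(flat)
        off = corr[~np.eye(N_VARS, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_imposed_correlation_recovered(self):
        cfg = WorldConfig(grid_rows=100, grid_cols=100, temp_lat_gradient=0.0,
                          seed=2)
        raster = generate_climate_raster(cfg)
        flat = raster.values.reshape(N_VARS, -1)
        corr = np.corrcoef(flat)
        # elevation clipping distorts its row slightly; exclude it
        keep = [i for i, c in enumerate(VARIABLE_CODES) if c != "Elev"]
        target = cfg.layer_correlation[np.ix_(keep, keep)]
        got = corr[np.ix_(keep, keep)]
        assert np.abs(got - target).max() < 0.15

    def test_latitudinal_temperature_gradient(self):
        # 1-degree pixels so the grid spans 60 degrees of latitude and the
        # deterministic gradient dominates the stochastic field
        cfg = WorldConfig(grid_rows=60, grid_cols=60, temp_lat_gradient=0.7,
                          lat_origin=60.0, pixel_size=60.0, seed=4)
        raster = generate_climate_raster(cfg)
        bio1_row_mean = raster.layer("BIO1").mean(axis=1)
        lat = np.abs(raster.latitudes())
        rho = np.corrcoef(lat, bio1_row_mean)[0, 1]
        assert rho < -0.8
        # and the injected trend itself is strictly monotone in |latitude|
        trend = -cfg.temp_lat_gradient * lat
        assert np.all(np.diff(trend[np.argsort(lat)]) < 0)

    def test_elevation_nonnegative(self, small_raster):
        assert (small_raster.layer("Elev") >= 0).all()

    def test_twelve_codes(self, small_raster):
        assert small_raster.variable_codes == VARIABLE_CODES
        assert len(small_raster.variable_codes) == 12


class TestChronogram:
    def test_two_species_minimal_tree(self):
        tree = simulate_chronogram(2, 1.0, 0)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        d = [leaf.distance_from_root() for leaf in leaves]
        assert d[0] == pytest.approx(d[1], rel=1e-12)

    def test_full_clade_size(self):
        # the real study covers 277 species; the generator must scale there
        tree = simulate_chronogram(277, 1.0, 1)
        assert len(tree.leaf_nodes()) == 277

    def test_ultrametric(self):
        for seed in range(5):
            tree = simulate_chronogram(12, 0.7, seed)
            d = np.array([l.distance_from_root() for l in tree.leaf_node_iter()])
            np.testing.assert_allclose(d, d[0], rtol=1e-8)

    def test_yule_height_expectation(self):
        # E[height] = sum_{k=2..n} 1/(k*lambda) for the tip-conditioned
        # pure-birth process
        n, lam, reps = 8, 1.0, 2000
        heights = np.array(
            [tree_height(simulate_chronogram(n, lam, s)) for s in range(reps)]
        )
        expected = sum(1.0 / k for k in range(2, n + 1)) / lam
        se = heights.std(ddof=1) / np.sqrt(reps)
        assert abs(heights.mean() - expected) < 3 * se

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_chronogram(1, 1.0, 0)


class TestMicrohabitatEvolution:
    def test_zero_rates_keep_root_state(self):
        tree = simulate_chronogram(10, 1.0, 0)
        labels = assign_microhabitats(tree, 0.0, 0.0, ARBOREAL, seed=1)
        assert set(labels.values()) == {ARBOREAL}

    def test_loss_biased_rates_keep_arboreality_rare(self):
        # with loss 23x gain and a terrestrial root, arboreal tips stay a
        # minority on average
        fracs = []
        for s in range(500):
            tree = simulate_chronogram(16, 1.0, s)
            labels = assign_microhabitats(tree, 0.05, 23 * 0.05, seed=s)
            fracs.append(
                np.mean([v == ARBOREAL for v in labels.values()])
            )
        assert np.mean(fracs) < 0.5

    def test_fast_chain_reaches_stationarity(self):
        # huge equal rates decouple tips from topology: fraction ~ 1/2
        fracs = []
        for s in range(300):
            tree = simulate_chronogram(16, 1.0, s)
            labels = assign_microhabitats(tree, 500.0, 500.0, seed=s)
            fracs.append(np.mean([v == ARBOREAL for v in labels.values()]))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.5) < 4 * se + 0.01

    def test_negative_rate_rejected(self):
        tree = simulate_chronogram(4, 1.0, 0)
        with pytest.raises(ValueError):
            assign_microhabitats(tree, -0.1, 1.0)


class TestNicheCenters:
    def test_degenerate_diffusion_returns_root(self):
        tree = simulate_chronogram(6, 1.0, 0)
        labels = {l.taxon.label: TERRESTRIAL for l in tree.leaf_node_iter()}
        root = np.linspace(1, 12, N_VARS)
        centers = evolve_niche_centers(
            tree, labels, np.zeros(N_VARS), np.zeros(N_VARS), root, seed=0
        )
        for v in centers.values():
            np.testing.assert_array_equal(v, root)

    def test_arboreal_shift_recovered(self):
        # mean(arboreal) - mean(terrestrial) across replicates ~ shift
        tree = simulate_chronogram(16, 1.0, 3)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        labels = {t: (ARBOREAL if i < 8 else TERRESTRIAL)
                  for i, t in enumerate(tips)}
        shift = np.full(N_VARS, 2.0)
        diffs = []
        for s in range(1000):
            centers = evolve_niche_centers(
                tree, labels, np.ones(N_VARS), shift, np.zeros(N_VARS), seed=s
            )
            arb = np.mean([centers[t] for t in tips[:8]], axis=0)
            ter = np.mean([centers[t] for t in tips[8:]], axis=0)
            diffs.append(arb - ter)
        diffs = np.array(diffs)
        se = diffs.std(axis=0, ddof=1) / np.sqrt(len(diffs))
        assert np.all(np.abs(diffs.mean(axis=0) - shift) < 3 * se)

    def test_tip_covariance_follows_shared_history(self):
        # cov of two tips' Brownian values ~ root-to-MRCA path length
        tree = simulate_chronogram(8, 1.0, 11)
        C, species = phylo_covariance(tree)
        labels = {sp: TERRESTRIAL for sp in species}
        vals = []
        for s in range(1000):
            centers = evolve_niche_centers(
                tree, labels, np.ones(N_VARS), np.zeros(N_VARS),
                np.zeros(N_VARS), seed=s,
            )
            vals.append([centers[sp][0] for sp in species])
        vals = np.array(vals)
        emp = np.cov(vals, rowvar=False)
        # Monte-Carlo SE of a covariance is ~ C_scale/sqrt(reps); allow a
        # generous band around the Brownian expectation
        scale = np.sqrt(np.outer(np.diag(C), np.diag(C)))
        assert np.abs(emp - C).max() < 4 * scale.max() / np.sqrt(1000) + 0.15


class TestOccurrences:
    def test_tiny_breadth_collapses_to_argmax(self, small_raster):
        # centering exactly on one pixel's climate makes that pixel the
        # unique suitability argmax; a near-degenerate Gaussian puts all
        # points there
        rows, cols, X = small_raster.valid_pixel_matrix()
        k = 37
        occ = sample_occurrences(
            X[k], np.full(N_VARS, 1e-4), small_raster, 20, seed=1
        )
        pts = occ[["longitude", "latitude"]].drop_duplicates()
        assert pts.shape[0] == 1
        lon, lat = small_raster.pixel_center(rows[k], cols[k])
        assert pts.iloc[0]["longitude"] == pytest.approx(float(lon))
        assert pts.iloc[0]["latitude"] == pytest.approx(float(lat))

    def test_three_points_meets_inclusion_floor(self, small_raster):
        occ = sample_occurrences(
            BASELINE_MEANS, np.full(N_VARS, 50.0) * BASELINE_MEANS.clip(1e-3),
            small_raster, 3, seed=0,
        )
        assert len(occ) == 3

    def test_mean_climate_approaches_center_as_breadth_shrinks(
        self, small_raster
    ):
        from arborclim.climate_summaries import extract_climate

        rows, cols, X = small_raster.valid_pixel_matrix()
        center = np.quantile(X, 0.7, axis=0)  # attainable target climate
        sds = X.std(axis=0)
        errs = []
        for factor in (3.0, 1.0, 0.3):
            occ = sample_occurrences(
                center, factor * sds, small_raster, 5000, seed=42
            )
            vals = extract_climate(occ, small_raster)
            got = vals[list(small_raster.variable_codes)].mean().to_numpy()
            errs.append(np.linalg.norm((got - center) / sds))
        assert errs[0] > errs[1] > errs[2]

    def test_unreachable_center_raises(self, small_raster):
        far = BASELINE_MEANS + 1e6
        with pytest.raises(SamplingError, match="suitability"):
            sample_occurrences(far, np.full(N_VARS, 1e-3), small_raster, 5)


class TestWholeWorld:
    def test_world_determinism(self):
        cfg = WorldConfig(n_species=8, grid_rows=25, grid_cols=25, seed=9)
        w1: World = build_world(cfg)
        w2: World = build_world(cfg)
        np.testing.assert_array_equal(w1.raster.values, w2.raster.values)
        assert w1.labels == w2.labels
        assert w1.occurrences.equals(w2.occurrences)
        assert (
            w1.tree.as_string(schema="newick")
            == w2.tree.as_string(schema="newick")
        )

    def test_occurrences_inside_extent(self):
        cfg = WorldConfig(n_species=6, grid_rows=25, grid_cols=25, seed=2)
        world = build_world(cfg)
        r = world.raster
        lon = world.occurrences["longitude"]
        lat = world.occurrences["latitude"]
        assert (lon >= r.lon_origin).all()
        assert (lon <= r.lon_origin + r.n_cols * r.pixel_deg).all()
        assert (lat <= r.lat_origin).all()
        assert (lat >= r.lat_origin - r.n_rows * r.pixel_deg).all()
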