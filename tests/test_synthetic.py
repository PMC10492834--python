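"""Synthetic catchment generator: determinism, spatial structure, marginal
targets, and exact round trips through the accounting modules."""
import math

import numpy as np
import pytest
from scipy import ndimage

import borealcarbon as bc
from borealcarbon.config import GeneratorConfig
from borealcarbon.errors import InvalidArgumentError
from borealcarbon.synthetic import (
    assign_moisture_class,
    generate_als_points,
    generate_catchment,
    generate_soil_profile,
    generate_tree_list,
    generate_wetness_surface,
    quantile_thresholds,
    sample_wetness,
)


def lag1_autocorr(field):
    a = field - field.mean()
    return float((a[:, :-1] * a[:, 1:]).sum() / (a * a).sum())


class TestWetnessSurface:
    def test_determinism(self):
        g1 = generate_wetness_surface((40, 40), 2.0, 10.0, seed=7)
        g2 = generate_wetness_surface((40, 40), 2.0, 10.0, seed=7)
        assert np.array_equal(g1.values, g2.values)

    def test_values_in_unit_interval(self):
        g = generate_wetness_surface((50, 50), 2.0, 8.0, seed=3)
        assert g.values.min() >= 0.0 and g.values.max() <= 1.0

    def test_no_smoothing_limit(self):
        """Correlation length far below the cell size: neighbouring cells
        are near-independent."""
        g = generate_wetness_surface((100, 100), 2.0, 0.01, seed=5)
        assert abs(lag1_autocorr(g.values)) < 0.2

    def test_smoothing_produces_autocorrelation(self):
        g = generate_wetness_surface((100, 100), 1.0, 10.0, seed=5)
        assert lag1_autocorr(g.values) > 0.5

    def test_convolution_oracle(self):
        """The smoothed Gaussian field equals a direct circular convolution
        with the same truncated Gaussian kernel on a subgrid."""
        seed, sigma = 11, 3.0
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        z = rng.standard_normal((20, 20))
        smoothed = ndimage.gaussian_filter(z, sigma=sigma, mode="wrap")
        # direct convolution oracle: separable truncated kernel, wrapped
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        direct = np.zeros_like(z)
        n = 20
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for di, wi in zip(x, k):
                    for dj, wj in zip(x, k):
                        acc += wi * wj * z[(i + di) % n, (j + dj) % n]
                direct[i, j] = acc
        assert np.allclose(smoothed, direct, atol=1e-10)

    def test_rejects_bad_extent(self):
        with pytest.raises(InvalidArgumentError):
            generate_wetness_surface((0, 10), 2.0, 5.0, seed=1)


class TestMoistureClasses:
    def test_boundaries(self):
        t = (0.1, 0.4, 0.6, 0.8)
        assert assign_moisture_class(0.0, t) == 1
        assert assign_moisture_class(1.0, t) == 5

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            assign_moisture_class(1.2, (0.1, 0.4, 0.6, 0.8))

    def test_class_frequencies_match_proportions(self, rng):
        """Quantile thresholds reproduce the configured 7/73/11/7/2 class
        frequencies within 1.5 points on 10,000 uniform draws."""
        w = rng.uniform(0, 1, 10_000)
        props = (0.07, 0.73, 0.11, 0.07, 0.02)
        t = quantile_thresholds(w, props)
        cls = assign_moisture_class(w, t)
        freq = np.bincount(cls, minlength=6)[1:] / w.size
        assert np.all(np.abs(freq - np.array(props)) < 0.015)


class TestSoilProfiles:
    def test_dry_end_minimum_no_noise(self):
        cfg = GeneratorConfig().noiseless()
        p = generate_soil_profile(0.0, seed=1, config=cfg)
        assert p.organic_thickness == pytest.approx(cfg.thickness_dry_cm)
        assert not p.is_peat

    def test_sd_zero_total_soc_on_curve(self):
        """With all residual sds at zero the accounted total SOC equals the
        generating log-quadratic exactly, through the full accounting."""
        cfg = GeneratorConfig().noiseless()
        for w in (0.0, 0.07, 0.18, 0.35, 0.8):
            p = generate_soil_profile(w, seed=2, config=cfg)
            got = bc.total_soc(p).total_soc
            want = math.exp(4.23 + 8.51 * w + 3.35 * w * w)
            assert got == pytest.approx(want, rel=1e-9)

    def test_peat_fraction_target(self):
        """Marginal peat fraction within 2 points of the 11 % target."""
        cfg = GeneratorConfig()
        w = sample_wetness(5000, seed=11, beta_params=cfg.wetness_beta)
        rngs = [np.random.default_rng(i) for i in range(5000)]
        frac = np.mean(
            [generate_soil_profile(x, 0, cfg, rng=r).is_peat for x, r in zip(w, rngs)]
        )
        assert abs(frac - 0.11) < 0.02

    def test_noise_injected_is_residual(self):
        """The log residual of the accounted SOC around the generating curve
        is exactly the injected noise draw (the inversion is exact even with
        noise on)."""
        cfg = GeneratorConfig()
        w = sample_wetness(200, seed=3, beta_params=cfg.wetness_beta)
        y = np.array(
            [
                bc.total_soc(
                    generate_soil_profile(x, 0, cfg, rng=np.random.default_rng(i))
                ).total_soc
                for i, x in enumerate(w)
            ]
        )
        resid = np.log(y) - (4.23 + 8.51 * w + 3.35 * w**2)
        assert abs(float(np.std(resid)) - cfg.soc_log_sd) < 0.04
        assert abs(float(np.mean(resid))) < 3 * cfg.soc_log_sd / math.sqrt(200)


class TestTreeLists:
    def test_zero_age_is_clear_cut(self):
        assert generate_tree_list(0.3, 0.0, seed=1, config=GeneratorConfig()) == []

    def test_determinism(self):
        cfg = GeneratorConfig()
        t1 = generate_tree_list(0.3, 90.0, seed=7, config=cfg)
        t2 = generate_tree_list(0.3, 90.0, seed=7, config=cfg)
        assert t1 == t2

    def test_sd_zero_plot_carbon_on_curve(self):
        cfg = GeneratorConfig().noiseless()
        for w in (0.0, 0.2, 0.5):
            trees = generate_tree_list(w, 120.0, seed=3, config=cfg)
            got = bc.plot_tree_carbon(trees, 10.0).tree_total
            want = max(0.0, 44.0 + 170.0 * w - 200.0 * w * w)
            assert got == pytest.approx(want, rel=1e-9)

    def test_dbh_recording_rule(self):
        trees = generate_tree_list(0.2, 150.0, seed=9, config=GeneratorConfig())
        assert all(t.dbh > 4.0 for t in trees)

    def test_unimodal_in_wetness(self):
        """With the generating vertex at x = 0.4, mean simulated tree C at
        0.4 exceeds the means at 0.05 and 0.95."""
        cfg = GeneratorConfig(tree_curve=(44.0, 180.0, -225.0))  # vertex at 0.4
        means = {}
        for w in (0.05, 0.4, 0.95):
            tot = 0.0
            for i in range(300):
                trees = generate_tree_list(
                    w, 100.0, config=cfg, rng=np.random.default_rng(1000 + i)
                )
                tot += bc.plot_tree_carbon(trees, 10.0).tree_total
            means[w] = tot / 300
        assert means[0.4] > means[0.05]
        assert means[0.4] > means[0.95]

    def test_measured_subsample_flagged(self):
        trees = generate_tree_list(0.25, 110.0, seed=5, config=GeneratorConfig())
        by_sp = {}
        for t in trees:
            by_sp.setdefault(t.species, []).append(t)
        for sp, group in by_sp.items():
            n_meas = sum(t.height_measured for t in group)
            assert n_meas == min(3, len(group))


class TestAlsPoints:
    def test_bare_ground(self):
        h = generate_als_points([], seed=2)
        assert np.all(h == 0.0)

    def test_support_bound_single_tree(self):
        tree = bc.TreeRecord("p", "pine", 40.0, height=20.0)
        h = generate_als_points([tree], seed=4)
        assert h.max() <= 20.0
        assert float(np.percentile(h, 95)) <= 20.0

    def test_poisson_count(self):
        """Density 20 on a 156.25 m2 cell gives 3125 returns up to Poisson
        noise (5 sigma band)."""
        counts = [
            len(generate_als_points([], cell_area_m2=156.25, density=20.0, seed=s))
            for s in range(30)
        ]
        lam = 20.0 * 156.25
        assert abs(np.mean(counts) - lam) < 5 * math.sqrt(lam / 30)

    def test_canopy_fraction_increases_with_density(self):
        dense = [bc.TreeRecord("p", "pine", 25.0, height=18.0)] * 30
        sparse = dense[:3]
        vr_dense = np.mean(generate_als_points(dense, seed=6) > 1.5)
        vr_sparse = np.mean(generate_als_points(sparse, seed=6) > 1.5)
        assert vr_dense > vr_sparse


class TestCatchment:
    def test_bit_reproducible(self, small_generator):
        c1 = generate_catchment(small_generator, seed=9)
        c2 = generate_catchment(small_generator, seed=9)
        assert np.array_equal(c1.wetness.values, c2.wetness.values)
        assert c1.trees == c2.trees
        assert [p.organic_core_dry_mass for p in c1.profiles] == [
            p.organic_core_dry_mass for p in c2.profiles
        ]

    def test_one_profile_per_plot_and_tree_references(self, small_generator):
        cat = generate_catchment(small_generator, seed=9)
        plot_ids = {p.plot_id for p in cat.plots}
        assert len(cat.profiles) == len(cat.plots)
        assert {p.plot_id for p in cat.profiles} == plot_ids
        assert all(t.plot_id in plot_ids for t in cat.trees)

    def test_wetness_in_unit_interval(self, small_generator):
        cat = generate_catchment(small_generator, seed=9)
        assert all(0.0 <= p.wetness <= 1.0 for p in cat.plots)

    def test_sd_zero_refit_recovers_generating_curves(self, small_generator):
        """Full round trip: accounting + refit on a noise-free catchment
        recovers both generating coefficient sets to numerical precision."""
        cfg = small_generator.noiseless()
        cat = generate_catchment(cfg, seed=9)
        w = np.array([p.wetness for p in cat.plots])
        soc = np.array([bc.total_soc(pr).total_soc for pr in cat.profiles])
        m = bc.fit_moisture_model(w, soc, degree=2, log_scale=True)
        assert m.coefficients_ == pytest.approx([4.23, 8.51, 3.35], abs=1e-7)

        ages = {p.plot_id: p.stand_age for p in cat.plots}
        mature = [p.plot_id for p in cat.plots if ages[p.plot_id] >= 80]
        if len(mature) >= 8:
            tree_c = {
                pid: bc.plot_tree_carbon(cat.trees_of(pid), cfg.plot_radius).tree_total
                for pid in mature
            }
            wm = np.array([w[int(pid[1:])] for pid in mature])
            ym = np.array([tree_c[pid] for pid in mature])
            keep = ym > 0.5  # exclude truncated-at-zero plots
            mt = bc.fit_moisture_model(wm[keep], ym[keep], degree=2, log_scale=False)
            assert mt.coefficients_ == pytest.approx([44.0, 170.0, -200.0], abs=1e-6)

    def test_belowground_share_band(self, small_generator):
        """Aggregate belowground share of tree C lands in a band around the
        conventional ~24 %."""
        cat = generate_catchment(small_generator, seed=9)
        above = below = 0.0
        for pid in {p.plot_id for p in cat.plots}:
            pools = bc.plot_tree_carbon(cat.trees_of(pid), 10.0)
            above += pools.tree_above
            below += pools.tree_below
        share = below / (above + below)
        assert 0.18 < share < 0.30
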