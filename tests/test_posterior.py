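"""Burn-in, chain merging, HPD regions, growth bands."""

import numpy as np
import pytest

from turingbayes.posterior import (
    GrowthBand,
    bands_separated,
    curve_in_band,
    detect_burn_in,
    growth_band,
    hpd_region,
    merge_chains,
    pairwise_hpd,
)
from turingbayes.samplers import Chain


def _chain(samples, names=("a", "b")):
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
        names = names[:1]
    n = len(samples)
    return Chain(
        samples=samples,
        phis=np.zeros(n),
        step_index=np.arange(n),
        seed=0,
        n_proposals=1,
        names=list(names),
    )


class TestBurnIn:
    def test_iid_samples_need_no_burn_in(self):
        rng = np.random.default_rng(0)
        assert detect_burn_in(rng.standard_normal((2000, 2))) == 0

    def test_constructed_transient_is_cut(self):
        rng = np.random.default_rng(1)
        clean = rng.standard_normal(1000)
        shifted = np.concatenate([clean[:500] + 10.0, clean[500:]])
        B = detect_burn_in(shifted[:, None])
        assert B >= 500

    def test_constant_chain(self):
        assert detect_burn_in(np.ones((500, 1))) == 0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            detect_burn_in(np.ones((50, 1)))


class TestMergeChains:
    def test_single_chain_returns_post_burn_in(self):
        rng = np.random.default_rng(2)
        c = _chain(rng.standard_normal((400, 2)))
        merged = merge_chains([c])
        assert set(merged.columns) == {"a", "b", "chain"}
        assert len(merged) == 400  # i.i.d.: no burn-in removed

    def test_name_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        c1 = _chain(rng.standard_normal((200, 2)), names=("a", "b"))
        c2 = _chain(rng.standard_normal((200, 2)), names=("d", "gamma"))
        with pytest.raises(ValueError):
            merge_chains([c1, c2])

    def test_merged_mean_is_weighted_chain_mean(self):
        rng = np.random.default_rng(4)
        s1 = rng.standard_normal((300, 2))
        s2 = rng.standard_normal((500, 2)) + 5.0
        merged = merge_chains([_chain(s1), _chain(s2)])
        # arithmetic identity against the per-chain post-burn-in samples
        kept = [s[detect_burn_in(s):] for s in (s1, s2)]
        total = np.concatenate(kept)
        assert len(merged) == len(total)
        np.testing.assert_allclose(
            merged[["a", "b"]].to_numpy().mean(axis=0), total.mean(axis=0), atol=1e-12
        )


class TestHPDRegion:
    def test_gaussian_1d_interval(self):
        rng = np.random.default_rng(5)
        samples = rng.standard_normal(60_000)
        region = hpd_region(samples, level=0.95, grid_resolution=400)
        box = region.bounding_box()
        assert box[0, 0] == pytest.approx(-1.96, abs=0.05)
        assert box[0, 1] == pytest.approx(1.96, abs=0.05)
        assert region.level == 0.95
        assert region.mass >= 0.95

    def test_gaussian_2d_disc_area(self):
        rng = np.random.default_rng(6)
        samples = rng.standard_normal((25_000, 2))
        region = hpd_region(samples, level=0.95, grid_resolution=120)
        # chi-square(2) 0.95 quantile: radius sqrt(5.9915) = 2.4477
        expected = np.pi * 5.9915
        assert abs(region.area() - expected) / expected < 0.05
        assert region.contains([0.0, 0.0])
        assert not region.contains([3.5, 3.5])

    def test_full_level_covers_all_samples(self):
        rng = np.random.default_rng(7)
        samples = rng.standard_normal(5000)
        region = hpd_region(samples, level=1.0, grid_resolution=200)
        assert region.contains([samples.min()])
        assert region.contains([samples.max()])
        assert region.mass == pytest.approx(1.0, abs=1e-9)

    def test_mass_close_to_level(self):
        rng = np.random.default_rng(8)
        for level in (0.5, 0.9, 0.95):
            region = hpd_region(rng.standard_normal(8_000), level=level, grid_resolution=150)
            assert level <= region.mass <= level + 0.02

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd_region(np.ones(2000), level=0.95)

    def test_region_shrinks_with_more_data(self):
        # conjugate Gaussian inference: doubling the observations halves the
        # posterior variance, and the HPD interval must shrink accordingly
        rng = np.random.default_rng(9)
        lengths = []
        for n_obs in (10, 40):
            post_sd = 1.0 / np.sqrt(n_obs)
            samples = rng.normal(0.3, post_sd, size=12_000)
            region = hpd_region(samples, level=0.95)
            lengths.append(region.side_lengths()[0])
        assert lengths[1] < 0.6 * lengths[0]

    def test_frequentist_coverage_on_linear_gaussian_problem(self):
        # y = theta + eps, eps ~ N(0, 1), flat prior: posterior N(y, 1).
        # The 95% HPD interval from exact posterior samples should cover the
        # true theta in ~95% of repetitions.
        rng = np.random.default_rng(10)
        theta = 1.7
        hits = 0
        reps = 500
        for _ in range(reps):
            y = theta + rng.standard_normal()
            post = rng.normal(y, 1.0, size=1000)
            region = hpd_region(post, level=0.95, grid_resolution=100)
            hits += region.contains([theta])
        assert 0.92 <= hits / reps <= 0.98


class TestPairwise:
    def test_2d_input_single_panel(self):
        rng = np.random.default_rng(11)
        samples = rng.standard_normal((5000, 2))
        panels = pairwise_hpd(samples, level=0.9)
        assert list(panels.keys()) == [(0, 1)]

    def test_4d_input_six_panels(self):
        rng = np.random.default_rng(12)
        samples = rng.standard_normal((3000, 4))
        panels = pairwise_hpd(samples, level=0.9, grid_resolution=60)
        assert len(panels) == 6

    def test_independent_gaussians_give_elliptical_region(self):
        # for independent Gaussians the 2-D 95% HPD region is the ellipse
        # with semi-axes sqrt(chi2_2(0.95)) * sigma_k = 2.4477 sigma_k,
        # so the bounding-box extent per axis is 4.8955 sigma_k
        rng = np.random.default_rng(13)
        samples = np.column_stack(
            [rng.normal(0, 1, 20_000), rng.normal(5, 3, 20_000)]
        )
        region2d = pairwise_hpd(samples, level=0.95)[(0, 1)]
        box = region2d.bounding_box()
        assert abs(box[0, 1] - box[0, 0]) == pytest.approx(2 * 2.4477 * 1.0, rel=0.05)
        assert abs(box[1, 1] - box[1, 0]) == pytest.approx(2 * 2.4477 * 3.0, rel=0.05)


class TestGrowthBand:
    T, rho_T = 600.0, 1.8221188

    def test_identical_samples_zero_width(self):
        dof = np.tile([0.1, -0.05, 0.2], (50, 1))
        band = growth_band(dof, self.T, self.rho_T, level=0.95)
        np.testing.assert_allclose(band.lower, band.upper, atol=1e-12)
        np.testing.assert_allclose(band.lower, band.mean_curve, atol=1e-12)

    def test_gaussian_linear_map_band_quantiles(self):
        # c1 ~ N(0.8, 0.1^2), c2 = c3 = 0, rho_T = 1.8: the curve value at
        # scaled time s is 1 + 0.8 s^4 + c1 (s - s^4), linear in c1, so the
        # 95% band is its Gaussian quantile interval (closed form)
        rng = np.random.default_rng(14)
        dof = np.zeros((50_000, 3))
        dof[:, 0] = rng.normal(0.8, 0.1, size=len(dof))
        band = growth_band(dof, self.T, 1.8, level=0.95, n_t=101)
        s0 = band.t[50] / self.T  # = 0.5
        base = 1.0 + 0.8 * s0**4
        lin = s0 - s0**4
        assert band.lower[50] == pytest.approx(base + lin * (0.8 - 1.96 * 0.1), abs=0.003)
        assert band.upper[50] == pytest.approx(base + lin * (0.8 + 1.96 * 0.1), abs=0.003)

    def test_band_contains_the_nominal_fraction_pointwise(self):
        rng = np.random.default_rng(15)
        dof = rng.normal(0, 0.3, size=(4000, 3))
        band = growth_band(dof, self.T, self.rho_T, level=0.95)
        from turingbayes.priors import growth_curves

        curves = growth_curves(dof, self.T, self.rho_T, band.t)
        frac = np.mean((curves >= band.lower) & (curves <= band.upper), axis=0)
        assert np.all(frac >= 0.94)


class TestBandsSeparated:
    def _band(self, offset, width=0.1):
        t = np.linspace(0, 1, 101)
        mid = 1.0 + offset * t
        return GrowthBand(t, mid - width, mid + width, mid, 0.95)

    def test_identical_bands_not_separated(self):
        b = self._band(0.5)
        assert not bands_separated(b, b)

    def test_disjoint_bands_separated(self):
        assert bands_separated(self._band(0.0), self._band(1.0))

    def test_touching_tail_below_contiguity_threshold(self):
        # disjoint only on a sub-interval shorter than 5% of the grid
        t = np.linspace(0, 1, 101)
        b1 = GrowthBand(t, np.zeros(101), np.ones(101), np.full(101, 0.5), 0.95)
        upper2 = np.full(101, 3.0)
        lower2 = np.full(101, 0.5)
        lower2[:3] = 1.5  # disjoint at only 3 of 101 grid times
        b2 = GrowthBand(t, lower2, upper2, np.full(101, 2.0), 0.95)
        assert bands_separated(b1, b2, min_fraction=0.02)
        assert not bands_separated(b1, b2, min_fraction=0.05)

    def test_curve_in_band(self):
        b = self._band(0.5, width=0.2)
        assert curve_in_band(b, b.mean_curve)
        assert not curve_in_band(b, b.mean_curve + 1.0)

    def test_grid_mismatch_rejected(self):
        b1 = self._band(0.0)
        t = np.linspace(0, 2, 101)
        b2 = GrowthBand(t, np.zeros(101), np.ones(101), np.full(101, 0.5), 0.95)
        with pytest.raises(ValueError):
            bands_separated(b1, b2)
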