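"""Axial circular statistics: resultant, CI, histograms, ROI summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from dichropam import (
    EmptySampleError,
    OrientationSample,
    axial_resultant,
    compute_dichroism,
    make_stack,
    mean_angle_ci95,
    PhantomSpec,
    polar_histogram,
    roi_summary,
    sample_axial_vonmises,
    wrap_axial,
)


class TestAxialResultant:
    def test_identical_angles_give_unit_resultant(self):
        mean, r = axial_resultant(OrientationSample(np.full(50, 40.0)))
        assert r == pytest.approx(1.0)
        assert mean == pytest.approx(40.0)

    def test_perpendicular_pair_cancels(self):
        mean, r = axial_resultant(OrientationSample(np.array([0.0, 90.0])))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(mean)

    def test_von_mises_resultant_matches_bessel_ratio(self):
        rng = np.random.default_rng(123)
        angles = sample_axial_vonmises(10.0, kappa=2.0, n=100_000, rng=rng)
        _, r = axial_resultant(OrientationSample(angles))
        assert r == pytest.approx(i1(2.0) / i0(2.0), abs=0.01)

    def test_uniform_axial_sample_has_near_zero_resultant(self):
        rng = np.random.default_rng(99)
        angles = rng.uniform(-90.0, 90.0, 10_000)
        _, r = axial_resultant(OrientationSample(angles))
        assert r < 0.02

    def test_branch_choice_does_not_matter(self):
        # theta and theta + 180 describe the same axis
        rng = np.random.default_rng(5)
        theta = rng.uniform(-90, 90, 200)
        m1, r1 = axial_resultant(OrientationSample(theta))
        m2, r2 = axial_resultant(OrientationSample(theta + 180.0))
        assert r1 == pytest.approx(r2)
        assert wrap_axial(m1 - m2) == pytest.approx(0.0, abs=1e-9)

    @given(delta=st.floats(min_value=-180, max_value=180))
    @settings(max_examples=25, deadline=None)
    def test_rotation_equivariance(self, delta):
        rng = np.random.default_rng(17)
        theta = sample_axial_vonmises(20.0, 4.0, 300, rng)
        m1, r1 = axial_resultant(OrientationSample(theta))
        m2, r2 = axial_resultant(OrientationSample(theta + delta))
        assert r2 == pytest.approx(r1, abs=1e-9)
        assert wrap_axial(m2 - m1 - delta) == pytest.approx(0.0, abs=1e-6)

    def test_resultant_increases_with_concentration(self):
        rng = np.random.default_rng(31)
        rs = []
        for kappa in (0.5, 1.0, 2.0, 4.0, 8.0):
            angles = sample_axial_vonmises(0.0, kappa, 10_000, rng)
            rs.append(axial_resultant(OrientationSample(angles))[1])
        assert all(b > a for a, b in zip(rs, rs[1:]))

    def test_empty_and_zero_weight_samples_rejected(self):
        with pytest.raises(EmptySampleError):
            OrientationSample(np.array([]))
        with pytest.raises(ValueError):
            OrientationSample(np.array([1.0, 2.0]), np.zeros(2))


class TestMeanAngleCI:
    def test_zero_dispersion_gives_zero_width(self):
        lo, hi = mean_angle_ci95(OrientationSample(np.full(30, 12.0)), seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        sample = OrientationSample(sample_axial_vonmises(30.0, 3.0, 100, rng))
        assert mean_angle_ci95(sample, seed=7) == mean_angle_ci95(sample, seed=7)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        widths = []
        for n in (50, 500, 5000):
            sample = OrientationSample(sample_axial_vonmises(0.0, 2.0, n, rng))
            lo, hi = mean_angle_ci95(sample, seed=1)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    @pytest.mark.parametrize("method", ["bootstrap", "fisher"])
    def test_coverage_near_nominal(self, method):
        """~95% of CIs over seeded replicates contain the true axial mean."""
        true_mean = 20.0
        rng = np.random.default_rng(1000)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            angles = sample_axial_vonmises(true_mean, 4.0, 200, rng)
            sample = OrientationSample(angles)
            lo, hi = mean_angle_ci95(sample, method=method, n_boot=500, seed=i)
            # containment on the axial circle, relative to the interval center
            center = (lo + hi) / 2.0
            half = (hi - lo) / 2.0
            hits += abs(wrap_axial(true_mean - center)) <= half
        assert 0.90 <= hits / n_rep <= 0.99

    def test_undefined_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_angle_ci95(OrientationSample(np.array([0.0, 90.0] * 10)))


class TestPolarHistogram:
    def test_uniform_grid_fills_bins_evenly(self):
        angles = np.arange(-90.0, 90.0, 1.0)
        _, counts = polar_histogram(OrientationSample(angles), n_bins=18)
        np.testing.assert_array_equal(counts, 10)

    def test_single_cluster_occupies_one_bin(self):
        _, counts = polar_histogram(OrientationSample(np.full(7, 42.0)), n_bins=18)
        assert counts.sum() == 7 and (counts > 0).sum() == 1

    @given(perm_seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_mass_conserved_under_permutation(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        angles = rng.uniform(-90, 90, 64)
        w = rng.uniform(0.1, 2.0, 64)
        perm = rng.permutation(64)
        _, c1 = polar_histogram(OrientationSample(angles, w))
        _, c2 = polar_histogram(OrientationSample(angles[perm], w[perm]))
        np.testing.assert_allclose(c1, c2)
        assert c1.sum() == pytest.approx(w.sum())


class TestRoiSummary:
    @pytest.fixture
    def result(self):
        shape = (20, 20)
        field = np.full(shape, 25.0)
        spec = PhantomSpec(field, np.ones(shape), np.full(shape, 0.8571428571428571))
        stack, _ = make_stack(spec)  # DoLD = b/(2a+b) = 0.3
        return compute_dichroism(stack, min_signal=0.0)

    def test_constant_roi_statistics(self, result):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:10, 2:10] = True
        table = roi_summary(result, {"center": mask})
        row = table.iloc[0]
        assert row.n_pixels == 64
        assert row.mean_dold == pytest.approx(0.3)
        assert row.sd_dold == pytest.approx(0.0, abs=1e-12)
        assert row.mean_aold_deg == pytest.approx(25.0)
        assert row.resultant_length == pytest.approx(1.0)

    def test_fully_invalid_roi_yields_empty_record(self, result):
        result.valid_mask[:] = False
        table = roi_summary(result, {"dead": np.ones((20, 20), dtype=bool)})
        assert table.iloc[0].n_pixels == 0
        assert np.isnan(table.iloc[0].mean_dold)

    def test_union_resultant_is_pooled_complex_sum(self):
        """Union R must equal the brute-force pooled resultant of the parts."""
        shape = (10, 20)
        rng = np.random.default_rng(12)
        field = rng.uniform(-90, 90, shape)
        spec = PhantomSpec(field, np.ones(shape), np.ones(shape))
        res = compute_dichroism(make_stack(spec)[0], min_signal=0.0)
        left = np.zeros(shape, bool)
        left[:, :10] = True
        right = ~left
        table = roi_summary(res, {"l": left, "r": right, "u": left | right})
        # brute-force pooling of the two complex sums
        z = np.exp(1j * np.deg2rad(2 * res.aold_deg))
        pooled = abs(z[left].sum() + z[right].sum()) / shape[0] / shape[1]
        r_union = table.set_index("region").loc["u", "resultant_length"]
        assert r_union == pytest.approx(pooled, abs=1e-12)

    def test_weight_modes(self, result):
        mask = {"all": np.ones((20, 20), dtype=bool)}
        amp = np.ones((20, 20))
        for mode in ("none", "amplitude", "dold"):
            table = roi_summary(result, mask, weight_mode=mode, amplitude=amp)
            assert table.iloc[0].resultant_length == pytest.approx(1.0)
        with pytest.raises(ValueError):
            roi_summary(result, mask, weight_mode="bogus")
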