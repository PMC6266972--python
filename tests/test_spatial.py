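"""Variogram estimation, ordinary kriging and error classification."""

import numpy as np
import pytest

from tritrace.spatial import (
    VariogramModel,
    empirical_variogram,
    error_classes,
    fit_variogram,
    krige,
    kriging_weights,
    leave_one_out,
)


def gaussian_field(rng, n, model="exponential", rng_m=600.0, sill=1.0, extent=3000.0):
    coords = rng.uniform(0, extent, size=(n, 2))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    if model == "exponential":
        cov = sill * np.exp(-3.0 * d / rng_m)
    else:
        hr = np.minimum(d / rng_m, 1.0)
        cov = sill * (1.0 - 1.5 * hr + 0.5 * hr**3)
    cov[np.diag_indices_from(cov)] += 1e-8
    vals = rng.multivariate_normal(np.zeros(n), cov, method="cholesky")
    return coords, vals


class TestEmpiricalVariogram:
    def test_constant_field_zero_gamma(self, rng):
        coords = rng.uniform(0, 100, size=(20, 2))
        emp = empirical_variogram(coords, np.full(20, 7.0))
        assert np.all(emp["gamma"] == 0.0)

    def test_two_sites_single_bin(self):
        emp = empirical_variogram(np.array([[0.0, 0.0], [10.0, 0.0]]), [1.0, 3.0])
        assert len(emp) == 1
        assert emp["gamma"].iloc[0] == pytest.approx(2.0)
        assert emp["n_pairs"].iloc[0] == 1

    def test_colocated_rejected(self):
        coords = np.zeros((6, 2))
        with pytest.raises(ValueError):
            empirical_variogram(coords, np.arange(6.0))


class TestFitVariogram:
    def test_pure_nugget(self, rng):
        coords = rng.uniform(0, 1000, size=(120, 2))
        vals = rng.normal(0, 1, size=120)  # spatially unstructured
        vg = fit_variogram(empirical_variogram(coords, vals), model="spherical")
        assert vg.nugget == pytest.approx(vg.sill, rel=0.35)

    def test_exponential_range_recovery(self, rng):
        """Fitted range within +-30% of the generating range at n=200."""
        coords, vals = gaussian_field(rng, 200, model="exponential", rng_m=800.0)
        vg = fit_variogram(empirical_variogram(coords, vals, n_lags=15),
                           model="exponential")
        assert vg.range_ == pytest.approx(800.0, rel=0.30)

    def test_spherical_round_trip(self, rng):
        coords, vals = gaussian_field(rng, 200, model="spherical", rng_m=900.0)
        vg = fit_variogram(empirical_variogram(coords, vals, n_lags=15),
                           model="spherical")
        assert vg.range_ == pytest.approx(900.0, rel=0.35)
        assert vg.sill == pytest.approx(1.0, rel=0.5)

    def test_single_bin_rejected(self):
        emp = empirical_variogram(np.array([[0.0, 0.0], [10.0, 0.0]]), [1.0, 3.0])
        with pytest.raises(ValueError):
            fit_variogram(emp)

    def test_invalid_model_params_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel(model="spherical", nugget=-1.0, sill=1.0, range_=10.0)
        with pytest.raises(ValueError):
            VariogramModel(model="spherical", nugget=2.0, sill=1.0, range_=10.0)


@pytest.fixture(scope="module")
def small_field():
    rng = np.random.default_rng(7)
    coords, vals = gaussian_field(rng, 40, rng_m=900.0)
    vals = vals + 10.0
    vg = VariogramModel(model="exponential", nugget=0.0, sill=1.0, range_=900.0)
    return coords, vals, vg


class TestKrige:
    def test_weights_sum_to_one(self, small_field):
        coords, vals, vg = small_field
        pts = np.random.default_rng(1).uniform(0, 3000, size=(25, 2))
        lam, _, _ = kriging_weights(coords, vals, vg, pts)
        np.testing.assert_allclose(lam.sum(axis=1), 1.0, atol=1e-10)

    def test_exact_at_samples_with_zero_nugget(self, small_field):
        coords, vals, vg = small_field
        _, preds, var = kriging_weights(coords, vals, vg, coords)
        assert np.max(np.abs(preds - vals)) < 1e-8
        assert np.max(var) < 1e-8

    def test_constant_field_constant_surface(self, small_field):
        coords, _, vg = small_field
        grid = krige(coords, np.full(len(coords), 4.2), vg, grid_shape=(8, 8))
        np.testing.assert_allclose(grid.prediction, 4.2, atol=1e-8)

    def test_two_site_midpoint_is_mean(self):
        """Symmetric two-site system: hand-solved weights are 1/2 each."""
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 40.0]])
        vals = np.array([2.0, 6.0, 4.0])
        vg = VariogramModel(model="exponential", nugget=0.0, sill=1.0, range_=50.0)
        # midpoint of the first two sites is equidistant from them, and the
        # third site is symmetric to both: weights on sites 1,2 must be equal
        lam, preds, _ = kriging_weights(coords, vals, vg, [[5.0, 0.0]])
        assert lam[0, 0] == pytest.approx(lam[0, 1], abs=1e-12)
        assert preds[0] == pytest.approx(
            lam[0, 0] * (2.0 + 6.0) + lam[0, 2] * 4.0
        )

    def test_translation_invariance(self, small_field):
        coords, vals, vg = small_field
        pts = np.array([[1500.0, 1500.0], [200.0, 2500.0]])
        _, p1, _ = kriging_weights(coords, vals, vg, pts)
        shift = np.array([1e5, -3e4])
        _, p2, _ = kriging_weights(coords + shift, vals, vg, pts + shift)
        np.testing.assert_allclose(p1, p2, rtol=1e-8)

    def test_duplicate_coordinates_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        vg = VariogramModel(model="exponential", nugget=0.0, sill=1.0, range_=10.0)
        with pytest.raises(ValueError, match="duplicate"):
            kriging_weights(coords, [1.0, 2.0, 3.0], vg, [[1.0, 1.0]])

    def test_loo_error_shrinks_with_density(self):
        """Doubling site density lowers mean leave-one-out error on a smooth field."""
        vg = VariogramModel(model="exponential", nugget=0.0, sill=1.0, range_=1500.0)
        errs = {}
        for n in (30, 120):
            rng = np.random.default_rng(5)
            coords = rng.uniform(0, 2000, size=(n, 2))
            vals = np.sin(coords[:, 0] / 500.0) + np.cos(coords[:, 1] / 700.0)
            preds = leave_one_out(coords, vals, vg)
            errs[n] = np.mean(np.abs(preds - vals))
        assert errs[120] < errs[30]


class TestErrorClasses:
    def test_perfect_prediction(self):
        counts, labels = error_classes([1.0, 2.0], [1.0, 2.0])
        assert counts == {"lt25": 2, "25to50": 0, "gt50": 0}

    def test_thirty_percent_band(self):
        counts, _ = error_classes([1.3, 2.6], [1.0, 2.0])
        assert counts == {"lt25": 0, "25to50": 2, "gt50": 0}

    def test_direct_binning(self):
        counts, labels = error_classes([1.0, 1.4, 3.0], [1.0, 1.0, 1.0])
        assert labels == ["lt25", "25to50", "gt50"]

    def test_half_open_boundaries(self):
        _, labels = error_classes([1.25, 1.5], [1.0, 1.0])
        assert labels == ["25to50", "gt50"]

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            error_classes([1.0], [0.0])
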