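"""OVR-CSP eigenstructure, log-variance features, feature-image assembly."""

import numpy as np
import pytest

from mfbnet.dataset import EpochedDataset
from mfbnet.fbcsp import (
    FBCSPFeatureExtractor,
    assemble_feature_image,
    csp_features,
    feature_width,
    fit_ovr_csp,
    spatial_filter,
    trial_covariance,
)
from mfbnet.preprocessing import (
    BandSpec,
    FilterBankSpec,
    TimeWindow,
    build_filter_bank,
    DEFAULT_WINDOWS,
)
from mfbnet.synthetic import generate_csp_separable_trials


class TestTrialCovariance:
    def test_trace_is_one(self, rng):
        c = trial_covariance(rng.standard_normal((4, 500)))
        assert np.trace(c) == pytest.approx(1.0)
        np.testing.assert_allclose(c, c.T)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((4, 500))
        np.testing.assert_allclose(trial_covariance(x), trial_covariance(5.0 * x))

    def test_white_noise_approaches_identity_over_channels(self, rng):
        c = trial_covariance(rng.standard_normal((4, 10000)))
        np.testing.assert_allclose(c, np.eye(4) / 4, atol=0.01)

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            trial_covariance(np.zeros((3, 100)))


@pytest.fixture(scope="module")
def two_class_axis_problem():
    return generate_csp_separable_trials(
        [np.diag([1.0, 4.0]), np.diag([4.0, 1.0])], n_trials=20, n_samples=5000, seed=0
    )


class TestFitOVRCSP:
    def test_closed_form_eigenvalues(self, two_class_axis_problem):
        proj = fit_ovr_csp(two_class_axis_problem.data, two_class_axis_problem.labels)
        np.testing.assert_allclose(proj.eigvals[1], [0.8, 0.2], atol=0.02)
        np.testing.assert_allclose(proj.eigvals[2], [0.8, 0.2], atol=0.02)

    def test_filters_axis_aligned(self, two_class_axis_problem):
        proj = fit_ovr_csp(two_class_axis_problem.data, two_class_axis_problem.labels)
        # class 1 has high variance on channel 2: leading filter ~ e2
        lead = proj.filters[1][:, 0]
        angle = np.degrees(np.arccos(min(1.0, abs(lead[1]) / np.linalg.norm(lead))))
        assert angle <= 5.0

    def test_whitening_of_pooled_covariance(self, two_class_axis_problem):
        data, labels = two_class_axis_problem.data, two_class_axis_problem.labels
        proj = fit_ovr_csp(data, labels)
        pooled = sum(
            np.mean([trial_covariance(x) for x in data[labels == k]], axis=0) for k in (1, 2)
        )
        pooled += 1e-8 * np.trace(pooled) / 2 * np.eye(2)  # the fitted ridge
        for k in (1, 2):
            w = proj.filters[k]
            np.testing.assert_allclose(w.T @ pooled @ w, np.eye(2), atol=1e-8)

    def test_shared_covariance_gives_uniform_eigenvalues(self, rng):
        data = rng.standard_normal((40, 3, 2000))
        labels = np.repeat([1, 2, 3, 4], 10)
        proj = fit_ovr_csp(data, labels)
        for k in range(1, 5):
            np.testing.assert_allclose(proj.eigvals[k], 0.25, atol=0.03)

    def test_eigenvalues_bounded_and_sorted(self, two_class_axis_problem):
        proj = fit_ovr_csp(two_class_axis_problem.data, two_class_axis_problem.labels)
        for v in proj.eigvals.values():
            assert np.all((v >= 0) & (v <= 1))
            assert np.all(np.diff(v) <= 0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_ovr_csp(rng.standard_normal((4, 2, 100)), np.ones(4))


class TestSpatialFilterAndFeatures:
    def test_identity_projection(self, rng):
        x = rng.standard_normal((3, 50))
        np.testing.assert_array_equal(spatial_filter(x, np.eye(3)), x)

    def test_basis_vector_selects_channel(self, rng):
        x = rng.standard_normal((3, 50))
        w = np.array([[1.0], [0.0], [0.0]])
        np.testing.assert_array_equal(spatial_filter(x, w)[0], x[0])

    def test_matches_manual_product(self, rng):
        x, w = rng.standard_normal((4, 30)), rng.standard_normal((4, 4))
        manual = np.array(
            [[sum(w[c, i] * x[c, s] for c in range(4)) for s in range(30)] for i in range(4)]
        )
        np.testing.assert_allclose(spatial_filter(x, w), manual, atol=1e-12)

    def test_features_are_logs_of_probability_vector(self, rng):
        x, w = rng.standard_normal((6, 400)), np.linalg.qr(rng.standard_normal((6, 6)))[0]
        feats = csp_features(x, w, m=2)
        assert feats.shape == (4,)
        assert np.sum(10.0**feats) == pytest.approx(1.0)

    def test_equal_variance_components(self):
        x = np.tile(np.eye(4), (1, 25))  # all four channels have equal power
        feats = csp_features(x, np.eye(4), m=2)
        np.testing.assert_allclose(feats, np.log10(0.25), atol=1e-9)

    def test_discriminative_direction_orders_features(self):
        ds = generate_csp_separable_trials(
            [np.diag([1.0, 4.0]), np.diag([4.0, 1.0])], n_trials=20, n_samples=5000, seed=2
        )
        proj = fit_ovr_csp(ds.data, ds.labels)
        f_own = csp_features(ds.data[0], proj.filters[1], m=1)
        f_other = csp_features(ds.data[1], proj.filters[1], m=1)
        # first component maximizes class-1 variance share
        assert f_own[0] > f_other[0]

    def test_too_few_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="columns"):
            csp_features(rng.standard_normal((3, 50)), np.eye(3), m=2)


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((12, 4, 1500))
    labels = np.tile([1, 2, 3, 4], 3)
    ds = EpochedDataset(data, labels, fs=250.0)
    bank = FilterBankSpec(bands=(BandSpec(8, 12), BandSpec(18, 24), BandSpec(4, 8)))
    windows = (TimeWindow(0.5, 1.5), TimeWindow(1.5, 2.5))
    return ds, bank, windows


class TestFeatureImage:
    def test_default_width_is_176(self):
        assert feature_width(11, 4, 2) == 176
        assert feature_width(11, 4, 3) == 264

    def test_assemble_shapes(self, small_problem):
        ds, bank, windows = small_problem
        from mfbnet.preprocessing import bandpass_array

        projections = [
            fit_ovr_csp(bandpass_array(ds.data, b, ds.fs), ds.labels) for b in bank.bands
        ]
        images = assemble_feature_image(ds, bank, windows, projections, m=1)
        assert images.shape == (12, 3, feature_width(2, 4, 1))
        assert np.all(np.isfinite(images))

    def test_extractor_matches_direct_assembly(self, small_problem):
        ds, bank, windows = small_problem
        ex = FBCSPFeatureExtractor(bank, windows, m=1).precompute(ds)
        ex.fit(np.arange(ds.n_trials))
        images = ex.transform()
        direct = assemble_feature_image(ds, bank, windows, ex.projections_, m=1)
        np.testing.assert_allclose(images, direct, atol=1e-8)

    def test_refit_reproducibility(self, small_problem):
        ds, bank, windows = small_problem
        tr = np.arange(8)
        ex = FBCSPFeatureExtractor(bank, windows, m=1).precompute(ds)
        a = ex.fit(tr).transform(tr)
        b = ex.fit(tr).transform(tr)
        np.testing.assert_array_equal(a, b)

    def test_full_bank_width_arithmetic(self):
        bank = build_filter_bank()
        assert bank.n_bands == 43
        assert feature_width(len(DEFAULT_WINDOWS), 4, 2) == 176

    def test_missing_projection_rejected(self, small_problem):
        ds, bank, windows = small_problem
        with pytest.raises(ValueError, match="projection"):
            assemble_feature_image(ds, bank, windows, [], m=1)
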