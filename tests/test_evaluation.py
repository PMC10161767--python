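"""Evaluation metrics: reconstruction RMSE, peak matching, label metrics."""

import dataclasses

import numpy as np
import pytest

from fiberchi import (ChiGrid, IChiCurve, OrientationParams, detect_peaks,
                      label_metrics, peak_pearson, reconstruct, rmse,
                      sample_labels, simulate_ichi, evaluate, build_dataset)
from fiberchi.evaluation import PeakSet, match_peaks, circular_diff


def wrapped_bump(grid, loc, width=8.0, amp=1.0):
    d = np.mod(grid.chi_centers - loc - 180.0, -360.0) + 180.0
    return amp * np.exp(-0.5 * (d / width) ** 2)


class TestRmse:
    def test_identical_curves_zero(self, grid, params):
        c = simulate_ichi(params)
        assert rmse(c, c) == 0.0

    def test_constant_offset_closed_form(self, grid):
        """Curves that differ by 0.1 on all bins after normalization."""
        a = IChiCurve(grid, np.full(grid.n_bins, 1.0))
        b = IChiCurve(grid, np.full(grid.n_bins, 1.0))
        b.intensity = b.intensity.copy()
        # construct post-normalization offset directly: a=1 everywhere, b has
        # max 1 and value 0.9 elsewhere
        b.intensity[1:] = 0.9
        got = rmse(a, b)
        expect = np.sqrt((grid.n_bins - 1) / grid.n_bins) * 0.1
        assert np.isclose(got, expect, atol=1e-12)

    def test_brute_force_oracle(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ia = rng.uniform(0.1, 2.0, grid.n_bins)
            ib = rng.uniform(0.1, 2.0, grid.n_bins)
            ma = rng.random(grid.n_bins) > 0.2
            mb = rng.random(grid.n_bins) > 0.2
            a, b = IChiCurve(grid, ia, ma), IChiCurve(grid, ib, mb)
            both = ma & mb
            x = ia[both] / ia[both].max()
            y = ib[both] / ib[both].max()
            expect = np.sqrt(np.mean((x - y) ** 2))
            assert abs(rmse(a, b) - expect) < 1e-12
            assert rmse(a, b) == rmse(b, a)

    def test_errors(self, grid):
        a = IChiCurve(grid, np.ones(grid.n_bins), np.zeros(grid.n_bins, bool))
        with pytest.raises(ValueError, match="overlap"):
            rmse(a, a)
        with pytest.raises(ValueError):
            rmse(IChiCurve(grid, np.ones(grid.n_bins)),
                 IChiCurve(ChiGrid(90), np.ones(90)))


class TestReconstruct:
    def test_truth_params_reproduce_clean_curve(self, params):
        clean = simulate_ichi(params)
        rec = reconstruct(params)
        assert np.array_equal(clean.intensity, rec.intensity)

    def test_codec_round_trip_reconstruction(self, params):
        from fiberchi import canonical_order, decode_labels, encode_labels
        p = canonical_order(params)
        rec = reconstruct(decode_labels(encode_labels(p)))
        assert np.abs(rec.intensity - reconstruct(p).intensity).max() < 1e-9

    def test_wrong_params_nonzero_rmse(self, params):
        wrong = dataclasses.replace(params, gamma1=params.gamma1 + 25.0)
        assert rmse(reconstruct(wrong), reconstruct(params)) > 0


class TestDetectPeaks:
    def test_single_bump(self, grid):
        c = IChiCurve(grid, wrapped_bump(grid, 30.0))
        ps = detect_peaks(c)
        assert len(ps) == 1
        assert abs(ps.locations[0] - 30.0) <= grid.step

    def test_flat_curve_empty(self, grid):
        assert len(detect_peaks(IChiCurve(grid, np.ones(grid.n_bins)))) == 0

    def test_wrap_straddling_peak(self, grid):
        c = IChiCurve(grid, wrapped_bump(grid, -180.0))
        ps = detect_peaks(c)
        assert len(ps) == 1
        d = abs(ps.locations[0] - (-180.0)) % 360
        assert min(d, 360 - d) <= grid.step

    def test_at_most_four_kept(self, grid):
        y = sum(wrapped_bump(grid, loc, 5.0, amp)
                for loc, amp in [(-150, 1), (-60, .9), (0, .8), (60, .7), (130, .6)])
        ps = detect_peaks(IChiCurve(grid, y / y.max()))
        assert len(ps) == 4
        assert np.all(np.diff(ps.locations) > 0)  # sorted by location

    def test_masked_peaks_discarded(self, grid):
        y = wrapped_bump(grid, 30.0)
        mask = np.ones(grid.n_bins, bool)
        mask[200:220] = False  # mask the peak at 30 deg (bins ~205-215)
        c = IChiCurve(grid, np.where(mask, y, 0.0), mask)
        assert len(detect_peaks(c)) == 0

    def test_peak_shift_monotone_with_gamma(self):
        """Sweeping gamma1 shifts detected peak locations monotonically."""
        locs = []
        for g1 in (20.0, 30.0, 40.0, 50.0):
            p = OrientationParams(0, 0, g1, 10.0, 0, 0, -60.0, 10.0, 5.0)
            ps = detect_peaks(simulate_ichi(p), min_prominence=0.3)
            # track the dominant-group peak nearest gamma1 + 90
            i = np.argmin(np.abs(ps.locations - (g1 + 90)))
            locs.append(ps.locations[i])
        assert np.all(np.diff(locs) > 0)


class TestPeakPearson:
    def test_perfect_match_gives_unit_correlations(self, grid):
        sets = []
        rng = np.random.default_rng(1)
        for _ in range(30):
            locs = np.sort(rng.uniform(-170, 170, 3))
            ints = rng.uniform(0.2, 1.0, 3)
            sets.append((PeakSet(locs, ints), PeakSet(locs.copy(), ints.copy())))
        r_loc, r_int = peak_pearson(sets)
        assert np.isclose(r_loc, 1.0, atol=1e-12)
        assert np.isclose(r_int, 1.0, atol=1e-12)

    def test_permuted_intensities_decorrelate(self, grid):
        rng = np.random.default_rng(2)
        pairs = []
        for _ in range(200):
            loc = rng.uniform(-170, 170)
            i_ref = rng.uniform(0.2, 1.0)
            i_rec = rng.uniform(0.2, 1.0)  # independent of reference
            pairs.append((PeakSet(np.array([loc]), np.array([i_rec])),
                          PeakSet(np.array([loc]), np.array([i_ref]))))
        r_loc, r_int = peak_pearson(pairs)
        assert r_loc > 0.999
        assert abs(r_int) < 0.2

    def test_hand_computed_pearson(self):
        """Five printed pairs against the explicit formula."""
        lr = np.array([10.0, 22.0, 31.0, 47.0, 58.0])
        lf = np.array([12.0, 20.0, 33.0, 45.0, 60.0])
        pairs = [(PeakSet(np.array([a]), np.array([0.5 + 0.02 * i])),
                  PeakSet(np.array([b]), np.array([0.5 + 0.01 * i])))
                 for i, (a, b) in enumerate(zip(lr, lf))]
        r_loc, _ = peak_pearson(pairs)
        x, y = lr - lr.mean(), lf - lf.mean()
        expect = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
        assert abs(r_loc - expect) < 1e-12

    def test_insufficient_matches(self):
        with pytest.raises(ValueError, match="matched"):
            peak_pearson([(PeakSet(np.array([0.0]), np.array([1.0])),
                           PeakSet(np.array([90.0]), np.array([1.0])))])

    def test_wrap_pair_unwrapped(self):
        """A -179/+179 matched pair counts as a 2-deg, not 358-deg, offset."""
        lr, lf, ir, i_f = match_peaks(
            PeakSet(np.array([179.0]), np.array([1.0])),
            PeakSet(np.array([-179.0]), np.array([1.0])))
        assert len(lr) == 1
        assert np.isclose(lr[0], -181.0)


class TestLabelMetrics:
    def test_perfect_prediction(self):
        truth = sample_labels(50, seed=3)
        r2, mae = label_metrics(truth, truth)
        assert all(np.isclose(v, 1.0) for v in r2.values())
        assert all(v == 0.0 for v in mae.values())

    def test_mean_prediction_gives_zero_r2(self):
        truth = sample_labels(200, seed=4)
        pred = np.tile(truth.mean(axis=0), (200, 1))
        r2, _ = label_metrics(pred, truth)
        # angles use circular residuals, so exact 0 holds for the ratio label
        assert np.isclose(r2["lam_ratio"], 0.0, atol=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        truth = sample_labels(100, seed=6)
        pred = truth + rng.normal(0, 3.0, truth.shape)
        pred[:, 8] = np.abs(pred[:, 8]) + 0.01
        r2, mae = label_metrics(pred, truth)
        from fiberchi.forward import PARAM_NAMES
        for j, name in enumerate(PARAM_NAMES):
            if name == "lam_ratio":
                err = pred[:, j] - truth[:, j]
            else:
                d = np.mod(pred[:, j] - truth[:, j], 180.0)
                err = np.where(d > 90.0, d - 180.0, d)
            exp_mae = np.abs(err).mean()
            exp_r2 = 1 - (err**2).sum() / ((truth[:, j] - truth[:, j].mean())**2).sum()
            assert abs(mae[name] - exp_mae) < 1e-12
            assert abs(r2[name] - exp_r2) < 1e-12

    def test_zero_variance_truth_rejected(self):
        truth = np.tile(sample_labels(1, seed=7), (5, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            label_metrics(truth, truth)

    def test_circular_diff_wraps(self):
        assert circular_diff(89.0, -89.0) == pytest.approx(-2.0)
        assert circular_diff(-89.0, 89.0) == pytest.approx(2.0)


class _OracleModel:
    """Returns the stored encoded truth for any input (perfect predictor);
    inputs are matched to stored curves by nearest Euclidean distance."""

    def __init__(self, dataset, split="test"):
        idx = dataset.indices(split)
        self.X = np.asarray(dataset.X[idx], dtype=np.float64)
        self.y = dataset.labels[idx]
        self.n_features_in_ = dataset.X.shape[1]

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        d = ((X[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
        return self.y[np.argmin(d, axis=1)]


@pytest.fixture(scope="module")
def clean_ds():
    labels = sample_labels(60, seed=8)
    return build_dataset(labels, ChiGrid(360), None, (0.5, 0.2, 0.3), seed=8)


class TestEvaluate:

    def test_perfect_oracle_phase1(self, clean_ds):
        report = evaluate(_OracleModel(clean_ds), clean_ds, "phase1")
        # float32 curve storage and codec rounding leave ~1e-8 residuals
        assert report.rmse_mean < 1e-6
        assert np.isclose(report.pearson_location, 1.0, atol=1e-9)
        assert np.isclose(report.pearson_intensity, 1.0, atol=1e-9)
        assert all(np.isclose(v[0], 1.0, atol=1e-9)
                   for v in report.per_label_r2.values())

    def test_single_repetition_sd_zero(self, clean_ds):
        report = evaluate([_OracleModel(clean_ds)], clean_ds, "phase1")
        assert report.n_repetitions == 1
        assert report.rmse_sd == 0.0
        assert report.pearson_location_sd == 0.0

    def test_invalid_phase(self, clean_ds):
        with pytest.raises(ValueError):
            evaluate(_OracleModel(clean_ds), clean_ds, "phase3")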