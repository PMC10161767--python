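"""Reconstruction-based and label-based performance metrics.

The central accuracy surrogate is the reconstruction RMSE: predicted
orientation parameters are pushed back through the forward model and the
regenerated curve is compared with the observed one on mutually valid bins
(both unit-max normalized first). This works identically whether ground-truth
labels exist (phase I, simulated test data) or not (phase II, curves with
unseen masking patterns), which is exactly why it is the headline metric.

Peak-level agreement is summarized by Pearson correlations of matched peak
locations and intensities pooled over the test set; label-level agreement
(phase I only) by per-parameter R^2 and MAE, with angles compared on the
doubled-circle metric so the +/-90 deg wrap is not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .forward import ChiGrid, IChiCurve, OrientationParams, PARAM_NAMES, simulate_ichi
from .sampling import Dataset
from .corruption import blockwise_mask
from .regressors import predict_params

__all__ = ["PeakSet", "EvalReport", "reconstruct", "rmse", "detect_peaks",
           "peak_pearson", "label_metrics", "evaluate", "make_phase2_testset",
           "circular_diff"]

ANGLE_LABELS = frozenset(n for n in PARAM_NAMES if n != "lam_ratio")


@dataclass
class PeakSet:
    """Detected peaks of one curve: locations (deg), normalized intensities,
    and full widths at half prominence (deg; zeros when not measured)."""

    locations: np.ndarray
    intensities: np.ndarray
    widths: np.ndarray = None

    def __post_init__(self):
        if self.widths is None:
            self.widths = np.zeros_like(np.asarray(self.locations, dtype=float))

    def __len__(self):
        return len(self.locations)


@dataclass
class EvalReport:
    """Aggregate metrics over n_repetitions, as mean and SD."""

    phase: str
    n_repetitions: int
    rmse_mean: float
    rmse_sd: float
    pearson_location: float
    pearson_location_sd: float
    pearson_intensity: float
    pearson_intensity_sd: float
    per_label_r2: dict = field(default_factory=dict)
    per_label_mae: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def reconstruct(params: OrientationParams, grid: ChiGrid = None,
                **sim_kwargs) -> IChiCurve:
    """Regenerate the clean forward-model curve from (predicted) parameters."""
    return simulate_ichi(params, grid, **sim_kwargs)


def rmse(curve_a: IChiCurve, curve_b: IChiCurve) -> float:
    """Root-mean-square difference over mutually valid bins, after unit-max
    normalization of each curve on those bins."""
    if curve_a.grid.n_bins != curve_b.grid.n_bins:
        raise ValueError("curves live on different grids")
    both = curve_a.valid_mask & curve_b.valid_mask
    if not both.any():
        raise ValueError("no overlapping valid bins")
    a = curve_a.intensity[both]
    b = curve_b.intensity[both]
    ma, mb = a.max(), b.max()
    if ma <= 0 or mb <= 0:
        raise ValueError("curve has no positive maximum on overlapping bins")
    return float(np.sqrt(np.mean((a / ma - b / mb) ** 2)))


def detect_peaks(curve: IChiCurve, min_prominence: float = 0.05,
                 max_peaks: int = 4) -> PeakSet:
    """Local maxima on the circular grid with prominence >= min_prominence.

    The curve is unwrapped over three periods so wrap-straddling peaks are
    found once; peaks whose bin (or either neighbor) is masked are discarded.
    At most ``max_peaks`` are kept (highest prominence first; two fiber groups
    give at most two pairs of arcs), sorted by location.
    """
    from scipy.signal import peak_widths
    n = curve.grid.n_bins
    y = curve.intensity
    y3 = np.concatenate([y, y, y])
    idx3, props = find_peaks(y3, prominence=min_prominence)
    sel = (idx3 >= n) & (idx3 < 2 * n)
    idx = idx3[sel] - n
    prom = props["prominences"][sel]
    widths = peak_widths(y3, idx3[sel], rel_height=0.5)[0] * curve.grid.step
    valid = curve.valid_mask
    ok = valid[idx] & valid[(idx - 1) % n] & valid[(idx + 1) % n]
    idx, prom, widths = idx[ok], prom[ok], widths[ok]
    if len(idx) > max_peaks:
        keep = np.argsort(prom)[::-1][:max_peaks]
        idx, widths = idx[keep], widths[keep]
    order = np.argsort(curve.grid.chi_centers[idx])
    idx, widths = idx[order], widths[order]
    return PeakSet(curve.grid.chi_centers[idx], y[idx], widths)


def _wrap180(d):
    return np.mod(np.asarray(d, dtype=float) - 180.0, -360.0) + 180.0


def match_peaks(recon: PeakSet, ref: PeakSet, window: float = 15.0):
    """Greedy nearest-circular-location matching within ``window`` degrees.

    Returns matched (loc_recon_unwrapped, loc_ref, int_recon, int_ref) arrays;
    reconstructed locations are unwrapped to the branch nearest the reference
    so a -179/+179 pair does not corrupt the pooled correlation.
    """
    if len(recon) == 0 or len(ref) == 0:
        return (np.empty(0),) * 4
    d = np.abs(_wrap180(recon.locations[:, None] - ref.locations[None, :]))
    pairs = []
    used_r, used_f = set(), set()
    for flat in np.argsort(d, axis=None):
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > window:
            break
        if i in used_r or j in used_f:
            continue
        used_r.add(i)
        used_f.add(j)
        pairs.append((i, j))
    if not pairs:
        return (np.empty(0),) * 4
    ri = np.array([p[0] for p in pairs])
    fj = np.array([p[1] for p in pairs])
    loc_ref = ref.locations[fj]
    loc_rec = loc_ref + _wrap180(recon.locations[ri] - loc_ref)
    return loc_rec, loc_ref, recon.intensities[ri], ref.intensities[fj]


def peak_pearson(pairs, window: float = 15.0):
    """Pooled Pearson correlations over matched peaks of many curve pairs.

    ``pairs`` is an iterable of (reconstructed PeakSet, reference PeakSet).
    Returns (r_location, r_intensity).
    """
    locs_r, locs_f, ints_r, ints_f = [], [], [], []
    for recon, ref in pairs:
        lr, lf, ir, i_f = match_peaks(recon, ref, window)
        locs_r.append(lr)
        locs_f.append(lf)
        ints_r.append(ir)
        ints_f.append(i_f)
    lr = np.concatenate(locs_r) if locs_r else np.empty(0)
    if lr.size < 2:
        raise ValueError("fewer than 2 matched peak pairs")
    lf = np.concatenate(locs_f)
    ir = np.concatenate(ints_r)
    i_f = np.concatenate(ints_f)
    r_loc = float(pearsonr(lr, lf).statistic)
    r_int = float(pearsonr(ir, i_f).statistic)
    return r_loc, r_int


def circular_diff(pred, truth, period: float = 180.0):
    """Signed angle difference on the doubled circle, in (-period/2, period/2]."""
    d = np.mod(np.asarray(pred, dtype=float) - np.asarray(truth, dtype=float),
               period)
    return np.where(d > period / 2.0, d - period, d)


def label_metrics(predicted: np.ndarray, truth: np.ndarray):
    """Per-label R^2 and MAE between predicted and true parameter rows (n, 9).

    Angles use the circular difference (period 180 deg) for residuals; R^2 is
    1 - SS_res/SS_tot with SS_tot the ordinary variance of the truth values
    (which live in the canonical range, so no wrap is present in the truth).
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if predicted.shape != truth.shape or predicted.shape[0] < 2:
        raise ValueError("need matching (n>=2, 9) arrays")
    r2, mae = {}, {}
    for j, name in enumerate(PARAM_NAMES):
        t = truth[:, j]
        if name in ANGLE_LABELS:
            err = circular_diff(predicted[:, j], t)
        else:
            err = predicted[:, j] - t
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"zero-variance truth for label {name}: R^2 undefined")
        r2[name] = float(1.0 - np.sum(err**2) / ss_tot)
        mae[name] = float(np.mean(np.abs(err)))
    return r2, mae


def make_phase2_testset(dataset: Dataset, indices: np.ndarray,
                        block_len_range=(70, 120), mask_ratio: float = 0.3,
                        seed: int = 0) -> list:
    """Synthetic phase-II stand-in: re-mask held-out *clean* curves with block
    lengths drawn from a range disjoint from the training corruption,
    emulating unseen missing-signal patterns. Requires keep_clean=True."""
    if dataset.clean is None:
        raise ValueError("dataset was built without keep_clean=True")
    ss = np.random.SeedSequence(seed).generate_state(len(indices))
    out = []
    for s, i in zip(ss, indices):
        c = IChiCurve(dataset.grid, dataset.clean[i].astype(float))
        out.append(blockwise_mask(c, mask_ratio, block_len_range, int(s)))
    return out


def _evaluate_one(model, curves, truth_params=None, min_prominence=0.05,
                  **sim_kwargs):
    """Metrics for a single fitted model on a list of observed curves."""
    X = np.stack([np.concatenate([c.intensity, c.valid_mask.astype(float)])
                  for c in curves])
    pred = predict_params(model, X)
    grid = curves[0].grid
    rmses, peak_pairs = [], []
    for row, obs in zip(pred, curves):
        rec = reconstruct(OrientationParams.from_array(row), grid, **sim_kwargs)
        rmses.append(rmse(rec, obs))
        peak_pairs.append((detect_peaks(rec, min_prominence),
                           detect_peaks(obs, min_prominence)))
    r_loc, r_int = peak_pearson(peak_pairs)
    res = {"rmse": float(np.mean(rmses)), "pearson_location": r_loc,
           "pearson_intensity": r_int}
    if truth_params is not None:
        res["r2"], res["mae"] = label_metrics(pred, truth_params)
    return res


def evaluate(models, dataset_or_curves, phase: str = "phase1",
             truth_params: np.ndarray = None, split: str = "test",
             min_prominence: float = 0.05, **sim_kwargs) -> EvalReport:
    """Evaluate one or more fitted models (repetitions) into an EvalReport.

    phase1: ``dataset_or_curves`` is a Dataset; its ``split`` curves are
    predicted, reconstructed and scored, including per-label metrics against
    the stored ground truth. phase2: a list of observed curves (no labels);
    only reconstruction metrics are computed.
    """
    if phase not in ("phase1", "phase2"):
        raise ValueError("phase must be 'phase1' or 'phase2'")
    if not isinstance(models, (list, tuple)):
        models = [models]
    if phase == "phase1":
        ds: Dataset = dataset_or_curves
        idx = ds.indices(split)
        curves = [ds.curve(i) for i in idx]
        truth_params = ds.raw_params[idx]
    else:
        curves = list(dataset_or_curves)
    runs = [_evaluate_one(m, curves, truth_params if phase == "phase1" else None,
                          min_prominence, **sim_kwargs) for m in models]

    def agg(key):
        v = np.array([r[key] for r in runs])
        return float(v.mean()), float(v.std(ddof=0))

    rm, rs = agg("rmse")
    pl, pls = agg("pearson_location")
    pi, pis = agg("pearson_intensity")
    report = EvalReport(phase, len(models), rm, rs, pl, pls, pi, pis)
    if phase == "phase1":
        for name in PARAM_NAMES:
            r2s = np.array([r["r2"][name] for r in runs])
            maes = np.array([r["mae"][name] for r in runs])
            report.per_label_r2[name] = (float(r2s.mean()), float(r2s.std(ddof=0)))
            report.per_label_mae[name] = (float(maes.mean()), float(maes.std(ddof=0)))
    return report
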