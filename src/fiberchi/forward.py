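"""Forward diffraction model: orientation parameters -> azimuthal intensity I(chi).

Two groups of nanofibers are each described by a tilted fiber plane (tilt
angles ``alpha`` about the lab x axis, then ``beta`` about the lab y axis), a
mean in-plane fiber angle ``gamma`` and an in-plane fan spread ``dgamma``.
Every fiber axis carries a pole circle of (110) reciprocal vectors at a fixed
angle (90 deg for the equatorial chitin (110) reflection) to the axis on the
|q| = Q110 sphere. The detector observes the intersection of that sphere with
the Ewald sphere: a ring at constant qz = -Q^2 / (2k). For each fiber axis the
pole circle crosses the ring at zero, one or two azimuths chi*, which are
deposited on the chi grid with a periodic Gaussian kernel.

Convention: the X-ray beam travels along +z, the detector plane is x-y, and
chi is measured from +x counter-clockwise. An untilted fiber plane is z = 0,
where a fiber at gamma points along (cos gamma, sin gamma, 0).

All orientation angles are physically periodic with period 180 deg (a fiber
axis equals its negation); they are normalized into (-90, 90] before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OrientationParams",
    "ChiGrid",
    "IChiCurve",
    "DiffractionGeometry",
    "PARAM_NAMES",
    "normalize_angle",
    "rotation_from_tilts",
    "group_fiber_axes",
    "simulate_ichi",
    "simulate_ichi_mc",
    "simulate_batch",
]

#: Order of the nine orientation labels throughout the package.
PARAM_NAMES = (
    "alpha1", "beta1", "gamma1", "dgamma1",
    "alpha2", "beta2", "gamma2", "dgamma2",
    "lam_ratio",
)

HC_KEV_ANGSTROM = 12.398419843320026  # h*c in keV * Angstrom


def normalize_angle(theta):
    """Map an angle in degrees into the canonical range (-90, 90] (period 180)."""
    return np.mod(np.asarray(theta, dtype=float) - 90.0, -180.0) + 90.0


@dataclass(frozen=True)
class DiffractionGeometry:
    """Constants placing the Ewald-intersection ring for the (110) reflection.

    energy_kev
        Incident photon energy; 10 keV matches a typical synchrotron WAXD setup.
    d_spacing
        (110) lattice spacing in Angstrom; 4.6 A for alpha-chitin.
    pole_angle_deg
        Angle between the (110) reciprocal vector and the fiber axis; 90 deg
        for an equatorial reflection.
    """

    energy_kev: float = 10.0
    d_spacing: float = 4.6
    pole_angle_deg: float = 90.0

    @property
    def k(self) -> float:
        """Incident wavevector magnitude 2*pi/lambda (1/A)."""
        return 2.0 * np.pi * self.energy_kev / HC_KEV_ANGSTROM

    @property
    def q_ring(self) -> float:
        """|q| of the (110) reflection (1/A)."""
        return 2.0 * np.pi / self.d_spacing

    @property
    def qz_ring(self) -> float:
        """Out-of-detector-plane component of q on the Ewald ring (1/A)."""
        return -self.q_ring**2 / (2.0 * self.k)

    @property
    def qrho_ring(self) -> float:
        """In-plane radius of the Ewald ring (1/A)."""
        return float(np.sqrt(self.q_ring**2 - self.qz_ring**2))


@dataclass(frozen=True)
class OrientationParams:
    """The nine physical labels for two fiber groups.

    Angles in degrees; ``lam_ratio`` is the quantity ratio lambda1/lambda2
    (only the ratio of the two group weights is identifiable).
    """

    alpha1: float
    beta1: float
    gamma1: float
    dgamma1: float
    alpha2: float
    beta2: float
    gamma2: float
    dgamma2: float
    lam_ratio: float

    def normalized(self) -> "OrientationParams":
        """Return a copy with all tilt/mean angles mapped into (-90, 90] and
        spreads clipped to [0, 180]."""
        return replace(
            self,
            alpha1=float(normalize_angle(self.alpha1)),
            beta1=float(normalize_angle(self.beta1)),
            gamma1=float(normalize_angle(self.gamma1)),
            dgamma1=float(np.clip(self.dgamma1, 0.0, 180.0)),
            alpha2=float(normalize_angle(self.alpha2)),
            beta2=float(normalize_angle(self.beta2)),
            gamma2=float(normalize_angle(self.gamma2)),
            dgamma2=float(np.clip(self.dgamma2, 0.0, 180.0)),
        )

    def validate(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite orientation parameter in {arr}")
        if self.dgamma1 < 0 or self.dgamma2 < 0:
            raise ValueError("dgamma must be >= 0")
        if not self.lam_ratio > 0:
            raise ValueError("lam_ratio must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "OrientationParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError(f"expected 9 parameters, got shape {arr.shape}")
        return cls(*[float(v) for v in arr])

    def swapped(self) -> "OrientationParams":
        """Exchange the two fiber groups (inverting the quantity ratio)."""
        return OrientationParams(
            self.alpha2, self.beta2, self.gamma2, self.dgamma2,
            self.alpha1, self.beta1, self.gamma1, self.dgamma1,
            1.0 / self.lam_ratio,
        )


@dataclass(frozen=True)
class ChiGrid:
    """Uniform circular azimuth grid over [-180, 180) degrees."""

    n_bins: int = 360

    def __post_init__(self):
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")

    @property
    def step(self) -> float:
        return 360.0 / self.n_bins

    @property
    def chi_centers(self) -> np.ndarray:
        return -180.0 + self.step * np.arange(self.n_bins)

    def bin_of(self, chi) -> np.ndarray:
        """Index of the bin containing azimuth ``chi`` (degrees, any branch)."""
        idx = np.round((np.asarray(chi, dtype=float) + 180.0) / self.step)
        return np.mod(idx.astype(int), self.n_bins)


@dataclass
class IChiCurve:
    """Azimuthal intensity profile with a validity mask (True = observed)."""

    grid: ChiGrid
    intensity: np.ndarray
    valid_mask: np.ndarray = None
    q_label: str = "(110)"
    degenerate: bool = False

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.grid.n_bins, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.intensity.shape != (self.grid.n_bins,):
            raise ValueError("intensity length must equal n_bins")
        if self.valid_mask.shape != (self.grid.n_bins,):
            raise ValueError("mask length must equal n_bins")

    def copy(self) -> "IChiCurve":
        return IChiCurve(self.grid, self.intensity.copy(), self.valid_mask.copy(),
                         self.q_label, self.degenerate)


def rotation_from_tilts(alpha: float, beta: float) -> np.ndarray:
    """Rotation tilting the fiber plane: about lab x by ``alpha`` then lab y by
    ``beta`` (degrees). Returns a proper 3x3 rotation matrix."""
    a = np.deg2rad(float(normalize_angle(alpha)))
    b = np.deg2rad(float(normalize_angle(beta)))
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    return ry @ rx


def _fan_offsets(dgamma: float, n_samples: int, weighting: str):
    """Fan node offsets (deg, relative to gamma) and normalized weights."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if dgamma < 0:
        raise ValueError("dgamma must be >= 0")
    if dgamma == 0 or n_samples == 1:
        delta = np.zeros(n_samples)
    else:
        # midpoint nodes over [-dgamma/2, dgamma/2]
        delta = -dgamma / 2.0 + (np.arange(n_samples) + 0.5) * dgamma / n_samples
    if weighting == "uniform":
        w = np.full(n_samples, 1.0 / n_samples)
    elif weighting == "gaussian":
        sigma = max(dgamma / 4.0, 1e-12)
        w = np.exp(-0.5 * (delta / sigma) ** 2)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return delta, w


def group_fiber_axes(alpha, beta, gamma, dgamma, n_samples=181, weighting="uniform"):
    """Unit fiber-axis vectors and quadrature weights for one fiber group.

    The fan lies in the plane z=0 rotated by (alpha, beta); axes are
    (cos(gamma+delta), sin(gamma+delta), 0) rotated, with delta spanning
    [-dgamma/2, dgamma/2].

    Returns (axes (n_samples, 3), weights (n_samples,)).
    """
    delta, w = _fan_offsets(dgamma, n_samples, weighting)
    ang = np.deg2rad(gamma + delta)
    u = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    rot = rotation_from_tilts(alpha, beta)
    return u @ rot.T, w


#: Lower clip on the sine of the pole-circle/Ewald-ring crossing angle; caps
#: the Lorentz-type divergence at tangency (arc-end cusps stay finite).
MIN_CROSSING_SINE = 0.05


def _intersection_azimuths(axes: np.ndarray, geom: DiffractionGeometry):
    """Azimuths (deg) where each fiber axis' pole circle crosses the Ewald ring.

    For axis f the pole circle is {q : |q| = Q, q.f = Q cos(sigma)}; on the ring
    q(chi) = (qrho cos chi, qrho sin chi, qz), so chi solves
    A cos chi + B sin chi = C with A = qrho fx, B = qrho fy,
    C = Q cos(sigma) - qz fz.

    Fiber symmetry distributes poles uniformly on the pole circle, so the
    intensity deposited at a crossing carries the geometric (Lorentz-type)
    factor 1/sin(psi), psi the crossing angle between the two curves on the
    |q| = Q sphere: glancing crossings sweep more poles per unit azimuth
    (the familiar intensity build-up at arc ends).

    Returns (chi (2, n), valid (2, n), lorentz (2, n)).
    """
    fx, fy, fz = axes[:, 0], axes[:, 1], axes[:, 2]
    a = geom.qrho_ring * fx
    b = geom.qrho_ring * fy
    c = geom.q_ring * np.cos(np.deg2rad(geom.pole_angle_deg)) - geom.qz_ring * fz
    r0 = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r0 > 0, c / np.where(r0 > 0, r0, 1.0), np.inf)
    valid = np.abs(ratio) <= 1.0
    dphi = np.arccos(np.clip(ratio, -1.0, 1.0))
    phi0 = np.arctan2(b, a)
    chi = np.stack([phi0 - dphi, phi0 + dphi])
    # crossing angle: ring tangent t_r ~ (-sin chi, cos chi, 0);
    # pole-circle tangent t_p ~ f x q(chi)
    cosx, sinx = np.cos(chi), np.sin(chi)
    qx = geom.qrho_ring * cosx
    qy = geom.qrho_ring * sinx
    qz = geom.qz_ring
    tpx = fy * qz - fz * qy
    tpy = fz * qx - fx * qz
    tpz = fx * qy - fy * qx
    norm_tp = np.sqrt(tpx**2 + tpy**2 + tpz**2)
    # |t_r x t_p| with t_r unit: component-wise cross product
    cx = cosx * tpz
    cy = sinx * tpz
    cz = -sinx * tpy - cosx * tpx
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_psi = np.sqrt(cx**2 + cy**2 + cz**2) / np.where(norm_tp > 0, norm_tp, 1.0)
    lorentz = 1.0 / np.maximum(sin_psi, MIN_CROSSING_SINE)
    return np.rad2deg(chi), np.broadcast_to(valid, chi.shape), lorentz


def _wrap180(d):
    """Wrap angle differences into (-180, 180]."""
    return np.mod(d - 180.0, -360.0) + 180.0


def _deposit(chi_stars, weights, grid: ChiGrid, smear_width: float) -> np.ndarray:
    """Sum of periodic Gaussian kernels at chi_stars, evaluated at bin centers.

    The kernel is evaluated on a window of +/-8 sigma around each azimuth
    (truncation error < 1e-14 relative) and wrapped circularly; for windows
    covering the whole grid the dense principal-branch evaluation is used.
    """
    if chi_stars.size == 0:
        return np.zeros(grid.n_bins)
    half = int(np.ceil(8.0 * smear_width / grid.step))
    if 2 * half + 1 >= grid.n_bins:
        d = _wrap180(grid.chi_centers[None, :] - chi_stars[:, None])
        return weights @ np.exp(-0.5 * (d / smear_width) ** 2)
    pos = (chi_stars + 180.0) / grid.step          # fractional bin position
    base = np.floor(pos)
    offs = np.arange(-half, half + 1)
    d = (offs[None, :] - (pos - base)[:, None]) * grid.step
    kern = weights[:, None] * np.exp(-0.5 * (d / smear_width) ** 2)
    bins = np.mod(base[:, None].astype(int) + offs[None, :], grid.n_bins)
    out = np.zeros(grid.n_bins)
    np.add.at(out, bins.ravel(), kern.ravel())
    return out


def _group_curve(alpha, beta, gamma, dgamma, grid, smear_width, n_quad,
                 weighting, geom) -> np.ndarray:
    axes, w = group_fiber_axes(alpha, beta, gamma, dgamma, n_quad, weighting)
    chi, valid, lorentz = _intersection_azimuths(axes, geom)
    w2 = np.broadcast_to(w, chi.shape) * lorentz
    return _deposit(chi[valid], w2[valid], grid, smear_width)


def simulate_ichi(params: OrientationParams, grid: ChiGrid = None, *,
                  smear_width: float = 5.0, n_quad: int = 181,
                  weighting: str = "uniform",
                  geometry: DiffractionGeometry = None) -> IChiCurve:
    """Simulate the azimuthal (110) intensity profile for two fiber groups.

    The curve is lam_ratio * C1 + 1 * C2 (C_i the per-group fan quadrature,
    weights summing to 1), normalized to unit maximum. Deterministic.

    A geometry with no pole-circle/Ewald-ring intersection anywhere yields an
    all-zero curve flagged ``degenerate`` (with a warning).
    """
    if grid is None:
        grid = ChiGrid()
    if geometry is None:
        geometry = DiffractionGeometry()
    if n_quad < 8:
        raise ValueError("n_quad must be >= 8")
    if smear_width <= 0:
        raise ValueError("smear_width must be > 0")
    params = params.normalized()
    params.validate()
    c1 = _group_curve(params.alpha1, params.beta1, params.gamma1, params.dgamma1,
                      grid, smear_width, n_quad, weighting, geometry)
    c2 = _group_curve(params.alpha2, params.beta2, params.gamma2, params.dgamma2,
                      grid, smear_width, n_quad, weighting, geometry)
    total = params.lam_ratio * c1 + c2
    peak = total.max()
    if peak <= 0:
        warnings.warn("degenerate geometry: no pole-circle/Ewald intersections",
                      RuntimeWarning, stacklevel=2)
        return IChiCurve(grid, total, degenerate=True)
    return IChiCurve(grid, total / peak)


def simulate_batch(params_array: np.ndarray, grid: ChiGrid = None, *,
                   smear_width: float = 5.0, n_quad: int = 181,
                   weighting: str = "uniform",
                   geometry: DiffractionGeometry = None) -> np.ndarray:
    """Simulate many label rows (n, 9) -> intensity matrix (n, n_bins)."""
    params_array = np.asarray(params_array, dtype=float)
    if grid is None:
        grid = ChiGrid()
    out = np.empty((params_array.shape[0], grid.n_bins))
    for i, row in enumerate(params_array):
        out[i] = simulate_ichi(
            OrientationParams.from_array(row), grid, smear_width=smear_width,
            n_quad=n_quad, weighting=weighting, geometry=geometry).intensity
    return out


def simulate_ichi_mc(params: OrientationParams, grid: ChiGrid = None, *,
                     smear_width: float = 5.0, n_draws: int = 100_000,
                     seed: int = 0, weighting: str = "uniform",
                     geometry: DiffractionGeometry = None) -> IChiCurve:
    """Monte-Carlo oracle for :func:`simulate_ichi`.

    Fiber axes are drawn at random from each group's fan distribution, their
    Ewald-ring crossing azimuths computed, jittered by a wrapped normal of the
    kernel width (realizing the Gaussian smear stochastically), and binned on
    the chi grid. Reproducible under a fixed seed; converges to the quadrature
    curve as n_draws grows.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    if grid is None:
        grid = ChiGrid()
    if geometry is None:
        geometry = DiffractionGeometry()
    params = params.normalized()
    params.validate()
    rng = np.random.default_rng(seed)
    lam = np.array([params.lam_ratio, 1.0])
    p_group = lam / lam.sum()
    groups = [(params.alpha1, params.beta1, params.gamma1, params.dgamma1),
              (params.alpha2, params.beta2, params.gamma2, params.dgamma2)]
    hist = np.zeros(grid.n_bins)
    which = rng.random(n_draws) < p_group[0]
    for gi, (alpha, beta, gamma, dgamma) in enumerate(groups):
        n_g = int(which.sum()) if gi == 0 else n_draws - int(which.sum())
        if n_g == 0:
            continue
        if weighting == "uniform":
            delta = rng.uniform(-dgamma / 2.0, dgamma / 2.0, size=n_g)
        elif weighting == "gaussian":
            # truncated normal on [-dgamma/2, dgamma/2] via inverse CDF
            from scipy.special import ndtr, ndtri
            sigma = max(dgamma / 4.0, 1e-12)
            lo, hi = ndtr(-dgamma / 2.0 / sigma), ndtr(dgamma / 2.0 / sigma)
            delta = sigma * ndtri(rng.uniform(lo, hi, size=n_g))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        ang = np.deg2rad(gamma + delta)
        u = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        rot = rotation_from_tilts(alpha, beta)
        chi, valid, lorentz = _intersection_azimuths(u @ rot.T, geometry)
        chis = chi[valid]
        if chis.size == 0:
            continue
        chis = chis + rng.normal(0.0, smear_width, size=chis.size)
        np.add.at(hist, grid.bin_of(chis), lorentz[valid])
    if hist.max() <= 0:
        warnings.warn("degenerate geometry: no pole-circle/Ewald intersections",
                      RuntimeWarning, stacklevel=2)
        return IChiCurve(grid, hist, degenerate=True)
    return IChiCurve(grid, hist / hist.max())
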