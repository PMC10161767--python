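"""Orientation-label sampling and paired (curve, label) dataset construction.

The training set is fully synthetic: orientation labels are sampled over the
physical parameter space, the forward model generates each I(chi) curve, the
corruption pipeline degrades it, and the codec produces the 17-value
regression target. Default ranges reflect a sectioned cuticle mounted
near-normal to the beam, with two well-separated fiber families: small
fiber-plane tilts (alpha uniform over [-4, 4] deg, beta over [-10, 10] deg),
mean in-plane angles in disjoint half-ranges (gamma1 over [0, 90),
gamma2 over [-90, 0)), arc-like in-plane spreads (dgamma over [5, 90] deg),
and the quantity ratio log-uniform over [0.1, 10] (a ratio and its inverse
are equally likely).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import codec
from .corruption import CorruptionConfig, corrupt
from .forward import ChiGrid, IChiCurve, simulate_batch

__all__ = ["LabelRanges", "Dataset", "sample_labels", "build_dataset"]

SPLIT_CODES = {"train": 0, "val": 1, "test": 2}


@dataclass(frozen=True)
class LabelRanges:
    """Closed sampling intervals per parameter (degrees; ratio dimensionless).

    The two groups are modeled as well separated in mean in-plane angle:
    group 1 draws gamma from ``gamma`` (default [0, 90)) and group 2 from
    ``gamma2`` (default [-90, 0)), so the two pairs of diffraction arcs stay
    distinguishable and the canonical ordering gamma1 >= gamma2 holds by
    construction. Set ``gamma2=None`` to draw both groups from ``gamma``
    (ordering then enforced by swapping).
    """

    alpha: tuple = (-4.0, 4.0)
    beta: tuple = (-10.0, 10.0)
    gamma: tuple = (0.0, 90.0)
    gamma2: tuple | None = (-90.0, 0.0)
    dgamma: tuple = (5.0, 90.0)
    lam_ratio: tuple = (0.1, 10.0)
    sampler: str = "uniform"  # "uniform" or "grid"
    grid_points: int = 13     # levels per parameter for the grid sampler
    log_ratio: bool = True

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "dgamma", "lam_ratio"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty range for {name}: {(lo, hi)}")
        if self.gamma2 is not None and self.gamma2[0] > self.gamma2[1]:
            raise ValueError(f"empty range for gamma2: {self.gamma2}")
        if self.dgamma[0] < 0 or self.dgamma[1] > 180:
            raise ValueError("dgamma range must lie within [0, 180]")
        if self.lam_ratio[0] <= 0:
            raise ValueError("lam_ratio range must be positive")
        if self.sampler not in ("uniform", "grid"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def _draw(rng, lo, hi, n, sampler, grid_points, log=False):
    if log:
        lo, hi = np.log(lo), np.log(hi)
    if sampler == "uniform":
        x = rng.uniform(lo, hi, size=n)
    else:  # grid: uniform draw from evenly spaced levels (avoids a 9D lattice)
        levels = np.linspace(lo, hi, grid_points)
        x = levels[rng.integers(0, grid_points, size=n)]
    return np.exp(x) if log else x


def sample_labels(n: int, ranges: LabelRanges = None, seed: int = 0) -> np.ndarray:
    """Sample ``n`` canonically ordered label rows (n, 9), reproducibly.

    Both groups' angles are drawn i.i.d. from the same ranges; rows are then
    canonicalized (gamma1 >= gamma2, ratio inverted on swap).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = LabelRanges()
    rng = np.random.default_rng(seed)
    cols = []
    for group in range(2):  # two groups
        for name in ("alpha", "beta", "gamma", "dgamma"):
            if name == "gamma" and group == 1 and ranges.gamma2 is not None:
                lo, hi = ranges.gamma2
            else:
                lo, hi = getattr(ranges, name)
            cols.append(_draw(rng, lo, hi, n, ranges.sampler, ranges.grid_points))
    lo, hi = ranges.lam_ratio
    cols.append(_draw(rng, lo, hi, n, ranges.sampler, ranges.grid_points,
                      log=ranges.log_ratio))
    arr = np.stack(cols, axis=1)
    swap = arr[:, 2] < arr[:, 6]
    if np.any(swap):
        tmp = arr[swap][:, [4, 5, 6, 7, 0, 1, 2, 3, 8]]
        tmp[:, 8] = 1.0 / tmp[:, 8]
        arr[swap] = tmp
    return arr


def _split_assignment(n, split_fracs, rng) -> np.ndarray:
    fr = np.asarray(split_fracs, dtype=float)
    if fr.size != 3 or abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise ValueError("split fractions must be 3 non-negative values summing to 1")
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    codes = np.full(n, SPLIT_CODES["test"], dtype=np.int8)
    perm = rng.permutation(n)
    codes[perm[:n_train]] = SPLIT_CODES["train"]
    codes[perm[n_train:n_train + n_val]] = SPLIT_CODES["val"]
    return codes


@dataclass
class Dataset:
    """Paired corrupted curves and encoded labels with split assignments.

    ``intensities``/``masks`` are (n, n_bins); ``clean`` optionally keeps the
    pre-corruption curves (needed to rebuild alternative test corruptions).
    """

    grid: ChiGrid
    intensities: np.ndarray
    masks: np.ndarray
    labels: np.ndarray        # (n, 17) encoded targets
    raw_params: np.ndarray    # (n, 9)
    split: np.ndarray         # (n,) int8 codes
    seed: int
    provenance: dict = field(default_factory=dict)
    clean: np.ndarray = None

    def __len__(self):
        return self.intensities.shape[0]

    @property
    def X(self) -> np.ndarray:
        """Regressor features: [intensity; mask] concatenated per curve."""
        return np.concatenate(
            [self.intensities, self.masks.astype(self.intensities.dtype)], axis=1)

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == SPLIT_CODES[split])

    def curve(self, i: int) -> IChiCurve:
        return IChiCurve(self.grid, self.intensities[i].astype(float),
                         self.masks[i].copy())

    def reshuffle_split(self, seed: int) -> "Dataset":
        """Copy with a fresh random split of the same fractions."""
        rng = np.random.default_rng(seed)
        fr = self.provenance.get("split_fracs", (0.8, 0.1, 0.1))
        new = Dataset(self.grid, self.intensities, self.masks, self.labels,
                      self.raw_params, _split_assignment(len(self), fr, rng),
                      seed, dict(self.provenance), self.clean)
        new.provenance["reshuffle_seed"] = int(seed)
        return new


def build_dataset(labels: np.ndarray, grid: ChiGrid = None,
                  corruption: CorruptionConfig | None = None,
                  split_fracs=(0.8, 0.1, 0.1), seed: int = 0,
                  keep_clean: bool = False, dtype=np.float32,
                  **sim_kwargs) -> Dataset:
    """Simulate, corrupt and encode every label row into a Dataset.

    ``corruption=None`` disables corruption (curves stay clean and fully
    valid). Reproducible: the split and every per-curve corruption sub-seed
    derive from ``seed``.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if grid is None:
        grid = ChiGrid()
    n = labels.shape[0]
    clean = simulate_batch(labels, grid, **sim_kwargs)
    intensities = np.empty((n, grid.n_bins), dtype=dtype)
    masks = np.ones((n, grid.n_bins), dtype=bool)
    if corruption is not None:
        from dataclasses import replace as _replace
        sub = np.random.SeedSequence([seed, corruption.seed]).generate_state(n)
        for i in range(n):
            cfg = _replace(corruption, seed=int(sub[i]))
            try:
                c = corrupt(IChiCurve(grid, clean[i]), cfg)
            except ValueError as exc:
                raise ValueError(f"corruption failed for label row {i}: {exc}") from exc
            intensities[i] = c.intensity
            masks[i] = c.valid_mask
    else:
        intensities[:] = clean
    encoded = codec.encode_batch(labels)
    rng = np.random.default_rng(seed)
    split = _split_assignment(n, split_fracs, rng)
    prov = {
        "n": int(n),
        "seed": int(seed),
        "split_fracs": tuple(float(f) for f in split_fracs),
        "corruption": None if corruption is None else asdict(corruption),
        "sim_kwargs": {k: repr(v) for k, v in sim_kwargs.items()},
    }
    return Dataset(grid, intensities, masks, encoded, labels, split, seed, prov,
                   clean.astype(dtype) if keep_clean else None)
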