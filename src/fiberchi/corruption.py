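"""Data corruption: make simulated curves resemble experimental ones.

Three steps, applied in order (Poisson counting noise -> circular blockwise
masking -> random peak-intensity scaling):

* Poisson noise emulates photon counting at a random exposure level.
* Blockwise masking invalidates contiguous runs of azimuth bins, with
  head-tail wrap-around, mimicking detector module gaps and the beamstop
  shadow; the masking ratio is exact (final block truncated).
* The maximum intensity is scaled to a random value in [0.95, 1.05] instead
  of exact unit normalization, emulating imperfect normalization of
  experimental profiles.

Masked bins carry intensity 0 and valid_mask False; regressors consume the
concatenation [intensity; mask] so true zeros remain distinguishable from
missing signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import IChiCurve

__all__ = ["CorruptionConfig", "add_poisson_noise", "blockwise_mask",
           "random_scale", "corrupt"]


@dataclass
class CorruptionConfig:
    """Settings for the three-step corruption pipeline.

    counts_level_range
        Expected counts at the curve maximum; drawn log-uniformly per curve.
        (None, None) disables the noise step.
    mask_ratio
        Fraction of azimuth bins invalidated; 0.3 is the default working point.
    block_len_range
        Min/max masked-block length in bins, spanning beamstop-sized through
        module-gap-sized occlusions on a 360-bin grid.
    scale_range
        Interval for the post-corruption curve maximum.
    """

    counts_level_range: tuple = (200.0, 20000.0)
    mask_ratio: float = 0.3
    block_len_range: tuple = (5, 60)
    scale_range: tuple = (0.95, 1.05)
    #: "poisson" (counting statistics, default), "gaussian" (additive noise of
    #: matching variance), or "poisson+gaussian" (both at half strength each)
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.noise not in ("poisson", "gaussian", "poisson+gaussian"):
            raise ValueError(f"unknown noise type {self.noise!r}")
        if not (0.0 <= self.mask_ratio < 1.0):
            raise ValueError("mask_ratio must be in [0, 1)")
        if self.block_len_range[0] < 1 or self.block_len_range[1] < self.block_len_range[0]:
            raise ValueError("invalid block_len_range")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid scale_range")


def _as_rng(seed):
    # accept a Generator (or any duck-typed source of draws) as-is
    if hasattr(seed, "integers") or hasattr(seed, "uniform"):
        return seed
    return np.random.default_rng(seed)


def add_poisson_noise(curve: IChiCurve, counts_level: float, seed=0,
                      noise: str = "poisson") -> IChiCurve:
    """Replace each bin by a noisy draw at mean intensity/max * counts_level,
    rescaled back to the original intensity scale.

    ``noise`` selects Poisson counting statistics (default), additive Gaussian
    noise of matching variance (clipped at zero), or an equal-variance mix.
    """
    if not counts_level > 0:
        raise ValueError("counts_level must be > 0")
    if np.any(curve.intensity < 0):
        raise ValueError("negative intensities")
    rng = _as_rng(seed)
    out = curve.copy()
    peak = curve.intensity.max()
    if peak <= 0:
        return out  # all-zero curve: Poisson(0) = 0
    scale = counts_level / peak
    lam = curve.intensity * scale
    if noise == "poisson":
        counts = rng.poisson(lam).astype(float)
    elif noise == "gaussian":
        counts = np.maximum(lam + rng.normal(0.0, np.sqrt(lam)), 0.0)
    elif noise == "poisson+gaussian":
        half = lam / 2.0
        counts = np.maximum(rng.poisson(half)
                            + half + rng.normal(0.0, np.sqrt(half)), 0.0)
    else:
        raise ValueError(f"unknown noise type {noise!r}")
    out.intensity = counts / scale
    return out


def blockwise_mask(curve: IChiCurve, mask_ratio: float, block_len_range=(5, 60),
                   seed=0) -> IChiCurve:
    """Invalidate exactly round(mask_ratio * n_bins) bins in contiguous blocks
    on the circular grid (blocks may wrap past the last bin to bin 0).

    Blocks are drawn repeatedly (uniform start bin, uniform length within
    ``block_len_range``) until the target count is reached; the final block is
    truncated bin-by-bin so the count is exact. Masked bins get intensity 0.
    """
    if not (0.0 <= mask_ratio < 1.0):
        raise ValueError("mask_ratio must be in [0, 1)")
    n = curve.grid.n_bins
    lo, hi = int(block_len_range[0]), int(block_len_range[1])
    if lo < 1 or hi < lo or hi > n:
        raise ValueError("block_len_range must lie within [1, n_bins]")
    rng = _as_rng(seed)
    out = curve.copy()
    target = int(round(mask_ratio * n))
    invalid = ~out.valid_mask
    guard = 0
    while invalid.sum() < target:
        guard += 1
        if guard > 100_000:
            raise ValueError("infeasible masking configuration")
        start = int(rng.integers(0, n))
        length = int(rng.integers(lo, hi + 1))
        bins = np.mod(start + np.arange(length), n)
        need = target - int(invalid.sum())
        new = bins[~invalid[bins]][:need] if need < length else bins
        invalid[new] = True
    out.valid_mask = ~invalid
    out.intensity = np.where(invalid, 0.0, out.intensity)
    return out


def random_scale(curve: IChiCurve, scale_range=(0.95, 1.05), seed=0) -> IChiCurve:
    """Scale the curve so its maximum equals a uniform draw from scale_range."""
    rng = _as_rng(seed)
    out = curve.copy()
    peak = out.intensity[out.valid_mask].max() if out.valid_mask.any() else 0.0
    if peak <= 0:
        raise ValueError("degenerate input: curve has no positive maximum")
    s = rng.uniform(scale_range[0], scale_range[1])
    out.intensity = out.intensity * (s / peak)
    return out


class BatchCorruptor:
    """Vectorized re-corruption of a matrix of clean curves, for training-time
    augmentation: each call returns a freshly corrupted ``[intensity; mask]``
    feature matrix (new Poisson noise, new mask placements, new scales), the
    masked-signal analogue of re-masking image patches every iteration.

    A bank of ``n_masks`` blockwise masks is pre-generated once; each call
    assigns every curve a random bank entry.
    """

    def __init__(self, clean: np.ndarray, config: CorruptionConfig,
                 n_masks: int = 4096, seed: int = 0):
        from .forward import ChiGrid
        self.clean = np.asarray(clean, dtype=np.float32)
        self.config = config
        n_bins = self.clean.shape[1]
        grid = ChiGrid(n_bins)
        rng = np.random.default_rng(seed)
        if config.mask_ratio > 0:
            bank = np.empty((n_masks, n_bins), dtype=bool)
            dummy = IChiCurve(grid, np.ones(n_bins))
            for i in range(n_masks):
                bank[i] = blockwise_mask(dummy, config.mask_ratio,
                                         config.block_len_range, rng).valid_mask
            self.mask_bank = bank
        else:
            self.mask_bank = np.ones((1, n_bins), dtype=bool)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Fresh corrupted feature matrix (n_curves, 2 * n_bins), float32."""
        cfg = self.config
        n = self.clean.shape[0]
        inten = self.clean
        lo, hi = cfg.counts_level_range
        if lo is not None and np.isfinite(lo):
            levels = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, 1)))
            # clean curves are unit-max normalized, so lam = I * level
            lam = inten * levels
            if cfg.noise == "poisson":
                counts = rng.poisson(lam).astype(np.float32)
            elif cfg.noise == "gaussian":
                counts = np.maximum(lam + rng.normal(0.0, np.sqrt(lam)), 0.0)
            else:  # poisson+gaussian
                half = lam / 2.0
                counts = np.maximum(rng.poisson(half) + half
                                    + rng.normal(0.0, np.sqrt(half)), 0.0)
            inten = counts.astype(np.float32) / levels
        masks = self.mask_bank[rng.integers(0, len(self.mask_bank), size=n)]
        inten = np.where(masks, inten, 0.0).astype(np.float32)
        peak = np.where(masks, inten, 0.0).max(axis=1, keepdims=True)
        s = rng.uniform(cfg.scale_range[0], cfg.scale_range[1], size=(n, 1))
        inten = inten * np.where(peak > 0, s / np.maximum(peak, 1e-12), 0.0)
        return np.concatenate([inten, masks.astype(np.float32)],
                              axis=1).astype(np.float32)


def corrupt(curve: IChiCurve, config: CorruptionConfig) -> IChiCurve:
    """Apply noise -> mask -> scale with independent sub-seeds from config.seed."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    out = curve
    lo, hi = config.counts_level_range
    if lo is not None and np.isfinite(lo):
        level_rng = np.random.default_rng(ss[0])
        counts_level = float(np.exp(level_rng.uniform(np.log(lo), np.log(hi))))
        out = add_poisson_noise(out, counts_level, np.random.default_rng(ss[1]),
                                noise=config.noise)
    if config.mask_ratio > 0:
        out = blockwise_mask(out, config.mask_ratio, config.block_len_range,
                             np.random.default_rng(ss[2]))
    out = random_scale(out, config.scale_range, np.random.default_rng(ss[3]))
    return out
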