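"""Readers/writers for curves, datasets and models; detector ring integration.

Curve text format: two whitespace-delimited columns (chi_deg, intensity); a
NaN intensity marks a masked bin. HDF5 layout: datasets ``chi``,
``intensity``, ``mask`` (+ optional ``params``) in one group. Datasets are a
single HDF5 file; models one joblib file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import joblib
import numpy as np

from .forward import ChiGrid, IChiCurve, PARAM_NAMES
from .sampling import Dataset

__all__ = ["read_curve", "write_curve", "save_dataset", "load_dataset",
           "save_model", "load_model", "BeamGeometry", "azimuthal_integrate"]


def _grid_from_chi(chi: np.ndarray, path) -> ChiGrid:
    if len(np.unique(chi)) != len(chi):
        dup = chi[np.where(np.diff(np.sort(chi)) == 0)[0][0]]
        raise ValueError(f"{path}: duplicate chi value {dup}")
    steps = np.diff(chi)
    if len(steps) and not np.allclose(steps, steps[0], atol=1e-6):
        line = int(np.argmax(~np.isclose(steps, steps[0], atol=1e-6))) + 2
        raise ValueError(f"{path}: non-uniform chi grid near line {line}")
    return ChiGrid(len(chi))


def write_curve(curve: IChiCurve, path) -> None:
    """Write a curve as text (.txt/.dat/.csv) or HDF5 (.h5/.hdf5)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("chi", data=curve.grid.chi_centers)
            f.create_dataset("intensity", data=curve.intensity)
            f.create_dataset("mask", data=curve.valid_mask)
            f.attrs["q_label"] = curve.q_label
    else:
        inten = np.where(curve.valid_mask, curve.intensity, np.nan)
        np.savetxt(path, np.column_stack([curve.grid.chi_centers, inten]),
                   fmt="%.8f", header="chi_deg intensity (NaN = masked)")


def read_curve(path) -> IChiCurve:
    """Read a curve written by :func:`write_curve` (text rows with NaN become
    masked bins)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            chi = np.asarray(f["chi"])
            inten = np.asarray(f["intensity"], dtype=float)
            mask = np.asarray(f["mask"], dtype=bool)
            grid = _grid_from_chi(chi, path)
            return IChiCurve(grid, inten, mask,
                             q_label=f.attrs.get("q_label", "(110)"))
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed row ({exc})") from exc
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, got {data.shape[1]}")
    grid = _grid_from_chi(data[:, 0], path)
    inten = data[:, 1]
    mask = ~np.isnan(inten)
    return IChiCurve(grid, np.where(mask, inten, 0.0), mask)


def save_dataset(dataset: Dataset, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("chi", data=dataset.grid.chi_centers)
        f.create_dataset("intensities", data=dataset.intensities)
        f.create_dataset("masks", data=dataset.masks)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("raw_params", data=dataset.raw_params)
        f.create_dataset("split", data=dataset.split)
        if dataset.clean is not None:
            f.create_dataset("clean", data=dataset.clean)
        f.attrs["seed"] = dataset.seed
        f.attrs["provenance"] = json.dumps(dataset.provenance, default=str)
        f.attrs["param_names"] = ",".join(PARAM_NAMES)


def load_dataset(path) -> Dataset:
    with h5py.File(str(path), "r") as f:
        grid = ChiGrid(f["chi"].shape[0])
        return Dataset(
            grid,
            np.asarray(f["intensities"]),
            np.asarray(f["masks"], dtype=bool),
            np.asarray(f["labels"]),
            np.asarray(f["raw_params"]),
            np.asarray(f["split"], dtype=np.int8),
            int(f.attrs["seed"]),
            json.loads(f.attrs["provenance"]),
            np.asarray(f["clean"]) if "clean" in f else None,
        )


def save_model(model, path) -> None:
    joblib.dump(model, str(path))


def load_model(path):
    return joblib.load(str(path))


# ------------------------------------------------------------ ring integration

@dataclass(frozen=True)
class BeamGeometry:
    """Detector geometry for azimuthal integration of a 2D frame.

    beam_center
        (row, col) of the direct beam in pixels.
    pixel_size_um
        Pixel pitch in micrometres.
    distance_mm
        Sample-to-detector distance in millimetres.
    energy_kev
        Photon energy in keV.
    radial_window_px
        (r_min, r_max) radii in pixels selecting the (110) ring.
    """

    beam_center: tuple
    pixel_size_um: float = 172.0
    distance_mm: float = 262.3
    energy_kev: float = 10.0
    radial_window_px: tuple = (300.0, 340.0)

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.distance_mm <= 0 or self.energy_kev <= 0:
            raise ValueError("geometry constants must be positive")
        if not self.radial_window_px[0] < self.radial_window_px[1]:
            raise ValueError("empty radial window")


def azimuthal_integrate(image: np.ndarray, geometry: BeamGeometry,
                        mask_image: np.ndarray = None, n_bins: int = 360,
                        threshold=(0.0, 100_000.0)) -> IChiCurve:
    """Mean intensity per chi bin of unmasked pixels inside the radial window.

    chi is 0 along the +x (column) detector axis, counter-clockwise, matching
    the simulator's convention. Pixels below threshold[0] or above
    threshold[1] are masked (dead/hot pixels and module gaps); chi bins with
    no contributing pixel come back as masked bins.
    """
    image = np.asarray(image, dtype=float)
    if mask_image is None:
        mask_image = np.ones_like(image, dtype=bool)
    mask_image = np.asarray(mask_image, dtype=bool)
    if mask_image.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.indices(image.shape)
    dy = -(rows - geometry.beam_center[0])  # +y up on the detector
    dx = cols - geometry.beam_center[1]
    r = np.hypot(dx, dy)
    rmin, rmax = geometry.radial_window_px
    good = (mask_image & (r >= rmin) & (r <= rmax)
            & (image >= threshold[0]) & (image <= threshold[1]))
    grid = ChiGrid(n_bins)
    chi = np.rad2deg(np.arctan2(dy[good], dx[good]))
    bins = grid.bin_of(chi)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=image[good], minlength=n_bins)
    valid = counts > 0
    inten = np.zeros(n_bins)
    inten[valid] = sums[valid] / counts[valid]
    return IChiCurve(grid, inten, valid)
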