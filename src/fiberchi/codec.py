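"""Canonical fiber-group ordering and periodic angle label encoding.

Angle labels live on a 180-deg-periodic circle (a fiber axis equals its
negation), so regressing raw degrees has a jump discontinuity at +/-90. Each
angle is therefore doubled and mapped to a point on the unit circle,
(x, y) = (cos 2*theta, sin 2*theta): beta = -90 and beta = +90 encode to the
same point and predictions stay continuous across the boundary. The quantity
ratio lambda1/lambda2 is regressed as its natural logarithm so that a ratio
and its inverse are treated symmetrically.

A label vector has 17 entries: (x, y) for each of the 8 angles in the order
alpha1, beta1, gamma1, dgamma1, alpha2, beta2, gamma2, dgamma2, then
log(lambda1/lambda2).
"""

from __future__ import annotations

import numpy as np

from .forward import OrientationParams, normalize_angle

__all__ = ["canonical_order", "is_canonical", "encode_labels", "decode_labels",
           "encode_batch", "decode_batch", "N_LABELS"]

N_LABELS = 17

# indices of the spread angles (dgamma1, dgamma2) within the 8-angle block
_SPREAD_SLOTS = (3, 7)


def canonical_order(params: OrientationParams) -> OrientationParams:
    """Order the two groups so gamma1 >= gamma2 (on canonical angles), swapping
    whole groups and inverting lam_ratio if needed. Ties broken by larger
    dgamma, then larger beta. Idempotent."""
    p = params.normalized()
    key1 = (p.gamma1, p.dgamma1, p.beta1)
    key2 = (p.gamma2, p.dgamma2, p.beta2)
    if key2 > key1:
        p = p.swapped()
    return p


def is_canonical(params: OrientationParams, tol: float = 0.0) -> bool:
    p = params.normalized()
    return (p.gamma1, p.dgamma1, p.beta1) >= (p.gamma2 - tol, p.dgamma2, p.beta2)


def _encode_angles(theta_deg: np.ndarray) -> np.ndarray:
    """(..., 8) angles in degrees -> (..., 16) interleaved (x, y) pairs."""
    t2 = np.deg2rad(2.0 * theta_deg)
    out = np.empty(theta_deg.shape[:-1] + (16,))
    out[..., 0::2] = np.cos(t2)
    out[..., 1::2] = np.sin(t2)
    return out


def encode_batch(params_array: np.ndarray, check: bool = True) -> np.ndarray:
    """Encode label rows (n, 9) -> (n, 17)."""
    arr = np.atleast_2d(np.asarray(params_array, dtype=float))
    if arr.shape[1] != 9:
        raise ValueError("expected 9 columns")
    if check:
        g1, g2 = arr[:, 2], arr[:, 6]
        if np.any(normalize_angle(g1) < normalize_angle(g2)):
            raise ValueError("non-canonical parameters: gamma1 < gamma2")
    if np.any(arr[:, 8] <= 0):
        raise ValueError("lam_ratio must be > 0")
    out = np.empty((arr.shape[0], N_LABELS))
    out[:, :16] = _encode_angles(arr[:, [0, 1, 2, 3, 4, 5, 6, 7]])
    out[:, 16] = np.log(arr[:, 8])
    return out


def encode_labels(params: OrientationParams, check: bool = True) -> np.ndarray:
    """Encode one parameter set into the 17-value label vector."""
    return encode_batch(params.to_array()[None, :], check=check)[0]


def decode_batch(vectors: np.ndarray) -> np.ndarray:
    """Decode raw regressor outputs (n, 17) -> label rows (n, 9).

    Each (x, y) pair need not lie on the unit circle (the two-argument
    arctangent is scale-free). Tilt/mean angles land in (-90, 90]; the spread
    angles use the [0, 360) branch before halving so dgamma recovers in
    [0, 180). Canonical ordering is re-applied.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[1] != N_LABELS:
        raise ValueError(f"expected {N_LABELS} columns")
    x, y = v[:, 0:16:2], v[:, 1:16:2]
    if np.any((x == 0) & (y == 0)):
        raise ValueError("undefined angle: (x, y) pair is exactly (0, 0)")
    ang2 = np.rad2deg(np.arctan2(y, x))  # in [-180, 180]
    theta = ang2 / 2.0
    # (-90, 90] branch for tilt/mean angles
    theta = np.where(theta <= -90.0, theta + 180.0, theta)
    # [0, 180) branch for the spread angles
    for j in _SPREAD_SLOTS:
        theta[:, j] = np.mod(ang2[:, j], 360.0) / 2.0
    out = np.empty((v.shape[0], 9))
    out[:, :8] = theta
    out[:, 8] = np.exp(np.clip(v[:, 16], -700.0, 700.0))
    # re-canonicalize rowwise
    swap = out[:, 2] < out[:, 6]
    ties = out[:, 2] == out[:, 6]
    if np.any(ties):
        swap = swap | (ties & (out[:, 3] < out[:, 7]))
    if np.any(swap):
        tmp = out[swap][:, [4, 5, 6, 7, 0, 1, 2, 3, 8]]
        tmp[:, 8] = 1.0 / tmp[:, 8]
        out[swap] = tmp
    return out


def decode_labels(vector17: np.ndarray) -> OrientationParams:
    """Decode one 17-value vector into orientation parameters."""
    return OrientationParams.from_array(decode_batch(np.asarray(vector17)[None, :])[0])
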