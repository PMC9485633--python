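"""Extracellular-volume (ECV) mapping with synthetic hematocrit.

ECV = (1 - Hct) * dR1_myo / dR1_blood with R1 = 1/T1 measured before and
after gadolinium contrast.  When a blood sample is unavailable the
hematocrit is estimated from the native blood-pool T1 through an
empirical linear relationship in R1 (synthetic hematocrit).  Native and
post-contrast maps are aligned with an exhaustive rigid (shift +
rotation) registration maximizing normalized cross-correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .maps import ParameterMap

__all__ = [
    "EcvInputs",
    "RigidTransform",
    "synthetic_hematocrit",
    "compute_ecv",
    "rigid_register",
    "apply_rigid",
    "align",
]

#: Default synthetic-hematocrit coefficients (slope ms, intercept) for the
#: linear model Hct = slope / T1_blood + intercept, established for native
#: MOLLI blood T1 at 1.5T.
DEFAULT_HCT_COEFFICIENTS = (866.0, -0.1232)

_HCT_CLIP = (0.2, 0.6)


@dataclass
class EcvInputs:
    """Pixel maps and scalars entering the ECV computation."""

    t1_native_map: ParameterMap
    t1_post_map: ParameterMap
    blood_t1_native: float
    blood_t1_post: float
    hematocrit: float

    def __post_init__(self) -> None:
        if self.blood_t1_native <= 0 or self.blood_t1_post <= 0:
            raise ValueError("blood T1 values must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.t1_native_map.shape != self.t1_post_map.shape:
            raise ValueError("native and post-contrast maps must have the same shape")


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid transform: integer pixel shifts and a rotation."""

    dx: float
    dy: float
    theta_deg: float
    score: float = np.nan


def synthetic_hematocrit(
    blood_t1_native: float,
    coefficients: tuple[float, float] = DEFAULT_HCT_COEFFICIENTS,
) -> float:
    """Estimate hematocrit from native blood-pool T1 (ms).

    ``hct = slope / T1 + intercept``; results outside [0.2, 0.6] are
    clipped with a warning (physiologically implausible blood T1).
    """
    if blood_t1_native <= 0:
        raise ValueError(f"blood T1 must be positive, got {blood_t1_native}")
    slope, intercept = coefficients
    hct = slope / blood_t1_native + intercept
    lo, hi = _HCT_CLIP
    if hct < lo or hct > hi:
        warnings.warn(
            f"synthetic hematocrit {hct:.3f} outside [{lo}, {hi}]; clipping", stacklevel=2
        )
        hct = min(max(hct, lo), hi)
    return float(hct)


def compute_ecv(inputs: EcvInputs, units: str = "fraction") -> ParameterMap:
    """Pixelwise ECV map from aligned native/post-contrast T1 maps.

    ECV = (1 - hct) * (1/T1_post - 1/T1_native) / (1/T1b_post - 1/T1b_native).
    Pixels with non-positive T1 (or NaN) are invalid; a non-positive blood
    dR1 invalidates the whole map.
    """
    t1n = inputs.t1_native_map.data.astype(float)
    t1p = inputs.t1_post_map.data.astype(float)
    dr1_blood = 1.0 / inputs.blood_t1_post - 1.0 / inputs.blood_t1_native
    with np.errstate(divide="ignore", invalid="ignore"):
        dr1_myo = np.where(t1p > 0, 1.0 / t1p, np.nan) - np.where(t1n > 0, 1.0 / t1n, np.nan)
        ecv = (1.0 - inputs.hematocrit) * dr1_myo / dr1_blood
    if dr1_blood <= 0:
        warnings.warn("blood dR1 <= 0; ECV map flagged invalid", stacklevel=2)
        ecv = np.full_like(ecv, np.nan)
    if units == "percent":
        ecv = ecv * 100.0
    elif units != "fraction":
        raise ValueError(f"unknown units {units!r}")
    return ParameterMap(
        ecv,
        units=units,
        name="ECV",
        meta={"hematocrit": inputs.hematocrit,
              "blood_t1_native": inputs.blood_t1_native,
              "blood_t1_post": inputs.blood_t1_post},
    )


def apply_rigid(image: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Forward-apply a transform: pixel shifts, then rotation about the centre.

    ``rigid_register(moving, fixed)`` estimates the transform such that
    ``moving ≈ apply_rigid(fixed, transform)``; use :func:`align` to map
    the moving image back onto the fixed frame.
    """
    out = np.asarray(image, dtype=float)
    if transform.dx or transform.dy:
        out = ndimage.shift(out, (transform.dy, transform.dx), order=0,
                            mode="constant", cval=np.nan)
    if transform.theta_deg != 0:
        out = ndimage.rotate(out, transform.theta_deg, reshape=False, order=1,
                             mode="constant", cval=np.nan)
    return out


def align(moving: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Resample the moving image onto the fixed frame (inverse of apply_rigid)."""
    out = np.asarray(moving, dtype=float)
    if transform.theta_deg != 0:
        out = ndimage.rotate(out, -transform.theta_deg, reshape=False, order=1,
                             mode="constant", cval=np.nan)
    if transform.dx or transform.dy:
        out = ndimage.shift(out, (-transform.dy, -transform.dx), order=0,
                            mode="constant", cval=np.nan)
    return out


def _int_shift(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer pixel shift with NaN fill (fast path for the search loop)."""
    out = np.full_like(img, np.nan)
    H, W = img.shape
    ys_dst = slice(max(dy, 0), H + min(dy, 0))
    xs_dst = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[ys_dst, xs_dst] = img[ys_src, xs_src]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return -np.inf
    av, bv = a[valid], b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        return -np.inf
    return float(av @ bv / (na * nb))


def rigid_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_shift: int = 10,
    max_angle_deg: float = 5.0,
    angle_step_deg: float = 0.5,
) -> RigidTransform:
    """Exhaustive rigid registration maximizing normalized cross-correlation.

    Searches integer shifts in [-max_shift, max_shift] and rotations in
    [-max_angle, max_angle] with the given step, and returns the
    displacement of the moving image relative to the fixed one (i.e.
    ``moving ≈ apply_rigid(fixed, transform)``); a moving image shifted by
    (3, -2) pixels is reported as dx=3, dy=-2.  Out-of-frame pixels are
    excluded from the correlation.  Flat (zero-variance) images return the
    identity with a warning.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must have the same shape")
    if np.nanstd(moving) == 0 or np.nanstd(fixed) == 0:
        warnings.warn("flat image: registration returns identity", stacklevel=2)
        return RigidTransform(0.0, 0.0, 0.0, score=np.nan)

    angles = np.arange(-max_angle_deg, max_angle_deg + angle_step_deg / 2, angle_step_deg)
    # evaluate the identity first so exact ties favour no transform
    order = np.argsort(np.abs(angles), kind="stable")
    shifts = sorted(range(-max_shift, max_shift + 1), key=abs)

    best = RigidTransform(0.0, 0.0, 0.0, score=-np.inf)
    for theta in angles[order]:
        # undo the candidate rotation, then undo candidate shifts; the
        # remaining mismatch is scored against the fixed image
        if theta != 0:
            rotated = ndimage.rotate(moving, -float(theta), reshape=False, order=1,
                                     mode="constant", cval=np.nan)
        else:
            rotated = moving
        for dy in shifts:
            for dx in shifts:
                shifted = _int_shift(rotated, -dx, -dy)
                score = _ncc(shifted, fixed)
                if score > best.score:
                    best = RigidTransform(float(dx), float(dy), float(theta), score=score)
    return best
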