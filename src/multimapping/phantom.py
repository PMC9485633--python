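"""Synthetic short-axis cardiac phantom and acquisition synthesis.

The phantom emulates a mid-ventricular short-axis slice: a circular left
ventricular blood pool, a surrounding myocardial annulus, optionally a
lesion sector of the annulus with altered relaxation times, a spatially
smooth background phase (second-order 2D polynomial) and complex Gaussian
noise.  Ground-truth T1/T2/M0/B1/phase maps are returned alongside every
synthesized acquisition, so the whole mapping pipeline can be validated
against known truth.

Default relaxation times are literature-typical native values at 1.5T:
blood 1600/250 ms, healthy myocardium 1100/50 ms, lesion 1400/70 ms
(edema-like).  They are configurable and carry no claim beyond
plausibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psir import ComplexImageSeries
from .sequence_model import (
    CardiacSchedule,
    PulseSequenceParams,
    TissueParams,
    molli_schedule,
    multimapping_schedule,
    simulate_series_bulk,
    t2bssfp_schedule,
)

__all__ = [
    "PhantomRegion",
    "PhantomDefinition",
    "PhantomMaps",
    "make_phantom",
    "septal_roi",
    "simulate_acquisition",
    "snr_noise_sd",
]

LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_LESION = 3


@dataclass(frozen=True)
class PhantomRegion:
    """One labeled tissue region with its ground-truth parameters."""

    label: int
    tissue: TissueParams
    m0: float = 1.0
    b1: float = 1.0


@dataclass(frozen=True)
class PhantomDefinition:
    """Geometry and ground truth of the short-axis phantom.

    The blood pool is a disk of radius ``blood_radius_px`` centred in the
    image; the myocardium is the annulus from ``blood_radius_px`` to
    ``outer_radius_px``.  ``lesion_angle_deg`` carves an angular sector of
    the annulus (centred on ``lesion_center_deg``) with its own tissue.
    ``phase_coefficients`` are the six coefficients (c0, cx, cy, cxx, cxy,
    cyy) of a second-order polynomial background phase in normalized
    [-1, 1] image coordinates, in radians.
    """

    shape: tuple[int, int] = (160, 160)
    blood_radius_px: float = 20.0
    outer_radius_px: float = 32.0
    blood: PhantomRegion = PhantomRegion(LABEL_BLOOD, TissueParams(1600.0, 250.0))
    myocardium: PhantomRegion = PhantomRegion(LABEL_MYOCARDIUM, TissueParams(1100.0, 50.0))
    lesion: PhantomRegion | None = PhantomRegion(LABEL_LESION, TissueParams(1400.0, 70.0))
    lesion_angle_deg: float = 60.0
    lesion_center_deg: float = 0.0
    phase_coefficients: tuple[float, ...] = (0.3, 0.8, -0.5, 0.4, 0.3, -0.2)
    b1: float = 1.0

    def __post_init__(self) -> None:
        if self.blood_radius_px <= 0 or self.outer_radius_px <= self.blood_radius_px:
            raise ValueError("need 0 < blood radius < outer radius")
        if min(self.shape) <= 2 * self.outer_radius_px:
            raise ValueError("phantom annulus does not fit in the image")


@dataclass
class PhantomMaps:
    """Ground-truth maps of a realized phantom."""

    label_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    m0_map: np.ndarray
    b1_map: np.ndarray
    phase_map: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape


def _grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    ang = np.degrees(np.arctan2(yy - cy, xx - cx))
    return yy, xx, r, ang


def make_phantom(definition: PhantomDefinition | None = None) -> PhantomMaps:
    """Realize the label and ground-truth maps of a phantom definition."""
    d = definition or PhantomDefinition()
    H, W = d.shape
    yy, xx, r, ang = _grids(d.shape)

    label = np.zeros(d.shape, dtype=np.int8)
    label[r <= d.blood_radius_px] = LABEL_BLOOD
    annulus = (r > d.blood_radius_px) & (r <= d.outer_radius_px)
    label[annulus] = LABEL_MYOCARDIUM
    regions = {LABEL_BLOOD: d.blood, LABEL_MYOCARDIUM: d.myocardium}
    if d.lesion is not None and d.lesion_angle_deg > 0:
        half = d.lesion_angle_deg / 2.0
        dang = (ang - d.lesion_center_deg + 180.0) % 360.0 - 180.0
        sector = annulus & (np.abs(dang) <= half)
        label[sector] = d.lesion.label
        regions[d.lesion.label] = d.lesion

    t1 = np.zeros(d.shape)
    t2 = np.zeros(d.shape)
    m0 = np.zeros(d.shape)
    b1 = np.full(d.shape, d.b1)
    for lab, reg in regions.items():
        sel = label == lab
        t1[sel] = reg.tissue.t1
        t2[sel] = reg.tissue.t2
        m0[sel] = reg.m0
        b1[sel] = reg.b1 * d.b1

    # second-order polynomial background phase in normalized coordinates
    xn = (xx - (W - 1) / 2.0) / ((W - 1) / 2.0)
    yn = (yy - (H - 1) / 2.0) / ((H - 1) / 2.0)
    c = d.phase_coefficients
    phase = c[0] + c[1] * xn + c[2] * yn + c[3] * xn**2 + c[4] * xn * yn + c[5] * yn**2

    return PhantomMaps(label, t1, t2, m0, b1, phase)


def septal_roi(
    definition: PhantomDefinition | None = None,
    center_deg: float = 180.0,
    span_deg: float = 60.0,
    radial_margin_px: float = 2.0,
) -> np.ndarray:
    """Septal myocardial ROI: an angular window of the annulus, radially eroded.

    With the default lesion sector centred at 0 deg, the default septal
    window at 180 deg lies in remote (healthy) myocardium.
    """
    d = definition or PhantomDefinition()
    _, _, r, ang = _grids(d.shape)
    dang = (ang - center_deg + 180.0) % 360.0 - 180.0
    return (
        (r > d.blood_radius_px + radial_margin_px)
        & (r <= d.outer_radius_px - radial_margin_px)
        & (np.abs(dang) <= span_deg / 2.0)
    )


def myocardial_roi(
    definition: PhantomDefinition | None = None, radial_margin_px: float = 1.0
) -> np.ndarray:
    """Full-annulus healthy-myocardium ROI (lesion sector excluded)."""
    d = definition or PhantomDefinition()
    maps = make_phantom(d)
    _, _, r, _ = _grids(d.shape)
    return (
        (maps.label_map == LABEL_MYOCARDIUM)
        & (r > d.blood_radius_px + radial_margin_px)
        & (r <= d.outer_radius_px - radial_margin_px)
    )


_PROTOCOLS = ("multimapping", "molli", "t2bssfp")


def _default_schedule(protocol: str, rr_ms: float, params: PulseSequenceParams) -> CardiacSchedule:
    if protocol == "multimapping":
        return multimapping_schedule(rr_ms, params=params)
    if protocol == "molli":
        return molli_schedule(rr_ms, params=params)
    if protocol == "t2bssfp":
        return t2bssfp_schedule(rr_ms, params=params)
    raise ValueError(f"unknown protocol {protocol!r}; expected one of {_PROTOCOLS}")


def simulate_acquisition(
    phantom: PhantomMaps,
    protocol: str = "multimapping",
    schedule: CardiacSchedule | None = None,
    params: PulseSequenceParams | None = None,
    rr_ms: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ComplexImageSeries, CardiacSchedule]:
    """Synthesize the complex image series of one protocol on the phantom.

    Per pixel the signed Bloch signal at that pixel's (T1, T2, B1) is
    scaled by M0, rotated by the background phase and corrupted with
    complex Gaussian noise of standard deviation ``noise_sd`` per channel.
    """
    if protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {_PROTOCOLS}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if params is None:
        params = (
            PulseSequenceParams.multimapping()
            if protocol == "multimapping"
            else PulseSequenceParams.reference()
        )
    if schedule is None:
        schedule = _default_schedule(protocol, rr_ms, params)

    H, W = phantom.shape
    L = schedule.n_acquired
    signal = np.zeros((L, H, W))
    tissue_pixels = phantom.m0_map > 0
    combos = np.stack(
        [phantom.t1_map[tissue_pixels], phantom.t2_map[tissue_pixels], phantom.b1_map[tissue_pixels]],
        axis=1,
    )
    uniq, inverse = np.unique(combos, axis=0, return_inverse=True)
    series = np.empty((uniq.shape[0], L))
    for i, (t1, t2, b1) in enumerate(uniq):
        series[i] = simulate_series_bulk(np.array([t1]), np.array([t2]), float(b1), params, schedule)[0]
    flat_idx = np.flatnonzero(tissue_pixels.ravel())
    sig_flat = signal.reshape(L, -1)
    sig_flat[:, flat_idx] = series[inverse].T
    signal *= phantom.m0_map[None]

    frames = signal.astype(complex) * np.exp(1j * phantom.phase_map)[None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + noise_sd * (
            rng.standard_normal(frames.shape) + 1j * rng.standard_normal(frames.shape)
        )
    meta = {"protocol": protocol, "noise_sd": noise_sd, "seed": seed}
    return ComplexImageSeries(frames=frames, meta=meta), schedule


def snr_noise_sd(
    phantom: PhantomMaps,
    snr: float,
    protocol: str = "multimapping",
    schedule: CardiacSchedule | None = None,
    params: PulseSequenceParams | None = None,
    rr_ms: float = 1000.0,
) -> float:
    """Noise sigma realizing a given SNR.

    SNR is defined as the noiseless blood-pool magnitude in the last
    acquired frame divided by the per-channel noise standard deviation.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean, _ = simulate_acquisition(
        phantom, protocol=protocol, schedule=schedule, params=params, rr_ms=rr_ms, noise_sd=0.0
    )
    blood = phantom.label_map == LABEL_BLOOD
    ref = float(np.mean(np.abs(clean.frames[-1][blood])))
    return ref / snr
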