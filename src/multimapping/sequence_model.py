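"""On-resonance Bloch simulation of ECG-triggered cardiac mapping sequences.

This module models the three acquisitions compared in the package: the
ten-beat inversion-recovery/T2prep bSSFP scheme used for simultaneous
T1/T2 mapping ("multimapping"), the MOLLI 5(3s)3 T1 mapping scheme, and
the four-echo T2-prepared bSSFP T2 mapping scheme.  Each single-shot
bSSFP readout is simulated pulse by pulse (startup ramp + phase-alternated
readout train) for a single on-resonance isochromat; the sequence-level
simulators chain shots across cardiac cycles with free T1 relaxation in
between and instantaneous ideal preparation modules.

The signed sample returned per shot is the transverse magnitude at the
k-space-centre echo carrying the sign of the longitudinal magnetization
entering the shot — the quantity that a phase-sensitive reconstruction
recovers from the acquired complex image.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_RAD_PER_S_PER_T",
    "MagnetizationState",
    "TissueParams",
    "PulseSequenceParams",
    "PrepEvent",
    "CardiacSchedule",
    "AdiabaticPulseParams",
    "SimulatedSeries",
    "relax",
    "apply_inversion",
    "apply_t2prep",
    "simulate_bssfp_shot",
    "simulate_series",
    "simulate_series_bulk",
    "simulate_multimapping_series",
    "simulate_molli_series",
    "simulate_t2bssfp_series",
    "simulate_hs_inversion",
    "multimapping_schedule",
    "molli_schedule",
    "t2bssfp_schedule",
]

#: Proton gyromagnetic ratio (rad / s / T).
GAMMA_RAD_PER_S_PER_T = 2.675221874e8

_MZ_TOL = 1e-9


@dataclass
class MagnetizationState:
    """Spin-system state: longitudinal and transverse components in units of M0."""

    mz: float
    mxy: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")
        if self.mxy < 0:
            raise ValueError(f"mxy is a magnitude and must be >= 0, got {self.mxy}")
        if abs(self.mz) > self.m0 * (1 + 1e-6) + _MZ_TOL:
            raise ValueError(f"|mz|={abs(self.mz)} exceeds m0={self.m0}")

    @classmethod
    def equilibrium(cls, m0: float = 1.0) -> "MagnetizationState":
        return cls(mz=m0, mxy=0.0, m0=m0)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times in milliseconds."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"T1 and T2 must be positive, got T1={self.t1}, T2={self.t2}")
        if self.t2 > self.t1:
            warnings.warn(
                f"T2={self.t2} ms exceeds T1={self.t1} ms; physically unusual",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PulseSequenceParams:
    """Readout and preparation parameters of one protocol.

    Defaults correspond to the multimapping protocol: 50 deg nominal flip
    angle, TR/TE 2.3/1.2 ms, ten linearly ramped startup pulses, 80
    acquired lines per shot (320 mm FOV / 2 mm resolution / SENSE 2,
    linear profile order), a fixed adiabatic inversion efficiency of 0.89,
    inversion pulses played 300 ms before the shot and T2prep echo times
    of 30/50/70 ms.  The clinical reference protocols differ only in the
    flip angle (35 deg) and their preparation scheme.
    """

    flip_angle_deg: float = 50.0
    tr_ms: float = 2.3
    te_ms: float = 1.2
    n_startup: int = 10
    n_readout_lines: int = 80
    profile_order: str = "linear"
    inversion_efficiency: float = 0.89
    inversion_delay_ms: float = 300.0
    t2prep_te_ms: tuple[float, ...] = (30.0, 50.0, 70.0)

    def __post_init__(self) -> None:
        if not 0 < self.flip_angle_deg <= 90:
            raise ValueError(f"flip_angle_deg must be in (0, 90], got {self.flip_angle_deg}")
        if not self.tr_ms > self.te_ms > 0:
            raise ValueError(f"need tr_ms > te_ms > 0, got tr={self.tr_ms}, te={self.te_ms}")
        if self.n_startup < 0:
            raise ValueError("n_startup must be >= 0")
        if not 0 < self.inversion_efficiency <= 1:
            raise ValueError(f"inversion_efficiency must be in (0, 1], got {self.inversion_efficiency}")
        if self.profile_order not in ("linear", "low-high"):
            raise ValueError(f"unknown profile_order {self.profile_order!r}")

    @classmethod
    def multimapping(cls, **overrides) -> "PulseSequenceParams":
        return cls(**overrides)

    @classmethod
    def reference(cls, **overrides) -> "PulseSequenceParams":
        """Clinical reference readout: identical but for the 35 deg flip angle."""
        overrides.setdefault("flip_angle_deg", 35.0)
        return cls(**overrides)

    @property
    def shot_duration_ms(self) -> float:
        return (self.n_startup + self.n_readout_lines) * self.tr_ms

    @property
    def center_line_index(self) -> int:
        """0-based index of the k-space-centre readout pulse within the shot."""
        if self.profile_order == "linear":
            line = self.n_readout_lines // 2  # line number, 1-based
        else:  # low-high: centre acquired first
            line = 1
        return self.n_startup + line - 1

    @property
    def echo_offset_ms(self) -> float:
        """Time of the k-space-centre echo relative to the start of the shot."""
        return self.center_line_index * self.tr_ms + self.tr_ms / 2.0

    def to_dict(self) -> dict:
        return {
            "flip_angle_deg": self.flip_angle_deg,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "n_startup": self.n_startup,
            "n_readout_lines": self.n_readout_lines,
            "profile_order": self.profile_order,
            "inversion_efficiency": self.inversion_efficiency,
            "inversion_delay_ms": self.inversion_delay_ms,
            "t2prep_te_ms": list(self.t2prep_te_ms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PulseSequenceParams":
        d = dict(d)
        d["t2prep_te_ms"] = tuple(d.get("t2prep_te_ms", (30.0, 50.0, 70.0)))
        return cls(**d)


@dataclass(frozen=True)
class PrepEvent:
    """Magnetization preparation preceding one cardiac cycle's shot.

    ``kind`` is one of ``"none"``, ``"inversion"`` or ``"t2prep"``.  For an
    inversion, ``delay_ms`` is the time from the pulse to the start of the
    shot (``None`` means the protocol default); for a T2prep, ``te_ms`` is
    the preparation echo time (0 is allowed and acts as identity).
    """

    kind: str = "none"
    te_ms: float | None = None
    delay_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "inversion", "t2prep"):
            raise ValueError(f"unknown prep kind {self.kind!r}")
        if self.kind == "t2prep" and (self.te_ms is None or self.te_ms < 0):
            raise ValueError("t2prep event requires te_ms >= 0")

    @property
    def label(self) -> str:
        if self.kind == "t2prep":
            return f"t2prep({self.te_ms:g})"
        return self.kind

    def to_dict(self) -> dict:
        return {"kind": self.kind, "te_ms": self.te_ms, "delay_ms": self.delay_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "PrepEvent":
        return cls(**d)


@dataclass(frozen=True)
class CardiacSchedule:
    """Per-beat R-R intervals, trigger delays, preparations and acquisition flags."""

    rr_intervals_ms: tuple[float, ...]
    trigger_delay_ms: tuple[float, ...]
    events: tuple[PrepEvent, ...]
    acquire: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.rr_intervals_ms)
        if n == 0:
            raise ValueError("schedule needs at least one beat")
        if any(rr <= 0 for rr in self.rr_intervals_ms):
            raise ValueError("all R-R intervals must be positive")
        if len(self.trigger_delay_ms) != n or len(self.events) != n:
            raise ValueError(
                f"per-beat field lengths differ: {n} beats, "
                f"{len(self.trigger_delay_ms)} trigger delays, {len(self.events)} events"
            )
        if any(td < 0 for td in self.trigger_delay_ms):
            raise ValueError("trigger delays must be >= 0")
        if not self.acquire:
            object.__setattr__(self, "acquire", tuple(True for _ in range(n)))
        elif len(self.acquire) != n:
            raise ValueError("acquire flags must match number of beats")

    @property
    def n_beats(self) -> int:
        return len(self.rr_intervals_ms)

    @property
    def n_acquired(self) -> int:
        return sum(self.acquire)

    def shot_start_times_ms(self) -> np.ndarray:
        """Start time of each beat's shot window relative to the first R-wave."""
        starts = np.concatenate([[0.0], np.cumsum(self.rr_intervals_ms)[:-1]])
        return starts + np.asarray(self.trigger_delay_ms)

    def fingerprint(self) -> str:
        """Hash of the scan-specific timing, used to key dictionary caches."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "rr_intervals_ms": list(self.rr_intervals_ms),
            "trigger_delay_ms": list(self.trigger_delay_ms),
            "events": [e.to_dict() for e in self.events],
            "acquire": list(self.acquire),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CardiacSchedule":
        return cls(
            rr_intervals_ms=tuple(d["rr_intervals_ms"]),
            trigger_delay_ms=tuple(d["trigger_delay_ms"]),
            events=tuple(PrepEvent.from_dict(e) for e in d["events"]),
            acquire=tuple(d.get("acquire", ())),
        )


@dataclass(frozen=True)
class AdiabaticPulseParams:
    """Hyperbolic-secant adiabatic inversion pulse.

    Defaults: 8.4 ms duration, 13.5 uT peak B1, classic HS1 shape with
    mu = 5 and beta = 672 rad/s.
    """

    duration_ms: float = 8.4
    peak_b1_ut: float = 13.5
    shape: str = "hyperbolic_secant"
    beta_rad_per_s: float = 672.0
    mu: float = 5.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if self.peak_b1_ut <= 0:
            raise ValueError("peak B1 must be positive")
        if self.shape != "hyperbolic_secant":
            raise ValueError(f"unsupported pulse shape {self.shape!r}")


@dataclass
class SimulatedSeries:
    """Ordered signed samples of one simulated acquisition."""

    samples: np.ndarray
    sample_times_ms: np.ndarray
    prep_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.sample_times_ms = np.asarray(self.sample_times_ms, dtype=float)
        if self.samples.shape != self.sample_times_ms.shape:
            raise ValueError("samples and sample_times_ms must have equal length")
        if len(self.samples) != len(self.prep_labels):
            raise ValueError("prep_labels must match number of samples")
        if np.any(np.diff(self.sample_times_ms) <= 0):
            raise ValueError("sample times must be strictly increasing")


# ---------------------------------------------------------------------------
# Elementary operators
# ---------------------------------------------------------------------------

def relax(state: MagnetizationState, duration_ms: float, tissue: TissueParams) -> MagnetizationState:
    """Free relaxation for ``duration_ms``: Mz recovers toward M0, Mxy decays."""
    if duration_ms < 0:
        raise ValueError(f"duration must be >= 0, got {duration_ms}")
    e1 = np.exp(-duration_ms / tissue.t1)
    e2 = np.exp(-duration_ms / tissue.t2)
    return MagnetizationState(
        mz=state.m0 + (state.mz - state.m0) * e1,
        mxy=state.mxy * e2,
        m0=state.m0,
    )


def apply_inversion(state: MagnetizationState, efficiency: float) -> MagnetizationState:
    """Adiabatic inversion: Mz -> -efficiency * Mz, transverse destroyed."""
    if not 0 < efficiency <= 1:
        raise ValueError(f"inversion efficiency must be in (0, 1], got {efficiency}")
    return MagnetizationState(mz=-efficiency * state.mz, mxy=0.0, m0=state.m0)


def apply_t2prep(state: MagnetizationState, te_ms: float, tissue: TissueParams) -> MagnetizationState:
    """Ideal T2 preparation: Mz -> Mz * exp(-TE/T2), transverse destroyed.

    The composite (hard 90x — adiabatic refocusing train — hard -90x) is
    modeled as instantaneous and ideal; the module occupies ``te_ms`` of
    sequence time during which no T1 recovery occurs.
    """
    if te_ms < 0:
        raise ValueError(f"T2prep TE must be >= 0, got {te_ms}")
    return MagnetizationState(
        mz=state.mz * np.exp(-te_ms / tissue.t2), mxy=0.0, m0=state.m0
    )


# ---------------------------------------------------------------------------
# bSSFP shot
# ---------------------------------------------------------------------------

def _shot_flip_angles(params: PulseSequenceParams, b1: float) -> np.ndarray:
    """Signed flip angles (radians) of the startup ramp + readout train.

    RF phase alternation (0/180 deg) is modeled as alternating rotation
    sense about a single axis; the alternation runs continuously through
    startup and readout pulses.
    """
    alpha = np.deg2rad(params.flip_angle_deg) * b1
    if params.n_startup > 0:
        ramp = alpha * np.arange(1, params.n_startup + 1) / params.n_startup
    else:
        ramp = np.empty(0)
    train = np.concatenate([ramp, np.full(params.n_readout_lines, alpha)])
    signs = np.where(np.arange(train.size) % 2 == 0, 1.0, -1.0)
    return train * signs


def _run_shot_arrays(
    mz: np.ndarray,
    e1h: np.ndarray,
    e2h: np.ndarray,
    angles: np.ndarray,
    echo_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate Mz arrays through one shot; return (echo magnitude, Mz after).

    State is (My, Mz); on resonance with RF about the x-axis Mx stays zero.
    Each TR: instantaneous rotation, relax TR/2 to the echo, relax TR/2 to
    the next pulse.  Residual transverse magnetization is discarded at shot
    end (no tip-back); Mz is carried forward.
    """
    my = np.zeros_like(mz)
    mz = mz.copy()
    echo = np.zeros_like(mz)
    for j, theta in enumerate(angles):
        c, s = np.cos(theta), np.sin(theta)
        my, mz = c * my + s * mz, -s * my + c * mz
        my *= e2h
        mz = 1.0 + (mz - 1.0) * e1h
        if j == echo_index:
            echo = np.abs(my)
        my *= e2h
        mz = 1.0 + (mz - 1.0) * e1h
    return echo, mz


def simulate_bssfp_shot(
    state: MagnetizationState,
    params: PulseSequenceParams,
    tissue: TissueParams,
    b1: float = 1.0,
) -> tuple[float, MagnetizationState]:
    """Simulate one single-shot bSSFP readout.

    Returns the signed sample (transverse magnitude at the k-space-centre
    echo, in units of M0, carrying the sign of Mz entering the shot) and
    the post-shot state.
    """
    if b1 <= 0:
        raise ValueError(f"b1 scaling must be positive, got {b1}")
    if params.n_readout_lines < 2:
        raise ValueError(f"need at least 2 readout lines, got {params.n_readout_lines}")
    sign = -1.0 if state.mz < 0 else 1.0
    angles = _shot_flip_angles(params, b1)
    e1h = np.exp(-params.tr_ms / 2.0 / tissue.t1)
    e2h = np.exp(-params.tr_ms / 2.0 / tissue.t2)
    mz_in = np.array([state.mz / state.m0])
    echo, mz_out = _run_shot_arrays(mz_in, np.array([e1h]), np.array([e2h]),
                                    angles, params.center_line_index)
    sample = float(sign * echo[0] * state.m0)
    new_state = MagnetizationState(mz=float(mz_out[0]) * state.m0, mxy=0.0, m0=state.m0)
    return sample, new_state


# ---------------------------------------------------------------------------
# Series engine
# ---------------------------------------------------------------------------

def _event_segments(
    params: PulseSequenceParams, schedule: CardiacSchedule
) -> list[tuple[float, PrepEvent | None, float, bool, float]]:
    """Flatten the schedule into per-beat (free_gap, event, post_gap, acquire, t_sample).

    ``free_gap`` is the free-relaxation time from the previous shot's end
    (or sequence start) to the preparation (or shot if no preparation);
    ``post_gap`` the free time between an inversion and the shot.  Gaps are
    clamped at zero when the nominal inversion delay does not fit in the
    available diastolic window (short R-R intervals).
    """
    starts = schedule.shot_start_times_ms()
    shot_dur = params.shot_duration_ms
    segments = []
    prev_end = 0.0
    first = True
    for b in range(schedule.n_beats):
        ev = schedule.events[b]
        t_shot = starts[b]
        t_sample = t_shot + params.echo_offset_ms
        if ev.kind == "inversion":
            delay = ev.delay_ms if ev.delay_ms is not None else params.inversion_delay_ms
            t_inv = t_shot - delay
            if not first and t_inv < prev_end:
                t_inv = prev_end  # clamp: inversion cannot precede previous readout
            gap = 0.0 if first else max(t_inv - prev_end, 0.0)
            segments.append((gap, ev, max(t_shot - t_inv, 0.0), schedule.acquire[b], t_sample))
        elif ev.kind == "t2prep":
            te = ev.te_ms or 0.0
            t_prep = t_shot - te
            gap = 0.0 if first else max(t_prep - prev_end, 0.0)
            segments.append((gap, ev, 0.0, schedule.acquire[b], t_sample))
        else:
            gap = 0.0 if first else max(t_shot - prev_end, 0.0)
            segments.append((gap, None, 0.0, schedule.acquire[b], t_sample))
        prev_end = t_shot + shot_dur
        first = False
    return segments


def simulate_series_bulk(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    b1: float,
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
) -> np.ndarray:
    """Simulate the acquisition for arrays of (T1, T2) at one B1 scaling.

    Vectorized over tissue-parameter grid points; returns an array of shape
    ``(n_points, n_acquired)`` of signed samples in units of M0.  This is
    the engine behind dictionary construction.
    """
    if b1 <= 0:
        raise ValueError(f"b1 scaling must be positive, got {b1}")
    if params.n_readout_lines < 2:
        raise ValueError("need at least 2 readout lines")
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("t1 and t2 arrays must have the same shape")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")

    angles = _shot_flip_angles(params, b1)
    echo_index = params.center_line_index
    e1h = np.exp(-params.tr_ms / 2.0 / t1)
    e2h = np.exp(-params.tr_ms / 2.0 / t2)

    mz = np.ones_like(t1)
    out = np.empty((t1.size, schedule.n_acquired), dtype=float)
    col = 0
    for gap, ev, post_gap, acquire, _ in _event_segments(params, schedule):
        if gap > 0:
            mz = 1.0 + (mz - 1.0) * np.exp(-gap / t1)
        if ev is not None and ev.kind == "inversion":
            mz = -params.inversion_efficiency * mz
            if post_gap > 0:
                mz = 1.0 + (mz - 1.0) * np.exp(-post_gap / t1)
        elif ev is not None and ev.kind == "t2prep":
            mz = mz * np.exp(-(ev.te_ms or 0.0) / t2)
        sign = np.where(mz < 0, -1.0, 1.0)
        echo, mz = _run_shot_arrays(mz, e1h, e2h, angles, echo_index)
        if acquire:
            out[:, col] = sign * echo
            col += 1
    return out


def simulate_series(
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
    tissue: TissueParams,
    b1: float = 1.0,
    m0: float = 1.0,
) -> SimulatedSeries:
    """Simulate one acquisition for a single tissue; samples scale with m0."""
    samples = simulate_series_bulk(
        np.array([tissue.t1]), np.array([tissue.t2]), b1, params, schedule
    )[0] * m0
    segs = _event_segments(params, schedule)
    times = [t for (_, _, _, acq, t) in segs if acq]
    labels = []
    for (_, ev, _, acq, _) in segs:
        if acq:
            labels.append(ev.label if ev is not None else "none")
    return SimulatedSeries(samples=samples, sample_times_ms=np.array(times), prep_labels=labels)


# ---------------------------------------------------------------------------
# Protocol schedule builders
# ---------------------------------------------------------------------------

def _trigger_delay_for(rr_ms: float, params: PulseSequenceParams, nominal: float = 500.0) -> float:
    """Mid-diastolic trigger delay, shortened when the R-R interval is short."""
    margin = 10.0
    return float(max(0.0, min(nominal, rr_ms - params.shot_duration_ms - margin)))


def multimapping_schedule(
    rr_ms: float | Sequence[float] = 1000.0,
    params: PulseSequenceParams | None = None,
    trigger_delay_ms: float | None = None,
) -> CardiacSchedule:
    """Ten-beat schedule: inversions in beats 1 and 5, T2preps in beats 8-10."""
    params = params or PulseSequenceParams.multimapping()
    rr = _expand_rr(rr_ms, 10)
    td = tuple(
        trigger_delay_ms if trigger_delay_ms is not None else _trigger_delay_for(r, params)
        for r in rr
    )
    tes = params.t2prep_te_ms
    if len(tes) != 3:
        raise ValueError(f"multimapping expects 3 T2prep echo times, got {len(tes)}")
    events = [PrepEvent("none")] * 10
    events[0] = PrepEvent("inversion")
    events[4] = PrepEvent("inversion")
    events[7] = PrepEvent("t2prep", te_ms=tes[0])
    events[8] = PrepEvent("t2prep", te_ms=tes[1])
    events[9] = PrepEvent("t2prep", te_ms=tes[2])
    return CardiacSchedule(rr_intervals_ms=rr, trigger_delay_ms=td, events=tuple(events))


def molli_schedule(
    rr_ms: float | Sequence[float] = 1000.0,
    ti1_ms: float = 120.0,
    ti2_ms: float = 200.0,
    pause_s: float = 3.0,
    params: PulseSequenceParams | None = None,
    trigger_delay_ms: float | None = None,
) -> CardiacSchedule:
    """MOLLI 5(3s)3: 5 images, a >=3 s recovery pause, then 3 images.

    ``ti1_ms``/``ti2_ms`` are the nominal inversion times of the first image
    of each Look-Locker block, measured to the k-space-centre echo.
    """
    params = params or PulseSequenceParams.reference()
    n_pause = max(1, int(np.ceil(pause_s * 1000.0 / np.mean(np.atleast_1d(rr_ms)))))
    n_beats = 5 + n_pause + 3
    rr = _expand_rr(rr_ms, n_beats)
    td = tuple(
        trigger_delay_ms if trigger_delay_ms is not None else _trigger_delay_for(r, params)
        for r in rr
    )
    events: list[PrepEvent] = [PrepEvent("none")] * n_beats
    acquire = [True] * 5 + [False] * n_pause + [True] * 3
    # inversion delay is specified to the echo; convert to shot start
    events[0] = PrepEvent("inversion", delay_ms=max(ti1_ms - params.echo_offset_ms, 0.0))
    events[5 + n_pause] = PrepEvent("inversion", delay_ms=max(ti2_ms - params.echo_offset_ms, 0.0))
    return CardiacSchedule(
        rr_intervals_ms=rr, trigger_delay_ms=td, events=tuple(events), acquire=tuple(acquire)
    )


def t2bssfp_schedule(
    rr_ms: float | Sequence[float] = 1000.0,
    te_list_ms: Sequence[float] = (0.0, 23.0, 46.0, 70.0),
    n_pause: int = 3,
    params: PulseSequenceParams | None = None,
    trigger_delay_ms: float | None = None,
) -> CardiacSchedule:
    """T2prep-bSSFP: four images at TE 0/23/46/70 ms, 3 pause beats between."""
    params = params or PulseSequenceParams.reference()
    n_img = len(te_list_ms)
    n_beats = n_img + n_pause * (n_img - 1)
    rr = _expand_rr(rr_ms, n_beats)
    td = tuple(
        trigger_delay_ms if trigger_delay_ms is not None else _trigger_delay_for(r, params)
        for r in rr
    )
    events: list[PrepEvent] = [PrepEvent("none")] * n_beats
    acquire = [False] * n_beats
    for i, te in enumerate(te_list_ms):
        b = i * (n_pause + 1)
        acquire[b] = True
        events[b] = PrepEvent("t2prep", te_ms=float(te))
    return CardiacSchedule(
        rr_intervals_ms=rr, trigger_delay_ms=td, events=tuple(events), acquire=tuple(acquire)
    )


def _expand_rr(rr_ms: float | Sequence[float], n: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(rr_ms, dtype=float))
    if arr.size == 1:
        return tuple(float(arr[0]) for _ in range(n))
    if arr.size != n:
        raise ValueError(f"expected {n} R-R intervals, got {arr.size}")
    return tuple(float(v) for v in arr)


# ---------------------------------------------------------------------------
# Protocol-level simulators
# ---------------------------------------------------------------------------

def _validate_multimapping_schedule(params: PulseSequenceParams, schedule: CardiacSchedule) -> None:
    if schedule.n_beats != 10 or schedule.n_acquired != 10:
        raise ValueError(f"multimapping schedule must have 10 acquired beats, got {schedule.n_beats}")
    kinds = [e.kind for e in schedule.events]
    expected = ["inversion", "none", "none", "none", "inversion", "none", "none",
                "t2prep", "t2prep", "t2prep"]
    if kinds != expected:
        raise ValueError(f"multimapping event pattern mismatch: {kinds}")
    tes = [schedule.events[i].te_ms for i in (7, 8, 9)]
    if list(params.t2prep_te_ms) != tes:
        raise ValueError(f"schedule T2prep TEs {tes} do not match params {params.t2prep_te_ms}")


def simulate_multimapping_series(
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
    tissue: TissueParams,
    b1: float = 1.0,
    m0: float = 1.0,
) -> SimulatedSeries:
    """Ten-sample fingerprint of the simultaneous T1/T2 mapping acquisition."""
    _validate_multimapping_schedule(params, schedule)
    return simulate_series(params, schedule, tissue, b1=b1, m0=m0)


def simulate_molli_series(
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
    tissue: TissueParams,
    b1: float = 1.0,
    m0: float = 1.0,
) -> tuple[SimulatedSeries, np.ndarray]:
    """MOLLI acquisition; returns the series and per-image effective TI (ms).

    The effective TI of each image is the time from the preceding inversion
    pulse to that image's k-space-centre echo.
    """
    series = simulate_series(params, schedule, tissue, b1=b1, m0=m0)
    starts = schedule.shot_start_times_ms()
    tis = []
    last_inv: float | None = None
    k = 0
    for b in range(schedule.n_beats):
        ev = schedule.events[b]
        if ev.kind == "inversion":
            delay = ev.delay_ms if ev.delay_ms is not None else params.inversion_delay_ms
            last_inv = starts[b] - delay
        if schedule.acquire[b]:
            if last_inv is None:
                raise ValueError("MOLLI image acquired before any inversion pulse")
            tis.append(starts[b] + params.echo_offset_ms - last_inv)
            k += 1
    return series, np.asarray(tis)


def simulate_t2bssfp_series(
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
    tissue: TissueParams,
    b1: float = 1.0,
    m0: float = 1.0,
) -> SimulatedSeries:
    """Four-image T2prep-bSSFP acquisition."""
    return simulate_series(params, schedule, tissue, b1=b1, m0=m0)


# ---------------------------------------------------------------------------
# Adiabatic pulse integration
# ---------------------------------------------------------------------------

def simulate_hs_inversion(
    pulse: AdiabaticPulseParams,
    tissue: TissueParams,
    dt_us: float = 10.0,
    mz_start: float = 1.0,
) -> float:
    """Inversion efficiency -Mz(end)/Mz(start) of a hyperbolic-secant pulse.

    Full three-component Bloch integration in the rotating frame with
    relaxation during the pulse, using symmetric operator splitting
    (hard rotation about the instantaneous effective field, then relax)
    with time step ``dt_us`` microseconds (must be <= 10).
    """
    if dt_us <= 0 or dt_us > 10.0:
        raise ValueError("time step must be in (0, 10] microseconds")
    if mz_start == 0:
        raise ValueError("mz_start must be nonzero")
    T = pulse.duration_ms * 1e-3
    dt = dt_us * 1e-6
    n = int(round(T / dt))
    beta = pulse.beta_rad_per_s
    t = (np.arange(n) + 0.5) * dt - T / 2.0
    w1 = GAMMA_RAD_PER_S_PER_T * pulse.peak_b1_ut * 1e-6 / np.cosh(beta * t)
    dw = -pulse.mu * beta * np.tanh(beta * t)

    t1_s, t2_s = tissue.t1 * 1e-3, tissue.t2 * 1e-3
    e1, e2 = np.exp(-dt / t1_s), np.exp(-dt / t2_s)
    m = np.array([0.0, 0.0, float(mz_start)])
    for k in range(n):
        wx, wz = w1[k], dw[k]
        omega = np.hypot(wx, wz)
        if omega > 0:
            ax, az = wx / omega, wz / omega
            ang = omega * dt
            c, s = np.cos(ang), np.sin(ang)
            dot = ax * m[0] + az * m[2]
            cross = np.array([-az * m[1], az * m[0] - ax * m[2], ax * m[1]])
            m = c * m + s * cross + (1.0 - c) * dot * np.array([ax, 0.0, az])
        m[0] *= e2
        m[1] *= e2
        m[2] = 1.0 + (m[2] - 1.0) * e1
    return float(-m[2] / mz_start)
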