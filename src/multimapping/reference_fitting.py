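"""Clinical reference map fitting: MOLLI T1 and T2prep-bSSFP T2.

MOLLI T1 is fitted on magnitude data with the standard three-parameter
model ``S(TI) = A - B exp(-TI/T1*)`` and a polarity-restoration search
(successively negating the k earliest-TI samples and keeping the
minimum-residual fit), followed by the Look-Locker correction
``T1 = T1* (B/A - 1)``.  T2 is fitted with a two-parameter monoexponential
``S(TE) = A exp(-TE/T2)`` (an optional three-parameter variant adds a
constant offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .maps import ParameterMap

__all__ = ["MolliFit", "T2Fit", "fit_molli", "fit_t2", "fit_molli_map", "fit_t2_map"]


@dataclass
class MolliFit:
    a: float
    b: float
    t1_star: float
    t1: float
    residual: float
    n_negated: int = 0
    converged: bool = True


@dataclass
class T2Fit:
    amplitude: float
    t2: float
    residual: float
    offset: float = 0.0
    converged: bool = True


def _fit_ir_three_param(signals: np.ndarray, tis: np.ndarray) -> tuple[float, float, float, float] | None:
    """Least-squares fit of S = A - B exp(-TI/T1*); returns (A, B, T1*, rms) or None."""
    a0 = float(np.max(np.abs(signals)))
    if a0 == 0:
        return None
    p0 = np.array([a0, 2.0 * a0, 800.0])

    def resid(p):
        a, b, t1s = p
        return a - b * np.exp(-tis / t1s) - signals

    try:
        sol = least_squares(
            resid,
            p0,
            bounds=([0.0, 0.0, 1.0], [np.inf, np.inf, 1e5]),
            max_nfev=400,
        )
    except Exception:
        return None
    if not sol.success and np.max(np.abs(sol.fun)) > 1e-6 * a0 and sol.cost > 1e-12:
        return None
    a, b, t1s = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return float(a), float(b), float(t1s), rms


def fit_molli(magnitude_signals: np.ndarray, tis_ms: np.ndarray) -> MolliFit:
    """Fit MOLLI magnitude samples with polarity search and Look-Locker correction.

    Samples are sorted by TI; for every split point k the k earliest
    samples are negated (restoring the unknown inversion-recovery
    polarity) and the three-parameter model is refitted; the
    minimum-residual solution wins.
    """
    s = np.asarray(magnitude_signals, dtype=float).ravel()
    tis = np.asarray(tis_ms, dtype=float).ravel()
    if s.size != tis.size:
        raise ValueError("signals and TIs must have equal length")
    if s.size < 4:
        raise ValueError(f"need at least 4 samples for the 3-parameter fit, got {s.size}")
    if np.any(s < 0):
        raise ValueError("magnitude signals must be non-negative")
    order = np.argsort(tis)
    s, tis = s[order], tis[order]

    if np.ptp(s) == 0:
        return MolliFit(a=0.0, b=0.0, t1_star=0.0, t1=0.0, residual=np.inf,
                        converged=False)

    best: tuple[float, int, tuple[float, float, float, float]] | None = None
    for k in range(s.size + 1):
        signed = s.copy()
        signed[:k] *= -1.0
        fit = _fit_ir_three_param(signed, tis)
        if fit is None:
            continue
        rms = fit[3]
        if best is None or rms < best[0]:
            best = (rms, k, fit)
    if best is None:
        return MolliFit(a=0.0, b=0.0, t1_star=0.0, t1=0.0, residual=np.inf, converged=False)
    rms, k, (a, b, t1s, _) = best
    if a <= 0 or b <= 0:
        return MolliFit(a=a, b=b, t1_star=t1s, t1=0.0, residual=rms, n_negated=k, converged=False)
    t1 = t1s * (b / a - 1.0)
    return MolliFit(a=a, b=b, t1_star=t1s, t1=float(t1), residual=rms, n_negated=k)


def fit_t2(
    signals: np.ndarray,
    tes_ms: np.ndarray = np.array([0.0, 23.0, 46.0, 70.0]),
    model: str = "2p",
) -> T2Fit:
    """Fit a monoexponential T2 decay ``S(TE) = A exp(-TE/T2)``.

    Non-positive samples are excluded; if fewer than two remain the pixel
    is flagged.  ``model="3p"`` adds a constant offset term.
    """
    s = np.asarray(signals, dtype=float).ravel()
    tes = np.asarray(tes_ms, dtype=float).ravel()
    if s.size != tes.size:
        raise ValueError("signals and TEs must have equal length")
    keep = s > 0
    s, tes = s[keep], tes[keep]
    if s.size < 2 or np.ptp(tes) == 0:
        return T2Fit(amplitude=0.0, t2=0.0, residual=np.inf, converged=False)

    # two-point closed form as initialization (and exact answer for n = 2)
    i0, i1 = np.argmin(tes), np.argmax(tes)
    ratio = s[i0] / s[i1]
    if ratio <= 1.0:
        t2_init = 200.0
    else:
        t2_init = float((tes[i1] - tes[i0]) / np.log(ratio))
    a_init = float(s[i0] * np.exp(tes[i0] / t2_init))

    if s.size == 2 and model == "2p":
        if ratio <= 1.0:
            return T2Fit(amplitude=0.0, t2=0.0, residual=np.inf, converged=False)
        return T2Fit(amplitude=a_init, t2=t2_init, residual=0.0)

    if model == "2p":
        p0 = np.array([a_init, t2_init])

        def resid(p):
            return p[0] * np.exp(-tes / p[1]) - s

        bounds = ([0.0, 0.1], [np.inf, 1e4])
    elif model == "3p":
        p0 = np.array([a_init, t2_init, 0.0])

        def resid(p):
            return p[0] * np.exp(-tes / p[1]) + p[2] - s

        bounds = ([0.0, 0.1, -np.inf], [np.inf, 1e4, np.inf])
    else:
        raise ValueError(f"unknown T2 model {model!r}")

    sol = least_squares(resid, p0, bounds=bounds, max_nfev=400)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    offset = float(sol.x[2]) if model == "3p" else 0.0
    return T2Fit(amplitude=float(sol.x[0]), t2=float(sol.x[1]), residual=rms, offset=offset)


def fit_molli_map(
    magnitude_frames: np.ndarray,
    tis_ms: np.ndarray,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Pixelwise MOLLI T1 map; non-convergent pixels are NaN."""
    frames = np.asarray(magnitude_frames, dtype=float)
    L, H, W = frames.shape
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out = np.full((H, W), np.nan)
    for r, c in zip(*np.nonzero(mask)):
        fit = fit_molli(frames[:, r, c], tis_ms)
        if fit.converged:
            out[r, c] = fit.t1
    return ParameterMap(out, units="ms", name="T1_MOLLI", meta={"method": "molli"})


def fit_t2_map(
    magnitude_frames: np.ndarray,
    tes_ms: np.ndarray,
    mask: np.ndarray | None = None,
    model: str = "2p",
) -> ParameterMap:
    """Pixelwise T2prep-bSSFP T2 map; flagged pixels are NaN."""
    frames = np.asarray(magnitude_frames, dtype=float)
    L, H, W = frames.shape
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out = np.full((H, W), np.nan)
    for r, c in zip(*np.nonzero(mask)):
        fit = fit_t2(frames[:, r, c], tes_ms, model=model)
        if fit.converged:
            out[r, c] = fit.t2
    return ParameterMap(out, units="ms", name="T2_bSSFP", meta={"method": "t2prep_bssfp"})
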