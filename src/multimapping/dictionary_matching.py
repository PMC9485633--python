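"""Dictionary construction and two-stage fingerprint matching.

Stage 1 matches a coarse (T1, T2, B1) dictionary inside a septal
myocardial ROI to estimate a single global RF-scaling (B1) factor; stage 2
rebuilds a fine (T1, T2) dictionary at that fixed B1 — 1 ms T1 resolution
— and matches every pixel.  Matching maximizes the normalized inner
product between the signed measured series and unit-norm simulated
fingerprints, which is equivalent to least squares under a free positive
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .maps import ParameterMap
from .sequence_model import CardiacSchedule, PulseSequenceParams, simulate_series_bulk

__all__ = [
    "DictionaryGrid",
    "Dictionary",
    "MatchResult",
    "coarse_default_grid",
    "fine_default_grid",
    "build_dictionary",
    "match_signals",
    "match_pixel_matrix",
    "estimate_global_b1",
    "match_fine",
]

_MATCH_CHUNK = 20000  # dictionary entries per matmul chunk (memory bound)


@dataclass(frozen=True)
class DictionaryGrid:
    """Strictly increasing T1/T2/B1 axes of a dictionary."""

    t1_values: tuple[float, ...]
    t2_values: tuple[float, ...]
    b1_values: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        for name, vals in (("t1", self.t1_values), ("t2", self.t2_values), ("b1", self.b1_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} axis must be non-empty")
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            if np.any(arr <= 0):
                raise ValueError(f"{name} axis values must be positive")

    @property
    def size(self) -> int:
        return len(self.t1_values) * len(self.t2_values) * len(self.b1_values)

    def t1_step(self) -> float:
        t1 = np.asarray(self.t1_values)
        return float(np.max(np.diff(t1))) if t1.size > 1 else 0.0


def coarse_default_grid() -> DictionaryGrid:
    """Stage-1 grid: T1 100-2000 ms step 20, T2 10-300 ms step 5, B1 0.5-1.2 step 0.05."""
    return DictionaryGrid(
        t1_values=tuple(np.arange(100.0, 2000.0 + 1, 20.0)),
        t2_values=tuple(np.arange(10.0, 300.0 + 1, 5.0)),
        b1_values=tuple(np.round(np.arange(0.5, 1.2 + 1e-9, 0.05), 10)),
    )


def fine_default_grid(
    t1_min: float = 50.0,
    t1_max: float = 2500.0,
    t2_min: float = 10.0,
    t2_max: float = 300.0,
) -> DictionaryGrid:
    """Stage-2 grid: 1 ms steps in both T1 and T2, B1 fixed externally."""
    return DictionaryGrid(
        t1_values=tuple(np.arange(t1_min, t1_max + 0.5, 1.0)),
        t2_values=tuple(np.arange(t2_min, t2_max + 0.5, 1.0)),
    )


@dataclass
class Dictionary:
    """Unit-normalized simulated fingerprints over a parameter grid.

    Entries are ordered by T1 ascending, then T2 ascending, then B1 by
    increasing distance from 1; first-occurrence argmax therefore realizes
    the tie-break (smaller T1, then smaller T2, then B1 nearest 1).
    """

    grid: DictionaryGrid
    entries: np.ndarray  # (n_entries, series_len), unit rows
    t1: np.ndarray  # (n_entries,)
    t2: np.ndarray
    b1: np.ndarray
    norms: np.ndarray  # pre-normalization Euclidean norms
    schedule_fingerprint: str
    meta: dict = field(default_factory=dict)

    @property
    def series_len(self) -> int:
        return self.entries.shape[1]


@dataclass
class MatchResult:
    """Best-matching grid point for one pixel series."""

    t1: float
    t2: float
    b1: float
    scale: float
    score: float
    flagged: bool = False


def _ordered_b1(b1_values: Sequence[float]) -> list[float]:
    return sorted(b1_values, key=lambda v: (abs(v - 1.0), v))


def build_dictionary(
    grid: DictionaryGrid,
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
) -> Dictionary:
    """Simulate and unit-normalize one fingerprint per grid point."""
    if grid.size == 0:
        raise ValueError("empty dictionary grid")
    n1, n2 = len(grid.t1_values), len(grid.t2_values)
    t1_mesh, t2_mesh = np.meshgrid(grid.t1_values, grid.t2_values, indexing="ij")
    t1_flat, t2_flat = t1_mesh.ravel(), t2_mesh.ravel()

    b1_order = _ordered_b1(grid.b1_values)
    L = schedule.n_acquired
    nb = len(b1_order)
    block = np.empty((n1 * n2, nb, L), dtype=float)
    for j, b1 in enumerate(b1_order):
        block[:, j, :] = simulate_series_bulk(t1_flat, t2_flat, b1, params, schedule)
    entries = block.reshape(n1 * n2 * nb, L)

    t1_col = np.repeat(t1_flat, nb)
    t2_col = np.repeat(t2_flat, nb)
    b1_col = np.tile(np.asarray(b1_order), n1 * n2)

    norms = np.linalg.norm(entries, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    entries = entries / safe[:, None]
    return Dictionary(
        grid=grid,
        entries=entries,
        t1=t1_col,
        t2=t2_col,
        b1=b1_col,
        norms=norms,
        schedule_fingerprint=schedule.fingerprint(),
        meta={"params": params.to_dict()},
    )


def match_pixel_matrix(
    signals: np.ndarray,
    dictionary: Dictionary,
    chunk: int = _MATCH_CHUNK,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-fingerprint search.

    Parameters
    ----------
    signals:
        ``(n_pixels, series_len)`` signed measured series (need not be
        normalized; matching is scale invariant).

    Returns
    -------
    indices, scores:
        Per-pixel argmax entry index and normalized inner product.
        All-zero pixels get index 0 and score 0.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != dictionary.series_len:
        raise ValueError(
            f"series length {signals.shape[1]} does not match dictionary {dictionary.series_len}"
        )
    norms = np.linalg.norm(signals, axis=1)
    unit = signals / np.where(norms > 0, norms, 1.0)[:, None]

    # de-duplicate identical rows (noiseless phantoms collapse to a handful)
    uniq, inverse = np.unique(unit, axis=0, return_inverse=True)
    n_uniq = uniq.shape[0]
    best_idx = np.zeros(n_uniq, dtype=np.int64)
    best_score = np.full(n_uniq, -np.inf)
    # block over pixels too, so the score buffer stays bounded
    pixel_block = max(1, min(n_uniq, int(4e7) // max(chunk, 1)))
    for p0 in range(0, n_uniq, pixel_block):
        p1 = min(p0 + pixel_block, n_uniq)
        block = uniq[p0:p1]
        rows = np.arange(p1 - p0)
        for start in range(0, dictionary.entries.shape[0], chunk):
            stop = min(start + chunk, dictionary.entries.shape[0])
            scores = block @ dictionary.entries[start:stop].T
            idx = np.argmax(scores, axis=1)
            val = scores[rows, idx]
            better = val > best_score[p0:p1]  # strict: keeps earliest chunk on ties
            sel = np.flatnonzero(better) + p0
            best_idx[sel] = idx[better] + start
            best_score[sel] = val[better]

    indices = best_idx[inverse]
    scores = best_score[inverse]
    zero = norms == 0
    indices = np.where(zero, 0, indices)
    scores = np.where(zero, 0.0, scores)
    return indices, scores


def match_signals(signed_pixel_series: np.ndarray, dictionary: Dictionary) -> MatchResult:
    """Match one pixel's signed series against the dictionary."""
    series = np.asarray(signed_pixel_series, dtype=float).ravel()
    if not np.any(series):
        return MatchResult(t1=np.nan, t2=np.nan, b1=np.nan, scale=0.0, score=0.0, flagged=True)
    idx, score = match_pixel_matrix(series[None, :], dictionary)
    i = int(idx[0])
    norm = dictionary.norms[i]
    scale = float(np.dot(series, dictionary.entries[i]) / norm) if norm > 0 else 0.0
    return MatchResult(
        t1=float(dictionary.t1[i]),
        t2=float(dictionary.t2[i]),
        b1=float(dictionary.b1[i]),
        scale=scale,
        score=float(score[0]),
    )


def estimate_global_b1(
    signed_frames: np.ndarray,
    septal_roi_mask: np.ndarray,
    coarse_dictionary: Dictionary,
) -> float:
    """Stage 1: median matched B1 over a septal myocardial ROI.

    ``signed_frames`` is ``(n_frames, H, W)``; the median over ROI pixels is
    snapped to the nearest grid B1 value (ties toward 1).
    """
    mask = np.asarray(septal_roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("septal ROI mask is empty")
    frames = np.asarray(signed_frames, dtype=float)
    pixels = frames.reshape(frames.shape[0], -1).T[mask.ravel()]
    indices, _ = match_pixel_matrix(pixels, coarse_dictionary)
    b1_matched = coarse_dictionary.b1[indices]
    med = float(np.median(b1_matched))
    b1_axis = np.asarray(coarse_dictionary.grid.b1_values)
    # snap to grid; break distance ties toward the value nearest 1
    d = np.abs(b1_axis - med)
    candidates = np.flatnonzero(d == d.min())
    best = candidates[np.argmin(np.abs(b1_axis[candidates] - 1.0))]
    return float(b1_axis[best])


def match_fine(
    signed_frames: np.ndarray,
    fixed_b1: float,
    fine_grid: DictionaryGrid,
    params: PulseSequenceParams,
    schedule: CardiacSchedule,
    mask: np.ndarray | None = None,
    allow_coarse: bool = False,
    dictionary: Dictionary | None = None,
) -> tuple[ParameterMap, ParameterMap]:
    """Stage 2: pixelwise (T1, T2) maps at a fixed global B1.

    The fine grid must have a single (placeholder) B1 axis and 1 ms T1
    steps unless ``allow_coarse`` is set.  A prebuilt ``dictionary`` for
    ``(fine_grid, fixed_b1, schedule)`` may be supplied to amortize the
    simulation cost across calls.
    """
    if fixed_b1 <= 0:
        raise ValueError(f"b1 must be positive, got {fixed_b1}")
    if len(fine_grid.b1_values) != 1:
        raise ValueError("fine grid must not have a B1 axis (B1 is fixed by stage 1)")
    if fine_grid.t1_step() > 1.0 + 1e-9 and not allow_coarse:
        raise ValueError(
            f"fine T1 step {fine_grid.t1_step():g} ms exceeds 1 ms; pass allow_coarse=True to override"
        )
    frames = np.asarray(signed_frames, dtype=float)
    H, W = frames.shape[1:]
    if dictionary is None:
        grid_at_b1 = DictionaryGrid(
            t1_values=fine_grid.t1_values,
            t2_values=fine_grid.t2_values,
            b1_values=(float(fixed_b1),),
        )
        dictionary = build_dictionary(grid_at_b1, params, schedule)

    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pixels = frames.reshape(frames.shape[0], -1).T[mask.ravel()]
    indices, scores = match_pixel_matrix(pixels, dictionary)

    t1_map = np.full((H, W), np.nan, dtype=float)
    t2_map = np.full((H, W), np.nan, dtype=float)
    t1_vals = dictionary.t1[indices]
    t2_vals = dictionary.t2[indices]
    zero = ~np.any(pixels, axis=1)
    t1_vals = np.where(zero, np.nan, t1_vals)
    t2_vals = np.where(zero, np.nan, t2_vals)
    t1_map[mask] = t1_vals
    t2_map[mask] = t2_vals
    meta = {
        "b1": fixed_b1,
        "schedule_fingerprint": schedule.fingerprint(),
        "method": "dictionary",
    }
    return (
        ParameterMap(t1_map, units="ms", name="T1", meta=dict(meta)),
        ParameterMap(t2_map, units="ms", name="T2", meta=dict(meta)),
    )
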