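"""Readers, writers and the end-to-end mapping pipeline.

A *study bundle* is a directory holding one acquisition: NIfTI frame
volumes (complex data as paired real/imaginary volumes, or a magnitude
volume for reference scans), a JSON sidecar with the protocol tag,
sequence parameters and the per-beat cardiac schedule, and optional named
ROI masks.  ``run_pipeline`` chains PSIR, stage-1 global-B1 estimation
and stage-2 fine matching into final T1/T2 maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .dictionary_matching import (
    Dictionary,
    DictionaryGrid,
    build_dictionary,
    coarse_default_grid,
    estimate_global_b1,
    fine_default_grid,
    match_fine,
)
from .maps import ParameterMap
from .psir import ComplexImageSeries, SignedImageSeries, restore_polarity
from .sequence_model import CardiacSchedule, PulseSequenceParams

__all__ = [
    "StudyBundle",
    "read_bundle",
    "write_bundle",
    "write_parameter_map",
    "read_parameter_map",
    "run_pipeline",
]

_SIDECAR = "bundle.json"


@dataclass
class StudyBundle:
    """One acquisition plus its metadata, as stored on disk."""

    series: ComplexImageSeries | np.ndarray
    schedule: CardiacSchedule
    params: PulseSequenceParams
    protocol: str
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_frames = (
            self.series.n_frames
            if isinstance(self.series, ComplexImageSeries)
            else np.asarray(self.series).shape[0]
        )
        if self.schedule.n_acquired != n_frames:
            raise ValueError(
                f"schedule has {self.schedule.n_acquired} acquired beats but the "
                f"series has {n_frames} frames"
            )
        shape = (
            self.series.frames.shape[1:]
            if isinstance(self.series, ComplexImageSeries)
            else np.asarray(self.series).shape[1:]
        )
        for name, mask in self.masks.items():
            if np.asarray(mask).shape != shape:
                raise ValueError(f"mask {name!r} shape {np.asarray(mask).shape} != image shape {shape}")

    @property
    def is_complex(self) -> bool:
        return isinstance(self.series, ComplexImageSeries)


def _save_nii(path: Path, data: np.ndarray) -> None:
    # frames stored as (H, W, n) volumes, row-major pixel indexing
    arr = np.moveaxis(np.asarray(data, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float32)
    return np.moveaxis(vol, -1, 0).astype(float)


def write_bundle(path: str | Path, bundle: StudyBundle) -> Path:
    """Write a study bundle directory (NIfTI frames + JSON sidecar + masks)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if bundle.is_complex:
        _save_nii(path / "frames_real.nii.gz", bundle.series.frames.real)
        _save_nii(path / "frames_imag.nii.gz", bundle.series.frames.imag)
        data_kind = "complex"
    else:
        _save_nii(path / "frames_mag.nii.gz", np.asarray(bundle.series))
        data_kind = "magnitude"
    for name, mask in bundle.masks.items():
        _save_nii(path / f"mask_{name}.nii.gz", np.asarray(mask, dtype=np.float32)[None])
    sidecar = {
        "format_version": 1,
        "protocol": bundle.protocol,
        "data_kind": data_kind,
        "schedule": bundle.schedule.to_dict(),
        "params": bundle.params.to_dict(),
        "masks": sorted(bundle.masks),
        "provenance": {**bundle.provenance, "tool_version": __version__},
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=2))
    return path


def read_bundle(path: str | Path) -> StudyBundle:
    """Read and validate a study bundle directory."""
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    schedule = CardiacSchedule.from_dict(sidecar["schedule"])
    params = PulseSequenceParams.from_dict(sidecar["params"])
    if sidecar["data_kind"] == "complex":
        real = _load_nii(path / "frames_real.nii.gz")
        imag = _load_nii(path / "frames_imag.nii.gz")
        series: ComplexImageSeries | np.ndarray = ComplexImageSeries(real + 1j * imag)
    else:
        series = _load_nii(path / "frames_mag.nii.gz")
    masks = {
        name: _load_nii(path / f"mask_{name}.nii.gz")[0] > 0.5
        for name in sidecar.get("masks", [])
    }
    return StudyBundle(
        series=series,
        schedule=schedule,
        params=params,
        protocol=sidecar["protocol"],
        masks=masks,
        provenance=sidecar.get("provenance", {}),
    )


def write_parameter_map(path: str | Path, pmap: ParameterMap) -> Path:
    """Write a map as 32-bit float NIfTI plus a JSON sidecar with units/meta."""
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.data.astype(np.float32), affine=np.eye(4)), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    meta = {"units": pmap.units, "name": pmap.name, "meta": _jsonable(pmap.meta)}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float32)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ParameterMap(
        data, units=meta.get("units", ""), name=meta.get("name", ""), meta=meta.get("meta", {})
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _config_hash(config: dict) -> str:
    return hashlib.sha1(json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(
    bundle: StudyBundle,
    coarse_grid: DictionaryGrid | None = None,
    fine_grid: DictionaryGrid | None = None,
    septal_roi_name: str = "septum",
    mask_name: str | None = None,
    reference_index: int = -1,
    fine_dictionary: Dictionary | None = None,
    assume_signed: bool = False,
) -> dict:
    """PSIR -> stage-1 global B1 -> stage-2 T1/T2 maps for one bundle.

    Returns a dict with the signed series, estimated B1, the maps and a
    report of every parameter used.  Deterministic given its inputs.
    """
    if bundle.protocol != "multimapping":
        raise ValueError(f"pipeline expects a multimapping bundle, got {bundle.protocol!r}")
    if septal_roi_name not in bundle.masks:
        raise ValueError(
            f"bundle has no {septal_roi_name!r} mask; supply one (CLI: --septal-roi mask.nii.gz)"
        )
    if bundle.is_complex:
        signed = restore_polarity(bundle.series, reference_index=reference_index)
    elif assume_signed:
        signed = SignedImageSeries(np.asarray(bundle.series, dtype=float))
    else:
        raise ValueError(
            "magnitude-only data cannot be polarity-restored; provide complex "
            "(real/imaginary) data or pass assume_signed=True"
        )

    coarse_grid = coarse_grid or coarse_default_grid()
    fine_grid = fine_grid or fine_default_grid()
    coarse_dict = build_dictionary(coarse_grid, bundle.params, bundle.schedule)
    b1 = estimate_global_b1(signed.frames, bundle.masks[septal_roi_name], coarse_dict)
    mask = bundle.masks.get(mask_name) if mask_name else None
    t1_map, t2_map = match_fine(
        signed.frames,
        b1,
        fine_grid,
        bundle.params,
        bundle.schedule,
        mask=mask,
        dictionary=fine_dictionary,
    )
    config = {
        "coarse_grid": {
            "t1": [coarse_grid.t1_values[0], coarse_grid.t1_values[-1], len(coarse_grid.t1_values)],
            "t2": [coarse_grid.t2_values[0], coarse_grid.t2_values[-1], len(coarse_grid.t2_values)],
            "b1": list(coarse_grid.b1_values),
        },
        "fine_grid": {
            "t1": [fine_grid.t1_values[0], fine_grid.t1_values[-1], len(fine_grid.t1_values)],
            "t2": [fine_grid.t2_values[0], fine_grid.t2_values[-1], len(fine_grid.t2_values)],
        },
        "reference_index": reference_index,
        "schedule_fingerprint": bundle.schedule.fingerprint(),
    }
    chash = _config_hash(config)
    for m in (t1_map, t2_map):
        m.meta["config_hash"] = chash
        m.meta["tool_version"] = __version__
    return {
        "signed_series": signed,
        "b1": b1,
        "t1_map": t1_map,
        "t2_map": t2_map,
        "config": config,
        "config_hash": chash,
    }
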