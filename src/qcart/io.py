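"""File I/O: image series, protocol files, label masks, reports.

Series are NIfTI (frames along the last axis) or multi-page TIFF; protocols
are JSON ({"name", "model", "times_ms"} or {"pulse_counts",
"pulse_duration_ms"}, plus free-form "metadata"); masks are integer label
images (0=background, 1=articular, 2=viable, 3=necrotic by default).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import nibabel as nib
import numpy as np
import tifffile

from .protocols import AcquisitionProtocol, build_time_axis
from .relaxometry import ImageSeries, ParameterMap

__all__ = [
    "read_protocol",
    "write_protocol",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "write_map",
    "write_report",
]

#: Default semantics of mask labels (overridable via a sidecar).
DEFAULT_LABELS = {"background": 0, "articular": 1, "viable": 2, "necrotic": 3}


class DataError(ValueError):
    """Raised when an input file is readable but inconsistent."""


def write_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    doc: dict[str, Any] = {"name": protocol.name, "model": protocol.model}
    if protocol.times_ms is not None:
        doc["times_ms"] = list(map(float, protocol.times_ms))
    if protocol.pulse_counts is not None:
        doc["pulse_counts"] = list(map(int, protocol.pulse_counts))
        doc["pulse_duration_ms"] = float(protocol.pulse_duration_ms)
    if protocol.metadata:
        doc["metadata"] = protocol.metadata
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_protocol(path: str | Path) -> AcquisitionProtocol:
    doc = json.loads(Path(path).read_text())
    unknown = set(doc) - {"name", "model", "times_ms", "pulse_counts", "pulse_duration_ms", "metadata"}
    if unknown:
        raise DataError(f"{path}: unknown protocol keys {sorted(unknown)}")
    try:
        return AcquisitionProtocol(
            name=doc["name"],
            model=doc["model"],
            times_ms=doc.get("times_ms"),
            pulse_counts=doc.get("pulse_counts"),
            pulse_duration_ms=doc.get("pulse_duration_ms"),
            metadata=doc.get("metadata", {}),
        )
    except KeyError as exc:
        raise DataError(f"{path}: missing protocol key {exc}") from exc


def _read_frames(path: Path) -> np.ndarray:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        if data.ndim != 3:
            raise DataError(f"{path}: expected a rank-3 NIfTI volume, got shape {data.shape}")
        return np.moveaxis(data, -1, 0)  # frames stored along the last axis
    if name.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path)).astype(float)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise DataError(f"{path}: expected a multi-page TIFF stack, got shape {data.shape}")
        return data
    raise DataError(f"{path}: unsupported series format (use .nii/.nii.gz/.tif/.tiff)")


def read_series(path: str | Path, protocol_path: str | Path) -> ImageSeries:
    """Load a frame stack and its protocol; frame count must match the axis."""
    protocol = read_protocol(protocol_path)
    frames = _read_frames(Path(path))
    times = build_time_axis(protocol)
    if frames.shape[0] != times.size:
        raise DataError(
            f"{path}: {frames.shape[0]} frames but protocol {protocol.name} "
            f"has {times.size} time points"
        )
    if np.any(frames < 0):
        raise DataError(f"{path}: negative intensities in a magnitude series")
    return ImageSeries(frames=frames, times_ms=times, protocol=protocol)


def write_series(series: ImageSeries, path: str | Path) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        data = np.moveaxis(series.frames, 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), series.frames.astype(np.float32), photometric="minisblack")
    else:
        raise DataError(f"{path}: unsupported series format")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj)
    elif name.endswith((".tif", ".tiff", ".png")):
        import imageio.v3 as iio

        data = iio.imread(str(path)) if name.endswith(".png") else tifffile.imread(str(path))
    else:
        raise DataError(f"{path}: unsupported mask format")
    data = np.squeeze(data)
    if data.ndim != 2:
        raise DataError(f"{path}: mask must be a single 2-D label image")
    return data.astype(np.int32)


def write_mask(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int16))


def write_map(pmap: ParameterMap, path: str | Path) -> None:
    """Float32 relaxation-time map; invalid pixels are NaN."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(pmap.tmap.astype(np.float32), affine=np.eye(4)), str(path))
    elif name.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), pmap.tmap.astype(np.float32))
    else:
        raise DataError(f"{path}: unsupported map format")


def _fmt(x: float) -> float:
    return float(np.round(x, 6))


def write_report(
    relaxation_table,
    difference_table,
    od_table,
    regressions: Mapping[str, Any],
    outdir: str | Path,
    config: Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write the cohort tables as CSV plus a JSON regression report.

    Emits ``relaxation_stats.csv`` (long format), ``relaxation_differences.csv``
    (week x parameter percent differences), ``od_stats.csv`` and
    ``regressions.json``; a ``run_config.json`` records the configuration and
    seed so a rerun is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["relaxation_stats"] = outdir / "relaxation_stats.csv"
    relaxation_table.to_csv(paths["relaxation_stats"], index=False, float_format="%.6g")
    paths["relaxation_differences"] = outdir / "relaxation_differences.csv"
    difference_table.to_csv(paths["relaxation_differences"], float_format="%.6g")
    paths["od_stats"] = outdir / "od_stats.csv"
    od_table.to_csv(paths["od_stats"], float_format="%.6g")

    def reg_doc(r):
        if hasattr(r, "slope"):
            return {"slope": _fmt(r.slope), "intercept": _fmt(r.intercept),
                    "r_squared": _fmt(r.r_squared), "n_points": r.n_points}
        return r

    paths["regressions"] = outdir / "regressions.json"
    doc = {k: reg_doc(v) for k, v in regressions.items()}
    paths["regressions"].write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    if config is not None:
        paths["run_config"] = outdir / "run_config.json"
        paths["run_config"].write_text(json.dumps(dict(config), indent=2, sort_keys=True, default=str) + "\n")
    return paths
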