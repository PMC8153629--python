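"""File interfaces: NIfTI-1 volumes with JSON sidecars, CSV tables.

Dynamic series are stored (H, W, 1, T) and multi-echo volumes
(H, W, S, E), both with a sidecar JSON carrying timestamps (min), echo
times (ms), protocol/agent parameters and the generator seed. Spectra and
hemolysis curves are plain CSV with header rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .esr import ESRSpectrum
from .krl import HemolysisCurve
from .motion import SignalTimeCourse
from .phantom import AcquisitionProtocol, ContrastAgentSpec, DynamicSeries
from .relaxometry import MultiEchoVolume

__all__ = [
    "save_dynamic_series",
    "load_dynamic_series",
    "save_multiecho_volume",
    "load_multiecho_volume",
    "save_mask",
    "load_mask",
    "save_timecourse",
    "load_timecourse",
    "save_spectrum",
    "load_spectrum",
    "save_hemolysis",
    "load_hemolysis",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_dynamic_series(series: DynamicSeries, path: str | Path) -> Path:
    path = Path(path)
    data = np.transpose(series.frames, (1, 2, 0))[:, :, None, :]
    vox = series.phantom.voxel_size_mm if series.phantom is not None else 1.0
    affine = np.diag([vox, vox, series.protocol.slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)
    sidecar = {
        "timestamps_min": series.timestamps_min.tolist(),
        "protocol": dataclasses.asdict(series.protocol),
        "agent": dataclasses.asdict(series.agent),
        "meta": series.meta,
    }
    if series.truth is not None:
        sidecar["truth"] = {
            "cmax_mM": series.truth.accumulation.cmax_mM,
            "tau_per_min": series.truth.accumulation.tau_per_min,
            "half_life_min": series.truth.accumulation.half_life_min,
            "noise_sigma": series.truth.noise_sigma,
            "motion_amplitude_vox": series.truth.motion_amplitude_vox,
        }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_dynamic_series(path: str | Path) -> DynamicSeries:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    sidecar = json.loads(_sidecar_path(path).read_text())
    return DynamicSeries(
        frames=frames,
        timestamps_min=np.asarray(sidecar["timestamps_min"], dtype=float),
        protocol=AcquisitionProtocol(**sidecar["protocol"]),
        agent=ContrastAgentSpec(**sidecar["agent"]),
        meta=sidecar.get("meta", {}),
    )


def save_multiecho_volume(volume: MultiEchoVolume, path: str | Path) -> Path:
    path = Path(path)
    data = np.transpose(volume.data, (2, 3, 1, 0))  # (H, W, S, E)
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), path)
    sidecar = {
        "echo_times_ms": volume.echo_times_ms.tolist(),
        "protocol": dataclasses.asdict(volume.protocol) if volume.protocol else None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_multiecho_volume(path: str | Path) -> MultiEchoVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 2, 0, 1))
    sidecar = json.loads(_sidecar_path(path).read_text())
    protocol = (
        AcquisitionProtocol(**sidecar["protocol"]) if sidecar.get("protocol") else None
    )
    return MultiEchoVolume(
        data=data,
        echo_times_ms=np.asarray(sidecar["echo_times_ms"], dtype=float),
        protocol=protocol,
    )


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    nib.save(nib.Nifti1Image(arr.astype(np.uint8), np.eye(4)), path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(Path(path)).dataobj)
    return np.squeeze(arr).astype(bool)


def save_timecourse(course: SignalTimeCourse, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "t_min": course.timestamps_min,
            "mean": course.mean,
            "sd": course.sd,
            "n_voxels": course.n_voxels,
        }
    ).to_csv(path, index=False)
    return path


def load_timecourse(path: str | Path) -> SignalTimeCourse:
    df = pd.read_csv(path)
    return SignalTimeCourse(
        timestamps_min=df["t_min"].to_numpy(float),
        mean=df["mean"].to_numpy(float),
        sd=df["sd"].to_numpy(float),
        n_voxels=df["n_voxels"].to_numpy(int),
    )


def save_spectrum(spectrum: ESRSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"field_mT": spectrum.field_mT, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )
    _sidecar_path(path).write_text(
        json.dumps({"freq_GHz": spectrum.freq_GHz, "mass_g": spectrum.mass_g}, indent=2)
    )
    return path


def load_spectrum(path: str | Path) -> ESRSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ESRSpectrum(
        field_mT=df["field_mT"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        freq_GHz=meta.get("freq_GHz", 9.54),
        mass_g=meta.get("mass_g"),
    )


def save_hemolysis(curve: HemolysisCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": curve.time_min, "hemolysis_pct": curve.hemolysis_pct}).to_csv(
        path, index=False
    )
    return path


def load_hemolysis(path: str | Path, label: str = "") -> HemolysisCurve:
    df = pd.read_csv(path)
    return HemolysisCurve(
        time_min=df["time_min"].to_numpy(float),
        hemolysis_pct=df["hemolysis_pct"].to_numpy(float),
        label=label or Path(path).stem,
    )
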