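"""Persistence: NIfTI image series, HDF5 k-space bundles, CSV tables, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .recon import ImageSeries
from .sequence import KSpaceShot, Protocol, full_phase_schedule

__all__ = [
    "save_series_nifti",
    "load_series_nifti",
    "save_masks_nifti",
    "load_masks_nifti",
    "save_shots_h5",
    "load_shots_h5",
    "save_motion_csv",
    "sha256_of",
    "write_manifest",
]


def _affine(pixel_mm, slice_mm: float = 10.0) -> np.ndarray:
    return np.diag([pixel_mm[0], pixel_mm[1], slice_mm, 1.0])


def save_series_nifti(series: ImageSeries, path, slice_mm: float = 10.0) -> Path:
    """Write a (slice, dynamic, nx, ny) series as a 4D NIfTI (x, y, slice, dynamic)."""
    data = np.transpose(series.data, (2, 3, 0, 1)).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(series.pixel_mm, slice_mm))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_series_nifti(path, pixel_mm=(1.9, 1.9)) -> ImageSeries:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return ImageSeries(data=np.transpose(data, (2, 3, 0, 1)).astype(float),
                       pixel_mm=pixel_mm)


def save_masks_nifti(masks: np.ndarray, path, pixel_mm=(1.9, 1.9),
                     slice_mm: float = 10.0) -> Path:
    data = np.transpose(masks.astype(np.uint8), (2, 3, 0, 1))
    img = nib.Nifti1Image(data, _affine(pixel_mm, slice_mm))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_masks_nifti(path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return np.transpose(data, (2, 3, 0, 1)).astype(bool)


def save_shots_h5(shots: list[KSpaceShot], protocol: Protocol, path) -> Path:
    """K-space series bundle: complex arrays + masks + JSON-encoded protocol."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = json.dumps(
            {k: v for k, v in protocol.__dict__.items() if not k.startswith("_")},
            default=lambda o: list(o) if isinstance(o, tuple) else o)
        f.attrs["n_shots"] = len(shots)
        for i, s in enumerate(shots):
            g = f.create_group(f"shot{i:05d}")
            g.create_dataset("kspace", data=s.kspace, compression="gzip")
            g.create_dataset("mask", data=s.mask)
            g.attrs["dynamic"] = s.dynamic
            g.attrs["pair"] = list(s.pair)
            g.attrs["time_s"] = s.time_s
            g.attrs["applied_offset_mm"] = s.applied_offset_mm
    return path


def load_shots_h5(path) -> tuple[list[KSpaceShot], Protocol]:
    with h5py.File(path, "r") as f:
        pdict = json.loads(f.attrs["protocol"])
        for key in ("fov_mm", "slice_pairing"):
            if pdict.get(key) is not None:
                pdict[key] = tuple(tuple(x) if isinstance(x, list) else x
                                   for x in pdict[key]) if key == "slice_pairing" \
                    else tuple(pdict[key])
        protocol = Protocol(**pdict)
        shots = []
        for i in range(int(f.attrs["n_shots"])):
            g = f[f"shot{i:05d}"]
            ksp = g["kspace"][()]
            shots.append(KSpaceShot(
                dynamic=int(g.attrs["dynamic"]),
                pair=tuple(int(x) for x in g.attrs["pair"]),
                kspace=ksp,
                mask=g["mask"][()].astype(bool),
                time_s=float(g.attrs["time_s"]),
                applied_offset_mm=float(g.attrs["applied_offset_mm"]),
                phase_schedule=full_phase_schedule(ksp.shape[-1]),
            ))
    return shots, protocol


def save_motion_csv(trace, path) -> Path:
    import pandas as pd

    df = pd.DataFrame(dict(
        time_s=trace.times_s,
        diaphragm_mm=trace.displacement_mm,
        heart_mm=trace.config.heart_scale * trace.displacement_mm,
    ))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, out_dir) -> Path:
    out = Path(out_dir) / "manifest.json"
    with open(out, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return out
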