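"""NIfTI volume I/O, YAML configuration and JSON provenance sidecars.

Volumes are NIfTI-1 in an RAS+ grid whose affine is diagonal in the voxel
spacing.  Complex echo series are stored as a real/imaginary pair of 4-D
volumes plus a JSON sidecar holding the echo times.  Every stage writes a
provenance sidecar (parameters, seed, package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import EchoSeries, PhantomSpec, PhantomTruth, TissueParams

__all__ = [
    "write_volume", "read_volume", "write_mask", "read_mask",
    "write_echo_series", "read_echo_series",
    "write_truth", "load_spec", "dump_spec", "write_sidecar",
]


def _affine(voxel_spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_spacing_mm
    return aff


def write_volume(path, data: np.ndarray, voxel_spacing_mm,
                 dtype=np.float32) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype),
                          _affine(voxel_spacing_mm))
    nib.save(img, path)
    return path


def read_volume(path, expect_spacing=None):
    """Returns ``(data, voxel_spacing_mm)``; optionally checks the grid."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if expect_spacing is not None and not np.allclose(spacing, expect_spacing):
        raise ValueError(f"{path}: voxel spacing {spacing} does not match "
                         f"expected {tuple(expect_spacing)}")
    return np.asarray(img.dataobj), spacing


def write_mask(path, mask: np.ndarray, voxel_spacing_mm) -> Path:
    return write_volume(path, np.asarray(mask, dtype=bool), voxel_spacing_mm,
                        dtype=np.uint8)


def read_mask(path):
    data, spacing = read_volume(path)
    vals = np.unique(data)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"{path}: mask values must be 0/1, found {vals}")
    return data.astype(bool), spacing


def write_echo_series(stem, series: EchoSeries) -> dict[str, Path]:
    """Real/imaginary NIfTI pair plus an echo-time JSON sidecar."""
    stem = Path(stem)
    paths = {
        "real": write_volume(stem.with_name(stem.name + "_real.nii.gz"),
                             series.signal.real, series.voxel_spacing_mm),
        "imag": write_volume(stem.with_name(stem.name + "_imag.nii.gz"),
                             series.signal.imag, series.voxel_spacing_mm),
    }
    sidecar = stem.with_name(stem.name + "_echoes.json")
    sidecar.write_text(json.dumps(
        {"echo_times_ms": series.echo_times_ms.tolist(),
         "voxel_spacing_mm": list(series.voxel_spacing_mm)}, indent=2))
    paths["echoes"] = sidecar
    return paths


def read_echo_series(stem) -> EchoSeries:
    stem = Path(stem)
    re, spacing = read_volume(stem.with_name(stem.name + "_real.nii.gz"))
    im, spacing_i = read_volume(stem.with_name(stem.name + "_imag.nii.gz"))
    if re.shape != im.shape or not np.allclose(spacing, spacing_i):
        raise ValueError("real/imaginary volumes disagree in grid")
    meta = json.loads(stem.with_name(stem.name + "_echoes.json").read_text())
    return EchoSeries(re.astype(np.float64) + 1j * im.astype(np.float64),
                      np.asarray(meta["echo_times_ms"], dtype=float),
                      tuple(meta["voxel_spacing_mm"]))


def write_truth(outdir, truth: PhantomTruth) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = truth.voxel_spacing_mm
    paths = {"labels": write_volume(outdir / "labels.nii.gz", truth.labels,
                                    sp, dtype=np.int16)}
    for name in ("fat_fraction", "ndb", "nmidb", "field_hz", "r2star"):
        paths[name] = write_volume(outdir / f"{name}.nii.gz",
                                   getattr(truth, name), sp)
    return paths


def dump_spec(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(spec)
    d["tissue_composition"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                               else dict(v)
                               for k, v in spec.tissue_composition.items()}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_spec(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    if "tissue_composition" in d:
        d["tissue_composition"] = {k: TissueParams(**v)
                                   for k, v in d["tissue_composition"].items()}
    for key in ("grid_shape", "voxel_spacing_mm", "breast_semiaxes_mm",
                "tumour_centre_mm", "field_map_coeffs_hz"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def write_sidecar(path, **entries) -> Path:
    """JSON provenance sidecar (parameters, seeds, versions)."""
    from . import __version__
    path = Path(path)
    payload = {"perilipid_version": __version__, **entries}
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
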