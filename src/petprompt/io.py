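"""On-disk formats: raw float32 sinograms/images with text sidecar headers,
CSV exports, and serializable run configuration.

A sinogram ``name.f32`` is flat little-endian float32, row-major
``[angle, radial]``, with a ``name.hdr`` sidecar of ``key = value`` lines
(nrad, nang, bin_mm, window_kev, duration_s, seed, isotopes, plus free-form
provenance).  Images use the same scheme with nx/ny/voxel_mm, and can
optionally be written as NIfTI when nibabel is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquisition import Sinogram
from .reconstruction import ImageVolume

__all__ = ["write_sinogram", "read_sinogram", "write_image", "read_image",
           "write_image_nifti", "sinogram_to_csv", "RunConfig"]

_HEADER_INTS = ("nrad", "nang", "nx", "ny", "seed", "overflow")
_HEADER_FLOATS = ("bin_mm", "duration_s", "voxel_mm", "fraction_percent")


def _write_header(path: Path, fields: dict) -> None:
    lines = [f"{k} = {fields[k]}" for k in sorted(fields)]
    path.write_text("\n".join(lines) + "\n")


def _read_header(path: Path) -> dict:
    out: dict = {}
    for line in path.read_text().splitlines():
        if not line.strip() or "=" not in line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        if k in _HEADER_INTS:
            out[k] = int(v)
        elif k in _HEADER_FLOATS:
            out[k] = float(v)
        else:
            out[k] = v
    return out


def write_sinogram(path, sino: Sinogram) -> Path:
    """Write ``path.f32`` + ``path.hdr``; returns the data path."""
    path = Path(path)
    data_path = path.with_suffix(".f32")
    sino.counts.astype("<f4").tofile(data_path)
    header = {"nang": sino.n_angles, "nrad": sino.n_radial,
              **{k: v for k, v in sino.meta.items() if v is not None}}
    _write_header(path.with_suffix(".hdr"), header)
    return data_path


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    meta = _read_header(path.with_suffix(".hdr"))
    nang, nrad = meta.pop("nang"), meta.pop("nrad")
    counts = np.fromfile(path.with_suffix(".f32"), dtype="<f4")
    if counts.size != nang * nrad:
        raise ValueError(f"{path}: expected {nang * nrad} values, "
                         f"got {counts.size}")
    return Sinogram(counts.reshape(nang, nrad).astype(float), meta)


def write_image(path, img: ImageVolume) -> Path:
    path = Path(path)
    data_path = path.with_suffix(".f32")
    img.values.astype("<f4").tofile(data_path)
    header = {"ny": img.values.shape[0], "nx": img.values.shape[1],
              "voxel_mm": img.voxel_mm, "is_suv": img.is_suv,
              "calibration_factor": img.calibration_factor,
              **{k: v for k, v in img.meta.items() if v is not None}}
    _write_header(path.with_suffix(".hdr"), header)
    return data_path


def read_image(path) -> ImageVolume:
    path = Path(path)
    meta = _read_header(path.with_suffix(".hdr"))
    ny, nx = meta.pop("ny"), meta.pop("nx")
    voxel = meta.pop("voxel_mm")
    is_suv = str(meta.pop("is_suv", "False")) == "True"
    calib = float(meta.pop("calibration_factor", 1.0))
    vals = np.fromfile(path.with_suffix(".f32"), dtype="<f4")
    return ImageVolume(vals.reshape(ny, nx).astype(float), voxel, meta,
                       is_suv=is_suv, calibration_factor=calib)


def write_image_nifti(path, img: ImageVolume) -> Path:
    """Optional NIfTI export (requires nibabel)."""
    import nibabel as nib
    affine = np.diag([img.voxel_mm, img.voxel_mm, 1.0, 1.0])
    nii = nib.Nifti1Image(img.values[..., None].astype(np.float32), affine)
    path = Path(path).with_suffix(".nii")
    nib.save(nii, path)
    return path


def sinogram_to_csv(sino: Sinogram) -> str:
    """CSV matrix (rows = angles) with a one-line ``# key=value`` preamble."""
    prov = ";".join(f"{k}={v}" for k, v in sorted(sino.meta.items()))
    body = "\n".join(",".join(f"{v:.6g}" for v in row)
                     for row in sino.counts)
    return f"# {prov}\n{body}\n"


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    phantom: str = "nema-nu4"
    f18_uci: float = 100.0
    i131_uci: float = 0.0
    window: str = "350-650"
    duration_s: float = 1.0
    seed: int = 0
    fraction_source: str = "table"   # table | linear | rate-model | value
    fraction_value: float | None = None
    correction_method: str = "tail-uniform"
    recon_filter: str = "ramp"
    scanner: dict = field(default_factory=dict)
    output_dir: str = "."

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
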