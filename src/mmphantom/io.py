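"""Volume I/O: NIfTI / MetaImage via SimpleITK, catalog sidecars as JSON.

Internally arrays are (z, y, x) with spacing/origin in the same axis order;
SimpleITK's (x, y, z) convention is translated at this boundary.
Displacement fields are stored as 3-component vector images with components
reordered to (dx, dy, dz) on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .modality import ModalityVolume
from .phantom import DisplacementField, OrganLabelVolume

__all__ = [
    "write_label_volume",
    "read_label_volume",
    "write_scalar_volume",
    "read_scalar_volume",
    "write_displacement_field",
    "read_displacement_field",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _EXTENSIONS):
        raise ValueError(f"unsupported volume format {path.name!r}; use one of {_EXTENSIONS}")


def _image_from_array(arr: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in reversed(spacing)))
    img.SetOrigin(tuple(float(o) for o in reversed(origin)))
    return img


def write_label_volume(vol: OrganLabelVolume, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    sitk.WriteImage(_image_from_array(vol.labels.astype(np.int16), vol.spacing, vol.origin), str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_catalog.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in vol.organ_catalog.items()}, indent=2))


def read_label_volume(path: str | Path) -> OrganLabelVolume:
    path = Path(path)
    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).astype(np.int16)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    sidecar = path.with_name(path.name.split(".")[0] + "_catalog.json")
    if sidecar.exists():
        catalog = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        catalog = {int(i): f"organ_{i}" for i in np.unique(labels)}
    return OrganLabelVolume(labels, spacing, origin, catalog)


def write_scalar_volume(vol: ModalityVolume, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    sitk.WriteImage(_image_from_array(vol.intensities.astype(np.float32), vol.spacing, vol.origin), str(path))


def read_scalar_volume(path: str | Path, modality: str = "CT", normalized: bool = False) -> ModalityVolume:
    img = sitk.ReadImage(str(Path(path)))
    data = sitk.GetArrayFromImage(img).astype(float)
    return ModalityVolume(
        data,
        modality,
        tuple(reversed(img.GetSpacing())),
        tuple(reversed(img.GetOrigin())),
        normalized=normalized,
    )


def write_displacement_field(field: DisplacementField, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    vectors_xyz = field.vectors[..., ::-1].astype(np.float64)  # (dz,dy,dx) -> (dx,dy,dz)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vectors_xyz), isVector=True)
    img.SetSpacing(tuple(float(s) for s in reversed(field.spacing)))
    img.SetOrigin(tuple(float(o) for o in reversed(field.origin)))
    sitk.WriteImage(img, str(path))
    meta = path.with_name(path.name.split(".")[0] + "_states.json")
    meta.write_text(json.dumps({"from_state": field.from_state, "to_state": field.to_state}))


def read_displacement_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    img = sitk.ReadImage(str(path))
    vectors = sitk.GetArrayFromImage(img)[..., ::-1]  # back to (dz, dy, dx)
    meta = path.with_name(path.name.split(".")[0] + "_states.json")
    if meta.exists():
        states = json.loads(meta.read_text())
        from_state, to_state = states["from_state"], states["to_state"]
    else:
        zero = not np.any(vectors)
        from_state, to_state = ("exhaled", "exhaled") if zero else ("exhaled", "inhaled")
    return DisplacementField(
        vectors,
        from_state,
        to_state,
        tuple(reversed(img.GetSpacing())),
        tuple(reversed(img.GetOrigin())),
    )
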