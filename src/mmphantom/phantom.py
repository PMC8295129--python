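"""Procedural abdominal phantom: labeled anatomy, respiratory motion, warping.

The phantom is the shared ground truth of the whole pipeline: a 3D integer
label map in which every organ occupies a known set of voxels.  All simulated
modalities are derived from the same label map, so the multimodal volumes are
co-registered by construction, and the respiratory displacement field that
links the exhaled and inhaled states is known exactly.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` with ``z`` increasing toward the head
  (superior), ``y`` increasing toward the anterior chest wall, and ``x``
  increasing toward the patient's left.
* ``spacing`` and ``origin`` are given in mm, in array-axis order
  ``(dz, dy, dx)``.
* Displacement fields store one mm-valued 3-vector ``(dz, dy, dx)`` per voxel.
  ``warp_volume`` pulls values *from* the displaced location, i.e.
  ``out[i] = vol[i + d(i)/spacing]``, so warping the exhaled phantom with the
  stored exhaled->inhaled field produces the inhaled phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "OrganLabelVolume",
    "MotionParameters",
    "DisplacementField",
    "PhantomConfig",
    "ORGAN_CATALOG",
    "generate_phantom",
    "generate_respiratory_deformation",
    "invert_displacement_field",
    "warp_volume",
    "warp_labels",
    "extract_organ_mask",
    "make_breathing_pair",
]

# Organ ids.  0 is reserved for background (air).
BACKGROUND = 0
BODY = 1
LUNG_LEFT = 2
LUNG_RIGHT = 3
LIVER = 4
HEPATIC_VESSELS = 5
KIDNEY_LEFT = 6
KIDNEY_RIGHT = 7
SPLEEN = 8
STOMACH = 9
SPINE = 10
AORTA = 11
ARM_LEFT = 12
ARM_RIGHT = 13

ORGAN_CATALOG: dict[int, str] = {
    BACKGROUND: "background",
    BODY: "body",
    LUNG_LEFT: "lung_left",
    LUNG_RIGHT: "lung_right",
    LIVER: "liver",
    HEPATIC_VESSELS: "hepatic_vessels",
    KIDNEY_LEFT: "kidney_left",
    KIDNEY_RIGHT: "kidney_right",
    SPLEEN: "spleen",
    STOMACH: "stomach",
    SPINE: "spine",
    AORTA: "aorta",
    ARM_LEFT: "arm_left",
    ARM_RIGHT: "arm_right",
}

#: organs that every generated phantom must contain
MANDATORY_ORGANS = (
    BODY, LUNG_LEFT, LUNG_RIGHT, LIVER, HEPATIC_VESSELS,
    KIDNEY_LEFT, KIDNEY_RIGHT, SPLEEN, STOMACH, SPINE, AORTA,
)


@dataclass
class OrganLabelVolume:
    """3D integer organ label map with physical geometry.

    ``labels`` holds one organ id per voxel; ``organ_catalog`` maps ids to
    names.  Label 0 is background air.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_catalog: Mapping[int, str] = field(default_factory=lambda: dict(ORGAN_CATALOG))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        present = set(np.unique(self.labels).tolist()) - {BACKGROUND}
        unknown = present - set(self.organ_catalog)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from organ_catalog")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, organ_ids) -> np.ndarray:
        return extract_organ_mask(self, organ_ids)

    def save(self, path: str | Path) -> None:
        """Write the label map (NIfTI/MetaImage by extension) + JSON catalog."""
        from . import io as _io

        _io.write_label_volume(self, path)


@dataclass(frozen=True)
class MotionParameters:
    """Respiratory motion amplitudes.

    ``diaphragm_motion_mm`` is the peak superior-inferior excursion of the
    diaphragm dome; ``chest_expansion_mm`` the peak anterior displacement of
    the chest wall.  The exhaled state is the zero-displacement reference.
    """

    diaphragm_motion_mm: float = 15.0
    chest_expansion_mm: float = 6.0
    state: str = "inhaled"

    def __post_init__(self) -> None:
        if self.diaphragm_motion_mm < 0 or self.chest_expansion_mm < 0:
            raise ValueError("motion amplitudes must be >= 0")
        if not np.isfinite(self.diaphragm_motion_mm) or not np.isfinite(self.chest_expansion_mm):
            raise ValueError("motion amplitudes must be finite")
        if self.state not in ("inhaled", "exhaled"):
            raise ValueError("state must be 'inhaled' or 'exhaled'")


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) linking two motion states."""

    vectors: np.ndarray  # (z, y, x, 3), components (dz, dy, dx) in mm
    from_state: str
    to_state: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (z, y, x, 3)")
        is_zero = not np.any(self.vectors)
        if (self.from_state == self.to_state) != is_zero:
            raise ValueError(
                "zero field if and only if from_state == to_state "
                f"(from={self.from_state!r}, to={self.to_state!r}, zero={is_zero})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def save(self, path: str | Path) -> None:
        from . import io as _io

        _io.write_displacement_field(self, path)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the procedural anatomy.

    ``shape`` is the voxel grid (z, y, x), ``spacing`` the voxel size in mm.
    ``body_scale`` scales all organ radii together; ``organ_jitter`` is the
    fractional half-width of the per-organ uniform size perturbation that
    individualizes phantoms.  Arms are optional because only the MRI protocol
    images them.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_scale: float = 1.0
    arms: bool = False
    organ_jitter: float = 0.05

    def __post_init__(self) -> None:
        if min(self.shape) < 24:
            raise ValueError("grid too small to place all mandatory organs (need >= 24 voxels per axis)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0 <= self.organ_jitter < 1:
            raise ValueError("organ_jitter must be in [0, 1)")


def _normalized_grid(shape: tuple[int, int, int]):
    """Coordinates in [-1, 1] per axis, one array per axis, broadcastable."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _superellipsoid(grid, center, radii, exponent=2.0) -> np.ndarray:
    """Boolean mask of |u/a|^p + |v/b|^p + |w/c|^p <= 1 in normalized coords."""
    z, y, x = grid
    cz, cy, cx = center
    rz, ry, rx = radii
    p = exponent
    q = (
        np.abs((z - cz) / rz) ** p
        + np.abs((y - cy) / ry) ** p
        + np.abs((x - cx) / rx) ** p
    )
    return q <= 1.0


def _tube(grid, center_yx, radius_yx, z_range, exponent=2.0) -> np.ndarray:
    """Axial tube: elliptical cross-section in (y, x) over a z interval."""
    z, y, x = grid
    cy, cx = center_yx
    ry, rx = radius_yx
    q = np.abs((y - cy) / ry) ** exponent + np.abs((x - cx) / rx) ** exponent
    return (q <= 1.0) & (z >= z_range[0]) & (z <= z_range[1])


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> OrganLabelVolume:
    """Generate a labeled abdominal phantom.

    Organs are parameterized superellipsoids and tubes composited
    back-to-front with a fixed precedence (vessels over liver over body), and
    their radii are jittered per organ by ``Uniform(1 - j, 1 + j)`` so each
    seed yields an individual anatomy.  Deterministic given (config, seed).
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    grid = _normalized_grid(config.shape)
    labels = np.zeros(config.shape, dtype=np.int16)

    def jitter(base):
        f = 1.0 + rng.uniform(-config.organ_jitter, config.organ_jitter)
        return tuple(config.body_scale * f * r for r in base)

    # torso: rounded elliptic cylinder spanning nearly the full grid
    body = _superellipsoid(grid, (0.0, -0.02, 0.0), jitter((0.97, 0.72, 0.80)), exponent=4.0)
    labels[body] = BODY

    # lungs above the diaphragm plane (z ~ +0.3)
    lung_r = jitter((0.34, 0.30, 0.26))
    left = _superellipsoid(grid, (0.62, 0.02, 0.38), lung_r)
    right = _superellipsoid(grid, (0.62, 0.02, -0.38), lung_r)
    labels[left & body] = LUNG_LEFT
    labels[right & body] = LUNG_RIGHT

    # stomach: left anterior, below the diaphragm
    stomach = _superellipsoid(grid, (0.12, 0.22, 0.30), jitter((0.18, 0.16, 0.20)))
    labels[stomach & body] = STOMACH

    # spleen: left posterior
    spleen = _superellipsoid(grid, (0.10, -0.28, 0.46), jitter((0.16, 0.12, 0.12)))
    labels[spleen & body] = SPLEEN

    # kidneys: paired, posterior, inferior
    kid_r = jitter((0.16, 0.10, 0.10))
    kl = _superellipsoid(grid, (-0.30, -0.30, 0.32), kid_r)
    kr = _superellipsoid(grid, (-0.30, -0.30, -0.32), kid_r)
    labels[kl & body] = KIDNEY_LEFT
    labels[kr & body] = KIDNEY_RIGHT

    # liver: large right-sided organ directly under the diaphragm
    liver = _superellipsoid(grid, (0.12, 0.08, -0.30), jitter((0.34, 0.44, 0.42)), exponent=2.5)
    liver &= body
    labels[liver] = LIVER

    # spine: posterior midline column, full z extent
    spine = _tube(grid, (-0.52, 0.0), jitter((0.10, 0.10))[:2], (-1.0, 1.0), exponent=2.0)
    labels[spine & body] = SPINE

    # aorta: just anterior to the spine
    aorta = _tube(grid, (-0.34, 0.02), jitter((0.05, 0.05))[:2], (-1.0, 1.0))
    labels[aorta & body] = AORTA

    # hepatic vessels: three thin tubes clipped to the liver (portal-like fan)
    vessels = np.zeros(config.shape, dtype=bool)
    z, y, x = grid
    for cy, cx, ry, rx in (
        (0.08, -0.30, 0.045, 0.045),
        (0.22, -0.18, 0.035, 0.035),
        (-0.06, -0.44, 0.035, 0.035),
    ):
        vessels |= _tube(grid, (cy, cx), (ry, rx), (-1.0, 1.0))
    vessels &= liver
    labels[vessels] = HEPATIC_VESSELS

    # optional arms: small cylinders lateral to the torso (MRI protocol only)
    if config.arms:
        arm_r = jitter((0.07, 0.07))[:2]
        for cx, lab in ((0.92, ARM_LEFT), (-0.92, ARM_RIGHT)):
            arm = _tube(grid, (-0.05, cx), arm_r, (-1.0, 1.0))
            labels[arm] = lab

    vol = OrganLabelVolume(labels, config.spacing, organ_catalog=dict(ORGAN_CATALOG))
    present = set(np.unique(labels).tolist())
    missing = [ORGAN_CATALOG[i] for i in MANDATORY_ORGANS if i not in present]
    if missing:
        raise ValueError(f"grid too small to place all mandatory organs; missing: {missing}")
    return vol


def _boundary_taper(n: int, width: int) -> np.ndarray:
    """Smooth ramp 0 -> 1 over ``width`` samples at the start of an axis."""
    t = np.ones(n)
    w = min(width, n)
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(w) / max(w - 1, 1))
    t[:w] = ramp
    return t


def generate_respiratory_deformation(
    phantom: OrganLabelVolume,
    motion: MotionParameters,
    diaphragm_plane_frac: float = 0.55,
    smooth_sigma_mm: float = 12.0,
) -> DisplacementField:
    """Build the exhaled->inhaled respiratory displacement field.

    Diaphragm motion is a superior-inferior translation weighted by a smooth
    axial window centered on the diaphragm plane; chest expansion is an
    anterior displacement weighted by an anterior-posterior window.  The two
    components are blended additively, Gaussian-smoothed, and rescaled so the
    peak per-component displacement equals the requested amplitude.  The field
    vanishes at the inferior and posterior volume boundaries.
    """
    nz, ny, nx = phantom.shape
    dz_mm, dy_mm, dx_mm = phantom.spacing
    A = float(motion.diaphragm_motion_mm)
    B = float(motion.chest_expansion_mm)

    vectors = np.zeros((*phantom.shape, 3))
    if A == 0.0 and B == 0.0:
        return DisplacementField(vectors, "exhaled", "exhaled", phantom.spacing, phantom.origin)

    z_idx = np.arange(nz)
    y_idx = np.arange(ny)
    z_d = diaphragm_plane_frac * (nz - 1)
    sigma_z = 0.22 * nz
    w_axial = np.exp(-0.5 * ((z_idx - z_d) / sigma_z) ** 2)

    # anterior window: 0 at the posterior boundary, 1 at the anterior wall
    w_ant = (y_idx / (ny - 1)) ** 2

    # zero-displacement constraints at the inferior (z=0) and posterior (y=0)
    # volume boundaries, applied after smoothing so they hold exactly
    taper = (
        _boundary_taper(nz, max(nz // 8, 2))[:, None, None]
        * _boundary_taper(ny, max(ny // 8, 2))[None, :, None]
    )
    sigma_vox = smooth_sigma_mm / np.array(phantom.spacing)

    if A > 0:
        # inhale pushes the diaphragm dome inferiorly (negative z)
        comp = -w_axial[:, None, None] * np.ones((nz, ny, nx))
        comp = ndimage.gaussian_filter(comp, sigma=sigma_vox) * taper
        comp *= A / np.abs(comp).max()
        vectors[..., 0] = comp
    if B > 0:
        comp = w_ant[None, :, None] * w_axial[:, None, None] * np.ones((nz, ny, nx))
        comp = ndimage.gaussian_filter(comp, sigma=sigma_vox) * taper
        comp *= B / np.abs(comp).max()
        vectors[..., 1] = comp

    return DisplacementField(vectors, "exhaled", "inhaled", phantom.spacing, phantom.origin)


def _field_in_voxels(field: DisplacementField) -> np.ndarray:
    return field.vectors / np.asarray(field.spacing)[None, None, None, :]


def warp_volume(
    volume: np.ndarray,
    field: DisplacementField,
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample ``volume`` through ``field`` (pull-back convention).

    ``out[i] = volume[i + d(i)/spacing]``.  Label maps must use
    ``interpolation='nearest'`` so no fractional labels appear.
    """
    volume = np.asarray(volume)
    if volume.shape != field.shape:
        raise ValueError(f"volume shape {volume.shape} != field shape {field.shape}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = 1 if interpolation == "linear" else 0
    disp = _field_in_voxels(field)
    coords = np.indices(volume.shape, dtype=float) + np.moveaxis(disp, -1, 0)
    out = ndimage.map_coordinates(
        volume.astype(float), coords, order=order, mode="nearest"
    )
    if interpolation == "nearest":
        out = out.astype(volume.dtype)
    return out


def warp_labels(phantom: OrganLabelVolume, field: DisplacementField) -> OrganLabelVolume:
    """Warp a label volume (nearest-neighbor) into the field's target state."""
    warped = warp_volume(phantom.labels, field, interpolation="nearest")
    return replace(phantom, labels=warped)


def invert_displacement_field(field: DisplacementField, iterations: int = 25) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration.

    Solves ``d_inv(i) = -d(i + d_inv(i))``; accurate for smooth,
    diffeomorphic-scale respiratory fields.
    """
    disp_vox = _field_in_voxels(field)
    inv = np.zeros_like(disp_vox)
    base = np.indices(field.shape, dtype=float)
    for _ in range(iterations):
        coords = base + np.moveaxis(inv, -1, 0)
        sampled = np.stack(
            [
                ndimage.map_coordinates(disp_vox[..., c], coords, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
        inv = -sampled
    vectors = inv * np.asarray(field.spacing)[None, None, None, :]
    if not np.any(vectors):  # zero in -> zero out: keep the state contract
        return DisplacementField(vectors, field.from_state, field.from_state, field.spacing, field.origin)
    return DisplacementField(vectors, field.to_state, field.from_state, field.spacing, field.origin)


def extract_organ_mask(phantom: OrganLabelVolume, organ_ids) -> np.ndarray:
    """Binary mask that is true exactly where the label is in ``organ_ids``."""
    ids = set(int(i) for i in organ_ids)
    unknown = ids - set(phantom.organ_catalog)
    if unknown:
        raise KeyError(f"organ ids {sorted(unknown)} not in catalog")
    return np.isin(phantom.labels, sorted(ids))


def make_breathing_pair(
    config: PhantomConfig | None = None,
    motion: MotionParameters | None = None,
    seed: int = 0,
):
    """Generate (exhaled phantom, inhaled phantom, exhaled->inhaled field).

    The inhaled phantom is *defined* as the exhaled labels warped through the
    generated field, so the stored field is exact ground truth by
    construction.
    """
    motion = motion or MotionParameters()
    exhaled = generate_phantom(config, seed=seed)
    fwd = generate_respiratory_deformation(exhaled, motion)
    inhaled = warp_labels(exhaled, fwd)
    return exhaled, inhaled, fwd


def save_catalog(catalog: Mapping[int, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in catalog.items()}, indent=2))


def load_catalog(path: str | Path) -> dict[int, str]:
    return {int(k): v for k, v in json.loads(Path(path).read_text()).items()}
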