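"""Modality simulation: label map -> CT / CBCT / MRI phantom volumes.

The CT pathway assigns each organ its linear attenuation coefficient at a
simulated tube energy (90-120 keV in 5 keV steps) and converts to Hounsfield
units; the CBCT pathway additionally applies a narrow cylindrical
field-of-view mask centered on the liver; the MRI pathway replaces
attenuation with the steady-state spoiled gradient-echo (VIBE) signal

    SI = rho * sin(a) * (1 - exp(-TR/T1)) / (1 - cos(a) * exp(-TR/T1)) * exp(-TE/T2)

computed from per-organ T1/T2/proton-density values, each independently
jittered by +-5 % to emulate inter-subject variability.  All volumes are then
windowed and affinely normalized to [-1, 1].  Because every modality is
painted onto the same label map, the outputs are co-registered voxel for
voxel.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import phantom as ph
from .phantom import OrganLabelVolume, extract_organ_mask

__all__ = [
    "ENERGIES_KEV",
    "TissuePropertyTable",
    "VibeParameters",
    "ModalityVolume",
    "FovSpec",
    "default_property_table",
    "attenuation_volume",
    "mu_to_hu",
    "apply_cbct_fov",
    "vibe_signal",
    "mri_phantom",
    "ct_phantom",
    "window_and_normalize",
    "inject_textured_noise",
    "simulate_modality",
    "DEFAULT_WINDOWS",
]

ENERGIES_KEV: tuple[int, ...] = (90, 95, 100, 105, 110, 115, 120)

#: default intensity windows; MRI uses per-volume percentiles instead
DEFAULT_WINDOWS = {
    "CT": (-1024.0, 1500.0),
    "CBCT": (-1024.0, 2000.0),
    "MRI": ("percentile", 10.0, 90.0),
}

#: default voxel spacings (dz, dy, dx) mm per modality protocol
DEFAULT_SPACINGS = {
    "CT": (2.0, 1.0, 1.0),
    "CBCT": (0.486, 0.486, 0.486),
    "MRI": (3.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class VibeParameters:
    """Spoiled gradient-echo acquisition parameters (defaults from a 3 T
    abdominal breath-hold protocol)."""

    TR: float = 7.25  # ms
    TE: float = 4.54  # ms
    alpha: float = 10.0  # degrees

    def __post_init__(self) -> None:
        if not (self.TR > self.TE >= 0):
            raise ValueError("require TR > TE >= 0")
        if not (0 <= self.alpha <= 90):
            raise ValueError("flip angle must be in [0, 90] degrees")


@dataclass
class ModalityVolume:
    """Scalar 3D image with modality tag and normalization state."""

    intensities: np.ndarray
    modality: str  # "CT" | "CBCT" | "MRI"
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    window: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3D")
        if self.modality not in ("CT", "CBCT", "MRI"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.normalized:
            lo, hi = self.intensities.min(), self.intensities.max()
            if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError("normalized volume must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> None:
        from . import io as _io

        _io.write_scalar_volume(self, path)


@dataclass(frozen=True)
class FovSpec:
    """Cylindrical field of view (axial circle x z extent), liver-centered."""

    center: tuple[float, float, float] | None = None  # physical mm (z, y, x); None -> liver centroid
    radius_mm: float = 60.0
    axial_extent_mm: float = np.inf

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.axial_extent_mm <= 0:
            raise ValueError("axial extent must be positive")


class TissuePropertyTable:
    """Per-organ physical properties driving the modality simulation.

    Holds, for every organ id, the linear attenuation coefficient mu(E)
    (1/cm) on the supported energy grid, plus T1 (ms), T2 (ms) and relative
    proton density rho (a.u.), and the water attenuation per energy used for
    the Hounsfield conversion.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        mu_water: Mapping[int, float],
        energies: Sequence[int] = ENERGIES_KEV,
    ) -> None:
        required = {"organ_id", "name", "T1_ms", "T2_ms", "rho"} | {f"mu_{e}" for e in energies}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"property table missing columns: {sorted(missing)}")
        frame = frame.set_index("organ_id", drop=False) if frame.index.name != "organ_id" else frame
        if (frame["T1_ms"] <= 0).any() or (frame["T2_ms"] <= 0).any() or (frame["rho"] < 0).any():
            raise ValueError("T1, T2 must be > 0 and rho >= 0")
        mu_cols = frame[[f"mu_{e}" for e in energies]]
        if (mu_cols.to_numpy() < 0).any():
            raise ValueError("attenuation coefficients must be >= 0")
        self.frame = frame
        self.energies = tuple(int(e) for e in energies)
        self._mu_water = {int(e): float(m) for e, m in mu_water.items()}
        for e in self.energies:
            if self._mu_water.get(e, 0.0) <= 0:
                raise ValueError(f"mu_water must be positive at {e} keV")

    # -- lookups ---------------------------------------------------------
    def organ_ids(self) -> set[int]:
        return set(int(i) for i in self.frame["organ_id"])

    def mu(self, organ_id: int, energy_keV: int) -> float:
        self._check_energy(energy_keV)
        try:
            return float(self.frame.loc[organ_id, f"mu_{energy_keV}"])
        except KeyError:
            raise KeyError(f"no attenuation entry for organ id {organ_id}") from None

    def relaxation(self, organ_id: int) -> tuple[float, float, float]:
        """(T1 ms, T2 ms, rho) for one organ."""
        try:
            row = self.frame.loc[organ_id]
        except KeyError:
            raise KeyError(f"no MR property entry for organ id {organ_id}") from None
        return float(row["T1_ms"]), float(row["T2_ms"]), float(row["rho"])

    def mu_water(self, energy_keV: int) -> float:
        self._check_energy(energy_keV)
        return self._mu_water[int(energy_keV)]

    def _check_energy(self, energy_keV: int) -> None:
        if int(energy_keV) not in self.energies:
            raise ValueError(
                f"energy {energy_keV} keV not on the simulated grid {self.energies}; "
                "no interpolation is performed"
            )

    def validate_covers(self, phantom: OrganLabelVolume) -> None:
        present = set(np.unique(phantom.labels).tolist())
        missing = present - self.organ_ids()
        if missing:
            names = [phantom.organ_catalog.get(i, "?") for i in sorted(missing)]
            raise KeyError(f"property table missing organs: {names}")

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        water = {f"mu_{e}": self._mu_water[e] for e in self.energies}
        water_row = {"organ_id": -1, "name": "water_reference", "T1_ms": 1.0, "T2_ms": 1.0, "rho": 0.0, **water}
        out = pd.concat([out, pd.DataFrame([water_row])], ignore_index=True)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | _stdio.StringIO) -> "TissuePropertyTable":
        frame = pd.read_csv(path)
        water = frame[frame["organ_id"] == -1]
        frame = frame[frame["organ_id"] != -1].copy()
        energies = sorted(int(c[3:]) for c in frame.columns if c.startswith("mu_"))
        if len(water):
            mu_water = {e: float(water.iloc[0][f"mu_{e}"]) for e in energies}
        else:
            raise ValueError("CSV lacks the water_reference row (organ_id = -1)")
        return cls(frame, mu_water, energies)


def _mu_water_by_energy() -> dict[int, float]:
    # linear attenuation of water, 1/cm, smoothly decreasing over 90-120 keV
    base = {90: 0.1837, 95: 0.1790, 100: 0.1707, 105: 0.1669, 110: 0.1632, 115: 0.1598, 120: 0.1566}
    return base


def default_property_table() -> TissuePropertyTable:
    """Built-in tissue property table covering the full organ catalog.

    Attenuation values follow broad tissue classes (air, lung, soft tissue,
    liver, blood, bone) with a mild downward energy trend; lung attenuation is
    pinned to 0.24 x water so the simulated lung reads -760 HU, the value the
    underlying torso model assigns.  T1/T2 (3 T) and relative proton density
    are literature-typical per-tissue defaults; the table is an editable
    fixture, not a measurement, and can be overridden via CSV.
    """
    mu_w = _mu_water_by_energy()
    energies = ENERGIES_KEV

    def mu_scaled(factor):
        return {f"mu_{e}": factor * mu_w[e] for e in energies}

    rows = []

    def add(organ_id, name, factor, T1, T2, rho):
        rows.append({"organ_id": organ_id, "name": name, "T1_ms": T1, "T2_ms": T2, "rho": rho, **mu_scaled(factor)})

    # factor = mu / mu_water at each energy (HU = 1000 * (factor - 1))
    add(ph.BACKGROUND, "background", 0.0, 1e9, 1e9, 1e-6)  # air: no signal
    add(ph.BODY, "body", 1.03, 1412.0, 50.0, 0.74)          # muscle-like soft tissue
    add(ph.LUNG_LEFT, "lung_left", 0.24, 1270.0, 30.0, 0.10)
    add(ph.LUNG_RIGHT, "lung_right", 0.24, 1270.0, 30.0, 0.10)
    add(ph.LIVER, "liver", 1.06, 809.0, 34.0, 0.70)
    add(ph.HEPATIC_VESSELS, "hepatic_vessels", 1.05, 1932.0, 275.0, 0.95)
    add(ph.KIDNEY_LEFT, "kidney_left", 1.04, 1194.0, 56.0, 0.81)
    add(ph.KIDNEY_RIGHT, "kidney_right", 1.04, 1194.0, 56.0, 0.81)
    add(ph.SPLEEN, "spleen", 1.05, 1328.0, 61.0, 0.80)
    add(ph.STOMACH, "stomach", 1.02, 1100.0, 45.0, 0.75)
    add(ph.SPINE, "spine", 1.80, 586.0, 49.0, 0.40)         # vertebral bone + marrow mix
    add(ph.AORTA, "aorta", 1.05, 1932.0, 275.0, 0.95)       # blood
    add(ph.ARM_LEFT, "arm_left", 1.03, 1412.0, 50.0, 0.74)
    add(ph.ARM_RIGHT, "arm_right", 1.03, 1412.0, 50.0, 0.74)

    return TissuePropertyTable(pd.DataFrame(rows), mu_w, energies)


# ---------------------------------------------------------------------------
# CT / CBCT pathway
# ---------------------------------------------------------------------------

def attenuation_volume(
    phantom: OrganLabelVolume,
    table: TissuePropertyTable,
    energy_keV: int,
) -> np.ndarray:
    """Voxelwise attenuation lookup mu(label, E) in 1/cm."""
    table._check_energy(energy_keV)
    table.validate_covers(phantom)
    lut_size = int(phantom.labels.max()) + 1
    lut = np.zeros(lut_size)
    for organ_id in np.unique(phantom.labels):
        lut[organ_id] = table.mu(int(organ_id), energy_keV)
    return lut[phantom.labels]


def mu_to_hu(mu_volume: np.ndarray, mu_water: float) -> np.ndarray:
    """HU = 1000 * (mu - mu_water) / mu_water."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return 1000.0 * (np.asarray(mu_volume, dtype=float) - mu_water) / mu_water


def ct_phantom(
    phantom: OrganLabelVolume,
    table: TissuePropertyTable,
    energy_keV: int = 100,
    modality: str = "CT",
) -> ModalityVolume:
    """Attenuation -> HU volume for one tube energy (native units, unwindowed)."""
    mu = attenuation_volume(phantom, table, energy_keV)
    hu = mu_to_hu(mu, table.mu_water(energy_keV))
    window = DEFAULT_WINDOWS[modality] if modality in ("CT", "CBCT") else None
    return ModalityVolume(hu, modality, phantom.spacing, phantom.origin, window=window)


def apply_cbct_fov(
    hu_volume: ModalityVolume,
    liver_mask: np.ndarray,
    fov: FovSpec | None = None,
) -> ModalityVolume:
    """Blank voxels outside a liver-centered cylinder to the window floor."""
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if liver_mask.shape != hu_volume.shape:
        raise ValueError("liver mask shape mismatch")
    if not liver_mask.any():
        raise ValueError("liver mask is empty")
    fov = fov or FovSpec()
    dz, dy, dx = hu_volume.spacing
    if fov.center is None:
        cz, cy, cx = ndimage.center_of_mass(liver_mask)
        center_mm = (cz * dz, cy * dy, cx * dx)
    else:
        center_mm = fov.center

    nz, ny, nx = hu_volume.shape
    z = np.arange(nz)[:, None, None] * dz
    y = np.arange(ny)[None, :, None] * dy
    x = np.arange(nx)[None, None, :] * dx
    in_plane = (y - center_mm[1]) ** 2 + (x - center_mm[2]) ** 2 <= fov.radius_mm**2
    axial = np.abs(z - center_mm[0]) <= fov.axial_extent_mm / 2.0
    keep = in_plane & axial

    if hu_volume.window is None or isinstance(hu_volume.window[0], str):
        floor = float(hu_volume.intensities.min())
    else:
        floor = float(hu_volume.window[0])
    out = np.where(keep, hu_volume.intensities, floor)
    return replace(hu_volume, intensities=out)


# ---------------------------------------------------------------------------
# MRI pathway
# ---------------------------------------------------------------------------

def vibe_signal(T1: float, T2: float, rho: float, p: VibeParameters | None = None):
    """Steady-state spoiled gradient-echo signal.

    SI = rho sin(a) (1 - E1) / (1 - cos(a) E1) * exp(-TE/T2),  E1 = exp(-TR/T1).
    Accepts scalars or broadcastable arrays; SI >= 0 under the parameter
    invariants (the denominator is bounded away from zero since cos(a) <= 1
    and E1 < 1).
    """
    p = p or VibeParameters()
    T1 = np.asarray(T1, dtype=float)
    T2 = np.asarray(T2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(T1 <= 0) or np.any(T2 <= 0) or np.any(rho < 0):
        raise ValueError("require T1 > 0, T2 > 0, rho >= 0")
    a = np.deg2rad(p.alpha)
    e1 = np.exp(-p.TR / T1)
    si = rho * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1) * np.exp(-p.TE / T2)
    return si if si.ndim else float(si)


def mri_phantom(
    phantom: OrganLabelVolume,
    table: TissuePropertyTable,
    p: VibeParameters | None = None,
    jitter_frac: float = 0.05,
    seed: int = 0,
) -> ModalityVolume:
    """Paint the VIBE signal organ by organ, with per-organ property jitter.

    For each organ in this phantom instance, T1, T2 and rho are independently
    multiplied by ``Uniform(1 - jitter, 1 + jitter)`` before the signal
    equation, emulating inter-subject tissue variability.  Deterministic
    given ``seed``.
    """
    if not 0 <= jitter_frac < 1:
        raise ValueError("jitter_frac must be in [0, 1)")
    p = p or VibeParameters()
    table.validate_covers(phantom)
    rng = np.random.default_rng(seed)
    out = np.zeros(phantom.shape)
    # iterate catalog order so the random stream does not depend on anatomy
    for organ_id in sorted(table.organ_ids()):
        f1, f2, fr = rng.uniform(1.0 - jitter_frac, 1.0 + jitter_frac, size=3)
        if organ_id == ph.BACKGROUND or not np.any(phantom.labels == organ_id):
            continue
        T1, T2, rho = table.relaxation(organ_id)
        si = vibe_signal(T1 * f1, T2 * f2, rho * fr, p)
        out[phantom.labels == organ_id] = si
    return ModalityVolume(out, "MRI", phantom.spacing, phantom.origin)


# ---------------------------------------------------------------------------
# Windowing / normalization / noise
# ---------------------------------------------------------------------------

def window_and_normalize(vol: ModalityVolume, window=None) -> ModalityVolume:
    """Clip to the window then map affinely onto [-1, 1].

    ``window`` may be ``(low, high)`` in native units or
    ``("percentile", p_lo, p_hi)``, evaluated on the whole 3D array
    (background included).  Defaults per modality: CT [-1024, 1500] HU,
    CBCT [-1024, 2000] HU, MRI 10th/90th percentile.
    """
    window = window if window is not None else (vol.window or DEFAULT_WINDOWS[vol.modality])
    data = vol.intensities
    if isinstance(window[0], str):
        if window[0] != "percentile":
            raise ValueError(f"unknown window spec {window!r}")
        lo, hi = np.percentile(data, [window[1], window[2]])
        if hi <= lo:
            raise ValueError("percentile window degenerate (constant volume?)")
    else:
        lo, hi = float(window[0]), float(window[1])
        if not lo < hi:
            raise ValueError("window low must be < high")
    clipped = np.clip(data, lo, hi)
    normed = (clipped - lo) / (hi - lo) * 2.0 - 1.0
    return replace(vol, intensities=normed, window=(lo, hi), normalized=True)


def _radial_filter_2d(shape_yx, spacing_yx, radial_shape) -> np.ndarray:
    """2D FFT-domain magnitude filter from a 1D radial profile.

    ``radial_shape`` is either a callable H(f) with f in cycles/mm, or a pair
    of 1D arrays (frequencies, H).  A scalar/None profile means white noise.
    """
    ny, nx = shape_yx
    fy = np.fft.fftfreq(ny, d=spacing_yx[0])
    fx = np.fft.fftfreq(nx, d=spacing_yx[1])
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    if radial_shape is None:
        return np.ones_like(fr)
    if callable(radial_shape):
        H = np.asarray(radial_shape(fr), dtype=float)
    else:
        freqs, vals = radial_shape
        H = np.interp(fr, np.asarray(freqs, dtype=float), np.asarray(vals, dtype=float))
    return np.abs(H)


def inject_textured_noise(
    vol: ModalityVolume,
    radial_shape=None,
    magnitude: float = 0.0,
    seed: int = 0,
    liver_mask: np.ndarray | None = None,
) -> ModalityVolume:
    """Add zero-mean Gaussian noise with a prescribed radial power spectrum.

    White noise is shaped slice-wise in the 2D Fourier domain so its radial
    power spectrum is proportional to ``|radial_shape|**2``, then scaled so
    the noise standard deviation (over the liver if a mask is given, else the
    whole volume) equals ``magnitude`` in native units.  This produces
    pseudo-"patient" volumes with controllable noise texture, so the realism
    metrics and the registration harness can be exercised without a trained
    network or clinical data.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0.0:
        return replace(vol, intensities=vol.intensities.copy())
    rng = np.random.default_rng(seed)
    nz, ny, nx = vol.shape
    H = _radial_filter_2d((ny, nx), vol.spacing[1:], radial_shape)
    white = rng.standard_normal(vol.shape)
    shaped = np.fft.ifft2(np.fft.fft2(white, axes=(1, 2)) * H[None, :, :], axes=(1, 2)).real
    region = shaped[np.asarray(liver_mask, dtype=bool)] if liver_mask is not None else shaped
    std = region.std()
    if std == 0:
        raise ValueError("shaping filter annihilated the noise")
    shaped *= magnitude / std
    out = vol.intensities + shaped
    if vol.normalized:
        out = np.clip(out, -1.0, 1.0)
    return replace(vol, intensities=out)


# ---------------------------------------------------------------------------
# High-level pipeline
# ---------------------------------------------------------------------------

def simulate_modality(
    phantom: OrganLabelVolume,
    modality: str,
    table: TissuePropertyTable | None = None,
    energy_keV: int = 100,
    vibe: VibeParameters | None = None,
    fov: FovSpec | None = None,
    jitter_frac: float = 0.05,
    seed: int = 0,
    normalize: bool = True,
) -> ModalityVolume:
    """Full pathway for one modality: simulate, (mask), window, normalize."""
    table = table or default_property_table()
    if modality in ("CT", "CBCT"):
        vol = ct_phantom(phantom, table, energy_keV, modality=modality)
        if modality == "CBCT":
            liver = extract_organ_mask(phantom, {ph.LIVER, ph.HEPATIC_VESSELS})
            vol = apply_cbct_fov(vol, liver, fov)
    elif modality == "MRI":
        vol = mri_phantom(phantom, table, vibe, jitter_frac=jitter_frac, seed=seed)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return window_and_normalize(vol) if normalize else vol
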