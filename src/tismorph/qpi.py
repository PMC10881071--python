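"""Morphometrics from 3-D refractive-index (RI) tomograms.

A holotomogram assigns each voxel a refractive index n. Cells are
segmented as voxels above the medium RI (PBS, n = 1.3342) by a small
margin; from the voxel mask follow volume, projected area and mean
thickness. Dry mass uses the linear relation between RI excess and dry
matter concentration, Δn = α·c with the refractive increment α (dn/dc):
0.19 ml/g for bulk cell matter and 0.135 ml/g for lipid. Two routes are
provided and agree on phantoms:

* volumetric:  DM = Σ_voxels Δn · dV / α
* phase projection:  DM = λ/(2πα) · ∫ φ(x, y) dA,   φ = (2π/λ)·∫ Δn dz

Lipid droplets are the cell voxels with 1.40 ≤ n ≤ 1.46, the RI band of
aggregated neutral-lipid vesicles, well above other organelles.

Units: lengths in µm, volumes in µm³, α in ml/g; then Δn[µm³]/α[ml/g]
is picograms directly (1 µm³ = 1e-12 cm³), e.g. Δn = 0.019 over 1 µm³
at α = 0.19 ml/g gives 0.1 pg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .acquisition import ALPHA_CELL_ML_PER_G, ALPHA_LIPID_ML_PER_G, LIPID_RI_RANGE, RI_BACKGROUND


class EmptyMask3DWarning(UserWarning):
    pass


@dataclass
class Tomogram:
    """3-D RI grid. Array axes are (z, y, x); voxel_size_um is (dx, dy, dz)."""

    ri: np.ndarray
    voxel_size_um: tuple[float, float, float]
    n_medium: float = RI_BACKGROUND
    tomo_id: str = ""
    condition: str = ""
    time_point: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ri = np.asarray(self.ri, dtype=float)
        if self.ri.ndim != 3:
            raise ValueError("ri must be a 3-D grid")
        if not np.all(np.isfinite(self.ri)) or np.any(self.ri < 1.0):
            raise ValueError("RI values must be finite and >= 1.0")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_um
        return dx * dy * dz


@dataclass
class QPIPhaseImage:
    """2-D optical phase-shift map (radians) with its illumination wavelength."""

    phase: np.ndarray
    wavelength_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("wavelength and pixel size must be positive")
        self.phase = np.asarray(self.phase, dtype=float)


@dataclass
class QpiMetrics:
    volume_um3: float
    projected_area_um2: float
    mean_thickness_um: float
    dry_mass_pg: float
    lipid_volume_um3: float
    lipid_dry_mass_pg: float
    alpha_cell: float = ALPHA_CELL_ML_PER_G
    alpha_lipid: float = ALPHA_LIPID_ML_PER_G
    lipid_ri_range: tuple[float, float] = LIPID_RI_RANGE
    tomo_id: str = ""
    condition: str = ""
    time_point: str = ""

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["lipid_ri_range"] = list(self.lipid_ri_range)
        return d


def segment_cell_3d(tomo: Tomogram, delta_n: float = 0.003, min_voxels: int = 100) -> np.ndarray:
    """Voxel mask of cell material: RI above medium by at least ``delta_n``.

    Thresholding is followed by a 3-D closing (ball radius 1) and
    removal of 26-connected components below ``min_voxels``. An empty
    result warns and leads to zeroed metrics downstream.
    """
    mask = tomo.ri > tomo.n_medium + delta_n
    if mask.any():
        mask = ndimage.binary_closing(mask, structure=ball(1))
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_voxels
            keep[0] = False
            mask = keep[labels]
    if not mask.any():
        warnings.warn("empty 3-D cell mask", EmptyMask3DWarning)
    return mask


def cell_volume(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Volume in µm³: voxel count times voxel volume."""
    dx, dy, dz = voxel_size_um
    return float(np.count_nonzero(mask)) * dx * dy * dz


def projected_area(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """x-y footprint area (µm²): columns containing at least one masked voxel."""
    dx, dy, _ = voxel_size_um
    return float(np.count_nonzero(np.asarray(mask, bool).any(axis=0))) * dx * dy


def mean_thickness(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Mean cell thickness (µm): volume over projected footprint area."""
    area = projected_area(mask, voxel_size_um)
    if area == 0:
        raise ValueError("empty mask: thickness undefined")
    return cell_volume(mask, voxel_size_um) / area


def max_thickness(mask: np.ndarray, voxel_size_um: tuple[float, float, float]) -> float:
    """Alternative output: maximum column thickness (µm)."""
    counts = np.asarray(mask, bool).sum(axis=0)
    return float(counts.max()) * voxel_size_um[2]


def dry_mass_from_ri(
    tomo: Tomogram, mask: np.ndarray, alpha_ml_per_g: float = ALPHA_CELL_ML_PER_G
) -> float:
    """Volumetric dry mass in pg: Σ_masked Δn · dV / α.

    Negative Δn voxels inside the mask (noise below the medium RI)
    contribute zero and are counted in a warning.
    """
    if alpha_ml_per_g <= 0:
        raise ValueError("alpha must be positive")
    mask = np.asarray(mask, bool)
    delta_n = tomo.ri[mask] - tomo.n_medium
    n_neg = int(np.count_nonzero(delta_n < 0))
    if n_neg:
        warnings.warn(f"{n_neg} masked voxels below medium RI clipped to zero mass")
    return float(np.clip(delta_n, 0, None).sum()) * tomo.voxel_volume_um3 / alpha_ml_per_g


def dry_mass_from_phase(ph: QPIPhaseImage, alpha_ml_per_g: float = ALPHA_CELL_ML_PER_G) -> float:
    """Phase-projection dry mass in pg: λ/(2πα) · Σ φ · dA."""
    if alpha_ml_per_g <= 0:
        raise ValueError("alpha must be positive")
    pixel_area = ph.pixel_size_um**2
    return float(ph.phase.sum()) * pixel_area * ph.wavelength_um / (2.0 * np.pi * alpha_ml_per_g)


def phase_from_tomogram(tomo: Tomogram, wavelength_um: float, mask: np.ndarray | None = None) -> QPIPhaseImage:
    """Project a tomogram to the optical phase map φ = (2π/λ)·Σ_z Δn·dz.

    Used to cross-validate the two dry-mass routes; with ``mask`` the
    projection is restricted to masked voxels (Δn clipped at 0).
    """
    delta_n = np.clip(tomo.ri - tomo.n_medium, 0, None)
    if mask is not None:
        delta_n = np.where(np.asarray(mask, bool), delta_n, 0.0)
    opl = delta_n.sum(axis=0) * tomo.voxel_size_um[2]  # optical path length, µm
    phase = 2.0 * np.pi * opl / wavelength_um
    return QPIPhaseImage(phase=phase, wavelength_um=wavelength_um, pixel_size_um=tomo.voxel_size_um[0])


def segment_lipid(
    tomo: Tomogram,
    cell_mask: np.ndarray,
    ri_range: tuple[float, float] = LIPID_RI_RANGE,
    alpha_ml_per_g: float = ALPHA_LIPID_ML_PER_G,
) -> tuple[np.ndarray, float, float]:
    """Lipid voxels (inclusive RI band within the cell), their volume and dry mass."""
    lo, hi = ri_range
    lipid_mask = np.asarray(cell_mask, bool) & (tomo.ri >= lo) & (tomo.ri <= hi)
    vol = cell_volume(lipid_mask, tomo.voxel_size_um)
    dm = dry_mass_from_ri(tomo, lipid_mask, alpha_ml_per_g) if lipid_mask.any() else 0.0
    return lipid_mask, vol, dm


def analyze_tomogram(
    tomo: Tomogram,
    delta_n: float = 0.003,
    min_voxels: int = 100,
    alpha_cell: float = ALPHA_CELL_ML_PER_G,
    alpha_lipid: float = ALPHA_LIPID_ML_PER_G,
    lipid_ri_range: tuple[float, float] = LIPID_RI_RANGE,
) -> QpiMetrics:
    """Full QPI metric row for one tomogram (union of its cells)."""
    mask = segment_cell_3d(tomo, delta_n=delta_n, min_voxels=min_voxels)
    if not mask.any():
        return QpiMetrics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, alpha_cell, alpha_lipid, lipid_ri_range,
                          tomo.tomo_id, tomo.condition, tomo.time_point)
    _, lipid_vol, lipid_dm = segment_lipid(tomo, mask, lipid_ri_range, alpha_lipid)
    return QpiMetrics(
        volume_um3=cell_volume(mask, tomo.voxel_size_um),
        projected_area_um2=projected_area(mask, tomo.voxel_size_um),
        mean_thickness_um=mean_thickness(mask, tomo.voxel_size_um),
        dry_mass_pg=dry_mass_from_ri(tomo, mask, alpha_cell),
        lipid_volume_um3=lipid_vol,
        lipid_dry_mass_pg=lipid_dm,
        alpha_cell=alpha_cell,
        alpha_lipid=alpha_lipid,
        lipid_ri_range=lipid_ri_range,
        tomo_id=tomo.tomo_id,
        condition=tomo.condition,
        time_point=tomo.time_point,
    )
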