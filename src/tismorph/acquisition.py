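"""Acquisition geometry and study-design arithmetic.

Defaults reflect the acquisition settings the pipeline is built around:
105 µm × 105 µm NLO fields of view rastered at 300 × 300 pixels, and
80.470 µm × 80.470 µm × 39.666 µm holotomograms on an 848 × 848 × 210
voxel grid.
"""

from __future__ import annotations

NLO_FOV_UM: float = 105.0
NLO_FOV_PX: int = 300
QPI_EXTENT_UM: tuple[float, float, float] = (80.470, 80.470, 39.666)
QPI_GRID: tuple[int, int, int] = (848, 848, 210)
RI_BACKGROUND: float = 1.3342  # PBS medium
ALPHA_CELL_ML_PER_G: float = 0.19  # refractive increment of bulk cell matter
ALPHA_LIPID_ML_PER_G: float = 0.135
LIPID_RI_RANGE: tuple[float, float] = (1.40, 1.46)
TPEF_THRESHOLD_AU: float = 0.25
SRS_THRESHOLD: float = 2.2e-4  # ΔI/I


def pixel_size_um(fov_um: float = NLO_FOV_UM, n_px: int = NLO_FOV_PX) -> float:
    """Raster pixel pitch in µm (105 µm / 300 px = 0.35 µm)."""
    if fov_um <= 0 or n_px <= 0:
        raise ValueError("fov_um and n_px must be positive")
    return fov_um / n_px


def nyquist_resolution_um(pixel_um: float) -> float:
    """Coarsest lateral feature size faithfully sampled: twice the pixel pitch."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    return 2.0 * pixel_um


def qpi_voxel_size_um(
    extent_um: tuple[float, float, float] = QPI_EXTENT_UM,
    grid: tuple[int, int, int] = QPI_GRID,
) -> tuple[float, float, float]:
    """(dx, dy, dz) voxel pitch of the tomographic grid."""
    return tuple(e / n for e, n in zip(extent_um, grid))


def nlo_cells_per_condition(
    n_plates: int = 5, fovs_per_plate: int = 2, cells_per_fov: int = 10
) -> int:
    """Cell population per condition and time point in the NLO design."""
    return n_plates * fovs_per_plate * cells_per_fov


def qpi_cells_per_condition(n_dishes: int = 2, cells_per_dish: int = 75) -> int:
    """Cell population per condition and time point in the QPI design."""
    return n_dishes * cells_per_dish
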