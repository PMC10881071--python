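"""Seeded synthetic control/TIS phenotypes with full ground truth.

The generator produces the two kinds of input the pipeline consumes:

* multimodal NLO fields of view (default 300×300 px at 0.35 µm/px) with
  cells as dark elliptical footprints on a bright transmission
  background, a perinuclear-diffuse or punctate TPEF pattern, sparse
  bright SRS lipid droplets co-occurring with F-CARS spots over a
  nonresonant background, an E-CARS channel partially overlapping the
  TPEF pattern, plus injectable 1-pixel outliers and a serpentine
  (even-row) shift;
* 3-D RI tomograms (default 212×212×64 voxels over
  80.470 × 80.470 × 39.666 µm, i.e. the instrument grid downscaled 4×
  laterally) with ellipsoidal cells above the medium RI 1.3342 and
  embedded lipid spheres in the 1.40–1.46 RI band.

Signals are phenomenological: no coherent image formation or phase
retrieval is simulated. Every draw comes from one seeded generator, so
identical (params, seed) give bit-identical rasters, and the returned
:class:`GroundTruth` records the painted geometry exactly.

Named presets encode the control and TIS conditions per time point
(senescent cells become larger and flatter, their TPEF condenses from a
perinuclear ring into bright puncta covering less area, and lipid
droplets become more numerous, larger and clustered at late times).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io
from .acquisition import RI_BACKGROUND
from .preprocess import CHANNELS, MultimodalImage, apply_serpentine_shift
from .qpi import Tomogram


class PlacementError(RuntimeError):
    """Requested objects could not be placed without overlap."""


_DEFAULT_NOISE = {
    "TPEF": 0.02,
    "SRS": 3.0e-5,
    "FCARS": 0.02,
    "ECARS": 0.015,
    "transmission": 0.01,
    "ri": 5.0e-4,
}

# default tomographic grid: instrument extent on a 4x-downscaled lateral grid
QPI_SHAPE = (64, 212, 212)  # (z, y, x)
QPI_VOXEL_UM = (80.470 / 212, 80.470 / 212, 39.666 / 64)  # (dx, dy, dz)


@dataclass
class PhenotypeParams:
    """Generator knobs for one condition × time point."""

    condition: str = "control"  # "control" | "TIS"
    time_point: str = "0h"
    n_cells_per_fov: int = 8
    cell_radius_um: float = 7.5
    cell_thickness_um: float = 9.0  # QPI only (full thickness of the ellipsoid)
    tpef_pattern: str = "diffuse_perinuclear"  # or "punctate"
    tpef_area_frac_target: float = 0.15
    tpef_peak: float = 1.0  # a.u.
    droplet_density_per_cell: float = 1.0
    droplet_radius_um: tuple[float, float] = (0.6, 0.05)  # (mean, sd)
    droplet_srs_amp: float = 2.0e-3  # ΔI/I
    nrb_level: float = 0.3  # F-CARS nonresonant background inside cells, a.u.
    ecars_overlap_frac: float = 0.7  # fraction of TPEF pattern echoed in E-CARS
    droplet_ecars_amp: float = 0.0  # E-CARS level of lipid droplets (TIS: strong)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    outlier_rate: float = 0.0
    serpentine_shift_px: int = 0
    lipid_ri: tuple[float, float] = (1.40, 1.46)
    cell_ri: tuple[float, float] = (1.345, 1.36)
    background_ri: float = RI_BACKGROUND
    pixel_size_um: float = 0.35
    fov_px: int = 300
    n_cells_per_tomogram: int = 1
    qpi_shape: tuple[int, int, int] = QPI_SHAPE  # (z, y, x)
    qpi_voxel_um: tuple[float, float, float] = QPI_VOXEL_UM  # (dx, dy, dz)
    shape_jitter: float = 0.1  # relative sd of cell radii between cells/FOVs

    def __post_init__(self) -> None:
        if isinstance(self.noise_sd, (int, float)):
            self.noise_sd = {k: float(self.noise_sd) for k in _DEFAULT_NOISE}
        else:
            self.noise_sd = {**_DEFAULT_NOISE, **dict(self.noise_sd)}
        self.validate()

    def validate(self) -> None:
        if self.condition not in ("control", "TIS"):
            raise ValueError("condition must be 'control' or 'TIS'")
        if self.tpef_pattern not in ("diffuse_perinuclear", "punctate"):
            raise ValueError(f"unknown tpef_pattern {self.tpef_pattern!r}")
        for name in ("tpef_area_frac_target", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("cell_radius_um", "cell_thickness_um", "tpef_peak", "droplet_srs_amp",
                     "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells_per_fov < 0 or self.droplet_density_per_cell < 0:
            raise ValueError("cell and droplet counts must be non-negative")
        if self.droplet_radius_um[0] <= 0 or self.droplet_radius_um[1] < 0:
            raise ValueError("droplet_radius_um must be (positive mean, non-negative sd)")
        lo, hi = self.lipid_ri
        if not (1.33 <= lo <= hi <= 1.50):
            raise ValueError("lipid_ri must be an ordered range within [1.33, 1.50]")
        if not (0 <= self.shape_jitter < 1):
            raise ValueError("shape_jitter must be in [0, 1)")

    def replace(self, **kw) -> "PhenotypeParams":
        return dataclasses.replace(self, **kw)


@dataclass
class DropletTruth:
    center_px: tuple[float, float]  # (row, col)
    radius_px: float
    amplitude: float  # ΔI/I


@dataclass
class CellTruth:
    centroid_px: tuple[float, float] | None = None
    radii_px: tuple[float, float] | None = None  # (row semi-axis, col semi-axis)
    footprint_area_px: int = 0
    tpef_area_frac: float = 0.0
    droplets: list[DropletTruth] = field(default_factory=list)
    # QPI-only fields
    center_vox: tuple[float, float, float] | None = None  # (z, y, x)
    semiaxes_um: tuple[float, float, float] | None = None  # (a, b, c); c along z
    cell_ri: float | None = None
    volume_um3: float | None = None
    dry_mass_pg: float | None = None
    mean_thickness_um: float | None = None
    lipid_spheres: list[dict] = field(default_factory=list)
    lipid_volume_um3: float = 0.0
    lipid_dry_mass_pg: float = 0.0


@dataclass
class GroundTruth:
    """Everything needed to verify the generator output downstream.

    NLO outlier coordinates refer to the corrected (de-serpentined)
    frame: outliers are injected before the row shift, as a detector
    would produce them during the scan.
    """

    seed: int
    kind: str  # "nlo" | "qpi"
    cells: list[CellTruth] = field(default_factory=list)
    serpentine_shift_px: int = 0
    outlier_pixels: list[tuple[str, int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    min_sep: np.ndarray,
    max_tries: int = 400,
) -> np.ndarray:
    """Rejection-sample ``n`` centers with pairwise separation; raises on failure."""
    centers: list[np.ndarray] = []
    for i in range(n):
        for _ in range(max_tries):
            c = rng.uniform(bounds_lo, bounds_hi)
            if all(np.linalg.norm(c - p) >= (min_sep[i] + min_sep[j])
                   for j, p in enumerate(centers)):
                centers.append(c)
                break
        else:
            raise PlacementError(f"could not place object {i + 1} of {n} without overlap")
    return np.asarray(centers) if centers else np.empty((0, bounds_lo.size))


def generate_nlo_fov(params: PhenotypeParams, seed: int) -> tuple[MultimodalImage, GroundTruth]:
    """One multimodal FOV plus its ground truth (deterministic in (params, seed))."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.fov_px
    px = params.pixel_size_um
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    trans = np.ones((n, n))
    tpef = np.full((n, n), 0.02)
    srs = np.zeros((n, n))
    fcars = np.full((n, n), 0.05)
    ecars = np.full((n, n), 0.05)
    # sub-resolution features composited after the optical blur
    tpef_sharp = np.zeros((n, n))
    ecars_sharp = np.zeros((n, n))

    truth = GroundTruth(seed=int(seed), kind="nlo",
                        serpentine_shift_px=int(params.serpentine_shift_px))

    r_mean_px = params.cell_radius_um / px
    if params.n_cells_per_fov > 0:
        radii = r_mean_px * np.clip(
            1.0 + params.shape_jitter * rng.standard_normal(params.n_cells_per_fov), 0.5, 1.5
        )
        margin = radii.max() + 2
        if 2 * margin >= n:
            raise PlacementError("cells too large for the FOV")
        centers = _place_centers(
            rng, params.n_cells_per_fov,
            np.array([margin, margin]), np.array([n - margin, n - margin]),
            min_sep=radii * 1.02,
        )
    else:
        radii, centers = np.empty(0), np.empty((0, 2))

    footprints: list[np.ndarray] = []
    speckles: list[tuple[float, float]] = []
    # per-FOV biological variability of the mitochondrial E-CARS/TPEF overlap
    ov_fov = float(np.clip(rng.normal(params.ecars_overlap_frac, 0.03), 0.05, 0.98))
    for (cy, cx), r in zip(centers, radii):
        ry = r * np.clip(1.0 + 0.5 * params.shape_jitter * rng.standard_normal(), 0.7, 1.3)
        rx = r
        norm2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        inside = norm2 <= 1.0
        area_px = int(inside.sum())
        # transmission drop, darker toward the cell center
        trans[inside] = 0.55 + 0.25 * norm2[inside]
        tpef[inside] = np.maximum(tpef[inside], 0.10)  # sub-threshold cytoplasm
        fcars[inside] = np.maximum(fcars[inside], params.nrb_level)

        cell = CellTruth(centroid_px=(float(cy), float(cx)), radii_px=(float(ry), float(rx)),
                         footprint_area_px=area_px)
        footprints.append(inside)

        # --- TPEF pattern (painted region stays above the 0.25 a.u. threshold)
        frac = float(np.clip(
            params.tpef_area_frac_target * rng.lognormal(0.0, 0.10), 0.0, 0.85))
        peak = params.tpef_peak * rng.lognormal(0.0, 0.08)
        # E-CARS shares part of the TPEF pattern (common mitochondrial source):
        # a coherent fraction ``ecars_overlap_frac`` of the pattern is echoed
        # at a fixed E-CARS level, and an area-matched complement of
        # E-CARS-only scatterers is added elsewhere in the cell, so that under
        # the quadrant statistics M1 ≈ M2 ≈ overlap fraction when droplets do
        # not contribute to E-CARS.
        ov = ov_fov
        ecars_level = 0.6
        tpef_pattern = np.zeros((n, n), bool)
        if frac > 0:
            if params.tpef_pattern == "diffuse_perinuclear":
                # annulus around the nucleus (normalised radius 0.35)
                rho_in2 = 0.35**2
                rho_out2 = min(frac + rho_in2, 1.0)
                ring = inside & (norm2 >= rho_in2) & (norm2 <= rho_out2)
                tpef[ring] = np.maximum(tpef[ring], 0.5 * peak)
                tpef_pattern = ring
                # coherent patches via a thresholded smooth random field
                fld = ndimage.gaussian_filter(rng.standard_normal((n, n)), 3.0)
                if ring.any():
                    echo = ring & (fld >= np.quantile(fld[ring], 1.0 - ov))
                    ecars[echo] = np.maximum(ecars[echo], ecars_level)
                nonpat = inside & ~ring
                n_extra = int(round((1.0 - ov) * ring.sum()))
                if n_extra > 0 and nonpat.sum() > n_extra:
                    cut = np.partition(fld[nonpat], -n_extra)[-n_extra]
                    sel = nonpat & (fld >= cut)
                    ecars[sel] = np.maximum(ecars[sel], ecars_level)
            else:  # punctate: compact bright puncta with a parabolic profile,
                # composited pixel-sharp after the blur (dense sub-µm granules)
                rp = max(2.0, 0.7 / px)
                punct_area = np.pi * rp**2
                n_puncta = max(1, int(round(frac * area_px / punct_area)))
                # whole puncta are echoed in E-CARS, plus E-CARS-only twins
                n_spots = n_puncta + int(round((1.0 - ov) * n_puncta))
                for i in range(n_spots):
                    theta = rng.uniform(0, 2 * np.pi)
                    rho = np.sqrt(rng.uniform(0, 1)) * 0.85
                    py, pxc = cy + rho * ry * np.sin(theta), cx + rho * rx * np.cos(theta)
                    d2 = (yy - py) ** 2 + (xx - pxc) ** 2
                    spot = d2 <= rp**2
                    if i < n_puncta:
                        prof = peak * (1.0 - 0.5 * d2 / rp**2)
                        tpef_sharp[spot] = np.maximum(tpef_sharp[spot], prof[spot])
                        tpef_pattern |= spot
                        if rng.uniform() < ov:
                            ecars_sharp[spot] = np.maximum(ecars_sharp[spot], ecars_level)
                    else:
                        ecars_sharp[spot] = np.maximum(ecars_sharp[spot], ecars_level)

        # --- SRS lipid droplets (geometry drawn now, painted sharp after the blur)
        n_drop = rng.poisson(params.droplet_density_per_cell)
        for _ in range(n_drop):
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1)) * 0.85
            dy, dx = cy + rho * ry * np.sin(theta), cx + rho * rx * np.cos(theta)
            r_um = max(0.5 * px, rng.normal(*params.droplet_radius_um))
            amp = params.droplet_srs_amp * rng.lognormal(0.0, 0.10)
            cell.droplets.append(DropletTruth((float(dy), float(dx)), float(r_um / px),
                                              float(amp)))

        # --- small NRB-amplified F-CARS speckles without SRS counterpart
        n_speck = rng.poisson(0.02 * area_px)
        for _ in range(n_speck):
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1)) * 0.9
            sy, sx = cy + rho * ry * np.sin(theta), cx + rho * rx * np.cos(theta)
            speckles.append((sy, sx))

        truth.cells.append(cell)

    # mimic the finite optical resolution of the smooth content; droplets and
    # speckles are near/below the resolution limit and stay pixel-sharp
    for raster in (trans, tpef, fcars, ecars):
        raster[...] = ndimage.gaussian_filter(raster, 0.6)
    np.maximum(tpef, tpef_sharp, out=tpef)
    np.maximum(ecars, ecars_sharp, out=ecars)
    for cell, inside in zip(truth.cells, footprints):
        cell.tpef_area_frac = float((tpef[inside] > 0.25).sum()) / max(cell.footprint_area_px, 1)
        for d in cell.droplets:
            dy, dx = d.center_px
            disk = (yy - dy) ** 2 + (xx - dx) ** 2 <= d.radius_px**2
            srs[disk] = np.maximum(srs[disk], d.amplitude)
            fcars[disk] = np.maximum(fcars[disk], params.nrb_level + 0.6)
            if params.droplet_ecars_amp > 0:
                ecars[disk] = np.maximum(ecars[disk], params.droplet_ecars_amp)
    for sy, sx in speckles:
        spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= 1.0
        fcars[spot] = np.maximum(fcars[spot], params.nrb_level + 0.62)

    channels = {"TPEF": tpef, "SRS": srs, "FCARS": fcars, "ECARS": ecars,
                "transmission": trans}
    for name in CHANNELS:
        sd = params.noise_sd.get(name, 0.0)
        noise = rng.normal(0.0, 1.0, size=(n, n)) * sd
        channels[name] = channels[name] + noise
    channels["transmission"] = np.clip(channels["transmission"], 1e-3, None)

    # 1-pixel outliers (cosmic rays): injected in scan order, before the shift
    for name in CHANNELS:
        n_out = rng.binomial(n * n, params.outlier_rate)
        if n_out == 0:
            continue
        flat_idx = rng.choice(n * n, size=n_out, replace=False)
        ch = channels[name]
        spread = float(np.ptp(ch)) + 1.0
        bright = rng.uniform(size=n_out) < 0.5
        vals = np.where(bright, ch.max() + 10.0 * spread, ch.min() - 10.0 * spread)
        ch.ravel()[flat_idx] = vals
        truth.outlier_pixels.extend(
            (name, int(i // n), int(i % n)) for i in flat_idx
        )

    if params.serpentine_shift_px != 0:
        channels = {
            name: apply_serpentine_shift(ch, params.serpentine_shift_px)
            for name, ch in channels.items()
        }

    image = MultimodalImage(channels=channels, pixel_size_um=px,
                            condition=params.condition, time_point=params.time_point)
    return image, truth


def paint_droplet_mask(truth: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Binary raster of the droplet disks recorded in an NLO ground truth."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    mask = np.zeros(shape, bool)
    for cell in truth.cells:
        for d in cell.droplets:
            cy, cx = d.center_px
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= d.radius_px**2
    return mask


def generate_qpi_tomogram(params: PhenotypeParams, seed: int) -> tuple[Tomogram, GroundTruth]:
    """One RI tomogram plus analytic ground truth (volume, dry mass, thickness)."""
    params.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.qpi_shape
    dx, dy, dz = params.qpi_voxel_um
    extent = np.array([nx * dx, ny * dy, nz * dz])  # (x, y, z) µm
    ri = np.full((nz, ny, nx), params.background_ri)
    truth = GroundTruth(seed=int(seed), kind="qpi")

    n_cells = params.n_cells_per_tomogram
    if n_cells > 0:
        a_list = params.cell_radius_um * np.clip(
            1.0 + params.shape_jitter * rng.standard_normal(n_cells), 0.5, 1.5)
        c_list = 0.5 * params.cell_thickness_um * np.clip(
            1.0 + params.shape_jitter * rng.standard_normal(n_cells), 0.5, 1.5)
        max_r = np.maximum(a_list, c_list)
        lo = np.stack([a_list, a_list, c_list], axis=1)
        if np.any(2 * lo.max(axis=0) >= extent):
            raise PlacementError("cell does not fit into the tomogram volume")
        centers = _place_centers(
            rng, n_cells, lo[0] * 0 + lo.max(axis=0), extent - lo.max(axis=0),
            min_sep=max_r * 1.02)
    else:
        a_list = c_list = np.empty(0)
        centers = np.empty((0, 3))

    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    zs = (np.arange(nz) + 0.5) * dz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    vox_vol = dx * dy * dz
    alpha_cell, alpha_lipid = 0.19, 0.135
    for (cx, cy, cz), a, c in zip(centers, a_list, c_list):
        b = a
        inside = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
        n_cell = rng.uniform(*params.cell_ri)
        ri[inside] = n_cell
        v_cell = 4.0 / 3.0 * np.pi * a * b * c

        cell = CellTruth(
            center_vox=(float(cz / dz), float(cy / dy), float(cx / dx)),
            semiaxes_um=(float(a), float(b), float(c)),
            cell_ri=float(n_cell),
            volume_um3=float(v_cell),
            mean_thickness_um=float(4.0 * c / 3.0),
        )

        n_lip = rng.poisson(params.droplet_density_per_cell)
        placed: list[tuple[np.ndarray, float]] = []
        for _ in range(n_lip):
            r_um = max(2 * min(dx, dz), rng.normal(*params.droplet_radius_um))
            ok = False
            for _ in range(100):
                # sample inside the shrunken ellipsoid so the sphere stays in the cell
                sa, sb, sc = max(a - r_um, 0.1), max(b - r_um, 0.1), max(c - r_um, 0.1)
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                rad = rng.uniform(0, 1) ** (1 / 3)
                p = np.array([cx, cy, cz]) + rad * u * np.array([sa, sb, sc])
                if ((p[0] - cx) / max(a - r_um, 1e-6)) ** 2 + \
                   ((p[1] - cy) / max(b - r_um, 1e-6)) ** 2 + \
                   ((p[2] - cz) / max(c - r_um, 1e-6)) ** 2 > 1.0:
                    continue
                if all(np.linalg.norm(p - q) >= r_um + rq for q, rq in placed):
                    ok = True
                    break
            if not ok:
                raise PlacementError("could not place a lipid sphere inside the cell")
            n_lipid = rng.uniform(*params.lipid_ri)
            sphere = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 <= r_um**2
            ri[sphere] = n_lipid
            placed.append((p, r_um))
            v_lip = 4.0 / 3.0 * np.pi * r_um**3
            cell.lipid_spheres.append(
                {"center_um": [float(v) for v in p], "radius_um": float(r_um),
                 "ri": float(n_lipid)})
            cell.lipid_volume_um3 += float(v_lip)
            cell.lipid_dry_mass_pg += float((n_lipid - params.background_ri) * v_lip / alpha_lipid)

        # pipeline-equivalent dry mass: cell matter plus lipid voxels at alpha_cell
        v_lip_tot = cell.lipid_volume_um3
        dm = (n_cell - params.background_ri) * (v_cell - v_lip_tot) / alpha_cell
        dm += sum(
            (s["ri"] - params.background_ri) * 4.0 / 3.0 * np.pi * s["radius_um"] ** 3
            for s in cell.lipid_spheres
        ) / alpha_cell
        cell.dry_mass_pg = float(dm)
        truth.cells.append(cell)

    sd = params.noise_sd.get("ri", 0.0)
    if sd > 0:
        ri = ri + rng.normal(0.0, sd, size=ri.shape)
        ri = np.clip(ri, 1.0, None)

    tomo = Tomogram(ri=ri, voxel_size_um=(dx, dy, dz), n_medium=params.background_ri,
                    condition=params.condition, time_point=params.time_point)
    _ = vox_vol  # voxel volume retained for readers; analytic truths are closed-form
    return tomo, truth


# ---------------------------------------------------------------------------
# presets: emulation targets for the control and TIS phenotypes per time point

NLO_TIME_POINTS = ("0h", "12h", "24h", "72h", "7d")
QPI_TIME_POINTS = ("0h", "24h", "48h", "72h", "7d")


def nlo_preset(condition: str, time_point: str) -> PhenotypeParams:
    """NLO generator parameters for one condition × time point.

    Controls keep a perinuclear-diffuse TPEF ring over ~15 % of the
    cell area and rare sub-µm droplets at all times. TIS cells shift to
    bright TPEF puncta over shrinking area (→ ~4 % at 7 d) while lipid
    droplets grow in number, size and clustering (SRS-positive area
    ~2-3 % at 72 h, ~20 % at 7 d).
    """
    base = dict(condition=condition, time_point=time_point, outlier_rate=2e-4,
                serpentine_shift_px=3)
    if condition == "control" or time_point == "0h":
        return PhenotypeParams(**base)
    tis = {
        "12h": dict(tpef_area_frac_target=0.13, tpef_peak=1.3,
                    droplet_density_per_cell=1.2),
        "24h": dict(tpef_pattern="punctate", droplet_ecars_amp=0.9, tpef_area_frac_target=0.09, tpef_peak=2.5,
                    droplet_density_per_cell=2.0, droplet_radius_um=(0.65, 0.05),
                    cell_radius_um=8.0, ecars_overlap_frac=0.75),
        "72h": dict(tpef_pattern="punctate", droplet_ecars_amp=0.9, tpef_area_frac_target=0.055, tpef_peak=6.0,
                    droplet_density_per_cell=6.0, droplet_radius_um=(0.70, 0.06),
                    cell_radius_um=9.0, n_cells_per_fov=7, ecars_overlap_frac=0.8),
        "7d": dict(tpef_pattern="punctate", droplet_ecars_amp=0.9, tpef_area_frac_target=0.04, tpef_peak=16.0,
                   droplet_density_per_cell=30.0, droplet_radius_um=(0.80, 0.08),
                   cell_radius_um=10.0, n_cells_per_fov=5, ecars_overlap_frac=0.85),
    }
    if time_point not in tis:
        raise KeyError(f"no TIS preset for time point {time_point!r}")
    return PhenotypeParams(**{**base, **tis[time_point]})


def qpi_preset(condition: str, time_point: str) -> PhenotypeParams:
    """QPI generator parameters: TIS cells enlarge, flatten and accumulate lipid."""
    base = dict(condition=condition, time_point=time_point, n_cells_per_fov=0,
                n_cells_per_tomogram=1, cell_radius_um=9.0, cell_thickness_um=9.0,
                droplet_density_per_cell=2.0, droplet_radius_um=(0.8, 0.1))
    if condition == "control" or time_point == "0h":
        return PhenotypeParams(**base)
    tis = {
        "24h": dict(cell_radius_um=10.0, cell_thickness_um=8.5,
                    droplet_density_per_cell=3.0, droplet_radius_um=(0.9, 0.1)),
        "48h": dict(cell_radius_um=11.0, cell_thickness_um=8.0,
                    droplet_density_per_cell=5.0, droplet_radius_um=(1.0, 0.12)),
        "72h": dict(cell_radius_um=12.5, cell_thickness_um=7.0,
                    droplet_density_per_cell=8.0, droplet_radius_um=(1.1, 0.12)),
        "7d": dict(cell_radius_um=14.0, cell_thickness_um=6.0,
                   droplet_density_per_cell=12.0, droplet_radius_um=(1.2, 0.15)),
    }
    if time_point not in tis:
        raise KeyError(f"no TIS preset for time point {time_point!r}")
    return PhenotypeParams(**{**base, **tis[time_point]})


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def generate_timecourse(
    design: list,
    seed: int,
    out_dir: str | Path,
    modality: str = "nlo",
) -> pd.DataFrame:
    """Write a seeded dataset for a study design and return its manifest.

    ``design`` is a list of per-plate entries ``(params, n_fovs)`` or
    ``(params, n_fovs, plate_label)``; without an explicit label, plates
    are numbered consecutively within each condition × time point. Each
    FOV (or tomogram, for ``modality="qpi"``) is written with a ground
    truth JSON sidecar; the manifest (condition, time_point, plate, fov,
    path, truth_path, seed) is written as ``manifest.csv``.
    """
    if not design:
        raise ValueError("empty design")
    if modality not in ("nlo", "qpi"):
        raise ValueError("modality must be 'nlo' or 'qpi'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    auto_plate: dict[tuple[str, str], int] = {}
    for entry in design:
        if len(entry) == 3:
            params, n_fovs, plate = entry
        else:
            params, n_fovs = entry
            key = (params.condition, params.time_point)
            auto_plate[key] = auto_plate.get(key, 0) + 1
            plate = f"p{auto_plate[key]}"
        entries.append((params, int(n_fovs), str(plate)))

    n_total = sum(n for _, n, _ in entries)
    seeds = iter(_child_seeds(seed, n_total))
    rows = []
    seen: set[tuple[str, str, str, int]] = set()
    for params, n_fovs, plate in entries:
        for f in range(n_fovs):
            key = (params.condition, params.time_point, plate, f)
            if key in seen:
                raise ValueError(f"duplicate (condition, time, plate, fov) key {key}")
            seen.add(key)
            s = next(seeds)
            stem = f"{params.condition}_{params.time_point}_{plate}_fov{f}"
            if modality == "nlo":
                image, truth = generate_nlo_fov(params, s)
                image.fov_id = stem
                path = io.write_multimodal_tiff(image, out_dir / f"{stem}.tif")
            else:
                tomo, truth = generate_qpi_tomogram(params, s)
                tomo.tomo_id = stem
                path = io.write_tomogram_h5(tomo, out_dir / f"{stem}.h5")
            truth_path = io.write_json(truth.as_dict(), out_dir / f"{stem}.truth.json")
            rows.append(dict(condition=params.condition, time_point=params.time_point,
                             plate=plate, fov=f, path=str(path),
                             truth_path=str(truth_path), seed=s))
    manifest = pd.DataFrame(rows)
    io.write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
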