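"""Per-FOV NLO metrics: cell footprint, mitochondrial (TPEF) indices and
lipid-droplet (SRS) particle statistics.

Conventions
-----------
* The cell footprint is segmented from linear transmission, where cells
  are darker than the substrate.
* TPEF metrics use a universal intensity threshold (default 0.25 a.u.)
  separating coenzyme fluorescence from diffuse background; SRS lipid
  metrics use a universal ΔI/I threshold (default 2.2e-4) separating
  dense vesicles from cytoplasmic lipid and background.
* "Clusters" are 8-connected above-threshold SRS components of at least
  5 px²; "quasi-single droplets" are the subset with circularity
  4πA/P² in [0.3, 1], i.e. compact blobs plausibly corresponding to a
  single vesicle. The perimeter P is the crack perimeter (total length
  of exposed pixel edges), so e.g. a 1×20 px line has P = 42 and
  circularity ≈ 0.14.
* The mitochondrial aggregation index is Max(TPEF) × [Area(TPEF)/Area(Cell)]%,
  where Max(TPEF) is the mean of the top-decile in-cell pixel values —
  an outlier-resistant maximum that scales with the peak density of
  fluorescent scatterers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .acquisition import SRS_THRESHOLD, TPEF_THRESHOLD_AU


class EmptyMaskWarning(UserWarning):
    pass


@dataclass
class CellMask:
    """Binary cell footprint for one FOV."""

    mask: np.ndarray
    pixel_size_um: float = 0.35
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def cell_area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_area_um2(self) -> float:
        return self.cell_area_px * self.pixel_size_um**2

    def require_nonempty(self) -> None:
        if self.cell_area_px == 0:
            raise ValueError("empty cell mask")


@dataclass
class Droplet:
    label: int
    area_px: int
    area_um2: float
    perimeter_px: float
    circularity: float
    centroid: tuple[float, float]
    quasi_single: bool


@dataclass
class DropletSet:
    """Labeled SRS lipid components of one FOV (clusters ≥ min area)."""

    droplets: list[Droplet]
    labels: np.ndarray
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.droplets)

    def __iter__(self):
        return iter(self.droplets)

    @property
    def quasi_single(self) -> list[Droplet]:
        return [d for d in self.droplets if d.quasi_single]


@dataclass
class NloMetrics:
    tpef_area_pct: float
    tpef_max: float
    aggregation_index: float
    tpef_mean: float
    srs_area_pct: float
    mean_quasi_single_area_um2: float  # NaN when no quasi-single droplet
    cluster_count: int
    clusters_per_cell_area: float  # count per µm² of cell footprint
    cell_area_um2: float
    fov_id: str = ""
    condition: str = ""
    time_point: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _drop_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_size`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def segment_cells(
    transmission: np.ndarray,
    pixel_size_um: float = 0.35,
    closing_radius_px: int = 2,
    min_component_px: int = 50,
) -> CellMask:
    """Segment cells as below-Otsu (dark) transmission regions.

    Otsu thresholding on the transmission histogram, morphological
    closing (disk radius 2 px), hole filling, then removal of components
    smaller than 50 px². A constant raster cannot be thresholded and
    yields an empty mask with a warning flag.
    """
    transmission = np.asarray(transmission, dtype=float)
    if np.ptp(transmission) == 0:
        warnings.warn("constant transmission raster: empty cell mask", EmptyMaskWarning)
        return CellMask(np.zeros(transmission.shape, bool), pixel_size_um, empty_warning=True)
    thr = threshold_otsu(transmission)
    mask = transmission < thr
    if closing_radius_px > 0:
        mask = ndimage.binary_closing(mask, structure=disk(closing_radius_px))
    mask = ndimage.binary_fill_holes(mask)
    mask = _drop_small_components(mask, min_component_px)
    empty = not mask.any()
    if empty:
        warnings.warn("cell segmentation produced an empty mask", EmptyMaskWarning)
    return CellMask(mask, pixel_size_um, empty_warning=empty)


def area_fraction_pct(channel: np.ndarray, mask: CellMask, threshold: float) -> float:
    """Percent of cell-footprint pixels strictly above ``threshold``."""
    mask.require_nonempty()
    vals = np.asarray(channel, dtype=float)[mask.mask]
    return 100.0 * float(np.count_nonzero(vals > threshold)) / vals.size


def top_decile_max(channel: np.ndarray, mask: CellMask) -> float:
    """Mean of the ⌈10 %⌉ highest in-mask pixel values."""
    mask.require_nonempty()
    vals = np.asarray(channel, dtype=float)[mask.mask]
    k = math.ceil(0.1 * vals.size)
    return float(np.partition(vals, vals.size - k)[vals.size - k :].mean())


def aggregation_index(tpef: np.ndarray, mask: CellMask, threshold: float = TPEF_THRESHOLD_AU) -> float:
    """Max(TPEF) × [Area(TPEF)/Area(Cell)]% (a.u. × percent)."""
    return top_decile_max(tpef, mask) * area_fraction_pct(tpef, mask, threshold)


def mean_intensity(channel: np.ndarray, mask: CellMask) -> float:
    """Arithmetic mean over the cell footprint (no thresholding)."""
    mask.require_nonempty()
    return float(np.asarray(channel, dtype=float)[mask.mask].mean())


def crack_perimeter(component: np.ndarray) -> float:
    """Total length of exposed pixel edges of a binary component.

    Every object pixel contributes 4 unit edges minus 2 per 4-adjacent
    object neighbour pair; for a 1×n line this gives 2(n+1).
    """
    m = np.asarray(component, dtype=bool)
    area = int(m.sum())
    adj = int(np.count_nonzero(m[1:, :] & m[:-1, :])) + int(np.count_nonzero(m[:, 1:] & m[:, :-1]))
    return float(4 * area - 2 * adj)


def detect_droplets(
    srs: np.ndarray,
    mask: CellMask,
    threshold: float = SRS_THRESHOLD,
    min_area_px: int = 5,
    circ_range: tuple[float, float] = (0.3, 1.0),
    connectivity: int = 8,
) -> DropletSet:
    """Detect lipid clusters and flag quasi-single droplets.

    In-mask SRS pixels strictly above ``threshold`` are labeled
    (8-connected by default); components of at least ``min_area_px``
    are clusters. A cluster is quasi-single when its circularity
    4πA/P² (clamped at 1.0) lies inside ``circ_range`` (inclusive).
    """
    mask.require_nonempty()
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = mask.mask & (np.asarray(srs, dtype=float) > threshold)
    labels = label(binary, connectivity=2 if connectivity == 8 else 1)
    droplets: list[Droplet] = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 0
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        next_id += 1
        keep[prop.label] = next_id
        comp = labels[prop.slice] == prop.label
        perim = crack_perimeter(comp)
        circ = 4.0 * math.pi * prop.area / perim**2
        circ_clamped = min(circ, 1.0)
        droplets.append(
            Droplet(
                label=next_id,
                area_px=int(prop.area),
                area_um2=float(prop.area) * mask.pixel_size_um**2,
                perimeter_px=perim,
                circularity=float(circ),
                centroid=tuple(prop.centroid),
                quasi_single=circ_range[0] <= circ_clamped <= circ_range[1],
            )
        )
    return DropletSet(droplets=droplets, labels=keep[labels], pixel_size_um=mask.pixel_size_um)


def droplet_summaries(droplets: DropletSet, mask: CellMask) -> dict:
    """Aggregate droplet statistics over the FOV cell footprint.

    ``mean_quasi_single_area_um2`` is NaN (missing) when no component
    passes the circularity filter — a FOV without compact droplets has
    no mean droplet size, not a zero one.
    """
    mask.require_nonempty()
    total_area_px = sum(d.area_px for d in droplets)
    quasi = droplets.quasi_single
    return {
        "srs_area_pct": 100.0 * total_area_px / mask.cell_area_px,
        "mean_quasi_single_area_um2": float(np.mean([d.area_um2 for d in quasi])) if quasi else float("nan"),
        "cluster_count": len(droplets),
        "clusters_per_cell_area": len(droplets) / mask.cell_area_um2,
    }


def quantify_fov(
    image,
    tpef_threshold: float = TPEF_THRESHOLD_AU,
    srs_threshold: float = SRS_THRESHOLD,
    min_area_px: int = 5,
    circ_range: tuple[float, float] = (0.3, 1.0),
    closing_radius_px: int = 2,
    min_component_px: int = 50,
) -> NloMetrics:
    """Full NLO metric row for one preprocessed multimodal FOV."""
    mask = segment_cells(
        image["transmission"],
        pixel_size_um=image.pixel_size_um,
        closing_radius_px=closing_radius_px,
        min_component_px=min_component_px,
    )
    mask.require_nonempty()
    tpef = image["TPEF"]
    srs = image["SRS"]
    droplets = detect_droplets(srs, mask, srs_threshold, min_area_px, circ_range)
    summ = droplet_summaries(droplets, mask)
    return NloMetrics(
        tpef_area_pct=area_fraction_pct(tpef, mask, tpef_threshold),
        tpef_max=top_decile_max(tpef, mask),
        aggregation_index=aggregation_index(tpef, mask, tpef_threshold),
        tpef_mean=mean_intensity(tpef, mask),
        srs_area_pct=summ["srs_area_pct"],
        mean_quasi_single_area_um2=summ["mean_quasi_single_area_um2"],
        cluster_count=summ["cluster_count"],
        clusters_per_cell_area=summ["clusters_per_cell_area"],
        cell_area_um2=mask.cell_area_um2,
        fov_id=image.fov_id,
        condition=image.condition,
        time_point=image.time_point,
    )
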