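"""Raw NLO image corrections.

Three corrections are applied to every raster before quantification:

1. 1-pixel outlier removal — isolated dark/bright pixels (cosmic rays,
   detector spikes) are replaced by their 3×3 neighbourhood median when
   they deviate from it by more than ``z_thresh`` robust standard
   deviations (MAD-scaled).
2. Serpentine correction — bidirectional stage scanning shifts the
   reverse-scan (even-indexed) rows laterally; the shift is estimated by
   integer cross-correlation against the adjacent forward rows and
   undone by a circular shift.
3. SRG normalisation — the lock-in stimulated-Raman-gain signal ΔI
   (V RMS) is divided pixelwise by the Stokes transmission I (V) to give
   the dimensionless ΔI/I raster used for all lipid metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# canonical channel names, in on-disk page order
CHANNELS = ("TPEF", "SRS", "FCARS", "ECARS", "transmission")

_MAD_TO_SD = 1.4826  # consistency factor: MAD -> sd for a normal distribution


class ConstantRasterWarning(UserWarning):
    """Raised (as a warning) when a raster carries no structure to estimate from."""


@dataclass
class MultimodalImage:
    """Co-registered named 2-D channels for one field of view.

    All channels share a pixel grid; the modalities are acquired
    simultaneously, so no registration step is needed or provided.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.35
    fov_id: str = ""
    condition: str = ""
    time_point: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        self.channels = {n: np.asarray(ch, dtype=float) for n, ch in self.channels.items()}
        srs = self.channels.get("SRS")
        if srs is not None and not np.all(np.isfinite(srs)):
            raise ValueError("SRS channel contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _require_finite(raster: np.ndarray) -> np.ndarray:
    raster = np.asarray(raster, dtype=float)
    bad = ~np.isfinite(raster)
    if bad.any():
        coords = np.argwhere(bad)[:10].tolist()
        raise ValueError(f"non-finite input pixels at (row, col) {coords}")
    return raster


def _window_view(raster: np.ndarray) -> np.ndarray:
    """(H, W, 3, 3) view of edge-padded 3×3 neighbourhoods."""
    padded = np.pad(raster, 1, mode="reflect")
    return np.lib.stride_tricks.sliding_window_view(padded, (3, 3))


def remove_outlier_pixels(raster: np.ndarray, z_thresh: float = 5.0) -> np.ndarray:
    """Replace isolated extreme pixels by their 3×3 neighbourhood median.

    A pixel is an outlier when ``|x - med| > z_thresh * 1.4826 * MAD*``
    where ``med`` is the median of its 3×3 neighbourhood (pixel
    included; borders reflected) and ``MAD*`` is the neighbourhood
    median absolute deviation floored at the image-wide median of the
    local MADs. The floor regularises the nine-sample MAD, which
    otherwise collapses by chance on pure noise and flags ordinary
    fluctuations; on a globally flat raster the floor is zero and any
    deviating pixel is replaced, the intended cosmic-ray behaviour.
    Non-flagged pixels pass through untouched, so the filter is
    idempotent on its own output.
    """
    raster = _require_finite(raster)
    if raster.ndim != 2 or min(raster.shape) < 3:
        raise ValueError("raster must be 2-D and at least 3x3")
    win = _window_view(raster)
    med = np.median(win, axis=(2, 3))
    mad = np.median(np.abs(win - med[..., None, None]), axis=(2, 3))
    dev = np.abs(raster - med)
    scale = _MAD_TO_SD * np.maximum(mad, np.median(mad))
    flagged = dev > z_thresh * np.maximum(scale, 1e-12)
    out = raster.copy()
    out[flagged] = med[flagged]
    return out


def _circular_derivative(rows: np.ndarray) -> np.ndarray:
    """First difference along the row axis (circular, so it commutes with
    the circular shift being estimated); sharpens the correlation peak."""
    return rows - np.roll(rows, 1, axis=1)


def _row_score(even_rows: np.ndarray, target_rows: np.ndarray, k: int) -> float:
    """Mean normalised correlation of even rows rolled by -k vs neighbours."""
    rolled = np.roll(even_rows, -k, axis=1)
    a = rolled - rolled.mean(axis=1, keepdims=True)
    b = target_rows - target_rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    valid = denom > 0
    if not valid.any():
        return -np.inf
    return float(((a * b).sum(axis=1)[valid] / denom[valid]).mean())


def correct_serpentine(
    raster: np.ndarray, max_shift: int = 10, even_rows_reversed: bool = True
) -> tuple[np.ndarray, int]:
    """Estimate and undo the lateral shift of the reverse-scan rows.

    The estimate k̂ maximises the mean normalised cross-correlation
    between the lateral derivative of each even-indexed row (circularly
    rolled by −k) and that of the average of its adjacent odd-indexed
    rows, over k in [−max_shift, max_shift]; ties break toward smaller
    |k|. Correlating derivatives rather than raw rows sharpens the peak
    at sharp cell boundaries, which makes the integer estimate robust to
    smooth intensity gradients and noise. Returns the corrected raster
    and k̂. A constant raster has no structure to correlate: the input
    is returned with k̂ = 0 under :class:`ConstantRasterWarning`.
    """
    raster = _require_finite(raster)
    if raster.ndim != 2 or raster.shape[0] < 4:
        raise ValueError("raster must be 2-D with at least 4 rows")
    if np.ptp(raster) == 0:
        warnings.warn("constant raster: serpentine shift undefined", ConstantRasterWarning)
        return raster.copy(), 0

    shifted_parity = 0 if even_rows_reversed else 1
    rows = np.arange(raster.shape[0])
    shifted_idx = rows[rows % 2 == shifted_parity]
    # average of available fixed-parity neighbours for each shifted row
    targets = []
    for i in shifted_idx:
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < raster.shape[0]]
        targets.append(raster[neigh].mean(axis=0))
    even_rows = _circular_derivative(raster[shifted_idx])
    target_rows = _circular_derivative(np.asarray(targets))

    best_k, best_score = 0, -np.inf
    for k in sorted(range(-max_shift, max_shift + 1), key=lambda k: (abs(k), k)):
        score = _row_score(even_rows, target_rows, k)
        if score > best_score:
            best_k, best_score = k, score
    out = raster.copy()
    out[shifted_idx] = np.roll(out[shifted_idx], -best_k, axis=1)
    return out, best_k


def apply_serpentine_shift(
    raster: np.ndarray, shift_px: int, even_rows_reversed: bool = True
) -> np.ndarray:
    """Circularly shift the reverse-scan rows by ``shift_px`` (inverse of correction)."""
    out = np.asarray(raster, dtype=float).copy()
    parity = 0 if even_rows_reversed else 1
    idx = np.arange(out.shape[0]) % 2 == parity
    out[idx] = np.roll(out[idx], shift_px, axis=1)
    return out


def normalize_srg(lockin_signal: np.ndarray, stokes_transmission: np.ndarray) -> np.ndarray:
    """Pixelwise ΔI/I: lock-in SRG signal over Stokes transmission.

    Both inputs in detector volts; the ratio is dimensionless and
    invariant under a common gain applied to both.
    """
    lockin = _require_finite(lockin_signal)
    stokes = _require_finite(stokes_transmission)
    if lockin.shape != stokes.shape:
        raise ValueError("lock-in and transmission rasters must share a shape")
    nonpos = stokes <= 0
    if nonpos.any():
        coords = np.argwhere(nonpos)[:10].tolist()
        raise ValueError(f"non-positive Stokes transmission at (row, col) {coords}")
    return lockin / stokes
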