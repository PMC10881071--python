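"""Pixel-wise colocalization statistics between NLO channel pairs.

Implements the Pearson correlation coefficient, the quadrant
(pixel-frequency) form of the Manders coefficients, and the Costes
randomization control.

The quadrant M1/M2 differ from the classical intensity-weighted Manders
coefficients: with crosshair thresholds (t1, t2) splitting the channel-1
vs channel-2 scatter into quadrants, M1 is the count of top-right
(both-above) pixels over all channel-1-above pixels (top-right +
bottom-right), and M2 the same count over all channel-2-above pixels
(top-right + top-left). The classical coefficients are provided
separately as :func:`manders_intensity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .nlo import CellMask


@dataclass
class ColocResult:
    pcc: float
    m1: float | None  # None when no pixel exceeds t1
    m2: float | None
    t1: float
    t2: float
    n_pixels: int
    channel_pair: tuple[str, str]
    costes_p: float | None = None
    scatter: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def _masked_pair(ch1, ch2, mask: CellMask) -> tuple[np.ndarray, np.ndarray]:
    mask.require_nonempty()
    m = mask.mask
    a = np.asarray(ch1, dtype=float)[m]
    b = np.asarray(ch2, dtype=float)[m]
    return a, b


def pearson(ch1: np.ndarray, ch2: np.ndarray, mask: CellMask) -> float:
    """Sample Pearson correlation over in-mask pixel pairs."""
    a, b = _masked_pair(ch1, ch2, mask)
    if a.size < 2:
        raise ValueError("need at least 2 in-mask pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: constant channel within mask")
    return float(np.corrcoef(a, b)[0, 1])


def manders_quadrant(
    ch1: np.ndarray, ch2: np.ndarray, t1: float, t2: float, mask: CellMask
) -> tuple[float | None, float | None]:
    """Count-based M1/M2 from the quadrants of the (ch1, ch2) scatter.

    M1 = N_TR / (N_TR + N_BR), M2 = N_TR / (N_TR + N_TL), with TR the
    both-above quadrant (strict > t). A zero denominator (no pixel above
    that channel's threshold) makes the coefficient missing (None).
    """
    a, b = _masked_pair(ch1, ch2, mask)
    above1, above2 = a > t1, b > t2
    n_tr = int(np.count_nonzero(above1 & above2))
    n_br = int(np.count_nonzero(above1 & ~above2))
    n_tl = int(np.count_nonzero(~above1 & above2))
    m1 = n_tr / (n_tr + n_br) if (n_tr + n_br) > 0 else None
    m2 = n_tr / (n_tr + n_tl) if (n_tr + n_tl) > 0 else None
    return m1, m2


def manders_intensity(
    ch1: np.ndarray, ch2: np.ndarray, t1: float, t2: float, mask: CellMask
) -> tuple[float | None, float | None]:
    """Classical intensity-weighted Manders coefficients (alternative form).

    M1 = Σ ch1 over pixels with ch2 > t2, divided by Σ ch1; M2
    symmetric. Missing when the denominator sum is zero.
    """
    a, b = _masked_pair(ch1, ch2, mask)
    s1, s2 = float(a.sum()), float(b.sum())
    m1 = float(a[b > t2].sum()) / s1 if s1 > 0 else None
    m2 = float(b[a > t1].sum()) / s2 if s2 > 0 else None
    return m1, m2


def _block_permutation_indices(mask_2d: np.ndarray, block_px: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Flat source/destination indices permuting in-mask blocks of side block_px."""
    h, w = mask_2d.shape
    blocks = []
    for r in range(0, h - block_px + 1, block_px):
        for c in range(0, w - block_px + 1, block_px):
            if mask_2d[r : r + block_px, c : c + block_px].all():
                blocks.append((r, c))
    if len(blocks) < 2:
        raise ValueError("mask too small for the requested block size")
    order = rng.permutation(len(blocks))
    src, dst = [], []
    rr, cc = np.meshgrid(np.arange(block_px), np.arange(block_px), indexing="ij")
    for i, j in enumerate(order):
        r0, c0 = blocks[i]
        r1, c1 = blocks[j]
        dst.append(((r0 + rr) * w + (c0 + cc)).ravel())
        src.append(((r1 + rr) * w + (c1 + cc)).ravel())
    return np.concatenate(src), np.concatenate(dst)


def costes_significance(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: CellMask,
    n_rand: int = 200,
    block_px: int = 1,
    seed: int | None = None,
) -> float:
    """One-sided Costes randomization p-value for the observed PCC.

    Channel 2 is spatially scrambled ``n_rand`` times (in-mask pixels
    for block_px = 1, else non-overlapping in-mask blocks) while
    channel 1 stays fixed; p = (1 + #{PCC_rand ≥ PCC_obs}) / (1 + n_rand).
    The default block of one pixel reflects sampling at or above the
    optical resolution, where adjacent pixels are independent.
    """
    if n_rand < 20:
        raise ValueError("n_rand < 20 gives an unstable p-value")
    observed = pearson(ch1, ch2, mask)
    rng = np.random.default_rng(seed)
    a = np.asarray(ch1, dtype=float)[mask.mask]
    za = (a - a.mean()) / a.std()
    count = 0
    if block_px <= 1:
        b = np.asarray(ch2, dtype=float)[mask.mask]
        zb = (b - b.mean()) / b.std()
        for _ in range(n_rand):
            r = float(np.mean(za * rng.permutation(zb)))
            if r >= observed:
                count += 1
    else:
        ch2f = np.asarray(ch2, dtype=float).ravel()
        for _ in range(n_rand):
            src, dst = _block_permutation_indices(mask.mask, block_px, rng)
            perm = ch2f.copy()
            perm[dst] = ch2f[src]
            b = perm.reshape(mask.mask.shape)[mask.mask]
            if np.ptp(b) == 0:
                continue
            r = float(np.mean(za * (b - b.mean()) / b.std()))
            if r >= observed:
                count += 1
    return (1 + count) / (1 + n_rand)


def coloc_report(
    image,
    mask: CellMask,
    pair: tuple[str, str],
    thresholds: tuple[float | None, float | None] = (None, None),
    n_rand: int = 200,
    block_px: int = 1,
    seed: int | None = None,
    with_costes: bool = True,
) -> ColocResult:
    """Bundle PCC, quadrant M1/M2 and Costes p for one channel pair.

    A threshold of None is replaced by Otsu's threshold on the in-mask
    pixels of that channel (used for the CARS channels, whose intensity
    scale carries a nonresonant background offset).
    """
    for name in pair:
        if name not in image.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(image.channels)}")
    ch1, ch2 = image[pair[0]], image[pair[1]]
    t1, t2 = thresholds
    if t1 is None:
        t1 = float(threshold_otsu(ch1[mask.mask]))
    if t2 is None:
        t2 = float(threshold_otsu(ch2[mask.mask]))
    pcc = pearson(ch1, ch2, mask)
    m1, m2 = manders_quadrant(ch1, ch2, t1, t2, mask)
    p = (
        costes_significance(ch1, ch2, mask, n_rand=n_rand, block_px=block_px, seed=seed)
        if with_costes
        else None
    )
    a, b = _masked_pair(ch1, ch2, mask)
    return ColocResult(
        pcc=pcc,
        m1=m1,
        m2=m2,
        t1=t1,
        t2=t2,
        n_pixels=int(a.size),
        channel_pair=pair,
        costes_p=p,
        scatter=(a, b),
    )
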