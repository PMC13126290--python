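"""pERK/ERK ratio-image quantification.

The activity readout is the ratio of phospho-ERK to total ERK staining
inside the brain: projected images are divided pixelwise, masked by
Huang fuzzy-entropy thresholding of the ERK channel followed by
border-connected hole filling, measured in polygonal brain-region
ROIs, and normalized per clutch against the maximum of the clutch's
reference (diploid or unstimulated control) average image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask


@dataclass
class RatioMap:
    ratio: np.ndarray
    mask: np.ndarray
    erk_threshold: float
    epsilon: float


def zproject(stack: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Collapse a (z, y, x) stack to 2-D by sum (default) or mean."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be (z, y, x) with at least one slice")
    if mode == "sum":
        return stack.sum(axis=0)
    if mode == "mean":
        return stack.mean(axis=0)
    raise ValueError("mode must be 'sum' or 'mean'")


def huang_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Huang-Wang fuzzy-entropy threshold of a grayscale image.

    For every candidate threshold the image is split into background and
    foreground; each pixel's membership to its class is
    ``1 / (1 + |g - mu_class| / C)`` with C the grayscale range, and the
    candidate minimizing the total Shannon entropy
    ``-sum h(g) [m ln m + (1-m) ln(1-m)]`` is returned (the algorithm
    behind FIJI's "Huang" auto-threshold).  The returned value is the
    upper edge of the selected bin: pixels >= threshold are foreground.
    Deterministic; an exhaustive scan over all histogram splits.
    """
    img = np.asarray(image, dtype=float)
    gmin, gmax = float(img.min()), float(img.max())
    if gmax == gmin:
        raise ValueError("constant image has no threshold")
    hist, edges = np.histogram(img, bins=n_bins, range=(gmin, gmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = gmax - gmin

    w = hist.astype(float)
    cum_w = np.cumsum(w)
    cum_wg = np.cumsum(w * centers)
    total_w, total_wg = cum_w[-1], cum_wg[-1]

    # first split attaining the minimum wins; the tolerance makes the
    # tie-break robust to float noise on exact plateaus (empty-bin runs)
    best_s, best_t = np.inf, None
    tol = 1e-9
    for t in range(n_bins - 1):
        w0, w1 = cum_w[t], total_w - cum_w[t]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_wg[t] / w0
        mu1 = (total_wg - cum_wg[t]) / w1
        mu = np.where(np.arange(n_bins) <= t, mu0, mu1)
        m = 1.0 / (1.0 + np.abs(centers - mu) / c)
        m = np.clip(m, 1e-12, 1 - 1e-12)
        s = float(np.sum(w * -(m * np.log(m) + (1 - m) * np.log(1 - m))))
        if best_t is None or s < best_s - tol * max(abs(best_s), 1.0):
            best_s, best_t = s, t
    if best_t is None:
        raise ValueError("no valid threshold found")
    return float(edges[best_t + 1])


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the border (4-connectivity)."""
    structure = ndimage.generate_binary_structure(2, 1)
    return ndimage.binary_fill_holes(mask, structure=structure)


def rasterize_rois(rois: dict, shape: tuple[int, int]) -> dict:
    """ROI name -> boolean mask from (row, col) polygon vertex lists."""
    out = {}
    for name, poly in rois.items():
        poly = np.asarray(poly, dtype=float)
        if poly.min() < -0.5 or np.any(poly.max(axis=0) > np.array(shape) - 0.5):
            raise ValueError(f"ROI {name!r} extends outside the image")
        out[name] = polygon2mask(shape, poly)
    return out


def ratio_mask_measure(
    perk: np.ndarray,
    erk: np.ndarray,
    rois: dict,
    epsilon: float | None = None,
) -> tuple[RatioMap, pd.DataFrame]:
    """pERK/ERK ratio map, Huang+fill mask, and per-ROI mean ratios.

    ``rois`` maps region names to polygon vertex arrays in (row, col)
    order.  ROIs with no in-mask pixels are reported with NaN mean
    (missing), not zero.  ``epsilon`` guards the division; the default
    is 1e-6 times the ERK maximum.
    """
    perk = np.asarray(perk, dtype=float)
    erk = np.asarray(erk, dtype=float)
    if perk.shape != erk.shape:
        raise ValueError("pERK and ERK images must have the same shape")
    if epsilon is None:
        epsilon = 1e-6 * float(erk.max())
    thr = huang_threshold(erk)
    mask = fill_holes(erk >= thr)
    ratio = np.zeros_like(erk)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[mask] = perk[mask] / (erk[mask] + epsilon)
    ratio[~np.isfinite(ratio)] = 0.0

    rows = []
    for name, roi_mask in rasterize_rois(rois, erk.shape).items():
        sel = roi_mask & mask
        n = int(sel.sum())
        rows.append(dict(
            region=name,
            mean_ratio=float(ratio[sel].mean()) if n else np.nan,
            n_pixels=n,
            missing=n == 0,
        ))
    rmap = RatioMap(ratio=ratio, mask=mask, erk_threshold=thr, epsilon=epsilon)
    return rmap, pd.DataFrame(rows)


def clutch_normalize(
    measurements: pd.DataFrame,
    ratio_maps: dict,
    clutch_of: dict,
    is_reference: dict,
) -> pd.DataFrame:
    """Divide ROI means by the max of each clutch's reference average image.

    ``measurements`` is a tidy frame with columns ``image_id``, ``region``
    and ``mean_ratio``.  ``ratio_maps`` maps image_id to its ratio array,
    ``clutch_of`` maps image_id to clutch, and ``is_reference`` flags the
    images (e.g. diploid, or unstimulated controls) whose clutch average
    defines the normalizer.
    """
    norms = {}
    clutches = set(clutch_of.values())
    for clutch in clutches:
        ref_ids = [i for i, c in clutch_of.items() if c == clutch and is_reference.get(i)]
        if not ref_ids:
            raise ValueError(f"clutch {clutch!r} has no reference image")
        avg = np.mean([ratio_maps[i] for i in ref_ids], axis=0)
        norms[clutch] = float(avg.max())
    out = measurements.copy()
    out["clutch"] = out["image_id"].map(clutch_of)
    out["normalizer"] = out["clutch"].map(norms)
    out["normalized_ratio"] = out["mean_ratio"] / out["normalizer"]
    return out
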