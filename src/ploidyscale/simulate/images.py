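"""Synthetic co-registered pERK/ERK image pairs.

The ERK channel is a bright brain-shaped region (an ellipse covering
the ROIs) over a near-zero background; the pERK channel equals ERK
times a region-specific activity fold inside each ROI polygon and 1.0
elsewhere in the brain.  Gaussian noise is added independently to both
channels.  A truth table records the configured fold per ROI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..imaging import rasterize_rois


def default_brain_rois(shape: tuple[int, int]) -> dict:
    """Four rectangular region ROIs stacked along the rostro-caudal axis."""
    h, w = shape
    names = ("telencephalon", "diencephalon", "midbrain", "hindbrain")
    rois = {}
    top, bottom = int(0.1 * h), int(0.9 * h)
    left, right = int(0.3 * w), int(0.7 * w)
    band = (bottom - top) // len(names)
    for i, name in enumerate(names):
        r0, r1 = top + i * band, top + (i + 1) * band - 2
        rois[name] = [(r0, left), (r0, right), (r1, right), (r1, left)]
    return rois


def simulate_ratio_images(
    shape: tuple[int, int] = (128, 96),
    roi_polygons: dict | None = None,
    base_erk: float = 1000.0,
    perk_fold_by_roi: dict | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Return (perk, erk, truth) with the configured per-ROI activity folds."""
    if base_erk <= 0:
        raise ValueError("base_erk must be positive")
    rois = roi_polygons if roi_polygons is not None else default_brain_rois(shape)
    folds = dict(perk_fold_by_roi or {})
    for name in rois:
        folds.setdefault(name, 1.0)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("pERK folds must be positive")

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    brain = (((yy - h / 2) / (0.45 * h)) ** 2 + ((xx - w / 2) / (0.3 * w)) ** 2) <= 1.0

    erk = np.where(brain, base_erk, background).astype(float)
    fold_map = np.ones(shape)
    roi_masks = rasterize_rois(rois, shape)
    for name, m in roi_masks.items():
        fold_map[m & brain] = folds[name]
    perk = erk * fold_map

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        erk = erk + rng.normal(0.0, noise_sd, shape)
        perk = perk + rng.normal(0.0, noise_sd, shape)
        erk = np.clip(erk, 0.0, None)
        perk = np.clip(perk, 0.0, None)

    truth = pd.DataFrame([
        dict(region=name, fold=folds[name], n_pixels=int((roi_masks[name] & brain).sum()))
        for name in rois
    ])
    return perk, erk, truth
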