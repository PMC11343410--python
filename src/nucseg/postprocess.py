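"""Probability map -> cleaned instance label mask.

The semantic-segmentation output is thresholded at 0.5, small objects are
removed and small interior holes filled, and the cleaned foreground is
converted to instances with connected components.  Minimum object/hole
areas are experiment-specific settings and are always logged with a run.
An optional per-label dilation/erosion mirrors the run-time mask adjustment
offered to users (positive radius dilates, negative erodes); dilation is
guarded so adjacent labels never merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import disk


@dataclass(frozen=True)
class PostprocessConfig:
    threshold: float = 0.5
    min_object_px: int = 0
    min_hole_px: int = 0
    connectivity: int = 8      # 4 or 8 neighbourhood for foreground
    morph_radius: int = 0      # >0 dilate, <0 erode, 0 none

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.min_object_px < 0 or self.min_hole_px < 0:
            raise ValueError("areas must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground iff p > threshold (strict: p == threshold is background)."""
    prob = np.asarray(prob)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return prob > threshold


def _skimage_connectivity(connectivity: int) -> int:
    return 2 if connectivity == 8 else 1


def clean(binary: np.ndarray, min_object_px: int = 0, min_hole_px: int = 0,
          connectivity: int = 8) -> np.ndarray:
    """Remove small foreground components, then fill small interior holes.

    Objects with area < ``min_object_px`` are removed; holes — background
    components (dual connectivity) not touching the image border — with
    area < ``min_hole_px`` are then filled.  Idempotent at fixed parameters.
    """
    binary = np.asarray(binary, dtype=bool).copy()
    conn = _skimage_connectivity(connectivity)
    if min_object_px > 0:
        lab = cc_label(binary, connectivity=conn)
        areas = np.bincount(lab.ravel())
        small = np.flatnonzero(areas < min_object_px)
        binary[np.isin(lab, small[small > 0])] = False
    if min_hole_px > 0:
        # background uses the dual connectivity of the foreground
        bg_conn = 1 if connectivity == 8 else 2
        bg = cc_label(~binary, connectivity=bg_conn)
        border = np.unique(
            np.concatenate([bg[0, :], bg[-1, :], bg[:, 0], bg[:, -1]])
        )
        areas = np.bincount(bg.ravel())
        for lbl in range(1, len(areas)):
            if lbl in border:
                continue
            if areas[lbl] < min_hole_px:
                binary[bg == lbl] = True
    return binary


def label_instances(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected components; labels numbered in raster order of first pixel."""
    return cc_label(
        np.asarray(binary, dtype=bool), connectivity=_skimage_connectivity(connectivity)
    ).astype(np.int32)


def morph_adjust(mask: np.ndarray, radius: int) -> np.ndarray:
    """Per-label disk dilation (radius > 0) or erosion (radius < 0).

    Dilation never merges labels: a pixel claimed by several labels goes to
    the label whose centroid is nearest (ties to the lower label).  Erosion
    can delete small labels entirely.
    """
    mask = np.asarray(mask)
    if radius == 0:
        return mask.copy()
    if abs(radius) >= min(mask.shape):
        raise ValueError("|radius| must be smaller than the image")
    labels = [int(v) for v in np.unique(mask) if v > 0]
    out = np.zeros_like(mask)
    se = disk(abs(radius))
    if radius < 0:
        for lbl in labels:
            kept = ndi.binary_erosion(mask == lbl, structure=se)
            out[kept] = lbl
        return out

    claims = np.zeros(mask.shape, dtype=np.int16)
    grown = {}
    centroids = {}
    for lbl in labels:
        obj = mask == lbl
        g = ndi.binary_dilation(obj, structure=se)
        grown[lbl] = g
        claims += g
        ys, xs = np.nonzero(obj)
        centroids[lbl] = (ys.mean(), xs.mean())
    for lbl in labels:
        sole = grown[lbl] & (claims == 1)
        out[sole] = lbl
    contested = claims > 1
    if contested.any():
        ys, xs = np.nonzero(contested)
        for y, x in zip(ys, xs):
            if mask[y, x] > 0:      # original pixels keep their label
                out[y, x] = mask[y, x]
                continue
            cands = [lbl for lbl in labels if grown[lbl][y, x]]
            best = min(
                cands,
                key=lambda l: ((y - centroids[l][0]) ** 2 + (x - centroids[l][1]) ** 2, l),
            )
            out[y, x] = best
    # original pixels always keep their label (erosion-free guarantee)
    keep = mask > 0
    out[keep] = mask[keep]
    return out


def postprocess(prob: np.ndarray, cfg: PostprocessConfig) -> np.ndarray:
    """Full chain: binarize -> clean -> label -> optional morph adjust."""
    binary = binarize(prob, cfg.threshold)
    binary = clean(binary, cfg.min_object_px, cfg.min_hole_px, cfg.connectivity)
    labelled = label_instances(binary, cfg.connectivity)
    if cfg.morph_radius:
        labelled = morph_adjust(labelled, cfg.morph_radius)
    return labelled
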