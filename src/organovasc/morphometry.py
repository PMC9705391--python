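"""Vessel-network morphometry: skeleton length and junction counts.

Binary vessel masks are thinned to 1-pixel-wide 8-connected skeletons.
Total vessel length is the sum over skeleton pixel adjacencies of step
lengths (1 for orthogonal, sqrt(2) for diagonal neighbors), each adjacency
counted once — the standard diagonal-corrected skeletal length estimator.
Junctions are skeleton pixels with three or more skeleton neighbors,
merged within a small radius because thinning can emit several adjacent
branch pixels at one anatomical junction.  Both metrics are reported per
unit image area.  Conditions are compared by one-way ANOVA and cluster
composition is related to vessel length by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, remove_small_objects, skeletonize

from .invivo import anova_oneway

__all__ = [
    "MorphometryResult",
    "binarize",
    "skeletonize_mask",
    "total_length",
    "count_junctions",
    "analyze_image",
    "condition_stats",
    "correlate_composition",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class MorphometryResult:
    """Per-image morphometry normalized by total image area."""

    total_length_per_area: float
    junctions_per_area: float
    skeleton_px: int
    total_length: float
    n_junctions: int


def binarize(image: np.ndarray, threshold: float = 0.5, min_object_px: int = 10) -> np.ndarray:
    """Threshold and drop connected components smaller than ``min_object_px``."""
    mask = np.asarray(image) > threshold
    if min_object_px > 1:
        # drop components with fewer than min_object_px pixels
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """1-px 8-connected medial skeleton via topology-preserving thinning."""
    return skeletonize(np.asarray(mask, dtype=bool))


def total_length(skeleton: np.ndarray, pixel_size: float = 1.0) -> float:
    """Diagonal-corrected skeletal length.

    Counts each 8-neighbor adjacency between skeleton pixels once, weighting
    orthogonal steps 1 and diagonal steps sqrt(2), scaled by ``pixel_size``.
    """
    s = np.asarray(skeleton, dtype=bool)
    orth = np.count_nonzero(s[:, :-1] & s[:, 1:]) + np.count_nonzero(s[:-1, :] & s[1:, :])
    diag = np.count_nonzero(s[:-1, :-1] & s[1:, 1:]) + np.count_nonzero(
        s[:-1, 1:] & s[1:, :-1]
    )
    return float((orth + diag * _SQRT2) * pixel_size)


def count_junctions(skeleton: np.ndarray, merge_radius_px: int = 2) -> int:
    """Number of skeleton branch points, merged within ``merge_radius_px``.

    A branch pixel has >= 3 skeleton neighbors (8-connectivity); clusters of
    branch pixels whose dilations by the merge radius touch collapse to a
    single junction.
    """
    s = np.asarray(skeleton, dtype=bool)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    neighbors = ndimage.convolve(s.astype(int), kernel, mode="constant")
    branch = s & (neighbors >= 3)
    if not branch.any():
        return 0
    if merge_radius_px > 0:
        merged = dilation(branch, disk(merge_radius_px))
    else:
        merged = branch
    return int(cc_label(merged, connectivity=2).max())


def analyze_image(
    image: np.ndarray,
    pixel_size: float = 1.0,
    threshold: float = 0.5,
    min_object_px: int = 10,
    merge_radius_px: int = 2,
) -> MorphometryResult:
    """Binarize, skeletonize and measure one vessel image.

    Per-area values use the full image area in physical units
    (``n_pixels * pixel_size**2``).
    """
    mask = binarize(image, threshold=threshold, min_object_px=min_object_px)
    skel = skeletonize_mask(mask)
    length = total_length(skel, pixel_size)
    njunc = count_junctions(skel, merge_radius_px)
    area = image.shape[0] * image.shape[1] * pixel_size**2
    return MorphometryResult(
        total_length_per_area=length / area,
        junctions_per_area=njunc / area,
        skeleton_px=int(skel.sum()),
        total_length=length,
        n_junctions=njunc,
    )


def condition_stats(results: pd.DataFrame, condition_key: str = "condition") -> pd.DataFrame:
    """One-way ANOVA across conditions for each per-area metric.

    ``results`` holds one row per image with columns
    ``total_length_per_area``, ``junctions_per_area`` and the condition
    label.  Returns one row per metric with F, p and a significance flag at
    p < 0.05.
    """
    rows = []
    for metric in ("total_length_per_area", "junctions_per_area"):
        groups = [g[metric].to_numpy() for _, g in results.groupby(condition_key)]
        F, p = anova_oneway(*groups)
        rows.append({"metric": metric, "F": F, "p": p, "significant": p < 0.05})
    return pd.DataFrame(rows)


def correlate_composition(
    ec_cluster_pct: np.ndarray, mean_length: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of per-condition cluster percentage vs length.

    Two-sided p from the t distribution on n-2 degrees of freedom.  Needs at
    least 3 conditions and non-constant inputs.
    """
    x = np.asarray(ec_cluster_pct, dtype=float)
    y = np.asarray(mean_length, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 conditions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
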