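"""K-means tissue classification and six-component intersection masks.

Sound-speed voxels inside the breast are split by 1-D K-means into fat (low)
vs fibroglandular (high); stiffness voxels into soft / intermediate / hard,
in analogy with the elasticity descriptors used for handheld ultrasound.
Intersecting the two-class sound-speed masks with the three-class stiffness
masks yields six whole-breast tissue components whose voxel counts sum to
the breast volume.

Clustering is fitted per breast, on voxel intensities only, matching the
per-breast relative stiffness scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .stacks import ImageStack

#: Stiffness class order (index 0 = lowest centroid).
STIFFNESS_CLASSES = ("soft", "intermediate", "hard")
#: Sound-speed class order.
SS_CLASSES = ("fat", "fibroglandular")

#: Six-component label codes: 3 * ss_class + stiffness_class + 1.
COMPONENT_NAMES = {
    1: "soft_fat",
    2: "intermediate_fat",
    3: "hard_fat",
    4: "soft_fibroglandular",
    5: "intermediate_fibroglandular",
    6: "hard_fibroglandular",
}


def kmeans_1d(values, k: int, seed: int = 0):
    """Lloyd's K-means on scalar values with stable, ascending class indices.

    Uses k-means++ initialization with ``n_init=10`` and ``tol=1e-6``;
    clusters are relabeled by ascending centroid so index 0 is always the
    lowest-intensity class.

    Returns
    -------
    centroids : ndarray, shape (k,), sorted ascending
    labels : ndarray of int, same length as ``values``
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values to cluster")
    n_distinct = np.unique(values).size
    if n_distinct < k:
        raise ValueError(
            f"k-means with k={k} needs at least {k} distinct values, got {n_distinct}"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6, random_state=seed)
    raw = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centers[order], remap[raw]


class IntensitySegmenter(BaseEstimator, ClusterMixin):
    """Per-breast K-means segmentation of within-mask voxel intensities.

    Attributes (after ``fit``)
    --------------------------
    centroids_ : ndarray, ascending
    label_map_ : ndarray of int, -1 outside the mask, 0..k-1 inside
    masks_ : list of boolean arrays, one per class (ascending centroid)
    degenerate_ : bool
        True when fewer distinct values than classes were available and all
        voxels were assigned to the lowest class.
    """

    def __init__(self, n_classes: int = 2, random_state: int = 0):
        self.n_classes = n_classes
        self.random_state = random_state

    def fit(self, stack: ImageStack, mask) -> "IntensitySegmenter":
        mask3d = (mask.data if isinstance(mask, ImageStack) else np.asarray(mask)).astype(bool)
        if not mask3d.any():
            raise ValueError("mask is empty")
        values = np.asarray(stack.data)[mask3d]
        label_map = np.full(mask3d.shape, -1, dtype=np.int16)
        try:
            centroids, labels = kmeans_1d(values, self.n_classes, self.random_state)
            self.degenerate_ = False
        except ValueError:
            warnings.warn(
                f"fewer than {self.n_classes} distinct intensities in mask; "
                "assigning all voxels to the lowest class",
                RuntimeWarning,
                stacklevel=2,
            )
            centroids = np.full(self.n_classes, float(values.mean()))
            labels = np.zeros(values.size, dtype=int)
            self.degenerate_ = True
        label_map[mask3d] = labels
        self.centroids_ = centroids
        self.label_map_ = label_map
        self.masks_ = [label_map == i for i in range(self.n_classes)]
        return self


def segment_sound_speed(ss: ImageStack, breast_mask, seed: int = 0):
    """Two-class fat / fibroglandular split of within-mask sound speed.

    Returns ``(masks, centroids)`` with ``masks = {"fat": ..,
    "fibroglandular": ..}``.  A (near-)constant stack degrades to all-fat
    with a warning rather than failing the pipeline.
    """
    seg = IntensitySegmenter(2, seed).fit(ss, breast_mask)
    return dict(zip(SS_CLASSES, seg.masks_)), seg.centroids_


def segment_stiffness(S: ImageStack, breast_mask, seed: int = 0):
    """Three-class soft / intermediate / hard split of within-mask stiffness."""
    seg = IntensitySegmenter(3, seed).fit(S, breast_mask)
    return dict(zip(STIFFNESS_CLASSES, seg.masks_)), seg.centroids_


def _check_partition(masks: dict, mask3d: np.ndarray, family: str) -> None:
    total = np.zeros(mask3d.shape, dtype=int)
    for m in masks.values():
        total += np.asarray(m, dtype=bool).astype(int)
    if not np.array_equal(total[mask3d], np.ones(int(mask3d.sum()), dtype=int)):
        raise ValueError(f"{family} masks do not partition the breast mask")
    if total[~mask3d].any():
        raise ValueError(f"{family} masks extend outside the breast mask")


def intersect_six(ss_masks: dict, stiff_masks: dict, spacing=None) -> ImageStack:
    """Intersect the 2-class sound-speed and 3-class stiffness masks.

    A voxel that is fibroglandular on sound speed and hard on stiffness gets
    the "hard_fibroglandular" label, and so on.  Label encoding is
    ``3 * ss_class + stiffness_class + 1`` (1..6); 0 marks outside.
    """
    if set(ss_masks) != set(SS_CLASSES) or set(stiff_masks) != set(STIFFNESS_CLASSES):
        raise ValueError("expected fat/fibroglandular and soft/intermediate/hard masks")
    any_mask = np.zeros(np.asarray(ss_masks["fat"]).shape, dtype=bool)
    for m in ss_masks.values():
        any_mask |= np.asarray(m, dtype=bool)
    _check_partition(ss_masks, any_mask, "sound-speed")
    _check_partition(stiff_masks, any_mask, "stiffness")

    labels = np.zeros(any_mask.shape, dtype=np.int16)
    for i_ss, ss_name in enumerate(SS_CLASSES):
        for i_st, st_name in enumerate(STIFFNESS_CLASSES):
            both = np.asarray(ss_masks[ss_name], bool) & np.asarray(stiff_masks[st_name], bool)
            labels[both] = 3 * i_ss + i_st + 1
    from .stacks import DEFAULT_SPACING

    return ImageStack(labels, spacing or DEFAULT_SPACING, "label", "")


@dataclass
class SixComponentSegmentation:
    """Bundled result of the whole-breast segmentation of one breast."""

    labels: ImageStack
    ss_masks: dict
    stiff_masks: dict
    ss_centroids: np.ndarray
    stiffness_centroids: np.ndarray


def segment_breast(ss: ImageStack, S: ImageStack, breast_mask, seed: int = 0,
                   boundary_erosion: int = 0) -> SixComponentSegmentation:
    """Full six-component segmentation from sound speed + stiffness stacks.

    ``boundary_erosion`` (off by default) fits the cluster centroids on the
    mask eroded in-plane by that many voxels, then assigns every mask voxel
    to its nearest centroid — a guard against partial-volume boundary
    voxels dragging the centroids.  The default reproduces plain
    intensity K-means, including its boundary misassignments.
    """
    ss.check_same_geometry(S)
    mask3d = (breast_mask.data if isinstance(breast_mask, ImageStack)
              else np.asarray(breast_mask)).astype(bool)
    fit_mask = mask3d
    if boundary_erosion > 0:
        from scipy.ndimage import binary_erosion

        structure = np.zeros((3, 3, 1), dtype=bool)
        structure[1, :, 0] = True
        structure[:, 1, 0] = True
        eroded = binary_erosion(mask3d, structure=structure, iterations=boundary_erosion)
        if eroded.any():
            fit_mask = eroded
    ss_masks, c_ss = segment_sound_speed(ss, fit_mask, seed)
    stiff_masks, c_st = segment_stiffness(S, fit_mask, seed)
    if boundary_erosion > 0 and fit_mask is not mask3d:
        ss_masks = _assign_by_centroid(ss.data, mask3d, c_ss, SS_CLASSES)
        stiff_masks = _assign_by_centroid(S.data, mask3d, c_st, STIFFNESS_CLASSES)
    labels = intersect_six(ss_masks, stiff_masks, spacing=ss.spacing)
    return SixComponentSegmentation(labels, ss_masks, stiff_masks, c_ss, c_st)


def _assign_by_centroid(data, mask3d, centroids, class_names):
    values = np.asarray(data)[mask3d]
    dists = np.abs(values[:, None] - np.asarray(centroids)[None, :])
    labels = np.argmin(dists, axis=1)
    masks = {}
    for i, name in enumerate(class_names):
        m = np.zeros(mask3d.shape, dtype=bool)
        m[mask3d] = labels == i
        masks[name] = m
    return masks
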