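"""Per-mass stiffness metrics from single-slice polygon ROIs.

Mass margins are traced as polygons (mm coordinates) on the single most
representative coronal slice.  Metrics are computed strictly inside the
traced contour: the mean stiffness index on the 0-1 scale, the distribution
of ROI pixels over the three stiffness classes (and six tissue components),
a gray-level co-occurrence homogeneity texture feature, and a size class
from the equivalent circular diameter with the 1.5 cm screening set-point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .segment import COMPONENT_NAMES, STIFFNESS_CLASSES
from .stacks import ImageStack

HISTOLOGIES = ("cancer", "fibroadenoma", "cyst", "other_benign")

#: Size split in mm: equivalent diameter <= 15 mm is "small".
SIZE_CUTOFF_MM = 15.0

#: Default co-occurrence offsets (row, col): E, S, SE, NE neighbors.
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class MassROI:
    """Hand-traced mass contour on one coronal slice.

    ``polygon`` holds (x, y) vertices in mm on the slice's physical
    coordinate frame; it must be simple (non-self-intersecting).
    """

    polygon: tuple
    slice_index: int
    histology: str
    breast_id: str = ""

    def __post_init__(self):
        poly = tuple((float(x), float(y)) for x, y in self.polygon)
        if len(poly) < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        shp = ShapelyPolygon(poly)
        if not shp.is_simple or shp.area == 0:
            raise ValueError("ROI polygon must be simple with nonzero area")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        object.__setattr__(self, "polygon", poly)


@dataclass
class MassRecord:
    """Derived metrics for one mass ROI."""

    breast_id: str
    histology: str
    stiffness_index: float
    pct_soft: float
    pct_intermediate: float
    pct_hard: float
    component_pcts: dict
    homogeneity: float
    equivalent_diameter_cm: float
    size_class: str  # "small" (<= 1.5 cm) or "large"
    filtered: bool
    area_mm2: float = 0.0
    extra: dict = field(default_factory=dict)


def rasterize_roi(roi: MassROI, grid_shape_xy, spacing_xy) -> np.ndarray:
    """Rasterize a polygon ROI onto the slice pixel grid.

    A pixel belongs to the ROI iff its center lies inside the polygon
    (even-odd rule; for the required simple polygons this coincides with the
    winding rule used here).  Area is then count x pixel area.
    """
    nx, ny = grid_shape_xy
    dx, dy = spacing_xy
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    path = MplPath(np.asarray(roi.polygon))
    inside = path.contains_points(pts).reshape(nx, ny)
    return inside


def stiffness_index(S_slice, roi_mask) -> float:
    """Mean stiffness pixel value inside the ROI, on the 0-1 scale."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(S_slice, float)[roi_mask]
    return float(vals.mean())


def roi_component_percentages(label_slice, roi_mask) -> tuple[dict, dict]:
    """Percent of ROI pixels per stiffness class and per six-way component.

    ``label_slice`` is a slice of the six-component label map (codes 1-6).
    Returns ``(stiffness_pcts, component_pcts)``; each family sums to 100.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    labels = np.asarray(label_slice)[roi_mask]
    if (labels < 1).any() or (labels > 6).any():
        raise ValueError("ROI extends outside the labeled breast region")
    n = labels.size
    comp = {
        name: 100.0 * float((labels == code).sum()) / n
        for code, name in COMPONENT_NAMES.items()
    }
    stiff = {}
    for i, cls in enumerate(STIFFNESS_CLASSES):
        codes = (i + 1, i + 4)  # fat and fibroglandular variants
        stiff[cls] = 100.0 * float(np.isin(labels, codes).sum()) / n
    return stiff, comp


def glcm_homogeneity(S_slice, roi_mask, levels: int = 8, offsets=GLCM_OFFSETS) -> float:
    """Gray-level co-occurrence homogeneity of stiffness texture in a ROI.

    Stiffness values in [0, 1] are uniformly quantized into ``levels`` bins;
    the co-occurrence matrix is symmetric, normalized, and restricted to
    pixel pairs that both lie inside the ROI.  Homogeneity is
    ``sum_ij P(i, j) / (1 + |i - j|)``, averaged over the offsets that have
    at least one valid pair; 1.0 for a constant region.
    """
    roi_mask = np.asarray(roi_mask, bool)
    S_slice = np.asarray(S_slice, float)
    if roi_mask.sum() < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    bins = np.clip(np.floor(S_slice * levels).astype(int), 0, levels - 1)
    homs = []
    weight = 1.0 / (1.0 + np.abs(np.arange(levels)[:, None] - np.arange(levels)[None, :]))
    for dr, dc in offsets:
        a_sl = (slice(max(0, -dr), bins.shape[0] - max(0, dr)),
                slice(max(0, -dc), bins.shape[1] - max(0, dc)))
        b_sl = (slice(max(0, dr), bins.shape[0] + min(0, dr) or None),
                slice(max(0, dc), bins.shape[1] + min(0, dc) or None))
        pair_ok = roi_mask[a_sl] & roi_mask[b_sl]
        if not pair_ok.any():
            continue
        i = bins[a_sl][pair_ok]
        j = bins[b_sl][pair_ok]
        P = np.zeros((levels, levels))
        np.add.at(P, (i, j), 1.0)
        P = P + P.T  # symmetric counts
        P /= P.sum()
        homs.append(float((P * weight).sum()))
    if not homs:
        raise ValueError("no valid co-occurrence pairs inside the ROI")
    return float(np.mean(homs))


def equivalent_diameter_mm(roi_mask, spacing_xy) -> float:
    """Equivalent circular diameter from rasterized ROI area, in mm."""
    area = float(np.asarray(roi_mask, bool).sum()) * spacing_xy[0] * spacing_xy[1]
    return 2.0 * np.sqrt(area / np.pi)


def classify_size(roi_mask, spacing_xy) -> str:
    """Size class from the equivalent diameter; ties at 15.0 mm are small."""
    return "small" if equivalent_diameter_mm(roi_mask, spacing_xy) <= SIZE_CUTOFF_MM else "large"


def compute_mass_record(
    S: ImageStack,
    labels: ImageStack,
    roi: MassROI,
    filtered: bool,
) -> MassRecord:
    """All per-mass metrics for one ROI on one stiffness + label stack."""
    S.check_same_geometry(labels)
    k = roi.slice_index
    if not (0 <= k < S.shape[2]):
        raise ValueError(f"slice_index {k} outside stack of {S.shape[2]} slices")
    roi_mask = rasterize_roi(roi, S.shape[:2], S.spacing[:2])
    if not roi_mask.any():
        raise ValueError("ROI rasterizes to zero pixels")
    S_slice = np.asarray(S.data)[:, :, k]
    lab_slice = np.asarray(labels.data)[:, :, k]
    stiff_pcts, comp_pcts = roi_component_percentages(lab_slice, roi_mask)
    try:
        hom = glcm_homogeneity(S_slice, roi_mask)
    except ValueError:
        warnings.warn("ROI too small for texture analysis; homogeneity set to NaN",
                      RuntimeWarning, stacklevel=2)
        hom = float("nan")
    d_mm = equivalent_diameter_mm(roi_mask, S.spacing[:2])
    return MassRecord(
        breast_id=roi.breast_id,
        histology=roi.histology,
        stiffness_index=stiffness_index(S_slice, roi_mask),
        pct_soft=stiff_pcts["soft"],
        pct_intermediate=stiff_pcts["intermediate"],
        pct_hard=stiff_pcts["hard"],
        component_pcts=comp_pcts,
        homogeneity=hom,
        equivalent_diameter_cm=d_mm / 10.0,
        size_class="small" if d_mm <= SIZE_CUTOFF_MM else "large",
        filtered=filtered,
        area_mm2=float(roi_mask.sum()) * S.spacing[0] * S.spacing[1],
    )


def circle_roi(center_xy, diameter_mm, slice_index, histology, breast_id="",
               n_vertices: int = 32) -> MassROI:
    """Convenience regular-polygon approximation of a circular contour."""
    cx, cy = center_xy
    r = diameter_mm / 2.0
    ang = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    poly = tuple((cx + r * np.cos(a), cy + r * np.sin(a)) for a in ang)
    return MassROI(poly, slice_index, histology, breast_id)
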