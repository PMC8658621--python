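"""Voxel-count volumetrics and cohort summaries of the six tissue components.

Component volumes are voxel counts times the voxel volume (1.40625 mm^3 at
the default 0.75 x 0.75 x 2.5 mm spacing).  Cohort tables average per-breast
volumes and recompute percentages from the mean volumes, which keeps the
table internally consistent (percent-of-total equals mean volume over mean
total).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .segment import COMPONENT_NAMES
from .stacks import ImageStack

#: Deterministic row order for report tables.
COMPONENT_ORDER = [COMPONENT_NAMES[i] for i in range(1, 7)]
_FG_COMPONENTS = [c for c in COMPONENT_ORDER if c.endswith("fibroglandular")]
_FAT_COMPONENTS = [c for c in COMPONENT_ORDER if c.endswith("_fat")]
SUMMARY_ROWS = ["fibroglandular_total", "fat_total", "total"]


def table_from_volumes(volumes_cc: dict) -> pd.DataFrame:
    """Build a component-volume table from per-component volumes in cc.

    Adds fibroglandular / fat subtotals and the grand total, plus percent of
    total breast volume for every row.
    """
    missing = set(COMPONENT_ORDER) - set(volumes_cc)
    if missing:
        raise ValueError(f"missing components: {sorted(missing)}")
    vols = {c: float(volumes_cc[c]) for c in COMPONENT_ORDER}
    if any(v < 0 for v in vols.values()):
        raise ValueError("volumes must be nonnegative")
    fg = sum(vols[c] for c in _FG_COMPONENTS)
    fat = sum(vols[c] for c in _FAT_COMPONENTS)
    total = fg + fat
    rows = dict(vols)
    rows["fibroglandular_total"] = fg
    rows["fat_total"] = fat
    rows["total"] = total
    df = pd.DataFrame(
        {"volume_cc": pd.Series(rows, index=COMPONENT_ORDER + SUMMARY_ROWS)}
    )
    df["pct_total"] = 100.0 * df["volume_cc"] / total if total > 0 else 0.0
    df.index.name = "component"
    return df


def component_volumes(labels: ImageStack, spacing=None) -> pd.DataFrame:
    """Component-volume table from a six-component label stack.

    Volume of a component is its voxel count times the voxel volume; the six
    components sum to the breast-mask volume by construction.
    """
    data = np.asarray(labels.data)
    spacing = spacing or labels.spacing
    known = set(range(0, 7))
    present = set(np.unique(data).tolist())
    if not present <= known:
        raise ValueError(f"unknown labels in map: {sorted(present - known)}")
    voxel_cc = float(np.prod(spacing)) / 1000.0  # mm^3 -> cc
    vols = {
        name: int((data == code).sum()) * voxel_cc
        for code, name in COMPONENT_NAMES.items()
    }
    return table_from_volumes(vols)


def cohort_average(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-breast component tables across a cohort.

    Mean volumes per component; percentages recomputed from the mean
    volumes (not averaged percentages).  Permutation-invariant in the order
    of breasts.
    """
    if len(tables) == 0:
        raise ValueError("cohort_average needs at least one table")
    mean_vols = {
        c: float(np.mean([t.loc[c, "volume_cc"] for t in tables]))
        for c in COMPONENT_ORDER
    }
    return table_from_volumes(mean_vols)


def ss_stiffness_correlation(ss: ImageStack, S: ImageStack, mask) -> float:
    """Pearson correlation between sound speed and stiffness inside the mask.

    Used to check that the relative stiffness map carries information beyond
    its sound-speed component.
    """
    ss.check_same_geometry(S)
    mask3d = (mask.data if isinstance(mask, ImageStack) else np.asarray(mask)).astype(bool)
    if not mask3d.any():
        raise ValueError("mask is empty")
    x = np.asarray(ss.data)[mask3d].astype(float)
    y = np.asarray(S.data)[mask3d].astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance within mask")
    return float(stats.pearsonr(x, y).statistic)
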