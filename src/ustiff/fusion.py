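"""Surrogate bulk-modulus ("stiffness fusion") mapping.

A hard lesion is dense (high sound speed) *and* attenuating; a non-solid
lesion such as a cyst attenuates almost nothing however fast it is.  The
fused stiffness map therefore combines the two transmission channels so that
it is high only where both are high, and zero wherever attenuation is zero.

Both channels are first rescaled per breast — the map is optimized for
relative stiffness differences within that breast, not calibrated to an
external standard — by mapping robust percentiles of the within-mask values
to [0, 1].  The default combination rule is the voxelwise geometric mean of
the two normalized channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from scipy.ndimage import binary_erosion
from sklearn.base import BaseEstimator, TransformerMixin

from .stacks import ImageStack


@dataclass(frozen=True)
class FusionParams:
    """Tunables of the stiffness-fusion step."""

    lo_percentile: float = 1.0
    hi_percentile: float = 99.0
    combine_rule: str = "geometric_mean"  # or "weighted_mean"
    weights: tuple[float, float] = (0.5, 0.5)
    #: In-plane erosion (voxels) of the mask used for percentile estimation
    #: only, so a high-attenuation skin rim cannot dominate the scale.
    erode_voxels: int = 2

    def __post_init__(self):
        if not (0.0 <= self.lo_percentile < self.hi_percentile <= 100.0):
            raise ValueError("need 0 <= lo_percentile < hi_percentile <= 100")
        if self.combine_rule not in ("geometric_mean", "weighted_mean"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        w = self.weights
        if len(w) != 2 or any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
            raise ValueError("weights must be two nonnegative values summing to 1")


def _as_bool_mask(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, ImageStack) else np.asarray(mask)
    return data.astype(bool)


def _percentile_mask(mask3d: np.ndarray, erode_voxels: int) -> np.ndarray:
    """Mask used for percentile fitting: eroded in-plane, slice by slice."""
    if erode_voxels <= 0:
        return mask3d
    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[1, :, 0] = True
    structure[:, 1, 0] = True
    eroded = binary_erosion(mask3d, structure=structure, iterations=erode_voxels)
    return eroded if eroded.any() else mask3d


class RobustIntensityNormalizer(BaseEstimator, TransformerMixin):
    """Per-breast percentile rescaling of a stack to the unit interval.

    ``fit`` learns the lo/hi percentile anchors of the within-mask voxel
    values; ``transform`` maps them linearly to [0, 1] and clips, setting
    voxels outside the mask to 0.

    Attributes
    ----------
    lo_value_, hi_value_ : float
        Intensity anchors mapped to 0 and 1.
    """

    def __init__(self, lo_percentile: float = 1.0, hi_percentile: float = 99.0,
                 erode_voxels: int = 2):
        self.lo_percentile = lo_percentile
        self.hi_percentile = hi_percentile
        self.erode_voxels = erode_voxels

    def fit(self, stack: ImageStack, mask) -> "RobustIntensityNormalizer":
        if not (0.0 <= self.lo_percentile < self.hi_percentile <= 100.0):
            raise ValueError("need 0 <= lo_percentile < hi_percentile <= 100")
        mask3d = _as_bool_mask(mask)
        if not mask3d.any():
            raise ValueError("mask is empty")
        pmask = _percentile_mask(mask3d, self.erode_voxels)
        vals = np.asarray(stack.data)[pmask]
        self.lo_value_, self.hi_value_ = np.percentile(
            vals, [self.lo_percentile, self.hi_percentile]
        )
        return self

    def transform(self, stack: ImageStack, mask) -> ImageStack:
        mask3d = _as_bool_mask(mask)
        lo, hi = self.lo_value_, self.hi_value_
        data = np.asarray(stack.data, dtype=float)
        if hi <= lo or np.isclose(hi, lo):
            warnings.warn(
                "constant stack: percentile anchors coincide; returning zeros",
                RuntimeWarning,
                stacklevel=2,
            )
            out = np.zeros_like(data)
        else:
            out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
        out[~mask3d] = 0.0
        return stack.like(out, units="")


def robust_normalize(stack: ImageStack, mask, lo: float = 1.0, hi: float = 99.0,
                     erode_voxels: int = 2) -> ImageStack:
    """Percentile-rescale a stack to [0, 1] within the mask (see
    :class:`RobustIntensityNormalizer`)."""
    norm = RobustIntensityNormalizer(lo, hi, erode_voxels)
    return norm.fit(stack, mask).transform(stack, mask)


def fuse_stiffness(ss_norm: ImageStack, att_norm: ImageStack,
                   params: FusionParams | None = None) -> ImageStack:
    """Combine normalized sound speed and attenuation into a stiffness map.

    Default rule: ``S = sqrt(ss_hat * att_hat)`` voxelwise, so ``S`` is zero
    wherever attenuation is zero (cysts stay soft regardless of their sound
    speed) and reaches 1 only where both channels do.
    """
    params = params or FusionParams()
    ss_norm.check_same_geometry(att_norm)
    a = np.asarray(ss_norm.data, dtype=float)
    b = np.asarray(att_norm.data, dtype=float)
    eps = 1e-9
    if a.min() < -eps or a.max() > 1 + eps or b.min() < -eps or b.max() > 1 + eps:
        raise ValueError("fuse_stiffness expects inputs normalized to [0, 1]")
    if params.combine_rule == "geometric_mean":
        S = np.sqrt(np.clip(a, 0, 1) * np.clip(b, 0, 1))
    else:
        w1, w2 = params.weights
        S = w1 * np.clip(a, 0, 1) + w2 * np.clip(b, 0, 1)
    return ss_norm.like(S, modality="stiffness", units="")


class StiffnessMapper(BaseEstimator, TransformerMixin):
    """Per-breast stiffness fusion: normalize both channels, then combine.

    ``fit`` learns the per-breast percentile anchors of both channels;
    ``transform`` produces the relative stiffness stack in [0, 1].
    """

    def __init__(self, lo_percentile: float = 1.0, hi_percentile: float = 99.0,
                 combine_rule: str = "geometric_mean",
                 weights: tuple[float, float] = (0.5, 0.5), erode_voxels: int = 2):
        self.lo_percentile = lo_percentile
        self.hi_percentile = hi_percentile
        self.combine_rule = combine_rule
        self.weights = weights
        self.erode_voxels = erode_voxels

    def _params(self) -> FusionParams:
        return FusionParams(
            self.lo_percentile, self.hi_percentile, self.combine_rule,
            tuple(self.weights), self.erode_voxels,
        )

    def fit(self, stacks, mask) -> "StiffnessMapper":
        ss, att = stacks
        self._params()  # validate
        self.ss_normalizer_ = RobustIntensityNormalizer(
            self.lo_percentile, self.hi_percentile, self.erode_voxels
        ).fit(ss, mask)
        self.att_normalizer_ = RobustIntensityNormalizer(
            self.lo_percentile, self.hi_percentile, self.erode_voxels
        ).fit(att, mask)
        return self

    def transform(self, stacks, mask) -> ImageStack:
        ss, att = stacks
        ss_n = self.ss_normalizer_.transform(ss, mask)
        att_n = self.att_normalizer_.transform(att, mask)
        return fuse_stiffness(ss_n, att_n, self._params())

    def fit_transform(self, stacks, mask) -> ImageStack:  # type: ignore[override]
        return self.fit(stacks, mask).transform(stacks, mask)


def compute_stiffness(ss: ImageStack, att: ImageStack, mask,
                      params: FusionParams | None = None) -> ImageStack:
    """One-call per-breast stiffness map from raw sound speed + attenuation."""
    params = params or FusionParams()
    mapper = StiffnessMapper(
        params.lo_percentile, params.hi_percentile, params.combine_rule,
        params.weights, params.erode_voxels,
    )
    return mapper.fit_transform((ss, att), mask)


#: Soft-to-hard display path: blue-black for soft, through green-yellow for
#: intermediate, to orange-red for hard.
_STIFFNESS_COLORS = [
    (0.00, (0.02, 0.02, 0.10)),  # near-black
    (0.18, (0.05, 0.10, 0.65)),  # blue
    (0.40, (0.05, 0.55, 0.30)),  # green
    (0.60, (0.90, 0.90, 0.15)),  # yellow
    (0.80, (1.00, 0.55, 0.05)),  # orange
    (1.00, (0.80, 0.02, 0.02)),  # red
]


def stiffness_colormap() -> LinearSegmentedColormap:
    """Matplotlib colormap for stiffness display (soft=blue-black, hard=red)."""
    return LinearSegmentedColormap.from_list("stiffness", _STIFFNESS_COLORS)


def render_stiffness(S) -> np.ndarray:
    """Map stiffness values in [0, 1] to RGBA floats deterministically."""
    data = S.data if isinstance(S, ImageStack) else np.asarray(S)
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise ValueError("stiffness values must lie in [0, 1]")
    return stiffness_colormap()(data)
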