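"""Synthetic pendant-breast phantoms with co-registered acoustic stacks.

The generator emulates what a ring-transducer ultrasound-tomography scan of a
pendant breast delivers after reconstruction: co-registered coronal stacks of
sound speed (m/s) and attenuation (relative units) at 0.75 x 0.75 mm in-plane
resolution and 2.5 mm slice thickness, together with a breast mask and a
ground-truth tissue label volume.

The breast interior is a two-tissue mixture: a fat baseline and
fibroglandular blobs obtained by thresholding a Gaussian-smoothed random
field at the quantile that realizes the requested fibroglandular volume
fraction exactly (up to voxel discreteness).  Masses are spheres in physical
mm overwriting the tissue underneath, with acoustic profiles expressing the
qualitative signatures of common breast masses: cysts are non-solid with
near-zero attenuation, fibroadenomas sit at intermediate, fairly homogeneous
values, and cancers combine high sound speed with high attenuation (dense
*and* attenuating, i.e. hard).

All absolute values are configurable; the downstream analysis is relative
(per-breast rescaling), so only the contrast ordering matters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .stacks import DEFAULT_SPACING, ImageStack

# Ground-truth label codes.
LABEL_OUTSIDE = 0
LABEL_FAT = 1
LABEL_FIBROGLANDULAR = 2
LABEL_SKIN = 7
MASS_LABELS = {"cyst": 3, "fibroadenoma": 4, "cancer": 5, "fibrosis": 6}

# Background acoustic defaults (contrast ordering is what matters downstream).
WATER_SS = 1500.0
FAT_SS = 1425.0
FG_SS = 1530.0
#: Reference (mean) attenuation per tissue class, relative units.
FAT_ATT = 0.20
FG_ATT = 0.55
SKIN_ATT = 0.90
#: Within-class ranges: sound speed and attenuation both vary smoothly with
#: the depth of the tissue field (dense fibroglandular cores are faster and
#: stiffer, fat far from parenchyma slowest and softest), continuous across
#: the fat/FG boundary, so both compartments carry soft, intermediate and
#: hard subregions and neither acoustic channel saturates breast-wide.
FAT_ATT_RANGE = (0.10, 0.30)
FG_ATT_RANGE = (0.30, 0.80)
FAT_SS_RANGE = (1412.0, 1438.0)
FG_SS_RANGE = (1490.0, 1570.0)

# Internal speckle of masses at heterogeneity = 1: amplitude per channel and
# correlation length (coarse enough to survive the acquisition blur).
_SPECKLE_SS = 30.0  # m/s
_SPECKLE_ATT = 0.30  # relative units
_SPECKLE_SCALE_MM = 3.0


@dataclass(frozen=True)
class MassSpec:
    """A single spherical mass to embed in a phantom.

    ``ss_value``/``att_value`` default to the profile for ``mass_type``;
    ``heterogeneity`` scales an internal smoothed-speckle field (0 gives a
    perfectly homogeneous interior before acquisition noise).
    """

    mass_type: str
    center: tuple[float, float, float]  # mm
    diameter: float  # mm
    ss_value: float | None = None
    att_value: float | None = None
    heterogeneity: float | None = None
    #: Radial stiffness structure: attenuation scaled by
    #: ``1 + central_enhancement * (1 - 2 (r/R)^2)`` so the core is stiffer
    #: than the margin (cancers show centrally dominant stiffness); 0 gives
    #: a flat interior.
    central_enhancement: float | None = None

    #: Default (sound speed, attenuation, heterogeneity, central
    #: enhancement) per mass type.
    #: Cancer attenuation sits at the top decile of the parenchymal range
    #: (hard fibroglandular tissue and cancers overlap in stiffness) rather
    #: than above it, so cancers do not saturate the per-breast scale;
    #: malignant-type masses are centrally dominant, benign ones flat.
    PROFILES = {
        "cyst": (1520.0, 0.02, 0.05, 0.0),
        "fibroadenoma": (1510.0, 0.45, 0.15, 0.0),
        "cancer": (1570.0, 0.60, 1.00, 0.50),
        "fibrosis": (1555.0, 0.60, 0.80, 0.40),
    }

    def __post_init__(self):
        if self.mass_type not in self.PROFILES:
            raise ValueError(f"unknown mass_type {self.mass_type!r}")
        if self.diameter <= 0:
            raise ValueError("mass diameter must be positive")
        het = self.heterogeneity
        if het is not None and not (0.0 <= het <= 1.0):
            raise ValueError("heterogeneity must lie in [0, 1]")

    def resolved(self) -> "MassSpec":
        """Fill unset acoustic values from the type profile."""
        ss, att, het, ce = self.PROFILES[self.mass_type]
        return replace(
            self,
            ss_value=ss if self.ss_value is None else self.ss_value,
            att_value=att if self.att_value is None else self.att_value,
            heterogeneity=het if self.heterogeneity is None else self.heterogeneity,
            central_enhancement=ce if self.central_enhancement is None else self.central_enhancement,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic breast.

    The defaults reproduce the cohort-level study conditions the analysis is
    exercised under: a 29.1% fibroglandular volume fraction (the cohort mean
    breast-density mix), acquisition geometry of 0.75 x 0.75 x 2.5 mm voxels,
    and modest acquisition noise on both channels.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 20)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    breast_radius: float = 50.0  # mm
    fibroglandular_fraction: float = 0.291
    #: Correlation length (mm) of the tissue blob field.  Parenchymal
    #: groupings are centimeter-scale structures, larger than the 1.5 cm
    #: mass-emphasis cutoff used downstream.
    fg_texture_scale: float = 20.0
    noise_sd_ss: float = 5.0  # m/s
    noise_sd_att: float = 0.05  # relative units
    #: In-plane acquisition blur (FWHM, mm) emulating the band-limited
    #: reconstruction: tissue interfaces and mass rims are gradual, not
    #: voxel-sharp.  Applied to the noiseless maps, before noise.  The
    #: attenuation channel is reconstructed at a coarser effective
    #: resolution than sound speed, so mass margins on the fused stiffness
    #: map are blended over a few pixels.
    psf_fwhm_ss_mm: float = 1.5
    psf_fwhm_att_mm: float = 4.0
    seed: int = 0
    masses: tuple[MassSpec, ...] = ()
    skin_rim: bool = False
    #: Forced-fibroglandular spheres, ``(center mm, diameter mm)`` or
    #: ``(center, diameter, attenuation)``: lets experiments place a mass
    #: inside a contiguous parenchymal region of known size and stiffness.
    fg_regions: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.fibroglandular_fraction <= 1.0):
            raise ValueError("fibroglandular_fraction must lie in [0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        nx, ny, _ = self.grid_shape
        half_x = nx * self.spacing[0] / 2.0
        half_y = ny * self.spacing[1] / 2.0
        if self.breast_radius > min(half_x, half_y):
            raise ValueError(
                f"breast_radius {self.breast_radius} mm does not fit a "
                f"{nx}x{ny} grid at spacing {self.spacing[:2]}"
            )
        object.__setattr__(self, "masses", tuple(self.masses))

    def voxel_centers(self):
        """Physical coordinates (mm) of voxel centers along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.spacing)
        )


def _coordinate_grids(spec: PhantomSpec):
    xs, ys, zs = spec.voxel_centers()
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _breast_mask(spec: PhantomSpec):
    """Cylindrical pendant-breast footprint centered in-plane, all slices."""
    nx, ny, _ = spec.grid_shape
    cx = nx * spec.spacing[0] / 2.0
    cy = ny * spec.spacing[1] / 2.0
    X, Y, _ = _coordinate_grids(spec)
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    return r2 <= spec.breast_radius**2, np.sqrt(r2)


def generate_phantom(spec: PhantomSpec):
    """Generate co-registered sound-speed / attenuation / truth / mask stacks.

    Returns
    -------
    (ss, att, truth, breast_mask) : tuple of ImageStack
        ``truth`` carries integer tissue labels; ``breast_mask`` is 0/1.

    Notes
    -----
    Deterministic for a fixed ``spec.seed``.  Masses are inserted on the
    noiseless tissue maps; acquisition noise is added last, inside the mask
    only, and attenuation is clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    mask, radial = _breast_mask(spec)

    truth = np.full(spec.grid_shape, LABEL_OUTSIDE, dtype=np.int16)
    truth[mask] = LABEL_FAT

    skin = np.zeros_like(mask)
    if spec.skin_rim:
        rim_width = 2.0 * spec.spacing[0]
        skin = mask & (radial > spec.breast_radius - rim_width)
        truth[skin] = LABEL_SKIN

    interior = mask & ~skin
    n_interior = int(interior.sum())
    frac = spec.fibroglandular_fraction
    if n_interior == 0:
        raise ValueError("breast mask is empty")
    if 0.0 < frac < 1.0 and n_interior < 20:
        raise ValueError(
            f"grid too small to realize a fibroglandular fraction: only "
            f"{n_interior} interior voxels"
        )

    # Correlated blob field thresholded at the within-mask quantile that
    # realizes the requested fibroglandular fraction exactly.
    sigma_vox = [spec.fg_texture_scale / s for s in spec.spacing]
    blob = gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=sigma_vox)
    # empirical CDF of the field inside the breast: u uniform on (0, 1)
    vals = blob[interior]
    u = np.zeros(spec.grid_shape)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(vals.size)
    u[interior] = (ranks + 0.5) / vals.size
    if frac >= 1.0:
        fg = interior.copy()
    elif frac > 0.0:
        fg = interior & (u > 1.0 - frac)
    else:
        fg = np.zeros_like(interior)
    truth[fg] = LABEL_FIBROGLANDULAR

    forced = []
    for entry in spec.fg_regions:
        center, diameter = entry[0], entry[1]
        att_override = entry[2] if len(entry) > 2 else None
        region = _sphere_region(spec, center, diameter)
        if not region[interior].any() or (region & ~interior).any():
            raise ValueError("forced fibroglandular region must lie inside the breast")
        truth[region] = LABEL_FIBROGLANDULAR
        forced.append((region, att_override))

    ss = np.full(spec.grid_shape, WATER_SS)
    att = np.zeros(spec.grid_shape)
    is_fat = truth == LABEL_FAT
    is_fg = truth == LABEL_FIBROGLANDULAR
    # both channels follow the tissue-field depth: piecewise-linear in the
    # within-mask quantile u, continuous at the fat/FG threshold 1 - frac
    for arr, fat_range, fg_range in (
        (att, FAT_ATT_RANGE, FG_ATT_RANGE),
        (ss, FAT_SS_RANGE, FG_SS_RANGE),
    ):
        if frac < 1.0:
            lo, hi = fat_range
            arr[is_fat] = lo + (hi - lo) * u[is_fat] / (1.0 - frac)
        if frac > 0.0:
            lo, hi = fg_range
            arr[is_fg] = lo + (hi - lo) * (u[is_fg] - (1.0 - frac)) / frac
    for region, att_override in forced:
        ss[region] = FG_SS
        att[region] = FG_ATT if att_override is None else att_override
    if spec.skin_rim:
        ss[skin] = FG_SS
        att[skin] = SKIN_ATT

    for m in spec.masses:
        _insert_mass_arrays(spec, ss, att, truth, mask, m, rng)

    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
    if spec.psf_fwhm_ss_mm > 0:
        s = spec.psf_fwhm_ss_mm / fwhm
        ss = gaussian_filter(ss, sigma=(s / spec.spacing[0], s / spec.spacing[1], 0.0))
        ss[~mask] = WATER_SS
    if spec.psf_fwhm_att_mm > 0:
        s = spec.psf_fwhm_att_mm / fwhm
        att = gaussian_filter(att, sigma=(s / spec.spacing[0], s / spec.spacing[1], 0.0))
        att[~mask] = 0.0

    n_mask = int(mask.sum())
    ss[mask] += rng.normal(0.0, spec.noise_sd_ss, size=n_mask)
    att[mask] += rng.normal(0.0, spec.noise_sd_att, size=n_mask)
    np.clip(att, 0.0, None, out=att)

    mk = lambda a, mod, units: ImageStack(a, spec.spacing, mod, units, meta={"seed": spec.seed})
    return (
        mk(ss, "sound_speed", "m/s"),
        mk(att, "attenuation", "rel"),
        mk(truth, "label", ""),
        mk(mask.astype(np.uint8), "mask", ""),
    )


def _sphere_region(spec: PhantomSpec, center, diameter: float):
    """Boolean region of voxels whose centers fall inside a sphere (mm)."""
    X, Y, Z = _coordinate_grids(spec)
    cx, cy, cz = center
    r = diameter / 2.0
    return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2


def _insert_mass_arrays(spec, ss, att, truth, mask, m: MassSpec, rng) -> None:
    m = m.resolved()
    region = _sphere_region(spec, m.center, m.diameter)
    if not region.any():
        raise ValueError(
            f"{m.mass_type} of diameter {m.diameter} mm at {m.center} covers no voxel centers"
        )
    if (region & ~mask).any():
        raise ValueError(f"{m.mass_type} at {m.center} extends outside the breast mask")
    under = truth[region]
    if np.isin(under, list(MASS_LABELS.values()) + [LABEL_SKIN]).any():
        raise ValueError(
            f"{m.mass_type} at {m.center} overlaps an existing mass or the skin rim"
        )
    ss[region] = m.ss_value
    att[region] = m.att_value
    if m.central_enhancement > 0.0:
        X, Y, Z = _coordinate_grids(spec)
        cx, cy, cz = m.center
        r2 = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (m.diameter / 2.0) ** 2
        factor = 1.0 + m.central_enhancement * (1.0 - 2.0 * r2[region])
        att[region] = np.clip(att[region] * factor, 0.0, None)
    if m.heterogeneity > 0.0:
        # smoothed unit-variance speckle restricted to the mass interior
        sigma_vox = [_SPECKLE_SCALE_MM / s for s in spec.spacing]
        speck = gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=sigma_vox)
        sd = speck[region].std()
        if sd > 0:
            speck = speck / sd
            ss[region] += m.heterogeneity * _SPECKLE_SS * speck[region]
            att[region] += m.heterogeneity * _SPECKLE_ATT * speck[region]
            np.clip(att, 0.0, None, out=att)
    truth[region] = MASS_LABELS[m.mass_type]


def insert_mass(ss: ImageStack, att: ImageStack, truth: ImageStack, m: MassSpec, rng=None):
    """Embed a mass into already-generated stacks, updating the truth labels.

    Rejects masses that extend outside the breast (truth == 0 region) or
    overlap a previously inserted mass, keeping the ground truth unambiguous.
    Returns the updated ``(ss, att, truth)`` stacks (modified in place).
    """
    ss.check_same_geometry(att)
    ss.check_same_geometry(truth)
    if rng is None:
        rng = np.random.default_rng(0)
    spec = PhantomSpec(
        grid_shape=ss.shape,
        spacing=ss.spacing,
        breast_radius=min(ss.shape[0] * ss.spacing[0], ss.shape[1] * ss.spacing[1]) / 2.0,
    )
    mask = truth.data != LABEL_OUTSIDE
    _insert_mass_arrays(spec, ss.data, att.data, truth.data, mask, m, rng)
    return ss, att, truth


def realized_fg_fraction(truth: ImageStack) -> float:
    """Fibroglandular voxel fraction inside the breast (masses excluded from
    the numerator but counted in the denominator)."""
    inside = truth.data != LABEL_OUTSIDE
    if not inside.any():
        raise ValueError("empty breast mask")
    return float((truth.data == LABEL_FIBROGLANDULAR).sum() / inside.sum())
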