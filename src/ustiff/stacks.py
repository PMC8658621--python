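"""Co-registered coronal image stacks and their on-disk representation.

An :class:`ImageStack` is a 3-D scalar voxel grid with anisotropic spacing
(in-plane resolution is finer than the slice thickness) and a modality tag.
Stacks are stored as NIfTI-1 volumes with a JSON sidecar carrying the
modality and unit metadata that the NIfTI header cannot hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Modalities a stack may carry.
MODALITIES = ("sound_speed", "attenuation", "stiffness", "reflection", "label", "mask")

#: Default voxel spacing in mm: in-plane x, in-plane y, slice thickness.
DEFAULT_SPACING = (0.75, 0.75, 2.5)


@dataclass
class ImageStack:
    """A 3-D image volume with spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nslices)
        Voxel values. Axis 2 indexes coronal slices.
    spacing : tuple of float
        Voxel size in mm, ``(dx, dy, dz)``; all strictly positive.
    modality : str
        One of :data:`MODALITIES`.
    units : str
        Physical units of the voxel values (e.g. ``"m/s"``), or ``""`` for
        unitless/relative scales.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    modality: str = "sound_speed"
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (1.40625 at the default spacing)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def like(self, data: np.ndarray, modality: str | None = None, units: str | None = None) -> "ImageStack":
        """New stack sharing this stack's geometry."""
        if data.shape != self.data.shape:
            raise ValueError(f"shape {data.shape} does not match stack shape {self.data.shape}")
        return ImageStack(
            data=data,
            spacing=self.spacing,
            modality=self.modality if modality is None else modality,
            units=self.units if units is None else units,
        )

    def check_same_geometry(self, other: "ImageStack") -> None:
        if self.data.shape != other.data.shape:
            raise ValueError(f"shape mismatch: {self.data.shape} vs {other.data.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as NIfTI-1 plus a JSON sidecar; returns the image path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(stack.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(stack.data), affine)
    img.header.set_zooms(stack.spacing)
    nib.save(img, str(path))
    sidecar = {
        "modality": stack.modality,
        "units": stack.units,
        "spacing_mm": list(stack.spacing),
        **{k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises
    ------
    FileNotFoundError
        If the JSON sidecar holding modality/units metadata is absent.
    ValueError
        If the sidecar lacks required keys or spacing is missing.
    """
    path = Path(path)
    img = nib.load(str(path))
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"missing JSON sidecar {sidecar_file.name}: modality and units metadata are required"
        )
    sidecar = json.loads(sidecar_file.read_text())
    for key in ("modality", "units", "spacing_mm"):
        if key not in sidecar:
            raise ValueError(f"sidecar {sidecar_file.name} missing required key {key!r}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header has no positive voxel spacing")
    if not np.allclose(zooms, sidecar["spacing_mm"], atol=1e-4):
        raise ValueError(
            f"header spacing {tuple(zooms)} disagrees with sidecar {sidecar['spacing_mm']}"
        )
    data = np.asanyarray(img.dataobj)
    extra = {k: v for k, v in sidecar.items() if k not in ("modality", "units", "spacing_mm")}
    return ImageStack(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        modality=sidecar["modality"],
        units=sidecar["units"],
        meta=extra,
    )


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False
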