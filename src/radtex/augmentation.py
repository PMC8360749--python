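"""Affine data augmentation for labeled volumes.

Four in-plane transform families — flips, scaling, rotation, shear — applied
slice-wise in the axial plane about the slice center. Intensities are
resampled with linear interpolation, masks with nearest-neighbor (so masks
stay binary); out-of-bounds regions are filled with 0. Flips are performed as
exact axis reversals.

Augmented copies keep their parent's label and ``source_id`` so that
downstream cross-validation can group a scan with all of its copies and avoid
train/test leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import ROIMask, VolumeImage

__all__ = ["AugmentationSpec", "AugmentedSample", "apply_affine", "augment_dataset"]

# parameter ranges used when a randomized parameter is drawn
ROTATE_RANGE = (25.0, 195.0)
SHEAR_RANGE = (0.3, 0.7)
SCALE_RANGE = (0.8, 1.2)

Kind = Literal["flip", "scale", "rotate", "shear"]


@dataclass(frozen=True)
class AugmentationSpec:
    """One affine transform. Parameters not matching ``kind`` are ignored.

    A ``None`` parameter means "draw uniformly from the standard range"
    (rotation angle in [25, 195] degrees, shear in [0.3, 0.7], scale factors
    in [0.8, 1.2]) when the spec is resolved with a random generator.
    """

    kind: Kind
    axis: Optional[Literal["horizontal", "vertical"]] = None
    sx: Optional[float] = None
    sy: Optional[float] = None
    angle_deg: Optional[float] = None
    shear_s: Optional[float] = None

    def validate(self) -> None:
        if self.kind == "flip":
            if self.axis not in ("horizontal", "vertical"):
                raise ValueError("flip requires axis 'horizontal' or 'vertical'")
        elif self.kind == "scale":
            for s in (self.sx, self.sy):
                if s is not None and s <= 0:
                    raise ValueError(f"scale factors must be positive, got {s}")
        elif self.kind == "rotate":
            pass
        elif self.kind == "shear":
            pass
        else:
            raise ValueError(f"unknown augmentation kind {self.kind!r}")

    def resolve(self, rng: np.random.Generator) -> "AugmentationSpec":
        """Fill in any randomized (None) parameters from the standard ranges."""
        self.validate()
        if self.kind == "scale":
            sx = self.sx if self.sx is not None else float(rng.uniform(*SCALE_RANGE))
            sy = self.sy if self.sy is not None else float(rng.uniform(*SCALE_RANGE))
            return replace(self, sx=sx, sy=sy)
        if self.kind == "rotate" and self.angle_deg is None:
            return replace(self, angle_deg=float(rng.uniform(*ROTATE_RANGE)))
        if self.kind == "shear" and self.shear_s is None:
            return replace(self, shear_s=float(rng.uniform(*SHEAR_RANGE)))
        return self

    def matrix(self) -> np.ndarray:
        """The forward in-plane 2x2 transform matrix (flip excluded)."""
        if self.kind == "scale":
            return np.array([[self.sx, 0.0], [0.0, self.sy]])
        if self.kind == "rotate":
            a = math.radians(self.angle_deg)
            return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        if self.kind == "shear":
            return np.array([[1.0, self.shear_s], [0.0, 1.0]])
        raise ValueError(f"no matrix for kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for k in ("axis", "sx", "sy", "angle_deg", "shear_s"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationSpec":
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class AugmentedSample:
    """A labeled volume plus provenance: its un-augmented parent scan id."""

    volume: VolumeImage
    mask: ROIMask
    label: int
    source_id: str
    spec: AugmentationSpec | str = "identity"


def _affine_slicewise(
    data: np.ndarray, mat2: np.ndarray, order: int, cval: float = 0.0
) -> np.ndarray:
    """Apply an in-plane 2x2 transform about each axial slice's center.

    The axial plane is spanned by array axes (0, 1); axis 2 indexes slices.
    ``ndimage.affine_transform`` maps output to input coordinates, so the
    inverse of the forward matrix is embedded in a 3x3 voxel-space matrix
    with identity on the slice axis.
    """
    inv2 = np.round(np.linalg.inv(mat2), 12)  # snap ~1e-16 trig noise so
    m = np.eye(3)                             # exact 90/180 deg stay on-grid
    m[:2, :2] = inv2
    center = (np.array(data.shape, dtype=float) - 1.0) / 2.0
    offset = np.round(center - m @ center, 12)
    return ndimage.affine_transform(
        data.astype(np.float64), m, offset=offset, order=order, mode="constant", cval=cval
    )


def apply_affine(
    vol: VolumeImage, mask: ROIMask, spec: AugmentationSpec
) -> tuple[VolumeImage, ROIMask]:
    """Apply one transform to a volume/mask pair; output shape equals input."""
    spec.validate()
    mask.check_compatible(vol)
    if spec.kind == "flip":
        ax = 0 if spec.axis == "horizontal" else 1
        new_data = np.flip(vol.data, axis=ax).copy()
        new_mask = np.flip(mask.data, axis=ax).copy()
    else:
        for s in (spec.sx, spec.sy):
            if spec.kind == "scale" and (s is None or s <= 0):
                raise ValueError("scale requires positive sx and sy")
        if spec.kind == "rotate" and spec.angle_deg is None:
            raise ValueError("rotate requires angle_deg")
        if spec.kind == "shear" and spec.shear_s is None:
            raise ValueError("shear requires shear_s")
        mat = spec.matrix()
        new_data = _affine_slicewise(vol.data, mat, order=1)
        new_mask = _affine_slicewise(mask.data.astype(np.float64), mat, order=0) > 0.5
    return (
        VolumeImage(data=new_data, spacing=vol.spacing, affine=vol.affine.copy()),
        ROIMask(data=new_mask),
    )


def augment_dataset(
    samples: Sequence[AugmentedSample],
    plan: Sequence[AugmentationSpec],
    seed: int = 0,
) -> list[AugmentedSample]:
    """Return originals plus one augmented copy per (sample, spec) pair.

    Randomized parameters (None entries in a spec) are drawn deterministically
    from ``seed``. Labels and source_ids are preserved.
    """
    if len(plan) == 0:
        raise ValueError("augmentation plan must be nonempty")
    rng = np.random.default_rng(seed)
    out: list[AugmentedSample] = list(samples)
    for sample in samples:
        for spec in plan:
            resolved = spec.resolve(rng)
            v, m = apply_affine(sample.volume, sample.mask, resolved)
            out.append(
                AugmentedSample(
                    volume=v,
                    mask=m,
                    label=sample.label,
                    source_id=sample.source_id,
                    spec=resolved,
                )
            )
    return out
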