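"""NIfTI volume I/O and gray-level discretization.

Texture matrices operate on a finite gray-level alphabet, so continuous MRI
intensities are binned into ``Ng`` integer levels ``1..Ng`` over the region of
interest; voxels outside the mask carry the sentinel level 0 and never
participate in any pair/zone/run/neighborhood count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "ROIMask",
    "DiscretizedVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "discretize",
]


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with physical voxel spacing (mm).

    ``affine`` places voxel (0,0,0) in scanner space; voxel indices are
    0-based and physical coordinates are ``index * spacing`` (+ origin).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every volume dimension must have size >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel (mm^3)."""
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """Binary region-of-interest mask sharing its volume's grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_compatible(self, vol: VolumeImage) -> None:
        if self.data.shape != vol.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match volume shape {vol.data.shape}"
            )


@dataclass
class DiscretizedVolume:
    """Integer gray levels over a masked region.

    ``levels`` holds values in {0 (outside mask), 1..Ng}; ``bin_edges`` is the
    strictly increasing intensity partition that produced them.
    """

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inside = self.levels[self.levels > 0]
        if inside.size and inside.max() > self.ng:
            raise ValueError("in-mask level exceeds Ng")
        if self.ng < 1:
            raise ValueError("Ng must be >= 1")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_masked(self) -> int:
        return int((self.levels > 0).sum())


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI volume, decoding data, voxel spacing and affine.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    non-3D image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data.astype(np.float64), spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a VolumeImage to NIfTI; spacing is encoded in the affine/header."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> ROIMask:
    """Read a mask NIfTI; any nonzero voxel is foreground."""
    vol = read_volume(path)
    return ROIMask(data=vol.data != 0)


def write_mask(mask: ROIMask, vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def discretize(vol: VolumeImage, mask: ROIMask, bin_count: int = 32) -> DiscretizedVolume:
    """Bin in-mask intensities into ``bin_count`` equal-width gray levels.

    Bins span the in-mask intensity range; the maximum intensity falls in the
    top bin (right-closed last bin). A constant region yields ``Ng = 1``.
    """
    mask.check_compatible(vol)
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    m = mask.data
    if not m.any():
        raise ValueError("empty ROI")
    vals = vol.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.data.shape, dtype=np.int64)
    if hi == lo:
        ng = 1
        levels[m] = 1
        edges = np.array([lo, lo + 1.0])
    else:
        ng = int(bin_count)
        edges = np.linspace(lo, hi, ng + 1)
        # digitize against interior edges: level k <=> intensity in bin k,
        # with the max clipped into the top bin
        lev = np.digitize(vol.data[m], edges[1:-1], right=False) + 1
        levels[m] = np.minimum(lev, ng)
        edges = edges.copy()
    return DiscretizedVolume(levels=levels, ng=ng, bin_edges=edges, spacing=vol.spacing)
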