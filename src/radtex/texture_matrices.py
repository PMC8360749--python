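"""The five standard texture matrices and their named features.

All builders operate on a :class:`~radtex.volume_io.DiscretizedVolume` whose
in-mask voxels carry levels 1..Ng (0 marks outside). Counting conventions:

* GLCM — ordered in-mask voxel pairs (x, x + delta*direction); the symmetric
  variant adds the transpose (Haralick convention).
* GLSZM — connected components of equal level (26-connectivity in 3D,
  direction-free); entry (i, s) counts zones of level i and size s.
* GLRLM — maximal same-level runs along a direction, broken by the mask.
* NGTDM — per-level sums s_i of |i - mean of in-mask Chebyshev neighbors|,
  center excluded; voxels with no valid neighbor are dropped.
* GLDM — voxels of level i classified by their number d of in-mask neighbors
  within gray-level tolerance gamma; the dependence column starts at d = 0.

Features of GLCM and GLRLM are computed per direction and averaged across
directions (13 unique directions in 3D, 4 in-plane directions in 2D mode).
Every builder is matched against an exhaustive brute-force enumerator in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import DiscretizedVolume

__all__ = [
    "TextureMatrix",
    "NGTDMTriple",
    "directions_3d",
    "directions_2d",
    "glcm",
    "glcm_features",
    "glszm",
    "glszm_features",
    "glrlm",
    "glrlm_features",
    "ngtdm",
    "ngtdm_features",
    "gldm",
    "gldm_features",
    "average_feature_maps",
    "texture_features",
]

_EPS = np.finfo(np.float64).eps


@dataclass
class TextureMatrix:
    kind: str  # GLCM / GLSZM / GLRLM / NGTDM / GLDM / DGLM
    counts: np.ndarray
    ng: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError("texture matrix entries must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        t = self.total
        if t <= 0:
            raise ValueError(f"empty texture matrix ({self.kind})")
        return self.counts / t


@dataclass
class NGTDMTriple:
    """Per-level voxel counts, probabilities, and absolute-difference sums."""

    n: np.ndarray  # n_i, length Ng (index 0 <-> level 1)
    s: np.ndarray  # s_i
    ng: int

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64)
        if (self.s < 0).any():
            raise ValueError("s_i must be non-negative")

    @property
    def n_valid(self) -> float:
        return float(self.n.sum())

    @property
    def p(self) -> np.ndarray:
        return self.n / self.n.sum()


# ---------------------------------------------------------------------------
# direction sets

def directions_3d() -> list[tuple[int, int, int]]:
    """The 13 unique (up to sign) 3D nearest-neighbor directions."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                # keep the representative whose first nonzero component is +1
                first = next(c for c in d if c != 0)
                if first > 0:
                    dirs.append(d)
    return dirs


def directions_2d() -> list[tuple[int, int, int]]:
    """In-plane directions at angles 0, 45, 90, 135 degrees (axes 0,1)."""
    return [(1, 0, 0), (1, 1, 0), (0, 1, 0), (-1, 1, 0)]


def _pair_views(a: np.ndarray, offset: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (src, dst) with dst[x] = a[x + offset]."""
    src, dst = [], []
    for size, o in zip(a.shape, offset):
        if abs(o) >= size:
            return a[0:0], a[0:0]
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return a[tuple(src)], a[tuple(dst)]


# ---------------------------------------------------------------------------
# GLCM

def glcm(
    dvol: DiscretizedVolume,
    direction: Sequence[int],
    delta: int = 1,
    symmetric: bool = True,
) -> TextureMatrix:
    """Gray-level co-occurrence counts for one (direction, distance) offset."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    ng = dvol.ng
    offset = tuple(int(d) * delta for d in direction)
    src, dst = _pair_views(dvol.levels, offset)
    valid = (src > 0) & (dst > 0)
    i, j = src[valid] - 1, dst[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    if counts.sum() == 0:
        warnings.warn(f"no valid voxel pairs for offset {offset}", stacklevel=2)
    return TextureMatrix(
        kind="GLCM", counts=counts, ng=ng,
        params={"direction": tuple(direction), "delta": delta, "symmetric": symmetric},
    )


def _haralick_imc1_mcc(p: np.ndarray) -> tuple[float, float]:
    """IMC1 and maximal correlation coefficient of a normalized (possibly
    non-symmetric) co-occurrence distribution."""
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz] + _EPS)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz] + _EPS)).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0] + _EPS)).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0] + _EPS)).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0

    rows = px > 0
    cols = py > 0
    if rows.sum() < 2 or cols.sum() < 2:
        mcc = 1.0
    else:
        sub = p[np.ix_(rows, cols)]
        q = (sub[:, None, :] * sub[None, :, :] / (px[rows][:, None, None] * py[cols][None, None, :])).sum(axis=2)
        ev = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(np.clip(ev[1], 0.0, 1.0)))
    return imc1, mcc


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    p = m.probabilities()
    ng = m.ng
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((np.arange(1, ng + 1) * px).sum())
    mu_y = float((np.arange(1, ng + 1) * py).sum())
    sig_x = float(np.sqrt(((np.arange(1, ng + 1) - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((np.arange(1, ng + 1) - mu_y) ** 2 * py).sum()))
    nz = p > 0
    autoc = float((i * j * p).sum())
    diff = np.abs(i - j)
    # p_{|i-j|}(k): distribution of absolute level differences
    pd = np.bincount(diff.ravel(), weights=p.ravel(), minlength=ng)
    off = i != j
    inv_var = float((p[off] / ((i - j) ** 2 * np.ones_like(p))[off]).sum())
    corr = (autoc - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 0.0
    imc1, mcc = _haralick_imc1_mcc(p)
    return {
        "autocorrelation": autoc,
        "joint_average": mu_x,
        "joint_entropy": float(-(p[nz] * np.log2(p[nz] + _EPS)).sum()),
        "variance": float((((i - mu_x) ** 2) * p).sum()),
        "contrast": float((((i - j) ** 2) * p).sum()),
        "energy": float((p**2).sum()),
        "homogeneity": float((p / (1.0 + diff)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "inverse_variance": inv_var,
        "correlation": float(corr),
        "cluster_shade": float((((i + j - mu_x - mu_y) ** 3) * p).sum()),
        "difference_average": float((np.arange(ng) * pd).sum()),
        "imc1": float(imc1),
        "mcc": float(mcc),
    }


# ---------------------------------------------------------------------------
# GLSZM

_CONN_RANK = {6: 1, 18: 2, 26: 3, 4: 1, 8: 2}


def glszm(dvol: DiscretizedVolume, connectivity: int = 26) -> TextureMatrix:
    """Size-zone counts: entry (i, s) = zones of level i with exactly s voxels."""
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}")
    if connectivity in (4, 8):
        # in-plane zones only: no connectivity across the slice axis
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[:, :, 1] = ndimage.generate_binary_structure(2, _CONN_RANK[connectivity])
    else:
        structure = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    ng = dvol.ng
    zones: dict[int, np.ndarray] = {}
    max_size = 1
    for level in range(1, ng + 1):
        labeled, n_comp = ndimage.label(dvol.levels == level, structure=structure)
        if n_comp == 0:
            zones[level] = np.array([], dtype=np.int64)
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zones[level] = sizes
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for level, sizes in zones.items():
        if sizes.size:
            counts[level - 1] += np.bincount(sizes, minlength=max_size + 1)[1:]
    return TextureMatrix(kind="GLSZM", counts=counts, ng=ng, params={"connectivity": connectivity})


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    p = m.probabilities()
    ng, ns = p.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, ns + 1)[None, :].astype(float)
    nz = m.total
    row = m.counts.sum(axis=1)
    col = m.counts.sum(axis=0)
    return {
        "small_area_emphasis": float((p / s**2).sum()),
        "large_area_emphasis": float((p * s**2).sum()),
        "gray_level_nonuniformity": float((row**2).sum() / nz),
        "gray_level_nonuniformity_normalized": float((row**2).sum() / nz**2),
        "size_zone_nonuniformity": float((col**2).sum() / nz),
        "size_zone_nonuniformity_normalized": float((col**2).sum() / nz**2),
        "small_area_low_gray_level_emphasis": float((p / (i**2 * s**2)).sum()),
        "small_area_high_gray_level_emphasis": float((p * i**2 / s**2).sum()),
        "large_area_low_gray_level_emphasis": float((p * s**2 / i**2).sum()),
        "large_area_high_gray_level_emphasis": float((p * i**2 * s**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm(dvol: DiscretizedVolume, direction: Sequence[int]) -> TextureMatrix:
    """Run-length counts: entry (i, r) = maximal runs of level i, length r."""
    lev = dvol.levels
    ng = dvol.ng
    off = tuple(int(d) for d in direction)
    # edge[x]: run continues from x to x+off
    edge = np.zeros(lev.shape, dtype=bool)
    succ = np.zeros(lev.shape, dtype=np.int64)  # consecutive successors count
    src_v, dst_v = _pair_views(lev, off)
    if src_v.size:
        src_slices, dst_slices = _view_slices(lev.shape, off)
        edge[src_slices] = (src_v > 0) & (src_v == dst_v)
        # fixpoint: succ[x] = edge[x] * (1 + succ[x + off])
        while True:
            nxt = np.zeros_like(succ)
            nxt[src_slices] = succ[dst_slices]
            new = edge * (1 + nxt)
            if (new == succ).all():
                break
            succ = new
    has_pred = np.zeros(lev.shape, dtype=bool)
    if src_v.size:
        has_pred[dst_slices] = edge[src_slices]
    starts = (lev > 0) & ~has_pred
    run_lengths = 1 + succ[starts]
    run_levels = lev[starts]
    max_r = int(run_lengths.max()) if run_lengths.size else 1
    counts = np.zeros((ng, max_r), dtype=np.float64)
    np.add.at(counts, (run_levels - 1, run_lengths - 1), 1.0)
    return TextureMatrix(kind="GLRLM", counts=counts, ng=ng, params={"direction": off})


def _view_slices(shape: Sequence[int], offset: Sequence[int]):
    src, dst = [], []
    for size, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def glrlm_features(m: TextureMatrix, n_masked: int | None = None) -> dict[str, float]:
    p = m.probabilities()
    ng, nr = p.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    r = np.arange(1, nr + 1)[None, :].astype(float)
    total = m.total
    row = m.counts.sum(axis=1)
    col = m.counts.sum(axis=0)
    if n_masked is None:
        n_masked = int(round(float((m.counts * r).sum())))  # runs partition voxels
    mu_i = float((i * p).sum())
    mu_r = float((r * p).sum())
    nz = p > 0
    return {
        "short_run_emphasis": float((p / r**2).sum()),
        "long_run_emphasis": float((p * r**2).sum()),
        "gray_level_nonuniformity": float((row**2).sum() / total),
        "gray_level_nonuniformity_normalized": float((row**2).sum() / total**2),
        "run_length_nonuniformity": float((col**2).sum() / total),
        "run_length_nonuniformity_normalized": float((col**2).sum() / total**2),
        "run_percentage": float(total / n_masked),
        "gray_level_variance": float((((i - mu_i) ** 2) * p).sum()),
        "run_variance": float((((r - mu_r) ** 2) * p).sum()),
        "run_entropy": float(-(p[nz] * np.log2(p[nz] + _EPS)).sum()),
        "low_gray_level_run_emphasis": float((p / i**2).sum()),
        "high_gray_level_run_emphasis": float((p * i**2).sum()),
        "short_run_low_gray_level_emphasis": float((p / (i**2 * r**2)).sum()),
        "short_run_high_gray_level_emphasis": float((p * i**2 / r**2).sum()),
        "long_run_low_gray_level_emphasis": float((p * r**2 / i**2).sum()),
        "long_run_high_gray_level_emphasis": float((p * i**2 * r**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm(dvol: DiscretizedVolume, radius: int = 1) -> NGTDMTriple:
    """Neighborhood gray-tone difference sums.

    For each in-mask voxel the neighborhood mean is taken over in-mask voxels
    within Chebyshev radius ``radius``, excluding the center; voxels with no
    valid neighbor are excluded entirely.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    lev = dvol.levels.astype(np.float64)
    m = (dvol.levels > 0).astype(np.float64)
    k = 2 * radius + 1
    kernel = np.ones((k, k, k))
    nbr_sum = ndimage.correlate(lev * m, kernel, mode="constant", cval=0.0) - lev * m
    nbr_cnt = ndimage.correlate(m, kernel, mode="constant", cval=0.0) - m
    valid = (dvol.levels > 0) & (nbr_cnt > 0.5)
    if not valid.any():
        raise ValueError("no in-mask voxel has a valid neighbor")
    gbar = nbr_sum[valid] / nbr_cnt[valid]
    levels = dvol.levels[valid]
    diffs = np.abs(levels - gbar)
    n = np.bincount(levels, minlength=dvol.ng + 1)[1:].astype(np.float64)
    s = np.bincount(levels, weights=diffs, minlength=dvol.ng + 1)[1:]
    return NGTDMTriple(n=n, s=s, ng=dvol.ng)


COARSENESS_SENTINEL = 1e6


def ngtdm_features(t: NGTDMTriple) -> dict[str, float]:
    present = t.n > 0
    n_gp = int(present.sum())
    n_vp = t.n_valid
    if n_vp <= 0:
        raise ValueError("empty NGTDM")
    p = t.p
    s = t.s
    i = np.arange(1, t.ng + 1).astype(float)
    ps_sum = float((p * s).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else COARSENESS_SENTINEL

    ip = i[present]
    pp = p[present]
    sp = s[present]
    if n_gp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum() / (n_gp * (n_gp - 1)) * (s.sum() / n_vp)
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps_sum / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum() / n_vp
        )
        s_sum = float(sp.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM

def gldm(dvol: DiscretizedVolume, radius: int = 1, gamma: int = 0) -> TextureMatrix:
    """Dependence counts: entry (i, d) = voxels of level i with exactly d
    in-mask Chebyshev neighbors whose level j satisfies |i - j| <= gamma."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    lev = dvol.levels
    ng = dvol.ng
    dep = np.zeros(lev.shape, dtype=np.int64)
    rng_off = range(-radius, radius + 1)
    for dx in rng_off:
        for dy in rng_off:
            for dz in rng_off:
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                src_sl, dst_sl = _view_slices(lev.shape, (dx, dy, dz))
                src, dst = lev[src_sl], lev[dst_sl]
                dep[src_sl] += ((src > 0) & (dst > 0) & (np.abs(src - dst) <= gamma)).astype(np.int64)
    inside = lev > 0
    d_vals = dep[inside]
    i_vals = lev[inside]
    max_d = int(d_vals.max()) if d_vals.size else 0
    counts = np.zeros((ng, max_d + 1), dtype=np.float64)
    np.add.at(counts, (i_vals - 1, d_vals), 1.0)
    return TextureMatrix(kind="GLDM", counts=counts, ng=ng, params={"radius": radius, "gamma": gamma})


def gldm_features(m: TextureMatrix) -> dict[str, float]:
    """GLDM features; the dependence count d (column index, starting at 0) is
    mapped to d+1 wherever it enters a squared/reciprocal term."""
    p = m.probabilities()
    ng, nd = p.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    d = (np.arange(nd) + 1.0)[None, :]  # d+1 mapping
    row = m.counts.sum(axis=1)
    col = m.counts.sum(axis=0)
    total = m.total
    mu_i = float((i * p).sum())
    mu_d = float((d * p).sum())
    nz = p > 0
    return {
        "small_dependence_emphasis": float((p / d**2).sum()),
        "large_dependence_emphasis": float((p * d**2).sum()),
        "gray_level_nonuniformity": float((row**2).sum() / total),
        "dependence_nonuniformity": float((col**2).sum() / total),
        "dependence_nonuniformity_normalized": float((col**2).sum() / total**2),
        "gray_level_variance": float((((i - mu_i) ** 2) * p).sum()),
        "dependence_variance": float((((d - mu_d) ** 2) * p).sum()),
        "dependence_entropy": float(-(p[nz] * np.log2(p[nz] + _EPS)).sum()),
        "low_gray_level_emphasis": float((p / i**2).sum()),
        "high_gray_level_emphasis": float((p * i**2).sum()),
        "small_dependence_low_gray_level_emphasis": float((p / (i**2 * d**2)).sum()),
        "small_dependence_high_gray_level_emphasis": float((p * i**2 / d**2).sum()),
        "large_dependence_low_gray_level_emphasis": float((p * d**2 / i**2).sum()),
    }


# ---------------------------------------------------------------------------
# aggregation

def average_feature_maps(maps: Iterable[dict[str, float]]) -> dict[str, float]:
    """Arithmetic mean of feature maps sharing the same keys."""
    maps = list(maps)
    if not maps:
        raise ValueError("no feature maps to average")
    keys = maps[0].keys()
    return {k: float(np.mean([mp[k] for mp in maps])) for k in keys}


def texture_features(
    dvol: DiscretizedVolume,
    delta: int = 1,
    ngtdm_radius: int = 1,
    gldm_radius: int = 1,
    gldm_gamma: int = 0,
    connectivity: int = 26,
    mode_2d: bool = False,
) -> dict[str, float]:
    """All standard texture-matrix features, direction-averaged and prefixed.

    GLCM and GLRLM features are averaged over the 13 unique 3D directions
    (4 in-plane directions in 2D mode); GLSZM/NGTDM/GLDM are direction-free.
    """
    dirs = directions_2d() if mode_2d else directions_3d()
    n_masked = dvol.n_masked
    glcm_maps = []
    glrlm_maps = []
    for direction in dirs:
        gm = glcm(dvol, direction, delta=delta, symmetric=True)
        if gm.total > 0:
            glcm_maps.append(glcm_features(gm))
        glrlm_maps.append(glrlm_features(glrlm(dvol, direction), n_masked=n_masked))
    feats: dict[str, float] = {}
    feats.update({f"glcm_{k}": v for k, v in average_feature_maps(glcm_maps).items()})
    feats.update({f"glrlm_{k}": v for k, v in average_feature_maps(glrlm_maps).items()})
    feats.update({f"glszm_{k}": v for k, v in glszm_features(glszm(dvol, connectivity)).items()})
    feats.update({f"ngtdm_{k}": v for k, v in ngtdm_features(ngtdm(dvol, ngtdm_radius)).items()})
    feats.update(
        {f"gldm_{k}": v for k, v in gldm_features(gldm(dvol, gldm_radius, gldm_gamma)).items()}
    )
    return feats
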