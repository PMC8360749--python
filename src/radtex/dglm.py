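"""The decreasing gray-level matrix (DGLM), a directional co-occurrence filter.

DGLM counts ordered in-plane pixel pairs (x, x + offset) whose gray levels
(i, j) satisfy i <= j; pairs with strictly decreasing intensity are
discarded. The result is upper-triangular (including the diagonal) and,
unlike the GLCM, inherently directional: no transpose-symmetrization is
applied. Equivalently, DGLM is the asymmetric co-occurrence matrix masked to
its upper triangle.

Matrices are accumulated slice-wise in the axial plane at the four in-plane
angles 0, 45, 90 and 135 degrees; features are computed per angle and then
averaged. Angle conventions (array axes 0, 1 in-plane):

* 0 degrees   -> offset (1, 0)
* 45 degrees  -> offset (1, 1)
* 90 degrees  -> offset (0, 1)
* 135 degrees -> offset (-1, 1)

A ``strict`` flag switches the keep-condition to i < j (dropping the
diagonal); the default keeps i <= j.
"""

from __future__ import annotations

import warnings

import numpy as np

from .texture_matrices import TextureMatrix, _haralick_imc1_mcc, _pair_views, average_feature_maps
from .volume_io import DiscretizedVolume

__all__ = ["DGLM_ANGLES", "dglm_matrix", "dglm_features", "dglm_averaged_features"]

_EPS = np.finfo(np.float64).eps

DGLM_ANGLES: dict[int, tuple[int, int]] = {
    0: (1, 0),
    45: (1, 1),
    90: (0, 1),
    135: (-1, 1),
}


def dglm_matrix(
    dvol: DiscretizedVolume,
    angle: int,
    delta: int = 1,
    strict: bool = False,
) -> TextureMatrix:
    """DGLM counts for one in-plane angle, pooled over all axial slices."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if angle not in DGLM_ANGLES:
        raise ValueError(f"angle must be one of {sorted(DGLM_ANGLES)}")
    da, db = DGLM_ANGLES[angle]
    offset = (da * delta, db * delta, 0)  # in-plane: slices never mix
    ng = dvol.ng
    src, dst = _pair_views(dvol.levels, offset)
    keep = (src > 0) & (dst > 0) & ((src < dst) if strict else (src <= dst))
    i, j = src[keep] - 1, dst[keep] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    if counts.sum() == 0:
        warnings.warn(f"DGLM angle {angle}: no pair satisfies the keep-condition", stacklevel=2)
    assert not np.tril(counts, -1).any(), "DGLM must be upper-triangular"
    return TextureMatrix(
        kind="DGLM", counts=counts, ng=ng,
        params={"angle": angle, "delta": delta, "strict": strict},
    )


def dglm_features(m: TextureMatrix) -> dict[str, float]:
    """Named DGLM features of one matrix.

    ``mean`` and the higher moments are first-order statistics of the row
    level i under the normalized matrix p(i, j) (marginal over i); IMC1 and
    the maximal correlation coefficient use the standard Haralick formulas
    applied to the non-symmetric normalized DGLM.
    """
    if m.total <= 0:
        raise ValueError("empty DGLM")
    p = m.probabilities()
    ng = m.ng
    iv = np.arange(1, ng + 1)[:, None].astype(float)
    jv = np.arange(1, ng + 1)[None, :].astype(float)
    nz = p > 0
    mean = float((iv * p).sum())
    var = float((((iv - mean) ** 2) * p).sum())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float((((iv - mean) / sd) ** 3 * p).sum())
        kurt = float((((iv - mean) / sd) ** 4 * p).sum())
    else:
        skew = kurt = 0.0
    imc1, mcc = _haralick_imc1_mcc(p)
    return {
        "energy": float((p**2).sum()),
        "mean": mean,
        "mean_absolute_deviation": float((np.abs(iv - mean) * p).sum()),
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": float(-(p[nz] * np.log2(p[nz] + _EPS)).sum()),
        "autocorrelation": float((iv * jv * p).sum()),
        "imc1": float(imc1),
        "mcc": float(mcc),
    }


def dglm_averaged_features(
    dvol: DiscretizedVolume,
    delta: int = 1,
    strict: bool = False,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> dict[str, float]:
    """DGLM features averaged over the angles with nonzero matrices.

    Keys are prefixed ``dglm_``. Raises if every angle yields an empty matrix.
    """
    maps = []
    for angle in angles:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = dglm_matrix(dvol, angle, delta=delta, strict=strict)
        if m.total > 0:
            maps.append(dglm_features(m))
    if not maps:
        raise ValueError("all DGLM angle matrices are empty")
    return {f"dglm_{k}": v for k, v in average_feature_maps(maps).items()}
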