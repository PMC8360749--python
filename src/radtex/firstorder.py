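"""First-order intensity statistics over the masked voxels.

Sixteen statistics of the raw in-mask intensity distribution; entropy alone
is computed on the discretized gray-level histogram x(i) = X(i)/N_v in bits.
Moments are population (1/N) moments; skewness and kurtosis are the
standardized third and fourth moments (kurtosis is not excess-corrected, so
a normal distribution scores ~3). For a constant region skewness and
kurtosis are returned as 0 with a warning rather than NaN.
"""

from __future__ import annotations

import warnings

import numpy as np

from .volume_io import DiscretizedVolume, ROIMask, VolumeImage

__all__ = ["firstorder_features"]

_EPS = np.finfo(np.float64).eps


def firstorder_features(
    vol: VolumeImage, mask: ROIMask, dvol: DiscretizedVolume
) -> dict[str, float]:
    mask.check_compatible(vol)
    m = mask.data
    if not m.any():
        raise ValueError("empty ROI")
    x = vol.data[m].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    std = float(x.std())  # population, ddof=0
    var = std * std
    if std == 0.0:
        warnings.warn("constant region: skewness/kurtosis set to 0", stacklevel=2)
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean())

    levels = dvol.levels[m]
    counts = np.bincount(levels, minlength=dvol.ng + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p + _EPS)).sum())

    energy = float((x**2).sum())  # c = 0
    p10, p90 = (float(v) for v in np.percentile(x, [10, 90]))
    return {
        "firstorder_energy": energy,
        "firstorder_total_energy": float(np.prod(dvol.spacing)) * energy,
        "firstorder_entropy": entropy,
        "firstorder_minimum": float(x.min()),
        "firstorder_p10": p10,
        "firstorder_p90": p90,
        "firstorder_maximum": float(x.max()),
        "firstorder_mean": mean,
        "firstorder_median": float(np.median(x)),
        "firstorder_range": float(x.max() - x.min()),
        "firstorder_mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "firstorder_rms": float(np.sqrt((x**2).mean())),
        "firstorder_std_dev": std,
        "firstorder_skewness": skew,
        "firstorder_kurtosis": kurt,
        "firstorder_variance": var,
    }
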