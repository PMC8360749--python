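"""Independent brute-force oracles for texture matrices and features.

Everything here is deliberately naive: explicit Python loops over voxels,
neighbors and matrix entries, written directly from the counting definitions.
These implementations share no code with the package and serve as the ground
truth the vectorized builders are checked against.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.finfo(np.float64).eps


def _in_bounds(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def bf_glcm(lev: np.ndarray, direction, delta=1, symmetric=True) -> np.ndarray:
    ng = int(lev.max())
    counts = np.zeros((ng, ng))
    off = tuple(d * delta for d in direction)
    for p in np.ndindex(lev.shape):
        if lev[p] == 0:
            continue
        q = tuple(c + o for c, o in zip(p, off))
        if _in_bounds(lev.shape, q) and lev[q] > 0:
            counts[lev[p] - 1, lev[q] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def _neighbor_offsets(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                manhattan = sum(abs(c) for c in d)
                if connectivity == 6 and manhattan == 1:
                    offs.append(d)
                elif connectivity == 18 and manhattan <= 2:
                    offs.append(d)
                elif connectivity == 26:
                    offs.append(d)
                elif connectivity == 4 and dz == 0 and manhattan == 1:
                    offs.append(d)
                elif connectivity == 8 and dz == 0 and manhattan >= 1:
                    offs.append(d)
    return offs


def bf_glszm(lev: np.ndarray, ng: int, connectivity=26) -> np.ndarray:
    """Zone sizes by flood fill per level."""
    offs = _neighbor_offsets(connectivity)
    visited = np.zeros(lev.shape, dtype=bool)
    zones = []  # (level, size)
    for p in np.ndindex(lev.shape):
        if lev[p] == 0 or visited[p]:
            continue
        level = lev[p]
        stack = [p]
        visited[p] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offs:
                q = tuple(c + o for c, o in zip(cur, off))
                if _in_bounds(lev.shape, q) and not visited[q] and lev[q] == level:
                    visited[q] = True
                    stack.append(q)
        zones.append((level, size))
    max_s = max(s for _, s in zones)
    counts = np.zeros((ng, max_s))
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def bf_glrlm(lev: np.ndarray, direction, ng: int) -> np.ndarray:
    runs = []
    off = tuple(direction)
    for p in np.ndindex(lev.shape):
        if lev[p] == 0:
            continue
        prev = tuple(c - o for c, o in zip(p, off))
        if _in_bounds(lev.shape, prev) and lev[prev] == lev[p]:
            continue  # not a run start
        length = 1
        q = tuple(c + o for c, o in zip(p, off))
        while _in_bounds(lev.shape, q) and lev[q] == lev[p]:
            length += 1
            q = tuple(c + o for c, o in zip(q, off))
        runs.append((lev[p], length))
    max_r = max(r for _, r in runs)
    counts = np.zeros((ng, max_r))
    for level, length in runs:
        counts[level - 1, length - 1] += 1
    return counts


def bf_ngtdm(lev: np.ndarray, ng: int, radius=1):
    """Returns (n_i, s_i) arrays of length ng (index 0 <-> level 1)."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    r = range(-radius, radius + 1)
    for p in np.ndindex(lev.shape):
        if lev[p] == 0:
            continue
        nbrs = []
        for dx in r:
            for dy in r:
                for dz in r:
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if _in_bounds(lev.shape, q) and lev[q] > 0:
                        nbrs.append(lev[q])
        if not nbrs:
            continue
        gbar = sum(nbrs) / len(nbrs)
        n[lev[p] - 1] += 1
        s[lev[p] - 1] += abs(lev[p] - gbar)
    return n, s


def bf_gldm(lev: np.ndarray, ng: int, radius=1, gamma=0) -> np.ndarray:
    rows = []
    r = range(-radius, radius + 1)
    for p in np.ndindex(lev.shape):
        if lev[p] == 0:
            continue
        dep = 0
        for dx in r:
            for dy in r:
                for dz in r:
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if _in_bounds(lev.shape, q) and lev[q] > 0 and abs(lev[p] - lev[q]) <= gamma:
                        dep += 1
        rows.append((lev[p], dep))
    max_d = max(d for _, d in rows)
    counts = np.zeros((ng, max_d + 1))
    for level, dep in rows:
        counts[level - 1, dep] += 1
    return counts


def bf_dglm(lev: np.ndarray, ng: int, angle_offset, delta=1, strict=False) -> np.ndarray:
    """Slice-wise directional co-occurrence keeping pairs with i <= j."""
    da, db = angle_offset
    counts = np.zeros((ng, ng))
    for z in range(lev.shape[2]):
        sl = lev[:, :, z]
        for x in range(sl.shape[0]):
            for y in range(sl.shape[1]):
                i = sl[x, y]
                if i == 0:
                    continue
                qx, qy = x + da * delta, y + db * delta
                if 0 <= qx < sl.shape[0] and 0 <= qy < sl.shape[1]:
                    j = sl[qx, qy]
                    if j > 0 and (i < j if strict else i <= j):
                        counts[i - 1, j - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# direct-summation feature oracles (loops over matrix entries)

def o_glcm_features(counts: np.ndarray) -> dict:
    p = counts / counts.sum()
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    out = dict.fromkeys(
        ["autocorrelation", "joint_average", "joint_entropy", "variance", "contrast",
         "energy", "homogeneity", "inverse_difference_moment", "inverse_variance",
         "cluster_shade", "difference_average"], 0.0,
    )
    pd = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            v = p[i][j]
            a, b = i + 1, j + 1
            out["autocorrelation"] += a * b * v
            out["joint_average"] += a * v
            if v > 0:
                out["joint_entropy"] -= v * math.log2(v + EPS)
            out["variance"] += (a - mu_x) ** 2 * v
            out["contrast"] += (a - b) ** 2 * v
            out["energy"] += v * v
            out["homogeneity"] += v / (1 + abs(a - b))
            out["inverse_difference_moment"] += v / (1 + (a - b) ** 2)
            if a != b:
                out["inverse_variance"] += v / (a - b) ** 2
            out["cluster_shade"] += (a + b - mu_x - mu_y) ** 3 * v
            pd[abs(a - b)] += v
    out["difference_average"] = sum(k * pd[k] for k in range(ng))
    out["correlation"] = (
        (out["autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 0.0
    )
    out["imc1"], out["mcc"] = o_imc1_mcc(p)
    return out


def o_imc1_mcc(p: np.ndarray) -> tuple[float, float]:
    ng = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hxy = hxy1 = hx = hy = 0.0
    for i in range(ng):
        if px[i] > 0:
            hx -= px[i] * math.log2(px[i] + EPS)
        if py[i] > 0:
            hy -= py[i] * math.log2(py[i] + EPS)
        for j in range(ng):
            if p[i][j] > 0:
                hxy -= p[i][j] * math.log2(p[i][j] + EPS)
                hxy1 -= p[i][j] * math.log2(px[i] * py[j] + EPS)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    rows = [i for i in range(ng) if px[i] > 0]
    cols = [k for k in range(ng) if py[k] > 0]
    if len(rows) < 2 or len(cols) < 2:
        return imc1, 1.0
    q = np.zeros((len(rows), len(rows)))
    for a, i in enumerate(rows):
        for b, j in enumerate(rows):
            q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * py[k]) for k in cols)
    ev = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
    return imc1, math.sqrt(min(max(ev[1], 0.0), 1.0))


def o_glszm_features(counts: np.ndarray) -> dict:
    nz = counts.sum()
    ng, ns = counts.shape
    p = counts / nz
    out = dict.fromkeys(
        ["small_area_emphasis", "large_area_emphasis",
         "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
         "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis"], 0.0,
    )
    for i in range(ng):
        for s in range(ns):
            v = p[i][s]
            a, b = i + 1, s + 1
            out["small_area_emphasis"] += v / b**2
            out["large_area_emphasis"] += v * b**2
            out["small_area_low_gray_level_emphasis"] += v / (a**2 * b**2)
            out["small_area_high_gray_level_emphasis"] += v * a**2 / b**2
            out["large_area_low_gray_level_emphasis"] += v * b**2 / a**2
            out["large_area_high_gray_level_emphasis"] += v * a**2 * b**2
    out["gray_level_nonuniformity"] = sum(counts[i].sum() ** 2 for i in range(ng)) / nz
    out["gray_level_nonuniformity_normalized"] = sum(counts[i].sum() ** 2 for i in range(ng)) / nz**2
    out["size_zone_nonuniformity"] = sum(counts[:, s].sum() ** 2 for s in range(ns)) / nz
    out["size_zone_nonuniformity_normalized"] = sum(counts[:, s].sum() ** 2 for s in range(ns)) / nz**2
    return out


def o_glrlm_features(counts: np.ndarray, n_masked: int) -> dict:
    total = counts.sum()
    ng, nr = counts.shape
    p = counts / total
    mu_i = sum((i + 1) * p[i][r] for i in range(ng) for r in range(nr))
    mu_r = sum((r + 1) * p[i][r] for i in range(ng) for r in range(nr))
    out = dict.fromkeys(
        ["short_run_emphasis", "long_run_emphasis", "gray_level_variance", "run_variance",
         "run_entropy", "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
         "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
         "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis"], 0.0,
    )
    for i in range(ng):
        for r in range(nr):
            v = p[i][r]
            a, b = i + 1, r + 1
            out["short_run_emphasis"] += v / b**2
            out["long_run_emphasis"] += v * b**2
            out["gray_level_variance"] += (a - mu_i) ** 2 * v
            out["run_variance"] += (b - mu_r) ** 2 * v
            if v > 0:
                out["run_entropy"] -= v * math.log2(v + EPS)
            out["low_gray_level_run_emphasis"] += v / a**2
            out["high_gray_level_run_emphasis"] += v * a**2
            out["short_run_low_gray_level_emphasis"] += v / (a**2 * b**2)
            out["short_run_high_gray_level_emphasis"] += v * a**2 / b**2
            out["long_run_low_gray_level_emphasis"] += v * b**2 / a**2
            out["long_run_high_gray_level_emphasis"] += v * a**2 * b**2
    out["gray_level_nonuniformity"] = sum(counts[i].sum() ** 2 for i in range(ng)) / total
    out["gray_level_nonuniformity_normalized"] = (
        sum(counts[i].sum() ** 2 for i in range(ng)) / total**2
    )
    out["run_length_nonuniformity"] = sum(counts[:, r].sum() ** 2 for r in range(nr)) / total
    out["run_length_nonuniformity_normalized"] = (
        sum(counts[:, r].sum() ** 2 for r in range(nr)) / total**2
    )
    out["run_percentage"] = total / n_masked
    return out


def o_ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict:
    ng = len(n)
    nvp = n.sum()
    p = n / nvp
    present = [i for i in range(ng) if n[i] > 0]
    ngp = len(present)
    ps_sum = sum(p[i] * s[i] for i in range(ng))
    coarseness = 1.0 / ps_sum if ps_sum > 0 else 1e6
    contrast = busyness = complexity = strength = 0.0
    if ngp > 1:
        acc = sum(
            p[i] * p[j] * (i - j) ** 2 for i in present for j in present
        )
        contrast = acc / (ngp * (ngp - 1)) * (s.sum() / nvp)
        den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        busyness = ps_sum / den if den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        s_sum = sum(s[i] for i in present)
        if s_sum > 0:
            strength = sum(
                (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
            ) / s_sum
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


def o_gldm_features(counts: np.ndarray) -> dict:
    total = counts.sum()
    ng, nd = counts.shape
    p = counts / total
    mu_i = sum((i + 1) * p[i][d] for i in range(ng) for d in range(nd))
    mu_d = sum((d + 1) * p[i][d] for i in range(ng) for d in range(nd))
    out = dict.fromkeys(
        ["small_dependence_emphasis", "large_dependence_emphasis", "gray_level_variance",
         "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
         "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
         "small_dependence_high_gray_level_emphasis",
         "large_dependence_low_gray_level_emphasis"], 0.0,
    )
    for i in range(ng):
        for d in range(nd):
            v = p[i][d]
            a, b = i + 1, d + 1  # d+1 mapping
            out["small_dependence_emphasis"] += v / b**2
            out["large_dependence_emphasis"] += v * b**2
            out["gray_level_variance"] += (a - mu_i) ** 2 * v
            out["dependence_variance"] += (b - mu_d) ** 2 * v
            if v > 0:
                out["dependence_entropy"] -= v * math.log2(v + EPS)
            out["low_gray_level_emphasis"] += v / a**2
            out["high_gray_level_emphasis"] += v * a**2
            out["small_dependence_low_gray_level_emphasis"] += v / (a**2 * b**2)
            out["small_dependence_high_gray_level_emphasis"] += v * a**2 / b**2
            out["large_dependence_low_gray_level_emphasis"] += v * b**2 / a**2
    out["gray_level_nonuniformity"] = sum(counts[i].sum() ** 2 for i in range(ng)) / total
    out["dependence_nonuniformity"] = sum(counts[:, d].sum() ** 2 for d in range(nd)) / total
    out["dependence_nonuniformity_normalized"] = (
        sum(counts[:, d].sum() ** 2 for d in range(nd)) / total**2
    )
    return out


def o_dglm_features(counts: np.ndarray) -> dict:
    p = counts / counts.sum()
    ng = p.shape[0]
    mean = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mean) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    sd = math.sqrt(var)
    out = {
        "energy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "mean": mean,
        "mean_absolute_deviation": sum(
            abs(i + 1 - mean) * p[i][j] for i in range(ng) for j in range(ng)
        ),
        "skewness": (
            sum(((i + 1 - mean) / sd) ** 3 * p[i][j] for i in range(ng) for j in range(ng))
            if sd > 0 else 0.0
        ),
        "kurtosis": (
            sum(((i + 1 - mean) / sd) ** 4 * p[i][j] for i in range(ng) for j in range(ng))
            if sd > 0 else 0.0
        ),
        "entropy": -sum(
            p[i][j] * math.log2(p[i][j] + EPS)
            for i in range(ng) for j in range(ng) if p[i][j] > 0
        ),
        "autocorrelation": sum(
            (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
        ),
    }
    out["imc1"], out["mcc"] = o_imc1_mcc(p)
    return out


def pad_to_match(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad two 2D count matrices to a common shape for comparison."""
    rows = max(a.shape[0], b.shape[0])
    cols = max(a.shape[1], b.shape[1])
    out = []
    for m in (a, b):
        pm = np.zeros((rows, cols))
        pm[: m.shape[0], : m.shape[1]] = m
        out.append(pm)
    return out[0], out[1]
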