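"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, NGTDM, GLDM) in 3-D.

All matrices operate on an integer level image (1..Ng inside the lesion,
0 outside) and aggregate over the 13 unique directions of the
26-neighborhood ("merged" strategy: matrices are summed over directions
before features are computed).  Conventions follow the common IBSI-style
definitions used by mainstream radiomics engines.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# 13 unique direction offsets of the 26-neighborhood (antiparallel pairs removed)
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_EPS = np.finfo(np.float64).tiny


def _shifted_views(a: np.ndarray, d: tuple[int, int, int]):
    """Return aligned views (src, dst) so that dst[v] = a[v + d] over the overlap."""
    sl_src, sl_dst = [], []
    for k, dk in enumerate(d):
        n = a.shape[k]
        if dk >= 0:
            sl_src.append(slice(0, n - dk))
            sl_dst.append(slice(dk, n))
        else:
            sl_src.append(slice(-dk, n))
            sl_dst.append(slice(0, n + dk))
    return a[tuple(sl_src)], a[tuple(sl_dst)]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix at distance 1, merged over 13 directions."""
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    for d in DIRECTIONS_13:
        a, b = _shifted_views(levels, d)
        valid = (a > 0) & (b > 0)
        ai, bi = a[valid] - 1, b[valid] - 1
        np.add.at(P, (ai, bi), 1.0)
        np.add.at(P, (bi, ai), 1.0)
    return P


def glcm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_NAMES}
    p = P / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)                 # symmetric: px == py
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    diff = np.abs(ii - jj)
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    px_py = np.outer(px, px)
    nz = (p > 0) & (px_py > 0)
    hxy1 = float(-(p[nz] * np.log2(px_py[nz])).sum())
    nz2 = px_py > 0
    hxy2 = float(-(px_py[nz2] * np.log2(px_py[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

    feats = {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": mu,
        "cluster_prominence": float((((ii + jj) - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float((((ii + jj) - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float((((ii + jj) - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": float(((ii - mu) * (jj - mu) * p).sum() / sigma2) if sigma2 > 0 else 1.0,
        "difference_average": da,
        "difference_entropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "dissimilarity": float((diff * p).sum()),
        "joint_energy": float((p ** 2).sum()),
        "joint_entropy": hxy,
        "imc1": float((hxy - hxy1) / hx) if hx > 0 else 0.0,
        "imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "id": float((p / (1.0 + diff)).sum()),
        "idn": float((p / (1.0 + diff / ng)).sum()),
        "inverse_variance": float((p[diff > 0] / diff[diff > 0] ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sa,
        "sum_entropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "joint_variance": sigma2,
        "mcc": _glcm_mcc(p, px),
    }
    return feats


def _glcm_mcc(p: np.ndarray, px: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    pk = p[np.ix_(keep, keep)]
    pxk = px[keep]
    # Q_ij = sum_k p_ik p_jk / (px_i px_k)
    Q = (pk / pxk[:, None]) @ (pk / pxk[None, :]).T
    ev = np.linalg.eigvals(Q)
    ev = np.sort(np.real(ev))
    second = ev[-2] if len(ev) >= 2 else ev[-1]
    return float(np.sqrt(max(0.0, second)))


GLCM_NAMES = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "dissimilarity", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "idmn", "id", "idn",
    "inverse_variance", "maximum_probability", "sum_average", "sum_entropy",
    "sum_variance", "joint_variance", "mcc",
]


# ---------------------------------------------------------------- GLRLM

def glrlm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix R[level, run_length], merged over 13 directions."""
    max_len = int(np.ceil(np.sqrt(3) * max(levels.shape))) + 1
    R = np.zeros((n_levels, max_len), dtype=np.float64)
    fg = levels > 0
    for d in DIRECTIONS_13:
        # run starts: foreground voxels whose predecessor along -d differs or is outside
        same_prev = np.zeros_like(fg)
        a, b = _shifted_views(levels, d)           # b[v] = levels[v + d]
        cont = (a > 0) & (a == b)                  # run continues from src to dst
        # mark dst voxels continued from their predecessor
        _, dst_view = _shifted_views(same_prev, d)
        dst_view |= cont
        starts = np.argwhere(fg & ~same_prev)
        if len(starts) == 0:
            continue
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts.copy()
        active = np.arange(len(starts))
        dd = np.asarray(d)
        shape = np.asarray(levels.shape)
        lv = levels[tuple(starts.T)]
        while len(active) > 0:
            nxt = cur[active] + dd
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            ok = np.zeros(len(active), dtype=bool)
            if inb.any():
                vals = levels[tuple(nxt[inb].T)]
                ok[inb] = vals == lv[active[inb]]
            lengths[active[ok]] += 1
            cur[active[ok]] = nxt[ok]
            active = active[ok]
        np.add.at(R, (lv - 1, lengths - 1), 1.0)
    # trim empty tail columns
    used = np.nonzero(R.sum(axis=0))[0]
    return R[:, : used[-1] + 1] if len(used) else R[:, :1]


def _size_family_features(M: np.ndarray, n_voxels: int, axis_name: str) -> dict[str, float]:
    """Shared run-length / zone-size / dependence feature formulas.

    M[level-1, size-1]; ``axis_name`` picks the naming convention
    ('run', 'zone' or 'dependence').
    """
    Ns = M.sum()
    if Ns == 0:
        return {k: 0.0 for k in size_family_names(axis_name)}
    ng, nl = M.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    l = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    p = M / Ns
    mu_i = float((p * i).sum())
    mu_l = float((p * l).sum())
    pre = {"run": "run", "zone": "zone", "dependence": "dependence"}[axis_name]
    short = {"run": "short_run", "zone": "small_area", "dependence": "small_dependence"}[axis_name]
    long_ = {"run": "long_run", "zone": "large_area", "dependence": "large_dependence"}[axis_name]
    feats = {
        f"{short}_emphasis": float((M / l ** 2).sum() / Ns),
        f"{long_}_emphasis": float((M * l ** 2).sum() / Ns),
        "gray_level_nonuniformity": float((M.sum(axis=1) ** 2).sum() / Ns),
        "gray_level_nonuniformity_normalized": float((M.sum(axis=1) ** 2).sum() / Ns ** 2),
        f"{pre}_nonuniformity": float((M.sum(axis=0) ** 2).sum() / Ns),
        f"{pre}_nonuniformity_normalized": float((M.sum(axis=0) ** 2).sum() / Ns ** 2),
        "gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        f"{pre}_variance": float((p * (l - mu_l) ** 2).sum()),
        f"{pre}_entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "low_gray_level_emphasis": float((M / i ** 2).sum() / Ns),
        "high_gray_level_emphasis": float((M * i ** 2).sum() / Ns),
        f"{short}_low_gray_level_emphasis": float((M / (i ** 2 * l ** 2)).sum() / Ns),
        f"{short}_high_gray_level_emphasis": float((M * i ** 2 / l ** 2).sum() / Ns),
        f"{long_}_low_gray_level_emphasis": float((M * l ** 2 / i ** 2).sum() / Ns),
        f"{long_}_high_gray_level_emphasis": float((M * i ** 2 * l ** 2).sum() / Ns),
    }
    if axis_name == "run":
        feats["run_percentage"] = float(Ns / n_voxels)
    elif axis_name == "zone":
        feats["zone_percentage"] = float(Ns / n_voxels)
    else:  # dependence family keeps the canonical 14-feature set
        del feats["gray_level_nonuniformity_normalized"]
    return feats


def size_family_names(axis_name: str) -> list[str]:
    pre = axis_name
    short = {"run": "short_run", "zone": "small_area", "dependence": "small_dependence"}[axis_name]
    long_ = {"run": "long_run", "zone": "large_area", "dependence": "large_dependence"}[axis_name]
    names = [
        f"{short}_emphasis", f"{long_}_emphasis",
        "gray_level_nonuniformity", "gray_level_nonuniformity_normalized",
        f"{pre}_nonuniformity", f"{pre}_nonuniformity_normalized",
        "gray_level_variance", f"{pre}_variance", f"{pre}_entropy",
        "low_gray_level_emphasis", "high_gray_level_emphasis",
        f"{short}_low_gray_level_emphasis", f"{short}_high_gray_level_emphasis",
        f"{long_}_low_gray_level_emphasis", f"{long_}_high_gray_level_emphasis",
    ]
    if axis_name in ("run", "zone"):
        names.insert(6, f"{pre}_percentage")
    else:
        names.remove("gray_level_nonuniformity_normalized")
    return names


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    R = glrlm_matrix(levels, n_levels)
    return _size_family_features(R, int((levels > 0).sum()), "run")


# ---------------------------------------------------------------- GLSZM

def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size matrix Z[level, zone_size] with 26-connected zones."""
    struct = ndimage.generate_binary_structure(3, 3)
    max_size = int((levels > 0).sum())
    Z = np.zeros((n_levels, max(max_size, 1)), dtype=np.float64)
    for g in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == g, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(Z, (g - 1, sizes - 1), 1.0)
    used = np.nonzero(Z.sum(axis=0))[0]
    return Z[:, : used[-1] + 1] if len(used) else Z[:, :1]


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    Z = glszm_matrix(levels, n_levels)
    return _size_family_features(Z, int((levels > 0).sum()), "zone")


# ---------------------------------------------------------------- neighborhood helpers

def _neighbor_sum_count(arr: np.ndarray, fg: np.ndarray):
    """Per-voxel sum and count of 26-neighborhood values restricted to fg."""
    s = np.zeros(arr.shape, dtype=np.float64)
    c = np.zeros(arr.shape, dtype=np.float64)
    for d in DIRECTIONS_13:
        for dd in (d, tuple(-x for x in d)):
            a_src, a_dst = _shifted_views(arr, dd)
            f_src, f_dst = _shifted_views(fg, dd)
            s_src, _ = _shifted_views(s, dd)
            c_src, _ = _shifted_views(c, dd)
            contrib = np.where(f_dst, a_dst, 0.0)
            s_src += contrib
            c_src += f_dst
    return s, c


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    fg = levels > 0
    nsum, ncnt = _neighbor_sum_count(levels.astype(np.float64), fg)
    has_nb = fg & (ncnt > 0)
    nbar = np.zeros(levels.shape)
    nbar[has_nb] = nsum[has_nb] / ncnt[has_nb]
    N = int(has_nb.sum())
    names = ["coarseness", "contrast", "busyness", "complexity", "strength"]
    if N == 0:
        return {k: 0.0 for k in names}
    lv = levels[has_nb]
    dev = np.abs(lv - nbar[has_nb])
    n_i = np.bincount(lv - 1, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(lv - 1, weights=dev, minlength=n_levels)
    p_i = n_i / N
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=np.float64)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        contrast = float((pi_ * pj_ * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / N)
        ip = i * p_i
        busy_den = float(np.abs(ip[present][:, None] - ip[present][None, :]).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        psi = p_i * s_i
        mask2 = present[:, None] & present[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = np.abs(ii - jj) * (psi[:, None] + psi[None, :]) / (pi_ + pj_)
        complexity = float(np.where(mask2, cx, 0.0).sum() / N)
        st_num = float(((pi_ + pj_) * (ii - jj) ** 2 * mask2).sum())
        strength = st_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness, "contrast": contrast, "busyness": busyness,
        "complexity": complexity, "strength": strength,
    }


# ---------------------------------------------------------------- GLDM

def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix D[level, dependence]; dependence = 1 + #neighbors within alpha."""
    fg = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for dd in (d, tuple(-x for x in d)):
            a_src, a_dst = _shifted_views(levels, dd)
            f_src, f_dst = _shifted_views(fg, dd)
            dep_src, _ = _shifted_views(dep, dd)
            dep_src += (f_dst & (np.abs(a_dst.astype(np.int64) - a_src.astype(np.int64)) <= alpha))
    dep = dep + 1  # include the center voxel
    max_dep = 27
    D = np.zeros((n_levels, max_dep), dtype=np.float64)
    lv = levels[fg] - 1
    dp = dep[fg] - 1
    np.add.at(D, (lv, dp), 1.0)
    used = np.nonzero(D.sum(axis=0))[0]
    return D[:, : used[-1] + 1] if len(used) else D[:, :1]


def gldm_features(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    D = gldm_matrix(levels, n_levels, alpha)
    return _size_family_features(D, int((levels > 0).sum()), "dependence")
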