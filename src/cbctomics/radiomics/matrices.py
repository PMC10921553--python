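"""Gray-level texture matrices and their standard features.

All matrix classes work on a :class:`DiscretizedROI` (integer levels 1..N_g,
0 outside the ROI).  Directional matrices (GLCM, GLRLM) use the 13 unique 3D
directions at distance 1 and are accumulated into a single merged matrix
before features are computed; GLCM is symmetric.  Degenerate definitions
(e.g. correlation of a constant ROI) return the documented values noted per
feature.
"""
from __future__ import annotations

import numpy as np
import numba
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
]

_EPS = np.finfo(np.float64).eps

#: The 13 unique direction vectors of a 26-neighbourhood (one per +/- pair).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _shifted_views(a: np.ndarray, d):
    """Pair of views of ``a`` displaced by direction ``d`` (overlap region)."""
    sl1, sl2 = [], []
    for k, n in zip(d, a.shape):
        if k == 0:
            sl1.append(slice(None))
            sl2.append(slice(None))
        elif k > 0:
            sl1.append(slice(0, n - k))
            sl2.append(slice(k, n))
        else:
            sl1.append(slice(-k, n))
            sl2.append(slice(0, n + k))
    return a[tuple(sl1)], a[tuple(sl2)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(d: DiscretizedROI, directions=None) -> np.ndarray:
    """Symmetric co-occurrence counts merged over the given directions."""
    if directions is None:
        directions = DIRECTIONS_13
    ng = d.n_levels
    P = np.zeros((ng, ng), dtype=np.float64)
    lab = d.labels
    for dvec in directions:
        a, b = _shifted_views(lab, dvec)
        valid = (a > 0) & (b > 0)
        ai = a[valid] - 1
        bi = b[valid] - 1
        np.add.at(P, (ai, bi), 1.0)
        np.add.at(P, (bi, ai), 1.0)
    return P


def glcm_features(d: DiscretizedROI, directions=None) -> dict[str, float]:
    P = glcm_matrix(d, directions)
    ng = P.shape[0]
    total = P.sum()
    if total == 0:  # single voxel ROI: no neighbour pairs
        p = np.zeros_like(P)
    else:
        p = P / total
    i = np.arange(1, ng + 1)[:, None] * np.ones((1, ng))
    j = i.T
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * p).sum())
    uy = float((j * p).sum())
    sx = np.sqrt(((np.arange(1, ng + 1) - ux) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(1, ng + 1) - uy) ** 2 * py).sum())

    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(i - j) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(i + j) == k].sum() for k in k_sum])

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.log2(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log2(pxy + _EPS)).sum())

    da = float((k_diff * p_diff).sum())
    off = np.abs(i - j) > 0

    feats = {
        "Autocorrelation": float((p * i * j).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((p * (i + j - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (i + j - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - ux - uy) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        # degenerate (constant ROI): perfect correlation by convention
        "Correlation": float(((p * i * j).sum() - ux * uy) / (sx * sy))
        if sx > 0 and sy > 0
        else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(i - j))).sum()),
        "Idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "InverseVariance": float((p[off] / (i - j)[off] ** 2).sum()),
        "MaximumProbability": float(p.max()) if total else 0.0,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": float((p * (i - ux) ** 2).sum()),
        "MCC": _mcc(p, px, py),
    }
    return feats


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient (sqrt of second-largest eigenvalue of Q)."""
    nz = (px > 0) & (py > 0)
    if nz.sum() < 2:
        return 1.0  # degenerate: single populated level
    pr = p[np.ix_(nz, nz)]
    pxr = px[nz]
    pyr = py[nz]
    # Q[i,j] = sum_k p[i,k] p[j,k] / (px[i] py[k])
    Q = (pr / pyr[None, :]) @ pr.T / pxr[:, None]
    ev = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
    return float(np.sqrt(max(0.0, ev[1].real))) if len(ev) > 1 else 1.0


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _scan_runs(lab, dx, dy, dz, R):  # pragma: no cover - exercised via glrlm
    X, Y, Z = lab.shape
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                g = lab[x, y, z]
                if g <= 0:
                    continue
                # run start: predecessor out of grid / ROI or different level
                px, py, pz = x - dx, y - dy, z - dz
                if (
                    0 <= px < X
                    and 0 <= py < Y
                    and 0 <= pz < Z
                    and lab[px, py, pz] == g
                ):
                    continue
                length = 1
                nx, ny, nz = x + dx, y + dy, z + dz
                while (
                    0 <= nx < X
                    and 0 <= ny < Y
                    and 0 <= nz < Z
                    and lab[nx, ny, nz] == g
                ):
                    length += 1
                    nx += dx
                    ny += dy
                    nz += dz
                R[g - 1, length - 1] += 1.0


def glrlm_matrix(d: DiscretizedROI, directions=None) -> np.ndarray:
    """Run-length counts R(g, l) merged (summed) over the given directions."""
    if directions is None:
        directions = DIRECTIONS_13
    lab = np.ascontiguousarray(d.labels)
    max_run = int(np.ceil(np.sqrt(sum(n**2 for n in lab.shape)))) + 1
    R = np.zeros((d.n_levels, max_run), dtype=np.float64)
    for dx, dy, dz in directions:
        _scan_runs(lab, dx, dy, dz, R)
    last = np.nonzero(R.sum(axis=0))[0]
    return R[:, : last[-1] + 1] if len(last) else R[:, :1]


def glrlm_features(d: DiscretizedROI, directions=None) -> dict[str, float]:
    if directions is None:
        directions = DIRECTIONS_13
    R = glrlm_matrix(d, directions)
    n_r = R.sum()
    n_p = float((d.labels > 0).sum()) * len(directions)
    p = R / n_r
    g = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    r_g = R.sum(axis=1)
    r_l = R.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_l = float((p * l).sum())
    pnz = p[p > 0]
    return {
        "ShortRunEmphasis": float((p / l**2).sum()),
        "LongRunEmphasis": float((p * l**2).sum()),
        "GrayLevelNonUniformity": float((r_g**2).sum() / n_r),
        "GrayLevelNonUniformityNormalized": float((r_g**2).sum() / n_r**2),
        "RunLengthNonUniformity": float((r_l**2).sum() / n_r),
        "RunLengthNonUniformityNormalized": float((r_l**2).sum() / n_r**2),
        "RunPercentage": float(n_r / n_p),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "RunVariance": float((p * (l - mu_l) ** 2).sum()),
        "RunEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelRunEmphasis": float((p / g**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * g**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (g**2 * l**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * g**2 / l**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * l**2 / g**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * g**2 * l**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts S(g, s): 26-connected zones of equal gray level."""
    struct = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level = []
    max_size = 1
    for g in range(1, d.n_levels + 1):
        labelled, nz = ndimage.label(d.labels == g, structure=struct)
        if nz:
            sizes = np.bincount(labelled.ravel())[1:]
            sizes_per_level.append((g, sizes))
            max_size = max(max_size, int(sizes.max()))
        else:
            sizes_per_level.append((g, np.array([], dtype=int)))
    S = np.zeros((d.n_levels, max_size), dtype=np.float64)
    for g, sizes in sizes_per_level:
        for s in sizes:
            S[g - 1, s - 1] += 1.0
    return S


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    S = glszm_matrix(d)
    n_z = S.sum()
    n_p = float((d.labels > 0).sum())
    p = S / n_z
    g = np.arange(1, S.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, S.shape[1] + 1, dtype=np.float64)[None, :]
    s_g = S.sum(axis=1)
    s_s = S.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_s = float((p * s).sum())
    pnz = p[p > 0]
    return {
        "SmallAreaEmphasis": float((p / s**2).sum()),
        "LargeAreaEmphasis": float((p * s**2).sum()),
        "GrayLevelNonUniformity": float((s_g**2).sum() / n_z),
        "GrayLevelNonUniformityNormalized": float((s_g**2).sum() / n_z**2),
        "SizeZoneNonUniformity": float((s_s**2).sum() / n_z),
        "SizeZoneNonUniformityNormalized": float((s_s**2).sum() / n_z**2),
        "ZonePercentage": float(n_z / n_p),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / g**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * g**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (g**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * g**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s**2 / g**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * g**2 * s**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(d: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts D(g, j): j = 1 + #26-neighbours with |level diff| <= alpha."""
    lab = d.labels
    roi = lab > 0
    dep = np.zeros(lab.shape, dtype=np.int32)
    for off in _OFFSETS_26:
        a, b = _shifted_views(lab, off)
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        pad = [(0, 0)] * 3
        for k, (o, n) in enumerate(zip(off, lab.shape)):
            if o > 0:
                pad[k] = (0, o)
            elif o < 0:
                pad[k] = (-o, 0)
        dep += np.pad(ok.astype(np.int32), pad)
    dep = (dep + 1) * roi  # the centre voxel depends on itself
    max_dep = int(dep.max())
    D = np.zeros((d.n_levels, max_dep), dtype=np.float64)
    np.add.at(D, (lab[roi] - 1, dep[roi] - 1), 1.0)
    return D


def gldm_features(d: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    D = gldm_matrix(d, alpha)
    n = D.sum()
    p = D / n
    g = np.arange(1, D.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, D.shape[1] + 1, dtype=np.float64)[None, :]
    d_g = D.sum(axis=1)
    d_j = D.sum(axis=0)
    mu_g = float((p * g).sum())
    mu_j = float((p * j).sum())
    pnz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((d_g**2).sum() / n),
        "DependenceNonUniformity": float((d_j**2).sum() / n),
        "DependenceNonUniformityNormalized": float((d_j**2).sum() / n**2),
        "GrayLevelVariance": float((p * (g - mu_g) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((p / g**2).sum()),
        "HighGrayLevelEmphasis": float((p * g**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (g**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * g**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / g**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * g**2 * j**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(d: DiscretizedROI):
    """Per-level (n_g, p_g, s_g): counts, probabilities and summed deviations
    |level - mean of valid 26-neighbour levels|."""
    lab = d.labels.astype(np.float64)
    roi = d.labels > 0
    padded = np.pad(lab, 1)
    padmask = np.pad(roi, 1)
    nb_sum = np.zeros(lab.shape)
    nb_cnt = np.zeros(lab.shape)
    X, Y, Z = lab.shape
    for ox, oy, oz in _OFFSETS_26:
        sl = (slice(1 + ox, 1 + ox + X), slice(1 + oy, 1 + oy + Y), slice(1 + oz, 1 + oz + Z))
        nb_sum += np.where(padmask[sl], padded[sl], 0.0)
        nb_cnt += padmask[sl]
    has_nb = roi & (nb_cnt > 0)
    avg = np.zeros(lab.shape)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    ng = d.n_levels
    n_vox = np.zeros(ng)
    s = np.zeros(ng)
    for g in range(1, ng + 1):
        sel = has_nb & (d.labels == g)
        n_vox[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - avg[sel]).sum()
    total = n_vox.sum()
    p = n_vox / total if total else n_vox
    return n_vox, p, s


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    n_vox, p, s = ngtdm_table(d)
    ng = len(p)
    n_total = n_vox.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    nz = p > 0
    n_gp = int(nz.sum())
    ps = float((p * s).sum())

    coarseness = 1.0 / ps if ps > 0 else 1e6
    if n_gp > 1:
        ii, jj = np.meshgrid(i[nz], i[nz], indexing="ij")
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        si = s[nz]
        contrast = (
            (pi * pj * (ii - jj) ** 2).sum() / (n_gp * (n_gp - 1))
        ) * (s.sum() / n_total)
        busy_den = np.abs(ii * pi - jj * pj).sum()
        busyness = ps / busy_den if busy_den > 0 else 0.0
        s_i = np.meshgrid(si, si, indexing="ij")
        complexity = (
            np.abs(ii - jj) * (pi * s_i[0] + pj * s_i[1]) / (pi + pj)
        ).sum() / n_total
        strength = ((pi + pj) * (ii - jj) ** 2).sum() / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
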