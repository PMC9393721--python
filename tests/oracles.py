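"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops, flood fill,
pairwise enumeration — and shares no code path with the package internals
it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]
OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in_bounds(p, shape):
    return all(0 <= p[i] < shape[i] for i in range(3))


def naive_glcm(levels: np.ndarray, n_levels: int, offsets=OFFSETS_13) -> np.ndarray:
    """Symmetric co-occurrence probability matrix by direct pair enumeration."""
    shape = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for (dx, dy, dz) in offsets:
                    q = (x + dx, y + dy, z + dz)
                    if not _in_bounds(q, shape):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def naive_glrlm(levels: np.ndarray, n_levels: int, offsets=OFFSETS_13) -> np.ndarray:
    """Run counts by walking every run start in every direction."""
    shape = levels.shape
    max_len = max(shape)
    counts = np.zeros((n_levels, max_len), dtype=float)
    for (dx, dy, dz) in offsets:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    v = levels[x, y, z]
                    if v == 0:
                        continue
                    prev = (x - dx, y - dy, z - dz)
                    if _in_bounds(prev, shape) and levels[prev] == v:
                        continue  # interior of a run
                    length = 1
                    cur = (x + dx, y + dy, z + dz)
                    while _in_bounds(cur, shape) and levels[cur] == v:
                        length += 1
                        cur = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                    counts[v - 1, length - 1] += 1
    return counts


def flood_fill_zones(levels: np.ndarray) -> list[tuple[int, list[tuple[int, int, int]]]]:
    """26-connected equal-level zones via BFS; returns (level, voxels) pairs."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                v = levels[x, y, z]
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                members = []
                while queue:
                    p = queue.popleft()
                    members.append(p)
                    for (dx, dy, dz) in OFFSETS_26:
                        q = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if _in_bounds(q, shape) and not seen[q] and levels[q] == v:
                            seen[q] = True
                            queue.append(q)
                zones.append((int(v), members))
    return zones


def naive_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = flood_fill_zones(levels)
    max_size = max(len(m) for _, m in zones)
    counts = np.zeros((n_levels, max_size), dtype=float)
    for v, members in zones:
        counts[v - 1, len(members) - 1] += 1
    return counts


def naive_city_block_distance(mask: np.ndarray) -> np.ndarray:
    """Per-voxel minimum taxicab distance to outside the ROI, by BFS from
    the (padded) background; border voxels have distance 1."""
    shape = mask.shape
    dist = np.full(shape, np.inf)
    queue = deque()
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                on_border = (
                    x in (0, shape[0] - 1)
                    or y in (0, shape[1] - 1)
                    or z in (0, shape[2] - 1)
                )
                if not on_border:
                    for (dx, dy, dz) in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                         (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        if not mask[x + dx, y + dy, z + dz]:
                            on_border = True
                            break
                if on_border:
                    dist[x, y, z] = 1
                    queue.append((x, y, z))
    while queue:
        p = queue.popleft()
        for (dx, dy, dz) in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                             (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = (p[0] + dx, p[1] + dy, p[2] + dz)
            if _in_bounds(q, mask.shape) and mask[q] and dist[q] > dist[p] + 1:
                dist[q] = dist[p] + 1
                queue.append(q)
    return dist


def naive_gldzm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    dist = naive_city_block_distance(levels > 0)
    zones = flood_fill_zones(levels)
    entries = [
        (v, int(min(dist[p] for p in members))) for v, members in zones
    ]
    max_d = max(d for _, d in entries)
    counts = np.zeros((n_levels, max_d), dtype=float)
    for v, d in entries:
        counts[v - 1, d - 1] += 1
    return counts


def naive_ngldm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    shape = levels.shape
    rows = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                dep = 0
                for (dx, dy, dz) in OFFSETS_26:
                    q = (x + dx, y + dy, z + dz)
                    if _in_bounds(q, shape) and levels[q] == v:
                        dep += 1
                rows.append((v, dep))
    max_j = max(d for _, d in rows) + 1
    counts = np.zeros((n_levels, max_j), dtype=float)
    for v, d in rows:
        counts[v - 1, d] += 1
    return counts


# ---------------------------------------------------------------------------
# Feature formulas recomputed with explicit loops


def oracle_glcm_features(p: np.ndarray, ng: int) -> dict[str, float]:
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i][j]
            p_sum[i + j] += p[i][j]
    da = sum(k * p_diff[k] for k in range(ng))
    sa = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))

    def ent(vals):
        return -sum(v * math.log2(v) for v in np.ravel(vals) if v > 0)

    hxy = ent(p)
    hx = ent(px)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = ent([px[i] * px[j] for i in range(ng) for j in range(ng)])
    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterProminence": sum((i + j + 2 - 2 * mu) ** 4 * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i + j + 2 - 2 * mu) ** 3 * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": (
            sum((i + 1 - mu) * (j + 1 - mu) * p[i][j] for i in range(ng) for j in range(ng)) / sigma2
            if sigma2 > 0 else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "Dissimilarity": sum(abs(i - j) * p[i][j] for i in range(ng) for j in range(ng)),
        "Energy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "Entropy": hxy,
        "IMC1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "IMC2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * max(0.0, hxy2 - hxy)))),
        "InverseDifference": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "InverseDifferenceMoment": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "InverseDifferenceMomentNormalized": sum(
            p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
        ),
        "InverseDifferenceNormalized": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "JointAverage": mu,
        "JointMaximum": max(p[i][j] for i in range(ng) for j in range(ng)),
        "JointVariance": sigma2,
        "SumAverage": sa,
        "SumEntropy": ent(p_sum),
        "SumVariance": sum((k + 2 - sa) ** 2 * p_sum[k] for k in range(2 * ng - 1)),
    }
    return out


def oracle_rl_features(counts: np.ndarray, n_voxels: int, n_dirs: int) -> dict[str, float]:
    ng, nl = counts.shape
    nr = counts.sum()
    p = counts / nr
    g = [counts[i].sum() for i in range(ng)]
    r = [counts[:, j].sum() for j in range(nl)]
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(nl))
    return {
        "SRE": sum(r[j] / (j + 1) ** 2 for j in range(nl)) / nr,
        "LRE": sum(r[j] * (j + 1) ** 2 for j in range(nl)) / nr,
        "LGLRE": sum(g[i] / (i + 1) ** 2 for i in range(ng)) / nr,
        "HGLRE": sum(g[i] * (i + 1) ** 2 for i in range(ng)) / nr,
        "SRLGLE": sum(counts[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nl)) / nr,
        "SRHGLE": sum(counts[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nl)) / nr,
        "LRLGLE": sum(counts[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nl)) / nr,
        "LRHGLE": sum(counts[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nl)) / nr,
        "GLN": sum(gi**2 for gi in g) / nr,
        "GLNN": sum(gi**2 for gi in g) / nr**2,
        "RLN": sum(rj**2 for rj in r) / nr,
        "RLNN": sum(rj**2 for rj in r) / nr**2,
        "RP": nr / (n_voxels * n_dirs),
        "GLV": sum(p[i][j] * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(nl)),
        "RLV": sum(p[i][j] * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(nl)),
        "RE": -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(nl) if p[i][j] > 0),
    }


def oracle_zone_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """GLSZM roster from a zone-size count matrix, explicit loops."""
    ng, ns = counts.shape
    nz = counts.sum()
    p = counts / nz
    g = [counts[i].sum() for i in range(ng)]
    s = [counts[:, j].sum() for j in range(ns)]
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ns))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(ns))
    return {
        "SAE": sum(s[j] / (j + 1) ** 2 for j in range(ns)) / nz,
        "LAE": sum(s[j] * (j + 1) ** 2 for j in range(ns)) / nz,
        "LGLZE": sum(g[i] / (i + 1) ** 2 for i in range(ng)) / nz,
        "HGLZE": sum(g[i] * (i + 1) ** 2 for i in range(ng)) / nz,
        "SALGLE": sum(counts[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)) / nz,
        "SAHGLE": sum(counts[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz,
        "LALGLE": sum(counts[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz,
        "LAHGLE": sum(counts[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz,
        "GLN": sum(gi**2 for gi in g) / nz,
        "GLNN": sum(gi**2 for gi in g) / nz**2,
        "ZSN": sum(sj**2 for sj in s) / nz,
        "ZSNN": sum(sj**2 for sj in s) / nz**2,
        "ZP": nz / n_voxels,
        "GLV": sum(p[i][j] * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(ns)),
        "ZSV": sum(p[i][j] * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(ns)),
        "ZSE": -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ns) if p[i][j] > 0),
    }


# ---------------------------------------------------------------------------
# Statistics oracles


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive comparison of every case/control pair."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def projection_residual(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residual via explicit normal equations."""
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    return y - design @ beta
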