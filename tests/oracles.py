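"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — O(n^2) double loops and voxel-by-
voxel enumeration — and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# surfaces and distances


def bf_surface_indices(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a 6-connected background/out-of-grid neighbour."""
    out = []
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz) or not mask[u, v, w]:
                        out.append((x, y, z))
                        break
    return out


def bf_directed_max(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """max over a of min over b of Euclidean distance — explicit double loop."""
    best = 0.0
    for a in points_a:
        dmin = min(float(np.sqrt(((a - b) ** 2).sum())) for b in points_b)
        best = max(best, dmin)
    return best


def bf_surface_dice(mask_a, mask_b, spacing, tau: float) -> float:
    pa = np.asarray(bf_surface_indices(mask_a), dtype=float) * np.asarray(spacing)
    pb = np.asarray(bf_surface_indices(mask_b), dtype=float) * np.asarray(spacing)
    ok = 0
    for a in pa:
        if min(np.sqrt(((a - b) ** 2).sum()) for b in pb) <= tau:
            ok += 1
    for b in pb:
        if min(np.sqrt(((b - a) ** 2).sum()) for a in pa) <= tau:
            ok += 1
    return ok / (len(pa) + len(pb))


# ---------------------------------------------------------------------------
# texture matrices (levels array uses 0 for voxels outside the ROI)

_NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_grid(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def bf_glcm(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction."""
    P = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(levels.shape):
        i = levels[idx]
        if i == 0:
            continue
        for sign in (1, -1):
            nb = tuple(c + sign * d for c, d in zip(idx, direction))
            if _in_grid(levels.shape, nb) and levels[nb] > 0:
                P[i - 1, levels[nb] - 1] += 1
    return P


def bf_glrlm(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run-length counts for one direction via explicit run walking."""
    runs = []
    for idx in np.ndindex(levels.shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        prev = tuple(c - d for c, d in zip(idx, direction))
        if _in_grid(levels.shape, prev) and levels[prev] == lvl:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(c + d for c, d in zip(cur, direction))
            if _in_grid(levels.shape, nxt) and levels[nxt] == lvl:
                length += 1
                cur = nxt
            else:
                break
        runs.append((lvl, length))
    max_len = max(l for _, l in runs)
    R = np.zeros((n_levels, max_len))
    for lvl, length in runs:
        R[lvl - 1, length - 1] += 1
    return R


def bf_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts via flood fill over 26-connected same-level zones."""
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for idx in np.ndindex(levels.shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        lvl = levels[idx]
        stack, size = [idx], 0
        seen[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in _NEIGHBORS_26:
                nb = tuple(c + dd for c, dd in zip(cur, d))
                if _in_grid(levels.shape, nb) and not seen[nb] and levels[nb] == lvl:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((lvl, size))
    Z = np.zeros((n_levels, max(s for _, s in zones)))
    for lvl, size in zones:
        Z[lvl - 1, size - 1] += 1
    return Z


def bf_gldm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: per voxel, number of 26-neighbours with the same
    level (alpha = 0)."""
    entries = []
    for idx in np.ndindex(levels.shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        dep = 0
        for d in _NEIGHBORS_26:
            nb = tuple(c + dd for c, dd in zip(idx, d))
            if _in_grid(levels.shape, nb) and levels[nb] == lvl:
                dep += 1
        entries.append((lvl, dep))
    D = np.zeros((n_levels, max(d for _, d in entries) + 1))
    for lvl, dep in entries:
        D[lvl - 1, dep] += 1
    return D


def bf_ngtdm(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i): per-level counts and absolute neighbourhood differences;
    voxels without any in-ROI 26-neighbour are excluded."""
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for idx in np.ndindex(levels.shape):
        lvl = levels[idx]
        if lvl == 0:
            continue
        nb_vals = [
            levels[tuple(c + dd for c, dd in zip(idx, d))]
            for d in _NEIGHBORS_26
            if _in_grid(levels.shape, tuple(c + dd for c, dd in zip(idx, d)))
        ]
        nb_vals = [v for v in nb_vals if v > 0]
        if not nb_vals:
            continue
        n_i[lvl - 1] += 1
        s_i[lvl - 1] += abs(lvl - sum(nb_vals) / len(nb_vals))
    return n_i, s_i


# ---------------------------------------------------------------------------
# log-rank


def bf_logrank_statistic(time_a, event_a, time_b, event_b) -> float:
    """Two-sample log-rank chi-square via the observed-minus-expected table
    over distinct event times."""
    times = sorted(
        {t for t, e in zip(list(time_a) + list(time_b), list(event_a) + list(event_b)) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_a = sum(1 for ta in time_a if ta >= t)
        n_b = sum(1 for tb in time_b if tb >= t)
        d_a = sum(1 for ta, ea in zip(time_a, event_a) if ea and ta == t)
        d_b = sum(1 for tb, eb in zip(time_b, event_b) if eb and tb == t)
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        o_minus_e += d_a - d * n_a / n
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
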