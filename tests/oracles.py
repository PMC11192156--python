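"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — enumeration, flood fill, dense
scans — and shares no code with the package paths it validates.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                comps.append(sorted(comp))
    return comps


def boundary_edge_count(mask: np.ndarray) -> int:
    """Number of pixel edges separating foreground from background,
    enumerated pair by pair (image border counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    pad = np.pad(mask, 1)
    count = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        count += int((pad & ~np.roll(pad, (dr, dc), axis=(0, 1))).sum())
    return count


def shoelace(verts: np.ndarray) -> float:
    x, y = np.asarray(verts, float).T
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def brute_force_feret(points: np.ndarray) -> float:
    """Max pairwise distance over all points, O(n^2)."""
    pts = np.asarray(points, float)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2).max()))


def brute_force_min_width(points: np.ndarray) -> float:
    """Minimum caliper width: the minimizing orientation is flush with a
    hull edge, and every hull edge joins two input points, so scanning all
    pairwise directions is exact."""
    pts = np.asarray(points, float)
    n = len(pts)
    best = np.inf
    dirs = []
    for i in range(n):
        d = pts - pts[i]
        norms = np.hypot(d[:, 0], d[:, 1])
        keep = norms > 0
        dirs.append(d[keep] / norms[keep, None])
    dirs = np.vstack(dirs)
    # width along the normal of each candidate direction
    normals = np.column_stack([-dirs[:, 1], dirs[:, 0]])
    proj = normals @ pts.T  # (n_dirs, n_pts)
    widths = proj.max(axis=1) - proj.min(axis=1)
    best = float(widths.min())
    return best


def otsu_best_variance(values: np.ndarray) -> float:
    """Max between-class variance over every possible threshold."""
    v = np.asarray(values).ravel()
    best = 0.0
    for t in np.unique(v)[:-1]:
        lo = v[v <= t]
        hi = v[v > t]
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        best = max(best, w0 * w1 * (lo.mean() - hi.mean()) ** 2)
    return best


def between_class_variance(values: np.ndarray, fg_mask: np.ndarray) -> float:
    v = np.asarray(values).ravel()
    f = np.asarray(fg_mask).ravel()
    if f.all() or not f.any():
        return 0.0
    w0 = f.mean()
    return float(w0 * (1 - w0) * (v[f].mean() - v[~f].mean()) ** 2)


def tally(labels) -> Counter:
    return Counter(labels)


def kappa_direct(mat: np.ndarray) -> float:
    mat = np.asarray(mat, float)
    n = mat.sum()
    po = np.trace(mat) / n
    pe = sum(mat[k].sum() * mat[:, k].sum() for k in range(len(mat))) / n ** 2
    return (po - pe) / (1 - pe)


def central_moments(rows: np.ndarray, cols: np.ndarray):
    """Second central moments of pixel centers by direct summation,
    plus the unit-square spread term."""
    x = cols + 0.5
    y = rows + 0.5
    mx, my = x.mean(), y.mean()
    mu20 = ((x - mx) ** 2).mean() + 1 / 12
    mu02 = ((y - my) ** 2).mean() + 1 / 12
    mu11 = ((x - mx) * (y - my)).mean()
    return mu20, mu02, mu11


def random_blob(rng: np.random.Generator, size: int = 9) -> np.ndarray:
    """A random small 8-connected blob mask (at least one pixel)."""
    while True:
        m = rng.random((size, size)) < 0.45
        comps = flood_fill_components(m)
        if comps:
            biggest = max(comps, key=len)
            out = np.zeros_like(m)
            for r, c in biggest:
                out[r, c] = True
            return out
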