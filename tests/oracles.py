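"""Brute-force reference implementations used only to check the package.

Each oracle recomputes a quantity from first principles (exhaustive
search, direct pairwise enumeration, closed forms) without touching the
library code paths it is used to verify.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def brute_otsu(values: np.ndarray) -> int:
    """Exhaustive 8-bit Otsu: the threshold t in 0..255 minimizing the
    pixel-weighted within-class variance of {v <= t} vs {v > t}."""
    v = np.asarray(values).ravel().astype(np.float64)
    best_t, best_var = None, np.inf
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * lo.var() + hi.size * hi.var()
        if var < best_var - 1e-9:
            best_var, best_t = var, t
    return best_t


def brute_merge(points: np.ndarray, delta: float) -> np.ndarray:
    """Connected-component averaging over the pairwise 'closer than
    delta' graph, iterated to a fixed point; rows sorted row-major."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    while len(pts) > 1:
        d = cdist(pts, pts)
        adj = (d < delta) & ~np.eye(len(pts), dtype=bool)
        if not adj.any():
            break
        # union-find over edges
        parent = list(range(len(pts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in zip(*np.nonzero(adj)):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        roots = np.array([find(i) for i in range(len(pts))])
        pts = np.array([pts[roots == r].mean(axis=0) for r in np.unique(roots)])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Direct density-connectivity DBSCAN from the distance matrix.

    Core points have >= min_pts points (incl. themselves) within eps;
    clusters are components of the core-core graph, numbered by their
    first core point in input order; a border point joins the
    earliest-numbered cluster that reaches it; the rest is noise (-1).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d = cdist(pts, pts)
    within = d <= eps
    core = within.sum(axis=1) >= min_pts
    cluster_id = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # flood the core component containing i
        stack, comp = [i], set()
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp.add(j)
            for k in np.flatnonzero(within[j] & core):
                if k not in comp:
                    stack.append(k)
        for j in comp:
            labels[j] = cluster_id
        cluster_id += 1
    for i in range(n):
        if labels[i] != -1 or core[i]:
            continue
        reaching = labels[np.flatnonzero(within[i] & core)]
        if reaching.size:
            labels[i] = reaching.min()
    return labels


def normalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by order of first appearance; noise stays -1."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def brute_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS of y on x via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = ((y - slope * x - intercept) ** 2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    return slope, intercept, 1.0 - ss_res / ss_tot


def brute_max_matching(det: np.ndarray, true: np.ndarray, tol: float) -> int:
    """Maximum one-to-one matching size within tol, by exhaustive search
    over assignments (small instances only)."""
    det = np.asarray(det, dtype=float).reshape(-1, 2)
    true = np.asarray(true, dtype=float).reshape(-1, 2)
    ok = cdist(det, true) <= tol
    n_det, n_true = len(det), len(true)
    best = 0
    for k in range(min(n_det, n_true), 0, -1):
        for det_sub in itertools.combinations(range(n_det), k):
            for true_perm in itertools.permutations(range(n_true), k):
                if all(ok[i, j] for i, j in zip(det_sub, true_perm)):
                    return k
    return best
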