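"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: gift-wrapping
instead of Qhull, Monte-Carlo rejection sampling instead of exact polygon
clipping, explicit root-path climbing instead of dendropy's distance
matrix, and textbook formulas instead of library statistics.
"""

from __future__ import annotations

import numpy as np


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull; returns vertices in CCW order."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])  # leftmost-lowest
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % n
        for r in range(n):
            if r == p:
                continue
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (
                cross == 0
                and np.linalg.norm(pts[r] - pts[p]) > np.linalg.norm(pts[q] - pts[p])
            ):
                q = r
        if q == start:
            break
        hull.append(q)
    return pts[hull]


def point_in_convex(poly: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorized point-in-convex-polygon test (CCW vertices, boundary in)."""
    poly = np.asarray(poly, dtype=float)
    pts = np.atleast_2d(pts)
    inside = np.ones(len(pts), dtype=bool)
    m = len(poly)
    for i in range(m):
        a, b = poly[i], poly[(i + 1) % m]
        cross = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        inside &= cross >= -tol
    return inside


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12,
                          center=(0.0, 0.0), scale: float = 1.0) -> np.ndarray:
    """Convex hull of Gaussian points: a generic random convex polygon."""
    pts = rng.normal(size=(n_points, 2)) * scale + np.asarray(center)
    return gift_wrap_hull(pts)


def mc_intersection_area(poly_a, poly_b, rng, n_samples: int = 100_000):
    """Monte-Carlo estimate of intersection area with its standard error."""
    allpts = np.vstack([poly_a, poly_b])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    box_area = float(np.prod(hi - lo))
    pts = rng.random((n_samples, 2)) * (hi - lo) + lo
    hit = point_in_convex(poly_a, pts) & point_in_convex(poly_b, pts)
    p = hit.mean()
    se = box_area * np.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return box_area * p, se


def mc_union_proportion(focal, others, rng, n_samples: int = 100_000):
    """MC estimate of the fraction of `focal` covered by union(others)."""
    focal = np.asarray(focal)
    lo, hi = focal.min(axis=0), focal.max(axis=0)
    pts = rng.random((n_samples, 2)) * (hi - lo) + lo
    in_focal = point_in_convex(focal, pts)
    n_in = int(in_focal.sum())
    if n_in == 0:
        return 0.0, 0.0
    sub = pts[in_focal]
    covered = np.zeros(n_in, dtype=bool)
    for o in others:
        covered |= point_in_convex(np.asarray(o), sub)
    p = covered.mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_in)
    return float(p), float(se)


def bruteforce_patristic(newick: str):
    """Tip-to-tip distances by explicit climbs to the root (not via pdm)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = {}
        node, dist = leaf, 0.0
        while node is not None:
            path[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            shared = set(paths[a]) & set(paths[b])
            out[(a, b)] = min(paths[a][s] + paths[b][s] for s in shared)
    return out


def paired_t_textbook(x, y):
    """t = mean(d) / (sd(d)/sqrt(n)) straight from the definition."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    sd = np.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    return d.mean() / (sd / np.sqrt(n))
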