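"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — double loops, flood fill, exhaustive
enumeration — and shares no code with the package's own algorithms.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point


def resample_nearest_bruteforce(src, target):
    """Loop over output cell centres and pick the containing source cell."""
    out = np.full(target.shape, src.nodata, dtype=float)
    for r in range(target.shape[0]):
        for c in range(target.shape[1]):
            x = target.x_origin + (c + 0.5) * target.cell_size_m
            y = target.y_origin - (r + 0.5) * target.cell_size_m
            sc = int(np.floor((x - src.x_origin) / src.cell_size_m))
            sr = int(np.floor((src.y_origin - y) / src.cell_size_m))
            if 0 <= sr < src.shape[0] and 0 <= sc < src.shape[1]:
                out[r, c] = src.values[sr, sc]
    return out


def zonal_mean_bruteforce(grid, geometry, nodata=None):
    """Mean of valid values at cell centres inside one polygon (point tests)."""
    nodata = grid.nodata if nodata is None else nodata
    total, n = 0.0, 0
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            v = grid.values[r, c]
            if v == nodata or (isinstance(v, float) and np.isnan(v)):
                continue
            p = Point(grid.x_centers[c], grid.y_centers[r])
            if geometry.intersects(p):
                total += v
                n += 1
    return total / n if n else float("nan")


def signed_distance_bruteforce(class_grid, target_class):
    """All-pairs nearest-opposite-cell scan, centre-to-centre metres."""
    valid = class_grid.valid_mask
    target = valid & (class_grid.values == target_class)
    other = valid & ~target
    cs = class_grid.cell_size_m
    t_cells = np.argwhere(target)
    o_cells = np.argwhere(other)
    out = np.full(class_grid.shape, class_grid.nodata, dtype=float)
    for r in range(class_grid.shape[0]):
        for c in range(class_grid.shape[1]):
            if not valid[r, c]:
                continue
            pool = o_cells if target[r, c] else t_cells
            d2 = ((pool - np.array([r, c])) ** 2).sum(axis=1)
            dist = np.sqrt(d2.min()) * cs
            out[r, c] = -dist if target[r, c] else dist
    return out


def flood_fill_count(selected: np.ndarray, connectivity: int) -> int:
    """Count connected components of True cells with an explicit flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(selected, dtype=bool)
    count = 0
    rows, cols = selected.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if selected[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and selected[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def proximity_edges_bruteforce(geometries, ids, d_max_m):
    """All-pairs boundary-distance edge set, strict inequality."""
    edges = set()
    for i in range(len(geometries)):
        for j in range(i + 1, len(geometries)):
            if geometries[i].distance(geometries[j]) < d_max_m:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


def modularity_double_loop(graph, membership):
    """Literal double-loop evaluation of the modularity formula."""
    nodes = list(graph.nodes)
    m = graph.number_of_edges()
    k = {v: graph.degree(v) for v in nodes}
    q = 0.0
    for u in nodes:
        for v in nodes:
            if membership[u] != membership[v]:
                continue
            a = 1.0 if graph.has_edge(u, v) else 0.0
            q += a - k[u] * k[v] / (2.0 * m)
    return q / (2.0 * m)


def iter_partitions(seq):
    """All set partitions of a sequence (Bell-number enumeration)."""
    if not seq:
        yield []
        return
    first, rest = seq[0], seq[1:]
    for part in iter_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_max_modularity(graph):
    """Maximum modularity over every partition of the vertex set."""
    best = -np.inf
    best_partition = None
    for part in iter_partitions(list(graph.nodes)):
        membership = {v: i for i, grp in enumerate(part) for v in grp}
        q = modularity_double_loop(graph, membership)
        if q > best:
            best, best_partition = q, part
    return best, best_partition


def integrate_population_bruteforce(geometry, pop_grid):
    """Sum of persons at valid cell centres covered by the geometry."""
    g = pop_grid.persons
    total = 0.0
    for r in range(g.shape[0]):
        for c in range(g.shape[1]):
            if not g.valid_mask[r, c]:
                continue
            if geometry.intersects(Point(g.x_centers[c], g.y_centers[r])):
                total += g.values[r, c]
    return total


def exhaustive_max_modularity_fast(graph):
    """Vectorized exhaustive maximum modularity (independent formula eval)."""
    import networkx as nx

    nodes = list(graph.nodes)
    m = graph.number_of_edges()
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / (2.0 * m)
    pos = {v: i for i, v in enumerate(nodes)}
    best = -np.inf
    for part in iter_partitions(nodes):
        mem = np.empty(len(nodes), dtype=int)
        for i, grp in enumerate(part):
            for v in grp:
                mem[pos[v]] = i
        same = mem[:, None] == mem[None, :]
        q = B[same].sum() / (2.0 * m)
        if q > best:
            best = q
    return best
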