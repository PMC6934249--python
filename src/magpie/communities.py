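"""Leading-eigenvector modularity communities and agglomeration merging.

The proximity graph is partitioned per connected component by Newman's
spectral method: recursively bisect a vertex group by the sign of the
leading eigenvector of its generalized modularity matrix

    B(g)_ij = A_ij - k_i k_j / (2m) - delta_ij * sum_{l in g} B_il,

accepting a split only when the leading eigenvalue is positive and the
modularity gain dQ = s^T B(g) s / (4m) is strictly positive.  Degrees k and
edge count m always refer to the full graph, as the method prescribes.
Communities of settlements are then merged into metropolitan agglomerations
(union geometry, summed population and area).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.linalg import eigsh
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .agglomeration import SettlementPolygon

#: components at or below this size use a dense symmetric eigendecomposition
_DENSE_LIMIT = 500
_EIG_TOL = 1e-10
_MIN_GAIN = 1e-12


class CommunityError(ValueError):
    pass


@dataclass
class Partition:
    """Community assignment of graph vertices plus its modularity Q."""

    membership: dict[Hashable, int]
    q: float

    @property
    def communities(self) -> list[list[Hashable]]:
        groups: dict[int, list[Hashable]] = {}
        for v, c in self.membership.items():
            groups.setdefault(c, []).append(v)
        return [groups[c] for c in sorted(groups)]

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


@dataclass
class MetroAgglomeration:
    """A merged community of settlements: one metropolitan agglomeration."""

    ma_id: int
    member_ids: list[int]
    geometry: BaseGeometry
    population: float
    area_ha: float
    size_class: object = None

    @property
    def density_per_ha(self) -> float:
        return self.population / self.area_ha


def modularity(graph: nx.Graph, membership: dict[Hashable, int]) -> float:
    """Newman-Girvan modularity Q of a vertex partition of a simple graph.

    Q = (1/2m) sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j).
    """
    m = graph.number_of_edges()
    if m == 0:
        raise CommunityError("modularity undefined for m=0")
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    c = np.array([membership[v] for v in nodes])
    same = c[:, None] == c[None, :]
    B = A - np.outer(k, k) / (2.0 * m)
    return float(B[same].sum() / (2.0 * m))


def _leading_eig(Bg: np.ndarray) -> tuple[float, np.ndarray]:
    n = Bg.shape[0]
    if n <= _DENSE_LIMIT:
        vals, vecs = np.linalg.eigh(Bg)
        lam, v = float(vals[-1]), vecs[:, -1]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(Bg, k=1, which="LA", v0=v0, tol=_EIG_TOL)
        lam, v = float(vals[0]), vecs[:, 0]
    # eigh sign is arbitrary: orient so the largest-magnitude entry is positive
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return lam, v


def _refine_split(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style vertex-moving refinement of a bisection vector.

    Repeatedly passes over the group: each pass moves every vertex exactly
    once, always the move with the greatest (possibly negative) change in
    s^T B(g) s, then rolls back to the best intermediate state.  Passes
    repeat until no improvement.  Deterministic: ties go to the lowest
    vertex index.
    """
    s = s.copy()
    n = s.size
    current = s @ Bg @ s
    while True:
        moved = np.zeros(n, dtype=bool)
        trial = s.copy()
        score = current
        best_seq_score = current
        best_seq_state = s.copy()
        for _ in range(n):
            # flipping vertex i changes s^T B s by -4 s_i (B s)_i + 4 B_ii
            Bs = Bg @ trial
            deltas = -4.0 * trial * Bs + 4.0 * np.diag(Bg)
            deltas[moved] = -np.inf
            i = int(np.argmax(deltas))
            trial[i] = -trial[i]
            moved[i] = True
            score += deltas[i]
            if score > best_seq_score:
                best_seq_score = score
                best_seq_state = trial.copy()
        if best_seq_score > current + 1e-12:
            s, current = best_seq_state, best_seq_score
        else:
            return s


def detect_communities(graph: nx.Graph, fine_tune: bool = True) -> Partition:
    """Partition a simple undirected graph by recursive spectral bisection.

    Each connected component is split recursively by the sign of the leading
    eigenvector of its generalized modularity matrix; a split is accepted
    only if the leading eigenvalue exceeds tolerance *and* modularity
    strictly increases.  Eigenvector entries within tolerance of zero join
    the positive side (deterministic tie-break).  Singleton and edgeless
    components each form their own community.  ``fine_tune`` applies the
    vertex-moving refinement to each proposed bisection before the
    modularity-gain test, correcting vertices the sign split misplaces.
    """
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    membership: dict[Hashable, int] = {}
    next_label = 0
    if n == 0:
        return Partition({}, 0.0)

    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        for v in nodes:
            membership[v] = next_label
            next_label += 1
        return Partition(membership, 0.0)

    def bisect(group: np.ndarray) -> list[np.ndarray]:
        """Recursively split a vertex-index group; returns final subgroups."""
        if group.size == 1:
            return [group]
        Bg = A[np.ix_(group, group)] - np.outer(k[group], k[group]) / two_m
        np.fill_diagonal(Bg, Bg.diagonal() - Bg.sum(axis=1))
        lam, v = _leading_eig(Bg)
        if lam <= _EIG_TOL:
            return [group]
        s = np.where(v < -_EIG_TOL, -1.0, 1.0)
        if fine_tune:
            s = _refine_split(Bg, s)
        negative = s < 0
        if not negative.any() or negative.all():
            return [group]
        gain = s @ Bg @ s / (2.0 * two_m)
        if gain <= _MIN_GAIN:
            return [group]
        return bisect(group[~negative]) + bisect(group[negative])

    for comp in nx.connected_components(graph):
        idx = np.array(sorted(index[v] for v in comp))
        for sub in bisect(idx):
            for i in sub:
                membership[nodes[i]] = next_label
            next_label += 1

    return Partition(membership, modularity(graph, membership))


def merge_into_agglomerations(
    settlements: Sequence[SettlementPolygon],
    partition: Partition,
    size_classifier: Callable[[float], object] | None = None,
) -> list[MetroAgglomeration]:
    """Union each community of settlements into one metropolitan agglomeration.

    Geometry is the union of members; population and area are sums.  Ids are
    assigned by descending population with ties broken on the smallest
    member settlement id.
    """
    by_id = {s.settlement_id: s for s in settlements}
    unknown = set(partition.membership) - set(by_id)
    if unknown:
        raise CommunityError(f"partition references unknown settlement ids: {sorted(unknown)}")
    missing = set(by_id) - set(partition.membership)
    if missing:
        raise CommunityError(f"partition does not cover settlement ids: {sorted(missing)}")

    groups: dict[int, list[SettlementPolygon]] = {}
    for sid, community in partition.membership.items():
        groups.setdefault(community, []).append(by_id[sid])

    merged = []
    for members in groups.values():
        members = sorted(members, key=lambda s: s.settlement_id)
        population = sum(s.population for s in members)
        merged.append(
            (
                -population,
                members[0].settlement_id,
                members,
                unary_union([s.geometry for s in members]),
            )
        )
    merged.sort(key=lambda t: (t[0], t[1]))

    out: list[MetroAgglomeration] = []
    for ma_id, (neg_pop, _, members, geometry) in enumerate(merged, start=1):
        population = -neg_pop
        area_ha = sum(s.area_ha for s in members)
        out.append(
            MetroAgglomeration(
                ma_id=ma_id,
                member_ids=[s.settlement_id for s in members],
                geometry=geometry,
                population=population,
                area_ha=area_ha,
                size_class=size_classifier(population) if size_classifier else None,
            )
        )
    return out
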