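"""Assembly of the four-tiered graph.

Tier 1 holds strains, tier 2 strain classes, tier 3 resource classes and
tier 4 resources.  Strain classes sit at their first-principal-component
coordinate, with vertically overlapping classes spread apart by a minimal
spacing epsilon while non-overlapping geometry is preserved; resource classes
sit at the barycenter of the strain classes linking to them; outer-tier
members are stacked around their class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .equivalence import (
    ClassGraph,
    Partition,
    build_class_graph,
    compute_strain_classes,
    compute_resource_classes,
)
from .io import PhenotypeMatrix
from .ordination import (
    OrdinationResult,
    hamming_distance_matrix,
    pca_on_similarity,
    pcoa_on_distance,
    similarity_matrix,
)

logger = logging.getLogger("phenotier")

__all__ = [
    "TierNode",
    "TieredGraph",
    "AssociationMatrix",
    "LayoutConfig",
    "place_strain_classes",
    "place_resource_classes",
    "place_outer_tiers",
    "build_tiered_graph",
]


@dataclass(frozen=True)
class TierNode:
    id: str
    label: str
    tier: int
    x: float
    y: float
    size: int  # class cardinality (1 for outer-tier nodes)
    degree: int  # annotated connection count


@dataclass
class TieredGraph:
    """Four-tier node/edge set with 2-D coordinates, serializable to GraphML."""

    nodes: list[TierNode]
    edges: list[tuple[str, str]]  # directed, left tier -> right tier
    epsilon: float

    def validate(self) -> None:
        by_id = {n.id: n for n in self.nodes}
        if len(by_id) != len(self.nodes):
            raise ValueError("duplicate node ids")
        tier_x: dict[int, float] = {}
        for n in self.nodes:
            if n.tier not in (1, 2, 3, 4):
                raise ValueError(f"node {n.id} has tier {n.tier} outside 1..4")
            if n.tier in tier_x and tier_x[n.tier] != n.x:
                raise ValueError(f"tier {n.tier} has inconsistent x coordinates")
            tier_x.setdefault(n.tier, n.x)
        xs = [tier_x[t] for t in sorted(tier_x)]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("tier x coordinates must increase strictly with tier")
        out_t1: dict[str, int] = {}
        in_t4: dict[str, int] = {}
        for src, dst in self.edges:
            if src not in by_id or dst not in by_id:
                raise ValueError(f"edge ({src}, {dst}) references unknown node")
            a, b = by_id[src], by_id[dst]
            if b.tier != a.tier + 1:
                raise ValueError(
                    f"edge ({src}, {dst}) spans tiers {a.tier}->{b.tier}; only t -> t+1 allowed"
                )
            if a.tier == 1:
                out_t1[src] = out_t1.get(src, 0) + 1
            if b.tier == 4:
                in_t4[dst] = in_t4.get(dst, 0) + 1
        for n in self.nodes:
            if n.tier == 1 and out_t1.get(n.id, 0) != 1:
                raise ValueError(f"tier-1 node {n.id} must have exactly one outgoing edge")
            if n.tier == 4 and in_t4.get(n.id, 0) != 1:
                raise ValueError(f"tier-4 node {n.id} must have exactly one incoming edge")

    def tier_nodes(self, tier: int) -> list[TierNode]:
        return [n for n in self.nodes if n.tier == tier]


@dataclass(frozen=True)
class AssociationMatrix:
    """All four tiers in layout order with their directed adjacency.

    Nodes are ordered by tier, within a tier top-to-bottom (decreasing y);
    nonzero blocks appear only between adjacent tiers.
    """

    node_ids: tuple[str, ...]
    adjacency: np.ndarray  # bool, directed


@dataclass(frozen=True)
class LayoutConfig:
    epsilon: float | str = "auto"  # "auto" = 1% of the PC1 coordinate range
    component: int = 1  # 1-based principal component used for placement
    tier_x: tuple[float, float, float, float] = (0.0, 1.0, 2.0, 3.0)
    method: str = "similarity_pca"  # or "pcoa"
    respace_outer: bool = True


def _respace(coords: np.ndarray, epsilon: float) -> np.ndarray:
    """Spread 1-D positions so no two are closer than epsilon.

    Maximal runs of mutually overlapping positions are re-spaced at exactly
    epsilon, centered on the run's mean raw coordinate; positions outside any
    run are untouched.  Runs that would still encroach on a neighbour after
    spreading are merged (cascaded left-to-right), which guarantees the
    min-gap invariant while keeping inter-run geometry intact.  Input order is
    preserved; ties keep their input order.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    coords = np.asarray(coords, dtype=float)
    n = coords.size
    if n <= 1:
        return coords.copy()
    tol = epsilon * 1e-9
    order = np.argsort(coords, kind="stable")
    sorted_c = coords[order]

    clusters: list[list[float]] = []  # [count, raw coordinate sum]
    for c in sorted_c:
        clusters.append([1.0, float(c)])
        while len(clusters) > 1:
            k2, s2 = clusters[-1]
            k1, s1 = clusters[-2]
            top1 = s1 / k1 + (k1 - 1) / 2 * epsilon
            bot2 = s2 / k2 - (k2 - 1) / 2 * epsilon
            if bot2 - top1 < epsilon - tol:
                clusters[-2] = [k1 + k2, s1 + s2]
                clusters.pop()
            else:
                break

    out_sorted = np.empty(n)
    pos = 0
    for k, s in clusters:
        k = int(k)
        mean = s / k
        for j in range(k):
            out_sorted[pos + j] = mean + epsilon * (j - (k - 1) / 2)
        pos += k
    result = np.empty(n)
    result[order] = out_sorted
    return result


def place_strain_classes(
    ordination: OrdinationResult,
    classes: Partition,
    epsilon: float,
    component: int = 1,
) -> dict[str, float]:
    """Vertical positions for strain classes from their PC coordinate.

    Every member of a class shares the same coordinate (identical rows give
    identical similarity profiles); the class inherits it.  Overlapping
    classes are separated by :func:`_respace`.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    coord = ordination.component(component)
    idx = {name: i for i, name in enumerate(ordination.names)}
    raw = []
    for c in classes.classes:
        member_coords = np.array([coord[idx[m]] for m in c.members])
        if not np.allclose(member_coords, member_coords[0], atol=1e-9):
            raise ValueError(f"members of {c.name} do not share an ordination coordinate")
        raw.append(float(member_coords[0]))
    # class-id order breaks PC ties deterministically (stable sort in _respace)
    spread = _respace(np.array(raw), epsilon)
    return {c.name: float(y) for c, y in zip(classes.classes, spread)}


def place_resource_classes(
    cg: ClassGraph, strain_y: dict[str, float]
) -> tuple[dict[str, float], set[str]]:
    """Barycenter placement of resource classes.

    Each resource class sits at the arithmetic mean of the y of the strain
    classes linking to it.  Classes with in-degree 0 go to the midpoint of
    the occupied strain-class y range and are returned in the flagged set.
    """
    ys = np.array([strain_y[c.name] for c in cg.strain_partition.classes])
    fallback = float((ys.min() + ys.max()) / 2)
    preds: dict[int, list[float]] = {y: [] for y in range(len(cg.resource_partition.classes))}
    for x, y in cg.links:
        preds[y].append(strain_y[cg.strain_partition.classes[x].name])
    placed: dict[str, float] = {}
    flagged: set[str] = set()
    for j, c in enumerate(cg.resource_partition.classes):
        if preds[j]:
            placed[c.name] = float(np.mean(preds[j]))
        else:
            placed[c.name] = fallback
            flagged.add(c.name)
            logger.warning("resource class %s has in-degree 0; placed at fallback y=%g",
                           c.name, fallback)
    return placed, flagged


def place_outer_tiers(
    classes: Partition,
    class_y: dict[str, float],
    epsilon: float,
    respace: bool = True,
) -> dict[str, float]:
    """Stack class members at epsilon spacing centered on their class position.

    Members are ordered top-to-bottom by input order within the class.  When
    ``respace`` is set, overlaps between consecutive stacks are resolved with
    the same run-spreading rule used for tier 2.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    names: list[str] = []
    raw: list[float] = []
    # bottom-up class order so equal-y ties resolve deterministically in _respace
    for c in sorted(classes.classes, key=lambda c: class_y[c.name]):
        k = c.size
        for i, member in enumerate(c.members):
            names.append(member)
            raw.append(class_y[c.name] + epsilon * ((k - 1) / 2 - i))
    if respace:
        spread = _respace(np.array(raw), epsilon)
    else:
        spread = np.array(raw)
    return {name: float(y) for name, y in zip(names, spread)}


def _auto_epsilon(coord: np.ndarray) -> float:
    span = float(coord.max() - coord.min())
    return 0.01 * span if span > 0 else 0.01


def build_tiered_graph(
    m: PhenotypeMatrix, config: LayoutConfig | None = None
) -> tuple[TieredGraph, AssociationMatrix]:
    """Run the full pipeline: classes -> ordination -> placement -> graph.

    Returns the tiered graph together with the directed association matrix
    over all nodes in tier order (within a tier, top to bottom).
    """
    config = config or LayoutConfig()
    sp = compute_strain_classes(m)
    rp = compute_resource_classes(m)
    cg = build_class_graph(sp, rp, m)

    d = hamming_distance_matrix(m, axis="strains")
    if config.method == "similarity_pca":
        ordination = pca_on_similarity(similarity_matrix(d))
    elif config.method == "pcoa":
        ordination = pcoa_on_distance(d)
    else:
        raise ValueError(f"unknown ordination method {config.method!r}")

    coord = ordination.component(config.component)
    epsilon = _auto_epsilon(coord) if config.epsilon == "auto" else float(config.epsilon)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    nv = ordination.variance_explained
    logger.info(
        "layout: %d strain classes, %d resource classes, epsilon=%g, "
        "variance explained PC1=%.3f PC2=%.3f",
        len(sp.classes), len(rp.classes), epsilon,
        nv[0] if nv.size else 0.0, nv[1] if nv.size > 1 else 0.0,
    )

    strain_y = place_strain_classes(ordination, sp, epsilon, config.component)
    resource_y, flagged = place_resource_classes(cg, strain_y)
    t1_y = place_outer_tiers(sp, strain_y, epsilon, config.respace_outer)
    t4_y = place_outer_tiers(rp, resource_y, epsilon, config.respace_outer)

    x1, x2, x3, x4 = config.tier_x
    nodes: list[TierNode] = []
    for name in m.strain_names:
        nodes.append(TierNode(f"strain:{name}", name, 1, x1, t1_y[name], 1, 1))
    for c, deg in zip(sp.classes, cg.out_degree):
        nodes.append(TierNode(c.name, c.name, 2, x2, strain_y[c.name], c.size, deg))
    for c, deg in zip(rp.classes, cg.in_degree):
        nodes.append(TierNode(c.name, c.name, 3, x3, resource_y[c.name], c.size, deg))
    for name in m.resource_names:
        nodes.append(TierNode(f"resource:{name}", name, 4, x4, t4_y[name], 1, 1))

    edges: list[tuple[str, str]] = []
    strain_class = sp.class_of()
    resource_class = rp.class_of()
    for name in m.strain_names:
        edges.append((f"strain:{name}", strain_class[name]))
    for x, y in cg.links:
        edges.append((sp.classes[x].name, rp.classes[y].name))
    for name in m.resource_names:
        edges.append((resource_class[name], f"resource:{name}"))

    graph = TieredGraph(nodes=nodes, edges=edges, epsilon=epsilon)
    graph.validate()
    return graph, _association_matrix(graph)


def _association_matrix(g: TieredGraph) -> AssociationMatrix:
    ordered = sorted(g.nodes, key=lambda n: (n.tier, -n.y))
    ids = tuple(n.id for n in ordered)
    pos = {nid: i for i, nid in enumerate(ids)}
    adj = np.zeros((len(ids), len(ids)), dtype=bool)
    for src, dst in g.edges:
        adj[pos[src], pos[dst]] = True
    return AssociationMatrix(ids, adj)
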