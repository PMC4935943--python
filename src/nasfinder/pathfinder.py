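"""Common-linkage edge scoring and hop-bounded max-product path retention.

Every interactome edge i–j is weighted with the common linkage index

    CL_ij = (D_ij + I_ij) / (n_i + n_j)

where D_ij is the adjacency indicator, I_ij the number of shared neighbors
and n_k the degree of node k; non-adjacent pairs score 0.  Shared
neighborhood is read as evidence of interaction strength, so a path's score
is the product of its edge CLs and the best regulator-to-gene route is the
maximum-product path of at most ``max_len`` edges (default 9; genes further
than 9 hops from every regulator are considered unreachable, long paths
being rare and uninformative).

On any edge, D_ij = 1 and each common neighbor contributes 1 to I_ij but 2
to n_i + n_j, so CL lies in (0, 1/2]; products over longer paths therefore
strictly decrease and the layered dynamic program below, which relaxes over
walks, can only return simple paths as optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .interactome import InteractomeNetwork
from .regulators import DEGModule

MAX_PATH_EDGES = 9  # hop cap: genes at distance >= 10 are out of reach


CL_VARIANTS = ("shared_fraction", "jaccard")


def common_linkage_index(
    net: InteractomeNetwork, i: str, j: str, variant: str = "shared_fraction"
) -> float:
    """Common linkage index CL_ij = (D_ij + I_ij)/(n_i + n_j).

    Returns 0 when i and j are not connected, regardless of shared
    neighbors.  Raises for i == j or unknown nodes.  ``variant="jaccard"``
    normalizes by the neighborhood union, (D_ij + I_ij)/(n_i + n_j - I_ij),
    instead of the degree sum.
    """
    if i == j:
        raise ValueError(f"common linkage index undefined for i == j ({i!r})")
    if variant not in CL_VARIANTS:
        raise ValueError(f"unknown CL variant {variant!r}; expected {CL_VARIANTS}")
    for g in (i, j):
        if g not in net:
            raise KeyError(f"unknown node {g!r}")
    if not net.has_edge(i, j):
        return 0.0
    common = len(net.neighbors(i) & net.neighbors(j))
    denom = net.degree(i) + net.degree(j)
    if variant == "jaccard":
        denom -= common
    return (1 + common) / denom


@dataclass
class WeightedNetwork:
    """Interactome plus per-edge CL weights (symmetric, in (0, 1])."""

    base: InteractomeNetwork
    weights: dict[frozenset[str], float] = field(default_factory=dict)

    def weight(self, u: str, v: str) -> float:
        return self.weights.get(frozenset((u, v)), 0.0)


def weight_edges(
    net: InteractomeNetwork, variant: str = "shared_fraction"
) -> WeightedNetwork:
    """Label every edge of the network with its common linkage index."""
    if len(net) == 0:
        raise ValueError("empty network")
    weights = {
        frozenset((u, v)): common_linkage_index(net, u, v, variant=variant)
        for u, v in net.graph.edges
    }
    return WeightedNetwork(base=net, weights=weights)


@dataclass(frozen=True)
class PathRecord:
    """One retained regulator-to-gene path with its CL-product score."""

    regulator: str
    target: str
    nodes: tuple[str, ...]
    score: float

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


def _better(a: tuple[float, tuple[str, ...]], b: tuple[float, tuple[str, ...]]) -> bool:
    """True if candidate a = (score, path) beats b: higher score, then fewer
    edges, then lexicographically smaller node sequence."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if len(a[1]) != len(b[1]):
        return len(a[1]) < len(b[1])
    return a[1] < b[1]


def best_paths_from(
    wnet: WeightedNetwork,
    source: str,
    targets: Iterable[str],
    max_len: int = MAX_PATH_EDGES,
) -> dict[str, PathRecord]:
    """Highest-CL-product paths (<= max_len edges) from source to each target.

    Layered dynamic program over hop counts: level h holds, per node, the
    best (score, path) reachable in exactly h edges; the per-target optimum
    is then the best over all levels.  Ties break toward fewer edges and
    then the lexicographically smallest node sequence, which makes the
    retained path unique and the traversal deterministic.  Targets beyond
    max_len hops are absent from the result.
    """
    if source not in wnet.base:
        raise KeyError(f"unknown node {source!r}")
    targets = set(targets)
    for t in targets - wnet.base.nodes:
        raise KeyError(f"unknown node {t!r}")
    targets.discard(source)

    g = wnet.base.graph
    # per node: best candidate at the current hop level
    level: dict[str, tuple[float, tuple[str, ...]]] = {source: (1.0, (source,))}
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    for _hop in range(max_len):
        nxt: dict[str, tuple[float, tuple[str, ...]]] = {}
        for u, (score, path) in level.items():
            for v in g.neighbors(u):
                cand = (score * wnet.weight(u, v), path + (v,))
                if v not in nxt or _better(cand, nxt[v]):
                    nxt[v] = cand
        for v, cand in nxt.items():
            if v in targets and (v not in best or _better(cand, best[v])):
                best[v] = cand
        level = nxt
        if not level:
            break
    return {
        t: PathRecord(regulator=source, target=t, nodes=path, score=score)
        for t, (score, path) in best.items()
    }


def best_path_champions(
    wnet: WeightedNetwork,
    source: str,
    targets: Iterable[str],
    max_len: int = MAX_PATH_EDGES,
) -> dict[str, list[PathRecord]]:
    """Per path length, the best-scoring path from source to each target.

    Alternative retention mode keeping one champion per hop count (1..
    max_len) instead of the single overall best; the overall best is always
    among the champions.  Champions at lengths other than the optimum are
    found by the same per-node dominance relaxation and are therefore a
    (deterministic) heuristic for those lengths; non-simple walks are
    discarded.
    """
    if source not in wnet.base:
        raise KeyError(f"unknown node {source!r}")
    targets = set(targets) & wnet.base.nodes - {source}
    g = wnet.base.graph
    level: dict[str, tuple[float, tuple[str, ...]]] = {source: (1.0, (source,))}
    champs: dict[str, list[PathRecord]] = {t: [] for t in targets}
    for _hop in range(max_len):
        nxt: dict[str, tuple[float, tuple[str, ...]]] = {}
        for u, (score, path) in level.items():
            for v in g.neighbors(u):
                cand = (score * wnet.weight(u, v), path + (v,))
                if v not in nxt or _better(cand, nxt[v]):
                    nxt[v] = cand
        for t in targets:
            if t in nxt:
                score, path = nxt[t]
                if len(set(path)) == len(path):  # simple paths only
                    champs[t].append(
                        PathRecord(regulator=source, target=t, nodes=path, score=score)
                    )
        level = nxt
        if not level:
            break
    return {t: recs for t, recs in champs.items() if recs}


def best_path(
    wnet: WeightedNetwork,
    source: str,
    target: str,
    max_len: int = MAX_PATH_EDGES,
) -> Optional[PathRecord]:
    """The single retained path from source to target, or None if the target
    lies more than max_len hops away."""
    if source == target:
        raise ValueError("source and target must differ")
    return best_paths_from(wnet, source, {target}, max_len=max_len).get(target)


@dataclass
class SubNetwork:
    """Minimal sub-network: merged best paths from one regulator to the
    reachable genes of one DEG module, optionally 1-neighbor extended."""

    regulator: str
    module_id: str
    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)
    extended: bool = False
    covered_genes: set[str] = field(default_factory=set)
    paths: tuple[PathRecord, ...] = ()


def build_subnetwork(
    wnet: WeightedNetwork,
    regulator: str,
    module: DEGModule,
    extend: bool = False,
    max_len: int = MAX_PATH_EDGES,
    retention: str = "best",
) -> SubNetwork:
    """Merge the retained regulator-to-gene paths into one minimal network.

    Module genes absent from the network or beyond the hop cap are simply
    not covered; an empty sub-network is a legal result.  With ``extend``,
    every neighbor of a path node is pulled in together with its connecting
    edge (the 1-neighbor context).  ``retention="per_length"`` merges one
    champion path per hop count instead of the single best path per gene.
    """
    if regulator not in wnet.base:
        raise KeyError(f"unknown regulator {regulator!r}")
    if retention not in ("best", "per_length"):
        raise ValueError(f"unknown retention mode {retention!r}")
    sub = SubNetwork(regulator=regulator, module_id=module.module_id, extended=extend)
    mapped = module.gene_set & wnet.base.nodes
    if retention == "best":
        found = {
            t: [rec]
            for t, rec in best_paths_from(
                wnet, regulator, mapped - {regulator}, max_len=max_len
            ).items()
        }
    else:
        found = best_path_champions(
            wnet, regulator, mapped - {regulator}, max_len=max_len
        )
    if regulator in mapped:
        sub.nodes.add(regulator)
        sub.covered_genes.add(regulator)
    for target in sorted(found):
        sub.covered_genes.add(target)
        for rec in found[target]:
            sub.nodes.update(rec.nodes)
            sub.edges.update(
                frozenset(pair) for pair in zip(rec.nodes, rec.nodes[1:])
            )
    sub.paths = tuple(rec for t in sorted(found) for rec in found[t])
    if extend and sub.nodes:
        g = wnet.base.graph
        for u in sorted(sub.nodes):
            for v in g.neighbors(u):
                sub.edges.add(frozenset((u, v)))
        sub.nodes.update({n for e in sub.edges for n in e})
    return sub
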