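"""Closest-regulator selection by breadth-first search.

A DEG module is connected to upstream regulator molecules of a user-chosen
role (receptors by default).  Each module gene nominates the role-labelled
nodes at its minimal positive hop distance; the union of nominations, plus
every role-labelled gene that is itself differentially expressed inside the
module (distance 0), forms the regulator set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .interactome import InputFormatError, InteractomeNetwork, RECEPTOR

log = logging.getLogger(__name__)


@dataclass
class DEGModule:
    """One set of co-expressed, functionally related DE genes.

    ``genes`` maps gene -> (log fold change, p-value); one entry per gene,
    p-values in [0, 1].
    """

    module_id: str
    comparison: str
    genes: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id!r}: empty gene set")
        for g, (_fc, p) in self.genes.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"module {self.module_id!r}: p-value {p} for {g} outside [0, 1]"
                )

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)

    def fold_changes(self) -> dict[str, float]:
        return {g: fc for g, (fc, _p) in self.genes.items()}


def read_deg_modules(path: str | Path, comparison: str = "") -> list[DEGModule]:
    """Read DEG modules from a headered TSV.

    Columns: ``gene``, ``logFC``, ``pvalue`` and optionally ``module_id``;
    without a module_id column the whole file is one module named after the
    file stem.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise InputFormatError(f"{path}: empty module file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        gi, fi, pi = header.index("gene"), header.index("logfc"), header.index("pvalue")
    except ValueError as exc:
        raise InputFormatError(
            f"{path}: header must contain gene, logFC, pvalue (got {header})"
        ) from exc
    mi = header.index("module_id") if "module_id" in header else None

    per_module: dict[str, dict[str, tuple[float, float]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < len(header):
            raise InputFormatError(f"{path}: line {lineno}: too few columns")
        mid = fields[mi].strip() if mi is not None else path.stem
        try:
            fc, p = float(fields[fi]), float(fields[pi])
        except ValueError as exc:
            raise InputFormatError(f"{path}: line {lineno}: non-numeric value") from exc
        per_module.setdefault(mid, {})[fields[gi].strip()] = (fc, p)
    return [
        DEGModule(module_id=mid, comparison=comparison, genes=genes)
        for mid, genes in per_module.items()
    ]


@dataclass
class RegulatorSet:
    """Regulators selected for one module: genes plus their hop distances.

    Distance 0 marks regulators that are differentially expressed members of
    the module itself.
    """

    regulators: set[str] = field(default_factory=set)
    distances: dict[str, int] = field(default_factory=dict)
    unmapped_module_genes: set[str] = field(default_factory=set)


def bfs_distances(
    net: InteractomeNetwork, sources: Iterable[str]
) -> dict[str, int]:
    """Unweighted shortest-hop distance from the nearest source to each node.

    Sources not in the network are skipped with a warning; nodes unreachable
    from every source are absent from the result.
    """
    sources = set(sources)
    missing = sources - net.nodes
    if missing:
        warnings.warn(
            f"{len(missing)} source gene(s) not in network, skipped: "
            f"{sorted(missing)[:5]}...", stacklevel=2,
        )
    effective = sources - missing
    if not effective:
        raise ValueError("no source gene maps into the network")
    dist: dict[str, int] = {}
    for depth, layer in enumerate(nx.bfs_layers(net.graph, sorted(effective))):
        for node in layer:
            dist[node] = depth
    return dist


def _nearest_role_nodes(
    net: InteractomeNetwork, source: str, role: str
) -> tuple[set[str], int] | None:
    """Role-labelled nodes at the minimal positive BFS distance from source."""
    for depth, layer in enumerate(nx.bfs_layers(net.graph, [source])):
        if depth == 0:
            continue
        hits = {n for n in layer if net.role(n) == role}
        if hits:
            return hits, depth
    return None


def select_regulators(
    net: InteractomeNetwork,
    module: DEGModule,
    role: str = RECEPTOR,
    scope: str = "per_gene",
) -> RegulatorSet:
    """Select the closest regulators of the given role for a DEG module.

    With ``scope="per_gene"`` (default) every mapped module gene nominates
    the role-labelled nodes at its own minimal positive hop distance and the
    nominations are unioned, so genes in distant network regions still get a
    regulator.  ``scope="module_global"`` instead keeps only the role nodes
    at the single minimal positive distance from the module as a whole.
    Role-labelled module members are always included at distance 0.
    """
    if scope not in ("per_gene", "module_global"):
        raise ValueError(f"unknown scope {scope!r}")
    mapped = module.gene_set & net.nodes
    unmapped = module.gene_set - mapped
    if not mapped:
        raise ValueError(
            f"module {module.module_id!r}: no gene maps into the network"
        )
    if unmapped:
        log.info("module %s: %d gene(s) not in network", module.module_id, len(unmapped))

    result = RegulatorSet(unmapped_module_genes=unmapped)
    # DE regulators inside the module (distance 0).
    for g in sorted(mapped):
        if net.role(g) == role:
            result.regulators.add(g)
            result.distances[g] = 0

    if scope == "per_gene":
        for g in sorted(mapped):
            found = _nearest_role_nodes(net, g, role)
            if found is None:
                continue
            hits, depth = found
            for r in hits:
                result.regulators.add(r)
                prev = result.distances.get(r)
                result.distances[r] = depth if prev is None else min(prev, depth)
    else:  # module_global
        dist = bfs_distances(net, mapped)
        role_dists = sorted(
            d for n, d in dist.items() if d > 0 and net.role(n) == role
        )
        if role_dists:
            dmin = role_dists[0]
            for n, d in dist.items():
                if d == dmin and net.role(n) == role:
                    result.regulators.add(n)
                    result.distances.setdefault(n, dmin)

    if not result.regulators:
        raise ValueError(
            f"module {module.module_id!r}: no regulator found "
            f"(no {role} reachable from any module gene and none in module)"
        )
    return result
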