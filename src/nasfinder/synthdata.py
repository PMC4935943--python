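"""Deterministic synthetic fixtures: interactome, roles, tissues, modules.

The generator emulates the modular organization of signaling interactomes:
preferential-attachment communities (degree-heterogeneous, locally dense)
joined by short linker chains (sparse inter-community cross-talk).  Each
community hosts one receptor-anchored gene cluster; one cluster is
"planted" with a real expression effect while the others receive pure
noise, giving a ground truth against which the whole pipeline — regulator
selection, path retention, enrichment and NAS ranking — can be scored.

All fixtures are emitted in the same TSV/GMT dialects the real readers
consume, so tests exercise the parsers, and every draw flows through one
seeded NumPy generator: identical seeds give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .enrichment import ReferenceGeneSet
from .interactome import (
    GE,
    OTHER,
    RECEPTOR,
    REFERENCE,
    TE,
    TEN,
    TRANSCRIPTION_FACTOR,
    TRANSPORTER,
    InteractomeNetwork,
    TissueTable,
)
from .regulators import DEGModule

_SOURCE_DBS = ("KEGG", "BioCarta", "PID", "Reactome")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study condition.

    Defaults describe a modular 240-gene interactome of 8 communities with
    8-gene receptor-anchored clusters, a planted log2 fold-change of 2
    (a 4-fold change, typical of a strong differentiation response) and
    expression noise of 0.1 on the log2 scale.
    """

    seed: int
    n_nodes: int = 240
    n_edges: int = 420
    n_communities: int = 8
    # 8 linker nodes = 9 edges per bridge: crossing a bridge exhausts the
    # path-length cap, so a receptor's sub-network stays community-local
    # while neighboring communities remain partially reachable
    linker_length: int = 8
    role_fractions: dict[str, float] = field(
        default_factory=lambda: {RECEPTOR: 0.10, TRANSCRIPTION_FACTOR: 0.05,
                                 TRANSPORTER: 0.05}
    )
    cluster_size: int = 8
    planted_pathway: Optional[frozenset[str]] = None
    planted_effect: float = 2.0
    noise_sd: float = 0.1
    tissue_profile: dict = field(
        default_factory=lambda: {
            "tissues": ("adipose", "liver", "brain", "muscle"),
            "annotated_fraction": 0.3,
            "class_probs": {TE: 0.3, GE: 0.2, TEN: 0.5},
        }
    )

    def __post_init__(self) -> None:
        if sum(self.role_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("role fractions must sum to <= 1")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError(
                f"need at least n_nodes - 1 = {self.n_nodes - 1} edges for a "
                f"connected graph, got {self.n_edges}"
            )
        if self.n_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("more edges requested than a simple graph allows")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(scenario: SyntheticScenario) -> tuple[InteractomeNetwork, TissueTable]:
    """Build the synthetic interactome and its tissue-specificity table.

    Community membership is recorded as a ``community`` node attribute
    (linker-chain nodes carry none); molecular roles are assigned by the
    scenario's fractions, with the receptor quota spread round-robin over
    communities so every community has an anchor candidate.
    """
    rng = np.random.default_rng(scenario.seed)
    n, k = scenario.n_nodes, scenario.n_communities
    n_linker = (k - 1) * scenario.linker_length
    if n - n_linker < 2 * k:
        raise ValueError(
            "scenario infeasible: communities would have fewer than 2 nodes; "
            "reduce n_communities or linker_length, or raise n_nodes"
        )

    names = [_gene_name(i) for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(names)

    # split non-linker nodes into k communities of near-equal size
    comm_nodes = names[: n - n_linker]
    linker_pool = names[n - n_linker:]
    communities: list[list[str]] = [list(arr) for arr in np.array_split(comm_nodes, k)]
    for ci, members in enumerate(communities):
        for node in members:
            g.nodes[node]["community"] = ci

    # preferential-attachment tree within each community
    for members in communities:
        degree = {members[0]: 1}
        for node in members[1:]:
            pool = list(degree)
            w = np.array([degree[p] for p in pool], dtype=float)
            target = pool[rng.choice(len(pool), p=w / w.sum())]
            g.add_edge(node, target, provenance=REFERENCE)
            degree[target] += 1
            degree[node] = 1

    # linker chains joining consecutive communities in a path
    pos = 0
    for ci in range(k - 1):
        u = communities[ci][rng.integers(len(communities[ci]))]
        v = communities[ci + 1][rng.integers(len(communities[ci + 1]))]
        chain = linker_pool[pos: pos + scenario.linker_length]
        pos += scenario.linker_length
        path = [u, *chain, v]
        for a, b in zip(path, path[1:]):
            g.add_edge(a, b, provenance=REFERENCE)

    # remaining edges: preferential attachment within communities first
    n_extra = scenario.n_edges - g.number_of_edges()
    attempts = 0
    while n_extra > 0 and attempts < 50 * scenario.n_edges:
        attempts += 1
        members = communities[rng.integers(k)]
        if len(members) < 3:
            continue
        w = np.array([g.degree(m) for m in members], dtype=float)
        a = members[rng.choice(len(members), p=w / w.sum())]
        b = members[rng.integers(len(members))]
        if a == b or g.has_edge(a, b):
            continue
        g.add_edge(a, b, provenance=REFERENCE)
        n_extra -= 1
    if n_extra > 0:  # dense request: spill over to arbitrary non-edges
        candidates = sorted(nx.non_edges(g))
        idx = rng.choice(len(candidates), size=n_extra, replace=False)
        for i in idx:
            a, b = candidates[i]
            g.add_edge(a, b, provenance=REFERENCE)

    # molecular roles: quota per role, receptors spread across communities
    nx.set_node_attributes(g, OTHER, "role")
    unassigned = set(names)
    n_receptors = int(round(scenario.role_fractions.get(RECEPTOR, 0.0) * n))
    ci = 0
    for _ in range(n_receptors):
        for _try in range(k):
            avail = [m for m in communities[ci % k] if m in unassigned]
            ci += 1
            if avail:
                node = avail[rng.integers(len(avail))]
                g.nodes[node]["role"] = RECEPTOR
                unassigned.discard(node)
                break
    for role, frac in scenario.role_fractions.items():
        if role == RECEPTOR:
            continue
        quota = int(round(frac * n))
        avail = sorted(unassigned)
        take = rng.choice(len(avail), size=min(quota, len(avail)), replace=False)
        for i in take:
            g.nodes[avail[i]]["role"] = role
            unassigned.discard(avail[i])

    net = InteractomeNetwork(g)
    tt = _generate_tissue_table(scenario, names, rng)
    return net, tt


def _generate_tissue_table(
    scenario: SyntheticScenario, names: list[str], rng: np.random.Generator
) -> TissueTable:
    prof = scenario.tissue_profile
    tissues = list(prof["tissues"])
    classes = list(prof["class_probs"])
    probs = np.array([prof["class_probs"][c] for c in classes], dtype=float)
    probs /= probs.sum()
    entries: dict[tuple[str, str], str] = {}
    for gene in names:
        if rng.random() >= prof["annotated_fraction"]:
            continue
        tissue = tissues[rng.integers(len(tissues))]
        cls = classes[rng.choice(len(classes), p=probs)]
        entries[(gene, tissue)] = cls
    return TissueTable(entries)


@dataclass
class SyntheticModule:
    """A generated DEG module with its reference collection and ground truth."""

    module: DEGModule
    collection: list[ReferenceGeneSet]
    planted_name: str
    planted_genes: frozenset[str]
    anchors: dict[str, str]  # pathway name -> anchor receptor


def generate_module(
    scenario: SyntheticScenario, net: InteractomeNetwork
) -> SyntheticModule:
    """Plant one active gene cluster among structurally matched decoys.

    Per community, one receptor is chosen as anchor and the
    ``cluster_size`` non-receptor genes nearest to it (BFS inside the
    community) form one reference set; the module is the union of all
    clusters.  A uniformly chosen cluster is planted: its genes draw log
    fold changes from ``planted_effect + N(0, noise_sd)``, decoy genes from
    ``N(0, noise_sd)``.  Clusters are pairwise disjoint by construction.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    comm_of = nx.get_node_attributes(net.graph, "community")
    if not comm_of:
        raise ValueError("network has no community annotation; use generate_network")
    k = max(comm_of.values()) + 1

    clusters: dict[int, list[str]] = {}
    anchors: dict[int, str] = {}
    for ci in range(k):
        members = sorted(gene for gene, c in comm_of.items() if c == ci)
        receptors = [m for m in members if net.role(m) == RECEPTOR]
        if not receptors:
            continue  # community without an anchor candidate contributes no cluster
        anchor = receptors[rng.integers(len(receptors))]
        sub = net.graph.subgraph(members)
        picked: list[str] = []
        for layer in nx.bfs_layers(sub, [anchor]):
            for node in sorted(layer):
                if node == anchor or net.role(node) == RECEPTOR:
                    continue
                picked.append(node)
                if len(picked) == scenario.cluster_size:
                    break
            if len(picked) == scenario.cluster_size:
                break
        if len(picked) < scenario.cluster_size:
            raise ValueError(
                f"community {ci} too small for a cluster of "
                f"{scenario.cluster_size} genes"
            )
        clusters[ci] = picked
        anchors[ci] = anchor
    if not clusters:
        raise ValueError("no community has a receptor to anchor a cluster")

    if scenario.planted_pathway is not None:
        planted_genes = frozenset(scenario.planted_pathway)
        if not planted_genes <= net.nodes:
            raise ValueError("planted pathway contains genes outside the network")
        planted_ci = None
    else:
        keys = sorted(clusters)
        planted_ci = keys[rng.integers(len(keys))]
        planted_genes = frozenset(clusters[planted_ci])

    collection: list[ReferenceGeneSet] = []
    name_of: dict[int, str] = {}
    for ci in sorted(clusters):
        name = f"PWY_C{ci}"
        name_of[ci] = name
        collection.append(
            ReferenceGeneSet(
                name=name,
                genes=frozenset(clusters[ci]),
                source_db=_SOURCE_DBS[ci % len(_SOURCE_DBS)],
            )
        )
    if scenario.planted_pathway is not None:
        planted_name = "PWY_PLANTED"
        collection.append(
            ReferenceGeneSet(name=planted_name, genes=planted_genes, source_db="other")
        )
    else:
        planted_name = name_of[planted_ci]

    genes: dict[str, tuple[float, float]] = {}
    for ci in sorted(clusters):
        for gene in clusters[ci]:
            effect = scenario.planted_effect if gene in planted_genes else 0.0
            fc = effect + rng.normal(0.0, scenario.noise_sd)
            p = float(rng.uniform(1e-6, 0.01))
            genes[gene] = (float(fc), p)
    module = DEGModule(
        module_id=f"synthetic-seed{scenario.seed}",
        comparison="treated_vs_control",
        genes=genes,
    )
    return SyntheticModule(
        module=module,
        collection=collection,
        planted_name=planted_name,
        planted_genes=planted_genes,
        anchors={name_of[ci]: anchors[ci] for ci in sorted(clusters)},
    )


def write_scenario_files(
    net: InteractomeNetwork,
    tissue_table: TissueTable,
    synth: SyntheticModule,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write all fixtures in the dialects the real readers parse.

    Returns a mapping of logical names (edges, roles, tissues, module, gmt)
    to the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "roles": outdir / "roles.tsv",
        "tissues": outdir / "tissues.tsv",
        "module": outdir / "module.tsv",
        "gmt": outdir / "pathways.gmt",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("# geneA\tgeneB\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(paths["roles"], "w") as fh:
        for gene in sorted(net.nodes):
            fh.write(f"{gene}\t{net.role(gene)}\n")
    with open(paths["tissues"], "w") as fh:
        for (gene, tissue), cls in sorted(tissue_table.entries.items()):
            fh.write(f"{gene}\t{tissue}\t{cls}\n")
    with open(paths["module"], "w") as fh:
        fh.write("gene\tlogFC\tpvalue\tmodule_id\n")
        for gene, (fc, p) in sorted(synth.module.genes.items()):
            fh.write(f"{gene}\t{fc:.6g}\t{p:.6g}\t{synth.module.module_id}\n")
    with open(paths["gmt"], "w") as fh:
        for ref in synth.collection:
            genes = "\t".join(sorted(ref.genes))
            fh.write(f"{ref.name}\t{ref.source_db}\t{genes}\n")
    return paths
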