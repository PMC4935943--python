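"""Reference interactome: loading, supplementary expansion, tissue pruning.

The interactome is an undirected gene–gene interaction network in which every
node carries a molecular-role label (receptor, transcription factor,
transporter, or other).  Any direction information present in input files is
deliberately ignored: all downstream traversal treats interactions as
symmetric information-exchange channels.

Tissue context is applied by *removing genes*, not edges: a gene classified as
tissue-enriched (TE) or group-enriched (GE) in a tissue other than the one
under study is dropped — unless it also carries a TE/GE/TEn class in the
selected tissue — together with every interaction it participates in.
Tissue-enhanced (TEn) classes in other tissues, and genes with no tissue
annotation at all, never cause removal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

log = logging.getLogger(__name__)

# Canonical role labels.
RECEPTOR = "receptor"
TRANSCRIPTION_FACTOR = "transcription_factor"
TRANSPORTER = "transporter"
OTHER = "other"
ROLES = frozenset({RECEPTOR, TRANSCRIPTION_FACTOR, TRANSPORTER, OTHER})

REFERENCE = "reference"
SUPPLEMENTARY = "supplementary"

# Tissue-specificity classes of the human-proteome tissue map.
TE = "TE"   # tissue enriched: >=5-fold over every other tissue
GE = "GE"   # group enriched: >=5-fold in a small tissue group
TEN = "TEn"  # tissue enhanced: >=5-fold over the all-tissue average
TISSUE_CLASSES = frozenset({TE, GE, TEN})

_ROLE_ALIASES = {
    "receptor": RECEPTOR,
    "transcription_factor": TRANSCRIPTION_FACTOR,
    "transcription factor": TRANSCRIPTION_FACTOR,
    "tf": TRANSCRIPTION_FACTOR,
    "transporter": TRANSPORTER,
    "other": OTHER,
}


class InputFormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


def normalize_role(raw: str) -> str:
    """Map a free-text role label to one of the four canonical roles.

    Matching is case-insensitive; unrecognized labels become ``other``.
    """
    return _ROLE_ALIASES.get(raw.strip().lower().replace("-", "_"), OTHER)


@dataclass
class InteractomeNetwork:
    """Undirected annotated gene network.

    Backed by a :class:`networkx.Graph`; each node has a ``role`` attribute
    and each edge a ``provenance`` attribute (``reference`` or
    ``supplementary``).  Self-loops are never stored.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, gene: str) -> str:
        return self.graph.nodes[gene].get("role", OTHER)

    def roles(self) -> dict[str, str]:
        return {g: d.get("role", OTHER) for g, d in self.graph.nodes(data=True)}

    def nodes_with_role(self, role: str) -> set[str]:
        return {g for g, d in self.graph.nodes(data=True) if d.get("role", OTHER) == role}

    def provenance(self, u: str, v: str) -> str:
        return self.graph.edges[u, v]["provenance"]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "InteractomeNetwork":
        return InteractomeNetwork(self.graph.copy())


def _iter_tsv(path: Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _read_edge_pairs(path: Path) -> Iterator[tuple[int, str, str]]:
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise InputFormatError(
                f"{path}: line {lineno}: expected at least two tab-separated "
                f"gene identifiers, got {len(fields)} field(s)"
            )
        yield lineno, fields[0].strip(), fields[1].strip()


def load_network(edge_file: str | Path, role_file: str | Path | None = None) -> InteractomeNetwork:
    """Load the reference interactome from a TSV edge list and role table.

    Duplicate edges (in either orientation) are collapsed, self-loops are
    dropped, and every edge is tagged with provenance ``reference``.  Genes
    absent from the role table — or carrying an unrecognized role — get role
    ``other``.

    Raises
    ------
    InputFormatError
        For an empty edge file or a line with fewer than two columns.
    """
    edge_file = Path(edge_file)
    g = nx.Graph()
    n_lines = 0
    for _lineno, a, b in _read_edge_pairs(edge_file):
        n_lines += 1
        if a == b:
            continue  # self-loop
        g.add_edge(a, b, provenance=REFERENCE)
    if n_lines == 0:
        raise InputFormatError(f"{edge_file}: empty edge file")

    nx.set_node_attributes(g, OTHER, "role")
    if role_file is not None:
        for lineno, fields in _iter_tsv(Path(role_file)):
            if len(fields) < 2:
                raise InputFormatError(
                    f"{role_file}: line {lineno}: expected gene<TAB>role"
                )
            gene, role = fields[0].strip(), normalize_role(fields[1])
            if gene in g:
                g.nodes[gene]["role"] = role
    return InteractomeNetwork(g)


def expand_network(
    net: InteractomeNetwork,
    extra_edges: str | Path,
    module_genes: Iterable[str],
) -> InteractomeNetwork:
    """Add supplementary interactions that touch a DEG-module gene.

    Only edges incident to at least one module gene are imported; the rest of
    the supplementary file is ignored so the background network stays
    comparable across modules.  Newly added genes get role ``other``; the set
    of typed regulator molecules is therefore never enlarged by expansion.
    Edges already present keep their ``reference`` provenance.
    """
    module_genes = set(module_genes)
    out = net.copy()
    g = out.graph
    added = 0
    for _lineno, a, b in _read_edge_pairs(Path(extra_edges)):
        if a == b:
            continue
        if a not in module_genes and b not in module_genes:
            continue
        if g.has_edge(a, b):
            continue  # reference provenance wins
        for gene in (a, b):
            if gene not in g:
                g.add_node(gene, role=OTHER)
        g.add_edge(a, b, provenance=SUPPLEMENTARY)
        added += 1
    log.info("expansion added %d supplementary edge(s)", added)
    return out


@dataclass
class TissueTable:
    """Per-tissue specificity classes (TE / GE / TEn) for genes.

    Absence of a (gene, tissue) entry means the gene is not specific in that
    tissue.  A gene may carry classes in several tissues.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def tissues(self) -> set[str]:
        return {t for (_g, t) in self.entries}

    def classes_of(self, gene: str) -> dict[str, str]:
        """Mapping tissue -> class for one gene."""
        return {t: c for (g, t), c in self.entries.items() if g == gene}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TissueTable":
        """Read gene<TAB>tissue<TAB>class lines (class in TE/GE/TEn)."""
        entries: dict[tuple[str, str], str] = {}
        for lineno, fields in _iter_tsv(Path(path)):
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected gene<TAB>tissue<TAB>class"
                )
            gene, tissue, cls_ = (f.strip() for f in fields[:3])
            if cls_ not in TISSUE_CLASSES:
                raise InputFormatError(
                    f"{path}: line {lineno}: unknown tissue class {cls_!r} "
                    f"(expected one of {sorted(TISSUE_CLASSES)})"
                )
            entries[(gene, tissue)] = cls_
        return cls(entries)


def prune_to_tissue(
    net: InteractomeNetwork, tt: TissueTable, tissue: str
) -> InteractomeNetwork:
    """Restrict the network to genes plausible in the selected tissue.

    A gene is removed when it is TE or GE in some tissue different from the
    selected one and carries no TE/GE/TEn class in the selected tissue.
    TEn-elsewhere genes and genes without any annotation are kept, as is
    every gene protected by a selected-tissue class.  Edges incident to a
    removed gene are dropped with it.
    """
    if tissue not in tt.tissues:
        raise ValueError(
            f"unknown tissue {tissue!r}; valid tissues: {sorted(tt.tissues)}"
        )
    to_remove: list[str] = []
    for gene in net.graph.nodes:
        classes = tt.classes_of(gene)
        if tissue in classes:
            if any(c in (TE, GE) for t, c in classes.items() if t != tissue):
                # protected by its selected-tissue class; may be GE in a group
                # spanning the selected tissue and others
                log.info("keeping %s: specific elsewhere but %s in %s",
                         gene, classes[tissue], tissue)
            continue
        if any(c in (TE, GE) for t, c in classes.items() if t != tissue):
            to_remove.append(gene)
    out = net.copy()
    out.graph.remove_nodes_from(to_remove)
    log.info("tissue pruning for %r removed %d gene(s)", tissue, len(to_remove))
    return out


def check_module_coverage(net: InteractomeNetwork, module_genes: Iterable[str]) -> float:
    """Fraction of module genes present in the network; warns below 50%.

    A low fraction usually indicates mismatched gene namespaces (symbols vs
    numeric IDs); no identifier translation is attempted.
    """
    module_genes = set(module_genes)
    if not module_genes:
        return 0.0
    frac = sum(1 for g in module_genes if g in net) / len(module_genes)
    if frac < 0.5:
        warnings.warn(
            f"only {frac:.0%} of module genes map to network nodes; "
            "check that gene namespaces match",
            stacklevel=2,
        )
    return frac
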