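"""Contextual enrichment of sub-networks against canonical pathways.

The genes of the DEG module that lie inside a minimal sub-network form the
target set T.  T is compared to each reference gene set R (a canonical
pathway from KEGG, BioCarta, PID or Reactome) by the Sorensen-Dice index
2|T∩R|/(|T|+|R|) and by an upper-tail hypergeometric p-value of the
overlap.  No multiple-testing correction is applied: the p-values only rank
candidate pathways, never gate them.

Selection rules: each sub-network keeps the reference set with the lowest
p-value (ties: larger Dice, then name order); when a regulator carries
several candidate sub-networks, the one with the largest Dice similarity is
marked selected (ties: larger network activity score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .interactome import InputFormatError
from .nas import NASRecord, compute_nas
from .pathfinder import SubNetwork
from .regulators import DEGModule


@dataclass(frozen=True)
class ReferenceGeneSet:
    """One named canonical pathway (gene set) from a source database."""

    name: str
    genes: frozenset[str]
    source_db: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"reference set {self.name!r} is empty")


def read_gmt(path: str | Path, source_db: str = "other") -> list[ReferenceGeneSet]:
    """Read a GMT pathway collection: name<TAB>description<TAB>gene...

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is an error naming the line.
    """
    path = Path(path)
    sets: list[ReferenceGeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(ReferenceGeneSet(name=fields[0].strip(), genes=genes,
                                         source_db=source_db))
    return sets


def collection_universe(collection: Iterable[ReferenceGeneSet]) -> set[str]:
    """Distinct genes across a collection (default hypergeometric universe)."""
    out: set[str] = set()
    for ref in collection:
        out |= ref.genes
    return out


def dice_similarity(T: Iterable[str], R: Iterable[str]) -> float:
    """Sorensen-Dice index 2|T∩R|/(|T|+|R|), in [0, 1].

    Symmetric; 1 exactly when the sets are equal; small reference sets are
    not swamped by large targets, which is why it is preferred here over a
    plain overlap count.
    """
    T, R = set(T), set(R)
    if not T and not R:
        raise ValueError("Dice similarity undefined for two empty sets")
    return 2 * len(T & R) / (len(T) + len(R))


def hypergeom_pvalue(k: int, t: int, r: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts reference-set genes among t draws without replacement from a
    universe of N genes containing r reference genes.  k = 0 gives exactly
    1.0.
    """
    if not (0 <= k <= min(t, r) and t <= N and r <= N and N >= 0):
        raise ValueError(
            f"inconsistent counts: k={k}, t={t}, r={r}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, r, t))


@dataclass
class EnrichmentResult:
    """Annotation of one sub-network by its best-matching canonical pathway."""

    subnetwork: SubNetwork
    target_set: frozenset[str]
    reference: ReferenceGeneSet
    dice: float
    p_value: float
    nas: float
    nas_record: Optional[NASRecord] = None
    selected: bool = False


def annotate_subnetworks(
    subnets: Sequence[SubNetwork],
    module: DEGModule,
    collection: Sequence[ReferenceGeneSet],
    fc_norm: Mapping[str, float],
    universe: int | None = None,
    similarity: str = "dice",
    cdr_scope: str = "target",
) -> list[EnrichmentResult]:
    """Annotate each sub-network and mark the selected one per regulator.

    ``fc_norm`` maps genes to min–max normalized fold changes (used for the
    network activity score).  ``universe`` defaults to the number of
    distinct genes in the collection; since the p-values are only used for
    ranking, any consistent universe preserves the result.  ``similarity``
    chooses the cross-sub-network criterion (``dice`` or ``neglogp``).
    ``cdr_scope`` sets which experimental gene list the activity score's
    overlap (CDR) is taken from: the network-restricted target set
    (``target``, default, consistent with the enrichment target) or the
    module's full DEG list (``module``).

    Sub-networks with an empty target set are skipped; if all are empty a
    ``ValueError("no mappable gene")`` is raised.
    """
    if similarity not in ("dice", "neglogp"):
        raise ValueError(f"unknown similarity criterion {similarity!r}")
    if cdr_scope not in ("target", "module"):
        raise ValueError(f"unknown cdr_scope {cdr_scope!r}")
    if not collection:
        raise ValueError("empty reference collection")
    N = universe if universe is not None else len(collection_universe(collection))

    results: list[EnrichmentResult] = []
    for sub in subnets:
        T = frozenset(sub.covered_genes & sub.nodes)
        if not T:
            continue
        # reference with the lowest p; ties -> larger Dice, then name order
        best: tuple[float, float, str, ReferenceGeneSet] | None = None
        for ref in collection:
            k = len(T & ref.genes)
            p = hypergeom_pvalue(k, len(T), len(ref.genes), N)
            d = dice_similarity(T, ref.genes)
            key = (p, -d, ref.name)
            if best is None or key < (best[0], -best[1], best[2]):
                best = (p, d, ref.name, ref)
        assert best is not None
        p, d, _name, ref = best
        nas_genes = T if cdr_scope == "target" else frozenset(module.gene_set)
        rec = compute_nas(nas_genes, ref, fc_norm)
        results.append(
            EnrichmentResult(
                subnetwork=sub, target_set=T, reference=ref,
                dice=d, p_value=p, nas=rec.nas, nas_record=rec,
            )
        )
    if not results:
        raise ValueError("no mappable gene: every sub-network has an empty target set")

    # one selected result per regulator: highest similarity, ties -> greatest NAS
    by_reg: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        by_reg.setdefault(res.subnetwork.regulator, []).append(res)
    for reg, cands in by_reg.items():
        def sim(res: EnrichmentResult) -> float:
            return res.dice if similarity == "dice" else -math.log10(res.p_value)
        winner = max(cands, key=lambda r: (sim(r), r.nas, r.reference.name))
        winner.selected = True
    return results


def functional_group_score(p_values: Sequence[float]) -> float:
    """DAVID-style enrichment score: -log10 of the geometric mean p-value.

    A group of terms all at p = 0.05 scores -log10(0.05) ~ 1.3, the usual
    significance-equivalent threshold for functional annotation clusters.
    """
    if not p_values:
        raise ValueError("empty p-value list")
    if any(p <= 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in (0, 1]")
    return -sum(math.log10(p) for p in p_values) / len(p_values)


def filter_functional_groups(
    groups: Mapping[str, Sequence[tuple[float, Iterable[str]]]],
    score_threshold: float = 1.0,
    term_alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Filter annotation clusters into DEG-module gene sets.

    ``groups`` maps a group label to its (term p-value, term genes) pairs.
    Groups with enrichment score > ``score_threshold`` are kept, and within
    a kept group only genes from terms with p < ``term_alpha`` contribute.
    Groups whose surviving gene set is empty are dropped.
    """
    out: dict[str, set[str]] = {}
    for label, terms in groups.items():
        score = functional_group_score([p for p, _g in terms])
        if score <= score_threshold:
            continue
        genes: set[str] = set()
        for p, term_genes in terms:
            if p < term_alpha:
                genes.update(term_genes)
        if genes:
            out[label] = genes
    return out


@dataclass
class ConsolidatedPathway:
    """Selected results sharing one canonical-pathway name, merged."""

    name: str
    source_dbs: frozenset[str]
    regulators: tuple[str, ...]
    nas: float        # max over members: the most active instance
    p_value: float    # min over members
    members: tuple[EnrichmentResult, ...] = ()


def consolidate(results: Sequence[EnrichmentResult]) -> list[ConsolidatedPathway]:
    """Group selected results by pathway name into consolidated pathways."""
    groups: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        if res.selected:
            groups.setdefault(res.reference.name, []).append(res)
    out = []
    for name in sorted(groups):
        members = groups[name]
        out.append(
            ConsolidatedPathway(
                name=name,
                source_dbs=frozenset(m.reference.source_db for m in members),
                regulators=tuple(m.subnetwork.regulator for m in members),
                nas=max(m.nas for m in members),
                p_value=min(m.p_value for m in members),
                members=tuple(members),
            )
        )
    return out
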