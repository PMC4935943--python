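"""Network activity score (NAS) and result ranking.

NAS = (MNF x CDR) / NGR measures how strongly a reference gene signature is
influenced by the experimental condition:

* CDR — number of experimental genes (target set T) shared with the
  reference signature,
* NGR — size of the reference signature,
* MNF — mean min–max-normalized fold change of the CDR genes.

Fold changes are normalized to [0, 1] via v -> (v - v_min)/(v_max - v_min)
with the extremes taken *with sign* over all DEGs of the comparison, so a
strong down-regulation maps near 0 and a strong up-regulation near 1; the
scheme deliberately favors activation.  NAS is therefore always in [0, 1]:
1 requires the signature to be fully covered by maximally up-regulated
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .enrichment import EnrichmentResult, ReferenceGeneSet

log = logging.getLogger(__name__)


def normalize_fold_changes(fcs: Mapping[str, float]) -> dict[str, float]:
    """Min–max scale signed fold changes into [0, 1].

    When every fold change is identical (v_max == v_min) all genes map to
    the neutral value 0.5 and a warning is logged.
    """
    if not fcs:
        raise ValueError("empty fold-change mapping")
    v_min, v_max = min(fcs.values()), max(fcs.values())
    if v_max == v_min:
        log.warning("degenerate fold changes (all equal to %g): mapping to 0.5", v_min)
        return {g: 0.5 for g in fcs}
    span = v_max - v_min
    return {g: (v - v_min) / span for g, v in fcs.items()}


def fold_change_extremes(fcs: Mapping[str, float]) -> tuple[float, float]:
    """(v_min, v_max) of a signed fold-change mapping."""
    if not fcs:
        raise ValueError("empty fold-change mapping")
    return min(fcs.values()), max(fcs.values())


@dataclass(frozen=True)
class NASRecord:
    """Audit record of one NAS computation."""

    cdr: int
    ngr: int
    mnf: float
    nas: float
    v_min: float | None = None
    v_max: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.cdr <= self.ngr:
            raise ValueError(f"CDR {self.cdr} outside [0, NGR={self.ngr}]")
        if not 0.0 <= self.nas <= 1.0 + 1e-12:
            raise ValueError(f"NAS {self.nas} outside [0, 1]")


def compute_nas(
    target_set: Iterable[str],
    reference: "ReferenceGeneSet",
    norm_fc: Mapping[str, float],
    v_min: float | None = None,
    v_max: float | None = None,
) -> NASRecord:
    """NAS = (MNF x CDR)/NGR for a target set against one reference signature.

    ``norm_fc`` must cover the target set with values already normalized to
    [0, 1].  With no overlap (CDR = 0) both MNF and NAS are 0.
    """
    T = set(target_set)
    if not reference.genes:
        raise ValueError("empty reference signature")
    overlap = T & set(reference.genes)
    cdr, ngr = len(overlap), len(reference.genes)
    if overlap:
        missing = overlap - set(norm_fc)
        if missing:
            raise KeyError(
                f"normalized fold change missing for {sorted(missing)[:5]}"
            )
        mnf = sum(norm_fc[g] for g in overlap) / cdr
    else:
        mnf = 0.0
    return NASRecord(cdr=cdr, ngr=ngr, mnf=mnf, nas=mnf * cdr / ngr,
                     v_min=v_min, v_max=v_max)


def rank_results(results: Sequence["EnrichmentResult"]) -> list["EnrichmentResult"]:
    """Order results by descending NAS; ties by ascending p-value, then
    pathway name."""
    return sorted(results, key=lambda r: (-r.nas, r.p_value, r.reference.name))
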