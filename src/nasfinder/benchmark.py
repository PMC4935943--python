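"""Benchmarking harness for ranked pathway-enrichment outputs.

Each tool emits, per dataset, pathways ranked by significance.  Against a
manual positive/negative annotation of every reference pathway, a pathway
called at p < 0.05 is a true or false positive depending on its label; one
not called (p >= 0.05, or outside the evaluation window) is a false or true
negative.  Three windows — top 10, top 100 and all results — avoid bias
from a single ranking cut; pathways beyond the window are treated as not
called, which is the only reading under which the windows differ.

Tools are compared on precision, recall (sensitivity), specificity and
accuracy, then aggregated by z-scoring each measure across tools and
averaging a tool's z-scores into one cumulative quality score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .interactome import InputFormatError

log = logging.getLogger(__name__)

SCENARIOS = {"top10": 10, "top100": 100, "all": None}
MEASURES = ("precision", "recall", "specificity", "accuracy")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class TruthTable:
    """Manual positive/negative annotation per (dataset, pathway)."""

    labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def label(self, dataset: str, pathway: str) -> str:
        try:
            return self.labels[(dataset, pathway)]
        except KeyError:
            raise KeyError(
                f"pathway {pathway!r} has no truth label for dataset {dataset!r}"
            ) from None

    def pathways(self, dataset: str) -> dict[str, str]:
        return {p: lab for (d, p), lab in self.labels.items() if d == dataset}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        """Read dataset<TAB>pathway<TAB>label lines."""
        labels: dict[tuple[str, str], str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3 or fields[2].strip() not in (POSITIVE, NEGATIVE):
                    raise InputFormatError(
                        f"{path}: line {lineno}: expected "
                        "dataset<TAB>pathway<TAB>positive|negative"
                    )
                labels[(fields[0].strip(), fields[1].strip())] = fields[2].strip()
        return cls(labels)


def confusion_counts(
    ranked: Sequence[tuple[str, float]],
    truth: TruthTable,
    dataset: str,
    scenario: str,
    alpha: float = 0.05,
) -> dict[str, int]:
    """tp/fp/tn/fn counts for one (tool, dataset) ranked output.

    Within the scenario window, p < alpha calls the pathway (tp if labelled
    positive, fp if negative); p >= alpha leaves it uncalled (fn/tn).
    Labelled pathways outside the window — ranked below the cut or missing
    from the output entirely — count as not called.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected {sorted(SCENARIOS)}")
    k = SCENARIOS[scenario]
    window = ranked if k is None else ranked[:k]

    counts = dict(tp=0, fp=0, tn=0, fn=0)
    seen: set[str] = set()
    for pathway, p in window:
        lab = truth.label(dataset, pathway)  # raises for unlabelled pathways
        seen.add(pathway)
        called = p < alpha
        if lab == POSITIVE:
            counts["tp" if called else "fn"] += 1
        else:
            counts["fp" if called else "tn"] += 1
    for pathway, lab in truth.pathways(dataset).items():
        if pathway in seen:
            continue
        counts["fn" if lab == POSITIVE else "tn"] += 1
    return counts


@dataclass
class MetricRecord:
    """Four standard measures for one (tool, dataset, scenario).

    A measure whose denominator is 0 is ``None`` (undefined) and is excluded
    from z-score aggregation.
    """

    tool: str
    dataset: str
    scenario: str
    tp: int
    fp: int
    tn: int
    fn: int
    precision: Optional[float] = None
    recall: Optional[float] = None
    specificity: Optional[float] = None
    accuracy: Optional[float] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def performance_metrics(
    counts: Mapping[str, int], tool: str = "", dataset: str = "", scenario: str = "all"
) -> MetricRecord:
    """Precision, recall, specificity and accuracy from confusion counts.

    precision = tp/(tp+fp); recall = tp/(tp+fn); specificity = tn/(tn+fp);
    accuracy = (tp+tn)/(positives+negatives).
    """
    tp, fp, tn, fn = (counts[k] for k in ("tp", "fp", "tn", "fn"))
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative confusion counts")
    return MetricRecord(
        tool=tool, dataset=dataset, scenario=scenario,
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
    )


def zscore_aggregate(
    records: Sequence[MetricRecord], pooled: bool = False
) -> pd.DataFrame:
    """Cross-tool z-scores per measure plus each tool's cumulative mean z.

    By default z-scores are computed within each (dataset, scenario,
    measure) cell across tools — sample (n-1) standard deviation — and then
    averaged per tool; with ``pooled`` the per-dataset measures are pooled
    before standardizing.  Zero variance across tools yields z = 0 for that
    cell.  Undefined (None) measures are left out.  Returns a tidy frame
    with columns tool, dataset, scenario, measure, value, z, plus per-tool
    ``mean_z`` accessible by averaging (see :func:`mean_z_per_tool`).
    """
    rows = []
    for rec in records:
        for m in MEASURES:
            v = getattr(rec, m)
            if v is None:
                continue
            rows.append(
                dict(tool=rec.tool, dataset=rec.dataset, scenario=rec.scenario,
                     measure=m, value=v)
            )
    if not rows:
        raise ValueError("no defined measure values to aggregate")
    df = pd.DataFrame(rows)
    group_cols = ["scenario", "measure"] if pooled else ["dataset", "scenario", "measure"]
    if df.groupby(group_cols)["tool"].nunique().min() < 2:
        raise ValueError("z-scores need at least two tools per measure")

    def _z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not sd or math.isnan(sd):
            log.warning("zero variance across tools; z set to 0")
            return pd.Series(0.0, index=s.index)
        return (s - s.mean()) / sd

    df["z"] = df.groupby(group_cols)["value"].transform(_z)
    return df


def mean_z_per_tool(zdf: pd.DataFrame) -> pd.Series:
    """Cumulative quality score: mean of a tool's z-scores over measures
    (and datasets/scenarios present in the frame), best first."""
    return zdf.groupby("tool")["z"].mean().sort_values(ascending=False)


def plot_mean_z(zdf: pd.DataFrame, path: str | Path) -> None:
    """Horizontal bar chart of the cumulative mean z-score per tool."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = mean_z_per_tool(zdf).sort_values()
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(means) + 1.5))
    ax.barh(means.index, means.values, color="steelblue")
    ax.set_xlabel("mean z-score (precision, recall, specificity, accuracy)")
    ax.axvline(0, color="black", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
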