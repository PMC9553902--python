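"""Classification of miRNA pull-down interactants into targets and sponge candidates.

The cascade operates on per-gene summaries from a biotinylated-miRNA pull-down
(read counts for the miR-16 bait and a control bait), a kinetic transcriptome
response to miRNA transfection (logFC per timepoint), and basal expression:

1. window filter  — genes well detected in the bait pull-down (> ``min_ip_reads``)
   fall into window *b* (down-regulated, candidate decay targets) or window *c*
   (up-regulated interactants) depending on the late kinetic response;
2. control filter — genes highly detected with the control bait
   (> ``max_ctr_reads``) are flagged as pull-down false positives;
3. basal filter   — surviving up-regulated interactants with basal expression
   > ``min_basal`` become sponge candidates (a sponge must be abundant enough
   to sequester the miRNA).

All thresholds are strict inequalities; boundary behaviour is unit-tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "GeneRecord",
    "InteractomeCall",
    "classify_kinetic_response",
    "window_filter",
    "remove_false_positives",
    "sponge_candidate_filter",
    "call_interactome",
    "calls_to_frame",
]

#: kinetic summary modes: mean of the two latest timepoints (default),
#: the last timepoint only, or the mean over all post-zero timepoints.
KINETIC_SUMMARIES = ("late_mean", "last", "all_mean")


@dataclass(frozen=True)
class FilterThresholds:
    """Cut-offs of the filter cascade (all comparisons strict)."""

    min_ip_reads: int = 100
    abs_logfc: float = 0.5
    max_ctr_reads: int = 500
    min_basal: float = 10.0
    kinetic_summary: str = "late_mean"

    def __post_init__(self) -> None:
        for name in ("min_ip_reads", "abs_logfc", "max_ctr_reads", "min_basal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kinetic_summary not in KINETIC_SUMMARIES:
            raise ValueError(
                f"kinetic_summary must be one of {KINETIC_SUMMARIES}, "
                f"got {self.kinetic_summary!r}"
            )


@dataclass
class GeneRecord:
    """One gene's observables: pull-down counts, basal expression, kinetics.

    ``logfc`` maps timepoint (hours post-transfection) to the log2 fold change
    of expression, bait-miRNA versus control-miRNA transfection.
    """

    gene_id: str
    reads_mir16: int
    reads_mirctr: int
    basal_expr: float
    logfc: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.reads_mir16 < 0 or self.reads_mirctr < 0:
            raise ValueError(f"{self.gene_id}: read counts must be non-negative")
        if int(self.reads_mir16) != self.reads_mir16 or int(self.reads_mirctr) != self.reads_mirctr:
            raise ValueError(f"{self.gene_id}: read counts must be integers")
        if self.basal_expr < 0:
            raise ValueError(f"{self.gene_id}: basal expression must be non-negative")
        vals = np.asarray(list(self.logfc.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.gene_id}: logFC values must be finite")


@dataclass
class InteractomeCall:
    """Per-gene classification with the trace of every filter decision."""

    gene_id: str
    kinetic_class: str            # down | stable | up
    window: str                   # b | c | none
    passed_ctr_filter: bool | None
    passed_basal_filter: bool | None
    final_label: str              # target | interactant_up | sponge_candidate |
    #                               excluded_false_positive | none


def _late_summary(logfc: Mapping[float, float], mode: str) -> float:
    tps = sorted(float(t) for t in logfc)
    if not tps:
        raise ValueError("logfc vector is empty")
    if mode == "last":
        return float(logfc[tps[-1]])
    if mode == "all_mean":
        post = [t for t in tps if t > 0]
        if not post:
            raise ValueError("no post-zero timepoints present")
        return float(np.mean([logfc[t] for t in post]))
    # late_mean: the two latest timepoints (24 h and 48 h in the default design)
    late = [t for t in tps if t > 0][-2:]
    if len(late) < 2:
        raise ValueError(
            "late-window summary requires at least two post-zero timepoints "
            f"(e.g. 24 and 48 h); got timepoints {tps}"
        )
    return float(np.mean([logfc[t] for t in late]))


def classify_kinetic_response(
    logfc: Mapping[float, float],
    thresholds: FilterThresholds = FilterThresholds(),
) -> str:
    """Classify the kinetic response as ``down``, ``stable`` or ``up``.

    The response is summarised over the late window (by default the mean of
    the two latest timepoints); the gene is *down* if the summary is strictly
    below ``-abs_logfc``, *up* if strictly above ``+abs_logfc``, else *stable*.
    """
    s = _late_summary(logfc, thresholds.kinetic_summary)
    if s < -thresholds.abs_logfc:
        return "down"
    if s > thresholds.abs_logfc:
        return "up"
    return "stable"


def window_filter(record: GeneRecord, thresholds: FilterThresholds = FilterThresholds()) -> str:
    """Assign a pull-down window: ``b`` (bound & down), ``c`` (bound & up), or ``none``."""
    if record.reads_mir16 <= thresholds.min_ip_reads:
        return "none"
    kin = classify_kinetic_response(record.logfc, thresholds)
    if kin == "down":
        return "b"
    if kin == "up":
        return "c"
    return "none"


def remove_false_positives(
    records: Sequence[GeneRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[GeneRecord]:
    """Drop windowed records highly detected with the control bait (strict >)."""
    return [r for r in records if r.reads_mirctr <= thresholds.max_ctr_reads]


def sponge_candidate_filter(
    records: Sequence[GeneRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[GeneRecord]:
    """Keep up-regulated interactants abundant enough to act as sponges (basal > min_basal)."""
    return [r for r in records if r.basal_expr > thresholds.min_basal]


def call_interactome(
    records: Iterable[GeneRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[InteractomeCall], dict[str, int]]:
    """Run the full cascade and return per-gene calls plus summary counts.

    Returns
    -------
    calls : list of InteractomeCall, in input order
    counts : dict with keys ``n_b``, ``n_c``, ``n_targets``,
        ``n_interactants_up``, ``n_sponge_candidates``,
        ``n_excluded_false_positive``
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id: {r.gene_id!r}")
        seen.add(r.gene_id)

    calls: list[InteractomeCall] = []
    counts = {
        "n_b": 0,
        "n_c": 0,
        "n_targets": 0,
        "n_interactants_up": 0,
        "n_sponge_candidates": 0,
        "n_excluded_false_positive": 0,
    }
    for r in records:
        kin = classify_kinetic_response(r.logfc, thresholds)
        win = window_filter(r, thresholds)
        passed_ctr: bool | None = None
        passed_basal: bool | None = None
        label = "none"
        if win == "b":
            counts["n_b"] += 1
            passed_ctr = r.reads_mirctr <= thresholds.max_ctr_reads
            if passed_ctr:
                label = "target"
                counts["n_targets"] += 1
            else:
                label = "excluded_false_positive"
                counts["n_excluded_false_positive"] += 1
        elif win == "c":
            counts["n_c"] += 1
            passed_ctr = r.reads_mirctr <= thresholds.max_ctr_reads
            if passed_ctr:
                passed_basal = r.basal_expr > thresholds.min_basal
                if passed_basal:
                    label = "sponge_candidate"
                    counts["n_sponge_candidates"] += 1
                else:
                    label = "interactant_up"
                    counts["n_interactants_up"] += 1
            else:
                label = "excluded_false_positive"
                counts["n_excluded_false_positive"] += 1
        calls.append(
            InteractomeCall(
                gene_id=r.gene_id,
                kinetic_class=kin,
                window=win,
                passed_ctr_filter=passed_ctr,
                passed_basal_filter=passed_basal,
                final_label=label,
            )
        )
    return calls, counts


def calls_to_frame(calls: Sequence[InteractomeCall]) -> pd.DataFrame:
    """Tabulate calls (one row per gene) for TSV export."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "kinetic_class": [c.kinetic_class for c in calls],
            "window": [c.window for c in calls],
            "passed_ctr_filter": [_tri(c.passed_ctr_filter) for c in calls],
            "passed_basal_filter": [_tri(c.passed_basal_filter) for c in calls],
            "final_label": [c.final_label for c in calls],
        }
    )


def _tri(v: bool | None) -> str:
    return "NA" if v is None else ("true" if v else "false")
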