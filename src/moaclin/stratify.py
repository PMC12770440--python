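"""Patient stratification: MOA extreme clusters and single-endpoint responder rules.

The multiobjective route takes the 20% of patients with the lowest front
numbers as the best-response cluster A1 and the 20% with the highest as the
worst-response cluster A2.  The two single-endpoint rules label responders
from the motor score alone: a strict decrease from baseline to V2, or a
median split on the percent change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import MDS_UPDRS_III, ClinicalCohort
from .pareto import FrontAssignment

logger = logging.getLogger(__name__)


@dataclass
class ClusterLabels:
    """Best (A1) and worst (A2) response clusters from front numbers."""

    best: tuple  # A1 patient ids
    worst: tuple  # A2 patient ids
    q: float
    target_size: int
    tie_events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.best) & set(self.worst):
            raise ValueError("A1 and A2 clusters overlap")

    def label(self, patient_id) -> str:
        if patient_id in set(self.best):
            return "A1"
        if patient_id in set(self.worst):
            return "A2"
        return "none"

    def to_frame(self, all_ids=None) -> pd.DataFrame:
        ids = sorted(all_ids) if all_ids is not None else sorted({*self.best, *self.worst})
        return pd.DataFrame({"patient_id": ids,
                             "cluster": [self.label(p) for p in ids]})


def _half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_extreme_clusters(
    fronts: FrontAssignment,
    objectives,
    q: float = 0.2,
) -> ClusterLabels:
    """Select the best/worst ``q`` fraction of patients by front number.

    The target size is round(q·N) half-up (0.2 × 72 → 14).  Patients are
    totally ordered by (front number, within-front tie-break, patient id);
    A1 is the first ``target_size`` of that order and A2 the last, which
    makes the clusters disjoint whenever 2·size ≤ N and monotone in ``q``.
    The tie-break when a front straddles the cutoff is the sum of each
    patient's per-objective ranks over the whole cohort (smaller = better).
    """
    if not 0 < q <= 0.5:
        raise ValueError(f"selection fraction q must be in (0, 0.5]; got {q}")
    series = fronts.fronts
    n = len(series)
    s = _half_up(q * n)
    if 2 * s > n:
        raise ValueError(f"q={q} requests 2×{s} patients from a cohort of {n}")

    values = objectives if isinstance(objectives, pd.DataFrame) else objectives.values
    values = values.loc[series.index]
    ranks = np.column_stack([rankdata(values[c].to_numpy()) for c in values.columns])
    rank_sum = pd.Series(ranks.sum(axis=1), index=values.index)

    # stable sort on an id-sorted frame: final tie-break is patient id
    order = (
        pd.DataFrame({"front": series, "rank_sum": rank_sum})
        .sort_index()
        .sort_values(["front", "rank_sum"], kind="mergesort")
    )
    ordered_ids = list(order.index)
    best = tuple(ordered_ids[:s])
    worst = tuple(ordered_ids[-s:][::-1])

    tie_events = []
    for name, members in (("A1", best), ("A2", worst)):
        boundary_front = int(series[members[-1]])
        front_members = set(series.index[series == boundary_front])
        if not front_members.issubset(set(members)):
            tie_events.append({
                "cluster": name,
                "front": boundary_front,
                "front_size": len(front_members),
                "taken": len(front_members & set(members)),
                "tie_break": "per-objective rank sum",
            })
    if tie_events:
        logger.info("front straddles cluster cutoff; tie-break applied: %s", tie_events)
    return ClusterLabels(best=best, worst=worst, q=q, target_size=s,
                         tie_events=tie_events)


@dataclass
class ResponderLabels:
    """R/NR label per patient under a single-endpoint motor-score rule."""

    labels: pd.Series  # patient_id -> "R" | "NR"
    rule: str
    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.sort_index().rename("responder").rename_axis("patient_id")
        return out.reset_index()


def classify_responders(
    cohort: ClinicalCohort,
    rule: str = "strict_decrease",
    score: str = MDS_UPDRS_III,
) -> ResponderLabels:
    """Label responders (R) vs nonresponders (NR) from the motor score.

    ``strict_decrease``: R iff V2 < baseline (no change or worsening → NR).
    ``median_split_pct_change``: percent change 100·(V2 − baseline)/baseline;
    R iff strictly below the cohort median (arms pooled); patients exactly
    at the median are NR, consistent with the "≥ baseline ⇒ NR" convention.
    Patients missing either visit are excluded; a zero baseline cannot enter
    a percent change and is excluded with a warning under the median rule.
    """
    if rule not in ("strict_decrease", "median_split_pct_change"):
        raise ValueError(f"unknown responder rule {rule!r}")
    wide = cohort.pivot((score,))
    excluded: dict[str, str] = {}
    base = wide.get((score, "baseline"), pd.Series(dtype=float))
    v2 = wide.get((score, "V2"), pd.Series(dtype=float))
    pair = pd.DataFrame({"baseline": base, "V2": v2}).reindex(cohort.patient_ids)
    incomplete = pair.index[pair.isna().any(axis=1)]
    for pid in incomplete:
        excluded[pid] = f"missing {score} at baseline or V2"
    pair = pair.drop(index=incomplete)

    if rule == "strict_decrease":
        labels = pd.Series(
            np.where(pair["V2"] < pair["baseline"], "R", "NR"), index=pair.index
        )
    else:
        zero_base = pair.index[pair["baseline"] == 0]
        for pid in zero_base:
            excluded[pid] = "zero baseline; percent change undefined"
            logger.warning("patient %s excluded from median split: zero baseline", pid)
        pair = pair.drop(index=zero_base)
        pct = 100.0 * (pair["V2"] - pair["baseline"]) / pair["baseline"]
        median = float(np.median(pct.to_numpy())) if len(pct) else math.nan
        labels = pd.Series(np.where(pct < median, "R", "NR"), index=pair.index)
    return ResponderLabels(labels=labels, rule=rule, excluded=excluded)
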