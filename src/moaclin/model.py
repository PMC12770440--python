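"""Model/Results surface for the multiobjective response analysis.

:class:`MultiObjectiveResponse` is constructed from a cohort (or a tidy
DataFrame / CSV file) together with the objective specifications and
policies; :meth:`MultiObjectiveResponse.fit` runs the full analysis —
objective deltas, nondominated sorting, extreme-cluster selection,
rank-normalized feature association — and returns a :class:`MOAResults`
carrying every intermediate product, a ``summary()`` table, plotting
helpers and a ``save_bundle`` writer that emits the CSV/JSON report bundle
with a complete run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .association import (
    ClusterFeatureStats,
    ParameterRanking,
    RankZMatrix,
    cluster_feature_stats,
    rank_normalize,
    rank_parameters,
)
from .cohort import (
    DEFAULT_OBJECTIVES,
    ClinicalCohort,
    CohortSchema,
    FeatureRatioMatrix,
    ObjectiveMatrix,
    ObjectiveSpec,
    compute_feature_log_ratios,
    compute_objective_deltas,
    load_cohort,
)
from .pareto import FrontAssignment, nondominated_sort
from .stratify import (
    ClusterLabels,
    ResponderLabels,
    classify_responders,
    select_extreme_clusters,
)

logger = logging.getLogger(__name__)

DOMINANCE_NOTE = (
    "Dominance uses the standard weak-Pareto form: X dominates Y iff "
    "f_i(X) <= f_i(Y) for all objectives and f_j(X) < f_j(Y) for some j "
    "(canonical minimize orientation)."
)


class MultiObjectiveResponse:
    """Multiobjective analysis of clinical response to an intervention.

    Patients are compared on the per-visit change of several conflicting
    clinical endpoints; nondominated sorting assigns each patient a front
    number, the extreme fractions form best/worst clusters, and the
    physiological parameter panel is screened for association with cluster
    membership via normalized rankings of ln(V2/baseline).

    Parameters
    ----------
    cohort : ClinicalCohort
        Long-form per-patient, per-visit measurements.
    objectives : sequence of ObjectiveSpec, optional
        Endpoints and their directions.  Default: PANDA (higher better),
        MDS-UPDRS III (lower better), olfactory score (higher better).
    parameters : sequence of str, optional
        Physiological parameters to screen; default: every non-objective
        variable in the cohort.
    pseudocount_policy : {"half_min", "exclude_cell"}
        Handling of nonpositive values inside ln(V2/baseline).
    """

    def __init__(
        self,
        cohort: ClinicalCohort,
        objectives=DEFAULT_OBJECTIVES,
        parameters=None,
        pseudocount_policy: str = "half_min",
    ) -> None:
        self.cohort = cohort
        self.objectives: tuple[ObjectiveSpec, ...] = tuple(objectives)
        self.parameters = tuple(parameters) if parameters is not None else cohort.parameters
        self.pseudocount_policy = pseudocount_policy
        self._source: dict = {"kind": "in-memory"}

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, objectives=DEFAULT_OBJECTIVES,
                       **kwargs) -> "MultiObjectiveResponse":
        """Build from a tidy long-form frame (patient_id, arm, visit, variable, value)."""
        names = {spec.name for spec in objectives}
        variables = sorted(data["variable"].unique())
        cohort = ClinicalCohort(
            data=data.copy(),
            objectives=tuple(v for v in variables if v in names),
            parameters=tuple(v for v in variables if v not in names),
        )
        return cls(cohort, objectives=objectives, **kwargs)

    @classmethod
    def from_csv(cls, path: str, schema: CohortSchema | None = None,
                 objectives=DEFAULT_OBJECTIVES, **kwargs) -> "MultiObjectiveResponse":
        """Load a delimited-text cohort table (long or wide) and build the model."""
        model = cls(load_cohort(path, schema), objectives=objectives, **kwargs)
        digest = hashlib.sha256(open(path, "rb").read()).hexdigest()
        model._source = {"kind": "file", "path": str(path), "sha256": digest}
        return model

    def fit(self, q: float = 0.2) -> "MOAResults":
        """Run the full analysis, selecting the extreme fraction ``q`` per cluster."""
        deltas = compute_objective_deltas(self.cohort, self.objectives)
        fronts = nondominated_sort(deltas)
        clusters = select_extreme_clusters(fronts, deltas, q=q)
        ratios = compute_feature_log_ratios(
            self.cohort, self.pseudocount_policy, self.parameters
        )
        rank_z = rank_normalize(ratios)
        stats = cluster_feature_stats(rank_z, clusters)
        rankings = {c: rank_parameters(stats, c) for c in ("A1", "A2")}
        responders = {
            rule: classify_responders(self.cohort, rule)
            for rule in ("strict_decrease", "median_split_pct_change")
        }
        return MOAResults(
            model=self, q=q, objective_matrix=deltas, fronts=fronts,
            clusters=clusters, feature_ratios=ratios, rank_z=rank_z,
            feature_stats=stats, rankings=rankings, responders=responders,
        )


@dataclass
class MOAResults:
    """Everything the analysis produced, stage by stage."""

    model: MultiObjectiveResponse = field(repr=False)
    q: float
    objective_matrix: ObjectiveMatrix
    fronts: FrontAssignment
    clusters: ClusterLabels
    feature_ratios: FeatureRatioMatrix
    rank_z: RankZMatrix
    feature_stats: ClusterFeatureStats
    rankings: dict[str, ParameterRanking]
    responders: dict[str, ResponderLabels]

    # -- tables -----------------------------------------------------------
    def parameter_table(self) -> pd.DataFrame:
        """Union of the per-cluster parameter rankings (long format)."""
        frames = [r.to_frame() for r in self.rankings.values() if len(r.table)]
        if not frames:
            return pd.DataFrame(columns=["parameter", "cluster", "mean", "sd",
                                         "abs_mean", "effective_n", "front_number"])
        return pd.concat(frames, ignore_index=True)

    def responder_table(self) -> pd.DataFrame:
        ids = sorted(self.model.cohort.patient_ids)
        out = pd.DataFrame({"patient_id": ids})
        for rule, labels in self.responders.items():
            col = labels.labels.reindex(ids).fillna("excluded")
            out[f"responder_{rule}"] = col.to_numpy()
        return out

    def cluster_table(self) -> pd.DataFrame:
        return self.clusters.to_frame(all_ids=list(self.fronts.fronts.index))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the run, statsmodels-style."""
        lines = []
        cohort = self.model.cohort
        w = self.fronts.n_fronts
        lines.append("Multiobjective response analysis")
        lines.append("=" * 56)
        lines.append(f"{'No. patients:':<28}{cohort.n_patients}")
        lines.append(f"{'Complete cases sorted:':<28}{self.objective_matrix.n_rows}")
        lines.append(f"{'Excluded (incomplete):':<28}{len(self.objective_matrix.excluded)}")
        obj = ", ".join(f"{s.name} ({'min' if s.sign == 1 else 'max'})"
                        for s in self.objective_matrix.specs)
        lines.append(f"{'Objectives:':<28}{obj}")
        lines.append(f"{'Fronts (F1..Fw):':<28}w = {w}")
        lines.append(f"{'Cluster fraction q:':<28}{self.q}")
        lines.append(f"{'|A1| = |A2|:':<28}{self.clusters.target_size}")
        lines.append(f"{'Parameters screened:':<28}{len(self.rank_z.values.columns)}")
        for cluster in ("A1", "A2"):
            ranking = self.rankings[cluster]
            tag = "best" if cluster == "A1" else "worst"
            front1 = ranking.front1
            lines.append("-" * 56)
            lines.append(f"Front-1 parameters, {cluster} ({tag} responders): "
                         f"{len(front1)}")
            sub = ranking.table[ranking.table["front_number"] == 1]
            for _, row in sub.iterrows():
                lines.append(f"  {row['parameter']:<24}mean {row['mean']:+.3f}  "
                             f"sd {row['sd']:.3f}")
        lines.append("=" * 56)
        lines.append(DOMINANCE_NOTE)
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Machine-readable record of every policy that shaped the output."""
        return {
            "software": {"name": "moaclin", "version": __version__},
            "input": self.model._source,
            "objectives": [
                {"name": s.name, "direction": s.direction}
                for s in self.objective_matrix.specs
            ],
            "policies": {
                "q": self.q,
                "cluster_target_size": self.clusters.target_size,
                "size_rounding": "round-half-up of q*N",
                "front_tie_break": "sum of per-objective ranks (cohort-wide), then patient id",
                "pseudocount_policy": self.feature_ratios.pseudocount_policy,
                "median_split_tie": "patients at the median labelled NR",
                "dominance": DOMINANCE_NOTE,
            },
            "counts": {
                "n_patients": self.model.cohort.n_patients,
                "n_sorted": self.objective_matrix.n_rows,
                "n_excluded": len(self.objective_matrix.excluded),
                "n_fronts": self.fronts.n_fronts,
                "front_sizes": self.fronts.sizes(),
                "n_parameters": len(self.rank_z.values.columns),
                "n_degenerate_parameters": len(self.rank_z.degenerate),
                "n_pseudocount_cells": len(self.feature_ratios.policy_applications),
            },
            "events": {
                "excluded_patients": self.objective_matrix.excluded,
                "cluster_tie_events": self.clusters.tie_events,
                "degenerate_parameters": list(self.rank_z.degenerate),
            },
        }

    def save_bundle(self, outdir: str, extra_manifest: dict | None = None) -> dict:
        """Write the report bundle: fronts, clusters, rankings, responders, manifest.

        All files are written deterministically (sorted rows, sorted JSON
        keys), so identical inputs reproduce byte-identical bundles.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fronts": os.path.join(outdir, "fronts.csv"),
            "clusters": os.path.join(outdir, "clusters.csv"),
            "parameter_ranking": os.path.join(outdir, "parameter_ranking.csv"),
            "responders": os.path.join(outdir, "responders.csv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        try:
            self.fronts.to_frame().to_csv(paths["fronts"], index=False)
            self.cluster_table().to_csv(paths["clusters"], index=False)
            self.parameter_table().to_csv(paths["parameter_ranking"], index=False)
            self.responder_table().to_csv(paths["responders"], index=False)
            manifest = self.manifest()
            if extra_manifest:
                manifest.update(extra_manifest)
            with open(paths["manifest"], "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
        except Exception:
            for p in paths.values():  # no partial bundles
                if os.path.exists(p):
                    os.remove(p)
            raise
        logger.info("report bundle written to %s", outdir)
        return paths

    # -- plotting ---------------------------------------------------------
    def plot_fronts(self, x=None, y=None, ax=None):
        """Scatter of two canonical objective deltas, colored by cluster."""
        import matplotlib.pyplot as plt

        values = self.objective_matrix.values
        x = x or values.columns[0]
        y = y or values.columns[1]
        if ax is None:
            _, ax = plt.subplots()
        labels = [self.clusters.label(p) for p in values.index]
        colors = {"A1": "tab:red", "A2": "tab:blue", "none": "0.6"}
        for group in ("none", "A1", "A2"):
            mask = [lab == group for lab in labels]
            ax.scatter(values.loc[mask, x], values.loc[mask, y],
                       c=colors[group], label=group, s=25)
        ax.set_xlabel(f"{x} (canonical delta, smaller = better)")
        ax.set_ylabel(f"{y} (canonical delta, smaller = better)")
        ax.legend(title="cluster")
        return ax

    def plot_parameter_ranking(self, cluster: str = "A1", ax=None):
        """Scatter of |mean| vs sd per parameter, front-1 members highlighted."""
        import matplotlib.pyplot as plt

        table = self.rankings[cluster].table
        if ax is None:
            _, ax = plt.subplots()
        front1 = table["front_number"] == 1
        ax.scatter(table.loc[~front1, "abs_mean"], table.loc[~front1, "sd"],
                   c="0.6", s=25, label="dominated")
        ax.scatter(table.loc[front1, "abs_mean"], table.loc[front1, "sd"],
                   c="tab:red", s=40, label="front 1")
        for _, row in table[front1].iterrows():
            ax.annotate(row["parameter"], (row["abs_mean"], row["sd"]),
                        fontsize=8, xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("|mean| of normalized ranks in cluster")
        ax.set_ylabel("sd of normalized ranks in cluster")
        ax.set_title(f"Parameter ranking, cluster {cluster}")
        ax.legend()
        return ax
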