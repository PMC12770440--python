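"""Rank-based feature association: which physiological parameters track response.

The panel of physiological parameters (immune-subset frequencies and the
like) spans wildly different scales and distributions, so their
ln(V2/baseline) changes are first converted to cohort-wide rankings and
z-normalized per parameter (mean 0, sample sd 1).  Within each extreme
cluster the mean of a parameter's normalized ranks measures how far the
cluster deviates from the rest of the population, and the standard
deviation measures how concentrated the cluster is.  A second nondominated
sort over (maximize |mean|, minimize sd) then ranks parameters: front 1
holds the parameters most strongly associated with that cluster's response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import FeatureRatioMatrix
from .pareto import nondominated_sort
from .stratify import ClusterLabels


@dataclass
class RankZMatrix:
    """Cohort-wide ranks of parameter log-ratios, z-scored per column.

    Each complete column has mean 0 and sample (n−1) sd 1.  Columns with a
    single distinct value cannot be ranked meaningfully; they are emitted as
    all-zeros and listed in ``degenerate``.
    """

    values: pd.DataFrame
    degenerate: tuple[str, ...] = ()


def rank_normalize(ratios: FeatureRatioMatrix | pd.DataFrame) -> RankZMatrix:
    """Convert each parameter column to normalized rankings.

    Ranks are computed over all non-missing patients with average ranks for
    ties, then centred and scaled by the sample standard deviation.
    """
    df = ratios.values if isinstance(ratios, FeatureRatioMatrix) else ratios
    out = {}
    degenerate = []
    for col in df.columns:
        x = df[col]
        mask = x.notna()
        z = pd.Series(np.nan, index=x.index)
        vals = x[mask].to_numpy(dtype=float)
        if len(vals) == 0 or np.unique(vals).size < 2:
            degenerate.append(col)
            warnings.warn(f"parameter {col!r} is constant; rank column set to 0",
                          stacklevel=2)
            z[mask] = 0.0
        else:
            ranks = rankdata(vals)
            z[mask] = (ranks - ranks.mean()) / ranks.std(ddof=1)
        out[col] = z
    return RankZMatrix(values=pd.DataFrame(out, index=df.index),
                       degenerate=tuple(degenerate))


@dataclass
class ClusterFeatureStats:
    """Per-parameter, per-cluster mean and sd of normalized ranks.

    ``table`` columns: parameter, cluster, mean, sd, abs_mean, effective_n,
    flagged.  A parameter-cluster pair with fewer than two non-missing
    members has no sample sd and is flagged out of the ranking.
    """

    table: pd.DataFrame
    clusters: ClusterLabels = field(repr=False, default=None)

    def for_cluster(self, cluster: str) -> pd.DataFrame:
        sub = self.table[self.table["cluster"] == cluster]
        return sub.set_index("parameter")


def cluster_feature_stats(z: RankZMatrix, clusters: ClusterLabels) -> ClusterFeatureStats:
    """Mean and sample sd of each parameter's normalized ranks, per cluster.

    Computed over cluster members with non-missing values (pairwise
    deletion), with the effective n reported per parameter.
    """
    rows = []
    for cluster_name, members in (("A1", clusters.best), ("A2", clusters.worst)):
        if not members:
            raise ValueError(f"cluster {cluster_name} is empty")
        missing = [m for m in members if m not in z.values.index]
        if missing:
            raise KeyError(f"cluster members {missing} absent from rank matrix")
        sub = z.values.loc[list(members)]
        for param in z.values.columns:
            vals = sub[param].dropna().to_numpy(dtype=float)
            n_eff = len(vals)
            mean = float(vals.mean()) if n_eff else np.nan
            sd = float(vals.std(ddof=1)) if n_eff >= 2 else np.nan
            rows.append({
                "parameter": param, "cluster": cluster_name,
                "mean": mean, "sd": sd, "abs_mean": abs(mean),
                "effective_n": n_eff,
                "flagged": n_eff < 2 or param in z.degenerate,
            })
    return ClusterFeatureStats(table=pd.DataFrame(rows), clusters=clusters)


@dataclass
class ParameterRanking:
    """Nondominated ranking of parameters for one cluster.

    Parameters are sorted in the two-objective space (−|mean|, sd), both
    minimized: front 1 contains the parameters whose normalized ranks
    deviate most within the cluster while varying least — the strongest
    response-associated candidates.
    """

    cluster: str
    table: pd.DataFrame  # parameter, mean, sd, abs_mean, effective_n, front_number
    status: str = "ok"

    @property
    def front1(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["front_number"] == 1, "parameter"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(1, "cluster", self.cluster)
        return out


def rank_parameters(stats: ClusterFeatureStats, cluster: str) -> ParameterRanking:
    """Second-stage nondominated sort of parameters for one cluster.

    Maximizing deviation |mean| and minimizing spread sd is cast as the
    canonical minimize pair (−|mean|, sd) and fed to the same Pareto engine
    used for patients.
    """
    if cluster not in ("A1", "A2"):
        raise ValueError(f"cluster must be 'A1' or 'A2'; got {cluster!r}")
    sub = stats.for_cluster(cluster)
    usable = sub[~sub["flagged"]]
    if usable.empty:
        return ParameterRanking(
            cluster=cluster,
            table=pd.DataFrame(columns=["parameter", "mean", "sd", "abs_mean",
                                        "effective_n", "front_number"]),
            status="all parameters flagged (degenerate or cluster too small)",
        )
    coords = pd.DataFrame({"neg_abs_mean": -usable["abs_mean"], "sd": usable["sd"]})
    fronts = nondominated_sort(coords)
    table = usable.reset_index()[["parameter", "mean", "sd", "abs_mean", "effective_n"]]
    table["front_number"] = fronts.fronts.loc[usable.index].to_numpy()
    table = table.sort_values(["front_number", "abs_mean"],
                              ascending=[True, False], kind="mergesort")
    return ParameterRanking(cluster=cluster, table=table.reset_index(drop=True))
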