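"""Cohort data structures and the deterministic transforms feeding the MOA.

A :class:`ClinicalCohort` holds per-patient, per-visit measurements in tidy
long form: clinical *objectives* (motor, cognitive and olfactory scores
assessed at baseline and the final visit V2) and an arbitrary panel of
*parameters* (physiological measurements such as immune-subset frequencies).
Two transforms feed the multiobjective analysis:

* :func:`compute_objective_deltas` — per-patient V2 − baseline changes in the
  objectives, canonically oriented so that smaller is always better;
* :func:`compute_feature_log_ratios` — per-patient ln(V2/baseline) for every
  physiological parameter.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VISITS = ("baseline", "V1", "V2")

#: Default endpoint set: motor score (lower is better), cognitive and
#: olfactory scores (higher is better).
MDS_UPDRS_III = "MDS-UPDRS III"
PANDA = "PANDA"
OLFACTORY = "olfactory score"

LONG_COLUMNS = ("patient_id", "arm", "visit", "variable", "value")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


class CohortParseError(ValueError):
    """Raised when a delimited-text cohort table cannot be parsed."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """A clinical objective and the direction of improvement.

    The delta rule is fixed: change = V2 − baseline, sign-flipped at
    ingestion when ``direction`` is ``"higher_is_better"`` so that a more
    negative canonical delta always means a better response.
    """

    name: str
    direction: str  # "lower_is_better" | "higher_is_better"

    def __post_init__(self) -> None:
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sign(self) -> int:
        """Multiplier applied to V2 − baseline to obtain a minimize-is-better delta."""
        return 1 if self.direction == "lower_is_better" else -1


DEFAULT_OBJECTIVES: tuple[ObjectiveSpec, ...] = (
    ObjectiveSpec(PANDA, "higher_is_better"),
    ObjectiveSpec(MDS_UPDRS_III, "lower_is_better"),
    ObjectiveSpec(OLFACTORY, "higher_is_better"),
)


@dataclass(frozen=True)
class CohortSchema:
    """Column naming for delimited-text cohort tables.

    ``layout`` is ``"long"`` (one row per patient × visit × variable, the
    canonical form), ``"wide"`` (one column per ``variable_visit``) or
    ``"auto"`` to detect from the header. ``objectives`` lists the variable
    names treated as clinical objectives; every other variable is a
    physiological parameter.
    """

    layout: str = "auto"
    patient_col: str = "patient_id"
    arm_col: str = "arm"
    visit_col: str = "visit"
    variable_col: str = "variable"
    value_col: str = "value"
    objectives: tuple[str, ...] = (PANDA, MDS_UPDRS_III, OLFACTORY)
    sep: str | None = None  # None = auto-detect among comma/tab


@dataclass
class ClinicalCohort:
    """Per-patient, per-visit measurements of objectives and parameters.

    ``data`` is a long-form frame with columns patient_id, arm, visit,
    variable, value.  Missingness is explicit: a missing measurement is an
    absent row, never a sentinel number.
    """

    data: pd.DataFrame
    objectives: tuple[str, ...]
    parameters: tuple[str, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"cohort frame lacks columns {missing_cols}")
        bad_visits = sorted(set(df["visit"]) - set(VISITS))
        if bad_visits:
            raise CohortValidationError(
                f"unknown visit labels {bad_visits}; expected one of {VISITS}"
            )
        dup = df.duplicated(subset=["patient_id", "visit", "variable"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["patient_id", "visit", "variable"]]
            raise CohortValidationError(
                "duplicate (patient_id, visit, variable) triple: "
                f"({first['patient_id']}, {first['visit']}, {first['variable']})"
            )
        values = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise CohortValidationError(
                "non-finite measurement values; encode missingness by omitting "
                "the row, not with NaN/inf sentinels"
            )
        arms = df.groupby("patient_id")["arm"].nunique()
        if (arms > 1).any():
            pid = arms.index[arms.to_numpy() > 1][0]
            raise CohortValidationError(f"patient {pid!r} assigned to multiple arms")

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    @property
    def arms(self) -> pd.Series:
        """Arm label per patient (index: patient_id)."""
        return self.data.groupby("patient_id")["arm"].first()

    def pivot(self, variables: tuple[str, ...] | list[str]) -> pd.DataFrame:
        """Patients × (variable, visit) wide view for the given variables."""
        sub = self.data[self.data["variable"].isin(variables)]
        return sub.pivot(index="patient_id", columns=["variable", "visit"], values="value")

    def missingness_report(self) -> dict[str, dict[str, int]]:
        """Per variable: number of patients lacking each of baseline/V2."""
        ids = set(self.patient_ids)
        report: dict[str, dict[str, int]] = {}
        for var in (*self.objectives, *self.parameters):
            sub = self.data[self.data["variable"] == var]
            report[var] = {
                visit: len(ids - set(sub.loc[sub["visit"] == visit, "patient_id"]))
                for visit in ("baseline", "V2")
            }
        return report


@dataclass
class ObjectiveMatrix:
    """Canonically oriented per-patient objective deltas (smaller = better).

    ``values`` has one row per complete-case patient and one column per
    objective; ``excluded`` records patients dropped for missing visits.
    """

    values: pd.DataFrame
    specs: tuple[ObjectiveSpec, ...]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise CohortValidationError("ObjectiveMatrix must be complete-case")

    @property
    def n_rows(self) -> int:
        return len(self.values)


@dataclass
class FeatureRatioMatrix:
    """Per-patient ln(V2/baseline) of every physiological parameter.

    ``pseudocount_policy`` names how nonpositive inputs were handled;
    ``policy_applications`` records every substituted cell.
    """

    values: pd.DataFrame
    pseudocount_policy: str
    policy_applications: list[dict] = field(default_factory=list)


def _detect_sep(path: str) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_table(path: str, sep: str | None) -> pd.DataFrame:
    sep = sep or _detect_sep(str(path))
    try:
        return pd.read_csv(path, sep=sep, dtype={0: str})
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise CohortParseError(f"malformed table {path}: {exc}") from exc


def load_cohort(path: str, schema: CohortSchema | None = None) -> ClinicalCohort:
    """Read a delimited-text cohort table (long or wide layout).

    Long layout needs columns patient_id, arm, visit, variable, value; wide
    layout needs patient_id, arm and one ``<variable>_<visit>`` column per
    measurement.  Rows with empty values are treated as explicitly missing
    measurements and dropped with a logged count.
    """
    schema = schema or CohortSchema()
    df = _read_table(path, schema.sep)

    layout = schema.layout
    if layout == "auto":
        long_cols = {schema.visit_col, schema.variable_col, schema.value_col}
        layout = "long" if long_cols.issubset(df.columns) else "wide"

    if layout == "long":
        rename = {
            schema.patient_col: "patient_id",
            schema.arm_col: "arm",
            schema.visit_col: "visit",
            schema.variable_col: "variable",
            schema.value_col: "value",
        }
        missing = [c for c in rename if c not in df.columns]
        if missing:
            raise CohortParseError(f"{path}: long layout lacks columns {missing}")
        long_df = df.rename(columns=rename)[list(LONG_COLUMNS)]
    elif layout == "wide":
        id_cols = [schema.patient_col, schema.arm_col]
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise CohortParseError(f"{path}: wide layout lacks columns {missing}")
        value_cols = [c for c in df.columns if c not in id_cols]
        melted = df.melt(id_vars=id_cols, value_vars=value_cols,
                         var_name="_varvisit", value_name="value")
        split = melted["_varvisit"].str.rsplit("_", n=1, expand=True)
        if split.shape[1] != 2 or not split[1].isin(VISITS).all():
            bad = melted.loc[~split[1].isin(VISITS), "_varvisit"].unique()[:3]
            raise CohortParseError(
                f"{path}: wide columns must end in _baseline/_V1/_V2; got {list(bad)}"
            )
        melted["variable"] = split[0]
        melted["visit"] = split[1]
        long_df = melted.rename(columns={schema.patient_col: "patient_id",
                                         schema.arm_col: "arm"})[list(LONG_COLUMNS)]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    long_df["patient_id"] = long_df["patient_id"].astype(str)
    long_df["value"] = pd.to_numeric(long_df["value"], errors="coerce")
    n_missing = int(long_df["value"].isna().sum())
    if n_missing:
        per_var = long_df.loc[long_df["value"].isna(), "variable"].value_counts()
        logger.info("dropping %d missing measurements: %s", n_missing, per_var.to_dict())
        long_df = long_df.dropna(subset=["value"])

    variables = sorted(long_df["variable"].unique())
    objectives = tuple(v for v in schema.objectives if v in variables)
    parameters = tuple(v for v in variables if v not in schema.objectives)
    return ClinicalCohort(long_df.reset_index(drop=True), objectives, parameters)


def write_cohort(cohort: ClinicalCohort, path: str) -> None:
    """Write the cohort in canonical long-form CSV (sorted, deterministic)."""
    out = cohort.data.sort_values(["patient_id", "visit", "variable"], kind="mergesort")
    out.to_csv(path, index=False)


def validation_report(cohort: ClinicalCohort, path: str | None = None) -> dict:
    """Counts, per-variable missingness and arm sizes, as a JSON-able dict."""
    report = {
        "n_patients": cohort.n_patients,
        "n_records": len(cohort.data),
        "arms": cohort.arms.value_counts().sort_index().to_dict(),
        "objectives": list(cohort.objectives),
        "n_parameters": len(cohort.parameters),
        "missingness": cohort.missingness_report(),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def compute_objective_deltas(
    cohort: ClinicalCohort,
    specs: tuple[ObjectiveSpec, ...] | list[ObjectiveSpec] = DEFAULT_OBJECTIVES,
) -> ObjectiveMatrix:
    """Per-patient oriented objective change, V2 − baseline.

    Higher-is-better objectives are sign-flipped so every column is
    minimize-is-better: an improvement is always a negative entry.  Patients
    missing baseline or V2 for *any* objective are excluded (complete-case)
    and listed with reasons.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("objective spec list is empty")
    available = set(cohort.data["variable"].unique())
    absent = [s.name for s in specs if s.name not in available]
    if absent:
        raise KeyError(f"objectives {absent} absent from cohort")

    wide = cohort.pivot(tuple(s.name for s in specs))
    deltas = {}
    reasons: dict[str, list[str]] = {}
    for spec in specs:
        for visit in ("baseline", "V2"):
            col = wide.get((spec.name, visit))
            missing_ids = (
                wide.index[col.isna()] if col is not None else wide.index
            )
            for pid in missing_ids:
                reasons.setdefault(pid, []).append(f"missing {spec.name} at {visit}")
        if (spec.name, "baseline") in wide.columns and (spec.name, "V2") in wide.columns:
            deltas[spec.name] = spec.sign * (
                wide[(spec.name, "V2")] - wide[(spec.name, "baseline")]
            )
        else:
            deltas[spec.name] = pd.Series(np.nan, index=wide.index)

    values = pd.DataFrame(deltas, index=wide.index)
    # patients with no objective rows at all were never in `wide`
    seen = set(wide.index)
    for pid in cohort.patient_ids:
        if pid not in seen:
            reasons[pid] = ["no objective measurements"]
    excluded = {pid: "; ".join(msgs) for pid, msgs in sorted(reasons.items())}
    values = values.drop(index=[p for p in excluded if p in values.index]).sort_index()
    if excluded:
        logger.info("excluded %d incomplete patients from objective matrix", len(excluded))
    return ObjectiveMatrix(values=values, specs=specs, excluded=excluded)


def compute_feature_log_ratios(
    cohort: ClinicalCohort,
    pseudocount_policy: str = "half_min",
    parameters: tuple[str, ...] | None = None,
) -> FeatureRatioMatrix:
    """ln(V2/baseline) per physiological parameter and patient.

    Nonpositive inputs cannot enter a log-ratio directly; the ``half_min``
    policy replaces a value ≤ 0 with half the smallest positive value
    observed for that parameter anywhere in the cohort, while the
    ``exclude_cell`` policy drops the cell (explicit missing).  Every
    substitution is recorded in ``policy_applications``.
    """
    if pseudocount_policy not in ("half_min", "exclude_cell"):
        raise ValueError(f"unknown pseudocount policy {pseudocount_policy!r}")
    parameters = parameters if parameters is not None else cohort.parameters
    if not parameters:
        raise ValueError("cohort has no physiological parameters")
    wide = cohort.pivot(tuple(parameters))

    applications: list[dict] = []
    columns: dict[str, pd.Series] = {}
    for param in parameters:
        base = wide.get((param, "baseline"))
        v2 = wide.get((param, "V2"))
        if base is None or v2 is None:
            raise KeyError(f"parameter {param!r} lacks a baseline or V2 column")
        pair = pd.DataFrame({"baseline": base, "V2": v2})
        nonpos_frac = (
            ((pair <= 0).any(axis=1) & pair.notna().all(axis=1)).sum()
            / max(pair.notna().all(axis=1).sum(), 1)
        )
        if nonpos_frac > 0.5:
            warnings.warn(
                f"parameter {param!r}: {nonpos_frac:.0%} of patients have a "
                "nonpositive baseline or V2 value",
                stacklevel=2,
            )
        positive = pair.to_numpy()[pair.to_numpy() > 0]
        half_min = positive.min() / 2.0 if positive.size else math.nan
        adjusted = pair.copy()
        for visit in ("baseline", "V2"):
            mask = (pair[visit] <= 0) & pair[visit].notna()
            for pid in pair.index[mask]:
                if pseudocount_policy == "half_min":
                    applications.append({
                        "parameter": param, "patient_id": pid, "visit": visit,
                        "original": float(pair.at[pid, visit]),
                        "replacement": float(half_min),
                    })
                    adjusted.at[pid, visit] = half_min
                else:
                    applications.append({
                        "parameter": param, "patient_id": pid, "visit": visit,
                        "original": float(pair.at[pid, visit]),
                        "replacement": None,
                    })
                    adjusted.at[pid, visit] = math.nan
        columns[param] = np.log(adjusted["V2"] / adjusted["baseline"])

    values = pd.DataFrame(columns).sort_index()
    values.index.name = "patient_id"
    if applications:
        logger.info("pseudocount policy %s applied to %d cells",
                    pseudocount_policy, len(applications))
    return FeatureRatioMatrix(values=values, pseudocount_policy=pseudocount_policy,
                              policy_applications=applications)
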