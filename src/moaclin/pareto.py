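"""Pareto dominance and nondominated sorting into fronts F1…Fw.

All routines assume canonical minimize orientation: every objective column
has already been oriented so that smaller values are better (see
:mod:`moaclin.cohort`).  Dominance is standard weak Pareto dominance — at
least as good everywhere, strictly better somewhere.  Comparisons are exact
floating-point comparisons with no tolerance: the deltas of clinical scores
are small integers or halves, and a tolerance would merge genuinely
distinct responses.

:func:`nondominated_sort` is the production path (vectorized domination
counts, Deb-style peeling); :func:`peel_fronts_oracle` is a deliberately
naive pure-Python re-derivation used to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def dominates(x, y) -> bool:
    """True iff row ``x`` Pareto-dominates row ``y`` (minimize orientation).

    x dominates y when x_i <= y_i for every objective i and x_j < y_j for at
    least one j.  Identical rows do not dominate each other.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"objective rows must be 1-D of equal length; got {x.shape} vs {y.shape}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("objective rows must be finite")
    return bool(np.all(x <= y) and np.any(x < y))


@dataclass
class FrontAssignment:
    """Front number per patient from nondominated sorting.

    ``fronts`` maps patient_id → front number, 1 (best, nondominated) to
    ``n_fronts`` (worst).  Fronts partition the patient set.
    """

    fronts: pd.Series

    def __post_init__(self) -> None:
        self.fronts = self.fronts.astype(int)
        numbers = np.sort(self.fronts.unique())
        if len(numbers) and not np.array_equal(numbers, np.arange(1, len(numbers) + 1)):
            raise ValueError(f"front numbers must be contiguous 1..w; got {numbers}")

    @property
    def n_fronts(self) -> int:
        return int(self.fronts.max()) if len(self.fronts) else 0

    def front(self, k: int) -> list:
        """Members of front ``k``, sorted by patient id."""
        return sorted(self.fronts.index[self.fronts == k])

    def sizes(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in
                self.fronts.value_counts().sort_index().items()}

    def summary(self) -> dict:
        return {"n_fronts": self.n_fronts, "front_sizes": self.sizes()}

    def to_frame(self) -> pd.DataFrame:
        out = self.fronts.sort_index().rename("front_number").rename_axis("patient_id")
        return out.reset_index()


def _as_matrix(m) -> tuple[np.ndarray, pd.Index]:
    """Accept an ObjectiveMatrix, DataFrame or ndarray; return (values, index)."""
    values = getattr(m, "values", m)
    if isinstance(values, pd.DataFrame):  # ObjectiveMatrix.values is a DataFrame
        return values.to_numpy(dtype=float), values.index
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), m.index
    arr = np.asarray(m, dtype=float)
    return arr, pd.RangeIndex(len(arr))


def _domination_matrix(values: np.ndarray) -> np.ndarray:
    """dom[i, j] = True iff row i dominates row j (vectorized pairwise)."""
    a = values[:, None, :]
    b = values[None, :, :]
    return np.all(a <= b, axis=2) & np.any(a < b, axis=2)


def nondominated_sort(m) -> FrontAssignment:
    """Sort rows into fronts by iterated removal of the nondominated set.

    Front 1 is the set of rows dominated by no other row; front k is the
    nondominated set once fronts 1…k−1 are removed.  Implemented with
    precomputed domination counts (the fast nondominated sort), which is
    provably equal to iterative peeling.
    """
    values, index = _as_matrix(m)
    if values.size == 0:
        raise ValueError("cannot sort an empty objective matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("objective matrix must be finite and complete")

    dom = _domination_matrix(values)
    counts = dom.sum(axis=0)  # number of rows dominating each row
    front_of = np.zeros(len(values), dtype=int)
    current = np.flatnonzero(counts == 0)
    k = 0
    remaining = len(values)
    while remaining:
        k += 1
        front_of[current] = k
        remaining -= len(current)
        counts = counts - dom[current].sum(axis=0)
        counts[front_of > 0] = -1  # already assigned
        current = np.flatnonzero(counts == 0)
    return FrontAssignment(pd.Series(front_of, index=index))


def pareto_front_oracle(m) -> set:
    """The nondominated set by brute-force quadratic scan — verification oracle.

    Returns the ids of rows x such that no row y dominates x.  Uses the
    scalar :func:`dominates` predicate pairwise with no shortcuts, so it is
    an independent check on :func:`nondominated_sort`.
    """
    values, index = _as_matrix(m)
    if values.size == 0:
        raise ValueError("cannot scan an empty objective matrix")
    front = set()
    for i in range(len(values)):
        if not any(dominates(values[j], values[i])
                   for j in range(len(values)) if j != i):
            front.add(index[i])
    return front


def peel_fronts_oracle(m) -> FrontAssignment:
    """Full front assignment by literal iterative peeling with the oracle."""
    values, index = _as_matrix(m)
    df = pd.DataFrame(values, index=index)
    assignment: dict = {}
    k = 0
    while len(df):
        k += 1
        front = pareto_front_oracle(df)
        for pid in front:
            assignment[pid] = k
        df = df.drop(index=list(front))
    return FrontAssignment(pd.Series(assignment).reindex(index))
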