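"""A priori power and sample size for a fixed-effects one-way ANOVA.

Under the fixed-effects model with k groups, total sample size N, Cohen's
effect size f and type-I error α, the test statistic follows a noncentral F
distribution with df1 = k − 1, df2 = N − k and noncentrality λ = f²·N.
Power is P(F′ > F_crit) with F_crit the central-F (1 − α) quantile — the
convention used by G*Power for this design.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

_MAX_N = 10**6


@dataclass(frozen=True)
class PowerDesign:
    """A solved design: smallest total N reaching the target power."""

    effect_size_f: float
    alpha: float
    k_groups: int
    target_power: float
    total_n: int
    achieved_power: float
    group_balance: bool = True

    @property
    def n_per_group(self) -> float:
        return self.total_n / self.k_groups

    def to_dict(self) -> dict:
        return {
            "effect_size_f": self.effect_size_f,
            "alpha": self.alpha,
            "k_groups": self.k_groups,
            "target_power": self.target_power,
            "total_n": self.total_n,
            "achieved_power": self.achieved_power,
            "group_balance": self.group_balance,
            "n_per_group": self.n_per_group,
        }


def _check_common(f: float, alpha: float, k: int) -> None:
    if f < 0:
        raise ValueError(f"effect size f must be >= 0; got {f}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if k < 2:
        raise ValueError(f"need at least 2 groups; got {k}")


def anova_power(f: float, alpha: float, k: int, n_total: int) -> float:
    """Power of the one-way fixed-effects ANOVA F test.

    Parameters
    ----------
    f : Cohen's effect size (between-group sd / within-group sd).
    alpha : type-I error rate.
    k : number of groups.
    n_total : total sample size across groups (must exceed k).
    """
    _check_common(f, alpha, k)
    if n_total <= k:
        raise ValueError(f"n_total must exceed the number of groups; got {n_total} <= {k}")
    df1, df2 = k - 1, n_total - k
    f_crit = stats.f.ppf(1.0 - alpha, df1, df2)
    if f == 0:  # null: statistic is central F, power is exactly alpha
        return float(stats.f.sf(f_crit, df1, df2))
    lam = f * f * n_total
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_sample_size(
    f: float,
    alpha: float,
    k: int,
    target_power: float,
    group_balance: bool = True,
) -> PowerDesign:
    """Smallest total N whose ANOVA power reaches the target.

    Scans N upward from k + 1; when ``group_balance`` is true the minimal N
    is then raised to the next multiple of k so groups can be equal sized.
    Returns the design with the power actually achieved at the reported N.
    """
    _check_common(f, alpha, k)
    if f == 0:
        raise ValueError("effect size must be positive to reach any power above alpha")
    if not 0 < target_power < 1:
        raise ValueError(f"target power must be in (0, 1); got {target_power}")

    n = k + 1
    while anova_power(f, alpha, k, n) < target_power:
        n += 1
        if n > _MAX_N:
            raise RuntimeError(
                f"target power {target_power} unreachable within N <= {_MAX_N}"
            )
    if group_balance and n % k:
        n += k - n % k
    return PowerDesign(
        effect_size_f=f, alpha=alpha, k_groups=k, target_power=target_power,
        total_n=n, achieved_power=anova_power(f, alpha, k, n),
        group_balance=group_balance,
    )
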