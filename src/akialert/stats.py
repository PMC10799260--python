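"""The trial's statistical machinery.

Binary outcomes are compared between arms as risk differences in percentage
points with Wald 95% confidence intervals and Pearson chi-square p-values
(no continuity correction).  Continuous outcomes use the Mann-Whitney
rank-sum test, with the Hodges-Lehmann shift estimate (median of all
between-group pairwise differences) and its rank-sum-inverted CI standing
behind the tables' median differences.  Exploratory subgroup effects come
from univariate binary logistic regression with an arm-by-subgroup
interaction term.  The power calculation is the classical two-sample
normal-approximation formula for a difference in means.

No multiple-testing correction is applied anywhere, matching the trial's
exploratory-analysis policy.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyCounts",
    "DifferenceEstimate",
    "PowerSpec",
    "SubgroupResult",
    "risk_difference_ci",
    "chi_square",
    "mann_whitney",
    "hodges_lehmann",
    "logistic_subgroup",
    "sample_size",
    "inflate_for_attrition",
    "incidence_per_100",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Per-arm event counts: group a is the comparison arm (e.g. alert),
    group b the reference (usual care)."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int

    def __post_init__(self) -> None:
        for e, n in ((self.events_a, self.n_a), (self.events_b, self.n_b)):
            if n <= 0:
                raise ValueError("denominators must be positive")
            if not 0 <= e <= n:
                raise ValueError(f"event count {e} outside [0, {n}]")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.events_a, self.n_a - self.events_a],
                [self.events_b, self.n_b - self.events_b],
            ]
        )


@dataclass(frozen=True)
class DifferenceEstimate:
    difference: float  # percentage points
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.difference <= self.ci_high:
            raise ValueError("difference must lie inside its CI")


def risk_difference_ci(c: ContingencyCounts, level: float = 0.95) -> DifferenceEstimate:
    """Risk difference (a minus b) in percentage points with Wald CI.

    The CI uses the unpooled normal (Wald) standard error without
    continuity correction; the p-value is Pearson's chi-square on the 2x2
    table.  This is the arithmetic that reproduces the trial's printed
    difference columns.
    """
    pa, pb = c.events_a / c.n_a, c.events_b / c.n_b
    diff = pa - pb
    se = math.sqrt(pa * (1 - pa) / c.n_a + pb * (1 - pb) / c.n_b)
    z = sps.norm.ppf(0.5 + level / 2)
    _, p = chi_square(c)
    return DifferenceEstimate(
        difference=100 * diff,
        ci_low=100 * (diff - z * se),
        ci_high=100 * (diff + z * se),
        p_value=p,
    )


def chi_square(c: ContingencyCounts) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table, 1 df, no continuity correction."""
    table = c.table
    expected = sps.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; chi-square approximation is unreliable",
            stacklevel=2,
        )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: number of (x, y) pairs with x > y, ties counting 1/2."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_limit: int = 12,
) -> tuple[float, float]:
    """Mann-Whitney U (for x over y) and two-sided p.

    method "asymptotic" uses the tie-corrected normal approximation;
    "exact" enumerates the permutation distribution of U over all group
    relabelings (valid with ties; feasible for small samples); "auto"
    (default) picks exact when n1 + n2 <= exact_limit.  The permutation
    distribution of U is symmetric about n1*n2/2, so the two-sided p is
    the probability of a U at least as far from that center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if n1 + n2 <= exact_limit else "asymptotic"

    if method == "exact":
        pooled = np.concatenate([x, y])
        center = n1 * n2 / 2
        dev = abs(u - center)
        hits = total = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            up = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            # small slack so ties at the observed deviation count
            if abs(up - center) >= dev - 1e-9:
                hits += 1
        return u, hits / total

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return u, 1.0
    z = (u - n1 * n2 / 2) / math.sqrt(var)
    return u, float(2 * sps.norm.sf(abs(z)))


def hodges_lehmann(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Hodges-Lehmann shift of y relative to x, with rank-sum-inverted CI.

    The estimate is the median of all n1*n2 pairwise differences y_j - x_i
    (so y = x + c gives c).  The CI takes order statistics of the sorted
    differences at depths from the normal approximation to the rank-sum
    null, the standard inversion of the Mann-Whitney test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diffs = np.sort((y[None, :] - x[:, None]).ravel())
    est = float(np.median(diffs))
    n1, n2 = len(x), len(y)
    m = n1 * n2
    z = sps.norm.ppf(0.5 + level / 2)
    c = m / 2 - z * math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    k = max(int(math.floor(c)), 0)
    lo = float(diffs[k]) if k < m else float(diffs[0])
    hi = float(diffs[m - 1 - k]) if k < m else float(diffs[-1])
    return est, lo, hi


@dataclass
class SubgroupResult:
    """Univariate logistic arm effect within each subgroup level."""

    odds_ratios: dict  # level -> (OR, ci_low, ci_high)
    interaction_p: float
    separation: bool = False


def _fit_logit(yv: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(yv, X)
        return model.fit(disp=0, maxiter=100)


def logistic_subgroup(
    outcome: Sequence[int],
    arm: Sequence[int],
    subgroup: Sequence[int],
    level: float = 0.95,
) -> SubgroupResult:
    """Arm odds ratio per subgroup level plus the interaction p-value.

    Within each subgroup level, a univariate logistic fit of outcome on arm
    gives the OR and Wald CI.  The interaction p comes from the Wald test
    of the arm-by-subgroup product term in the pooled fit.  Complete
    separation is flagged and the affected CI reported as unbounded.
    """
    import statsmodels.api as sm

    outcome = np.asarray(outcome, dtype=float)
    arm = np.asarray(arm, dtype=float)
    subgroup = np.asarray(subgroup, dtype=float)
    z = sps.norm.ppf(0.5 + level / 2)

    ors: dict = {}
    separation = False
    for lev in sorted(np.unique(subgroup)):
        mask = subgroup == lev
        if len(np.unique(arm[mask])) < 2:
            raise ValueError(f"both arms required within subgroup level {lev}")
        X = sm.add_constant(arm[mask])
        try:
            res = _fit_logit(outcome[mask], X)
            beta, se = res.params[1], res.bse[1]
        except Exception:
            beta, se = np.nan, np.inf
        if not np.isfinite(se) or se > 1e3:
            separation = True
            ors[float(lev)] = (math.exp(beta) if np.isfinite(beta) else np.nan,
                               0.0, np.inf)
        else:
            ors[float(lev)] = (
                math.exp(beta),
                math.exp(beta - z * se),
                math.exp(beta + z * se),
            )

    X = np.column_stack([np.ones_like(arm), arm, subgroup, arm * subgroup])
    try:
        res = _fit_logit(outcome, X)
        se_int = res.bse[3]
        inter_p = float(res.pvalues[3]) if np.isfinite(se_int) else float("nan")
        if not np.isfinite(se_int) or se_int > 1e3:
            separation = True
    except Exception:
        separation = True
        inter_p = float("nan")
    return SubgroupResult(odds_ratios=ors, interaction_p=inter_p,
                          separation=separation)


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample means power specification.

    Defaults are the trial's: SD 13.4 mL/min/1.73m2 of the absolute eGFR
    change, a clinically significant reduction from 19.0 to 17.1 (10%
    relative), 90% power at overall two-sided alpha 0.05, and 30% expected
    attrition from missing follow-up creatinine.
    """

    sd: float = 13.4
    mean_control: float = 19.0
    mean_treat: float = 17.1
    alpha_overall: float = 0.05
    power: float = 0.90
    attrition: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0,1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.mean_control == self.mean_treat:
            raise ValueError("means must differ (effect size zero)")
        if not 0 <= self.attrition < 1:
            raise ValueError("attrition must be in [0,1)")


def sample_size(spec: PowerSpec, granularity: int = 100) -> tuple[int, int]:
    """Per-group n and attrition-inflated total for a two-sample mean test.

    n = ceil( 2 sigma^2 (z_{1-alpha/2} + z_{power})^2 / delta^2 ), the
    classical normal-approximation formula; the inflated total divides the
    evaluable total 2n by (1 - attrition) and rounds up to `granularity`.
    """
    delta = abs(spec.mean_control - spec.mean_treat)
    z_a = sps.norm.ppf(1 - spec.alpha_overall / 2)
    z_b = sps.norm.ppf(spec.power)
    n = math.ceil(2 * spec.sd**2 * (z_a + z_b) ** 2 / delta**2)
    return n, inflate_for_attrition(2 * n, spec.attrition, granularity)


def inflate_for_attrition(
    n_evaluable: int, attrition: float, granularity: int = 100
) -> int:
    """Total enrolment needed so that (1 - attrition) of it is evaluable,
    rounded up to the given granularity."""
    raw = n_evaluable / (1 - attrition)
    return int(math.ceil(raw / granularity) * granularity)


def incidence_per_100(cases: int, admissions: int) -> float:
    """Episodes per 100 admissions, reported to one decimal."""
    if admissions <= 0:
        raise ValueError("admissions must be positive")
    return round(100 * cases / admissions, 1)
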