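"""Group-comparison decision tree for cytometry-style group data.

The comparison of two groups of animal-level measurements follows a fixed,
deterministic decision tree:

1. **Size gate.**  If either group has n <= 4, a two-tailed Mann–Whitney
   U test is used directly — with so few points a normality test has
   essentially no power, so the nonparametric test is forced.
2. **Normality gate** (both groups n > 4).  Each group is tested for
   normality with a Kolmogorov–Smirnov-type test against a normal
   distribution with estimated mean and s.d. — by default the Lilliefors
   variant, whose p-values account for the estimated parameters.  If both
   groups are compatible with normality (p > alpha, default 0.05), an
   unpaired two-tailed t-test is used; otherwise the Mann–Whitney U test.

The Mann–Whitney p-value is exact (full rank-permutation distribution)
when both groups have n <= 8 and there are no ties, and uses the
tie-corrected normal approximation otherwise.  Significance tiers follow
the star convention NS (p > 0.05), * (p < 0.05), ** (p < 0.01),
*** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "StatsConfig",
    "TestResult",
    "select_test",
    "run_comparison",
    "mannwhitney_p",
    "star_tier",
]

#: group sizes at or below this always take the nonparametric branch
SMALL_N_GATE = 4

#: largest per-group n for the exact Mann-Whitney null distribution
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class StatsConfig:
    alpha_normality: float = 0.05
    #: "lilliefors" (KS with estimated-parameter correction) or "ks"
    #: (plain KS against the fitted normal)
    normality_test: str = "lilliefors"
    #: "student" (equal-variance unpaired t) or "welch"
    t_variant: str = "student"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_normality < 1:
            raise ValueError("alpha_normality must lie in (0, 1)")
        if self.normality_test not in ("lilliefors", "ks"):
            raise ValueError(f"unknown normality_test {self.normality_test!r}")
        if self.t_variant not in ("student", "welch"):
            raise ValueError(f"unknown t_variant {self.t_variant!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TestResult:
    test_used: str  # "mann_whitney" | "t_test"
    p_value: float
    n_a: int
    n_b: int
    normality_checked: bool
    normality_p: float | None = None  # min of the two per-group p-values
    degenerate: bool = False  # all values tied across both groups

    @property
    def stars(self) -> str:
        return star_tier(self.p_value)


def star_tier(p: float) -> str:
    """NS / * / ** / *** significance annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _as_groups(group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("groups must not contain missing values")
    return a, b


def _normality_p(x: np.ndarray, config: StatsConfig) -> float:
    if np.ptp(x) == 0:
        return 0.0  # a constant group is maximally non-normal
    if config.normality_test == "lilliefors":
        _, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(p)


def select_test(
    group_a, group_b, config: StatsConfig = StatsConfig()
) -> str:
    """Apply the size and normality gates; returns "mann_whitney" or
    "t_test".  Deterministic in the data."""
    a, b = _as_groups(group_a, group_b)
    if min(a.size, b.size) <= SMALL_N_GATE:
        return "mann_whitney"
    if (
        _normality_p(a, config) > config.alpha_normality
        and _normality_p(b, config) > config.alpha_normality
    ):
        return "t_test"
    return "mann_whitney"


def mannwhitney_p(a, b) -> float:
    """Two-sided Mann-Whitney p: exact rank-permutation distribution when
    both groups have n <= 8 without ties, tie-corrected normal
    approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if max(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # scipy applies the tie correction
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def run_comparison(
    group_a, group_b, config: StatsConfig = StatsConfig()
) -> TestResult:
    """Run the full decision tree on two groups and return the two-tailed
    p-value with its provenance.

    Degenerate input with all values tied across both groups returns p = 1
    with the ``degenerate`` flag set.
    """
    a, b = _as_groups(group_a, group_b)
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(
            test_used="mann_whitney",
            p_value=1.0,
            n_a=a.size,
            n_b=b.size,
            normality_checked=False,
            degenerate=True,
        )

    small = min(a.size, b.size) <= SMALL_N_GATE
    normality_p: float | None = None
    if small:
        test = "mann_whitney"
    else:
        normality_p = min(_normality_p(a, config), _normality_p(b, config))
        test = "t_test" if normality_p > config.alpha_normality else "mann_whitney"

    if test == "t_test":
        p = float(
            sps.ttest_ind(a, b, equal_var=(config.t_variant == "student")).pvalue
        )
    else:
        p = mannwhitney_p(a, b)
    return TestResult(
        test_used=test,
        p_value=min(p, 1.0),
        n_a=a.size,
        n_b=b.size,
        normality_checked=not small,
        normality_p=normality_p,
    )
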