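"""Group statistics: one-way fixed-effects ANOVA and Tukey's HSD.

The ANOVA is the classical decomposition F = MS_between / MS_within with
(k - 1, N - k) degrees of freedom.  Because published group comparisons are
often printed only as mean +/- SD with group sizes, an exact
summary-statistics variant is provided: the between- and within-group sums
of squares depend on the data only through (n_i, mean_i, sd_i), so the
summary route reproduces the raw-data F identically.

Tukey's HSD uses the studentized-range statistic
``q_ij = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))``
(the Tukey-Kramer standard error for unequal group sizes), with adjusted
p-values from the studentized-range distribution with (k, N - k) degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "anova_oneway",
    "anova_from_summary",
    "tukey_hsd",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table form of one group: label, n, mean, SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class TukeyPair:
    label_a: str
    label_b: str
    mean_difference: float  # mean_a - mean_b
    q_statistic: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]
    alpha: float = 0.05

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.label_a, p.label_b} == {a, b}:
                return p
        raise KeyError(f"no pair ({a}, {b})")


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrs


def _anova_from_moments(
    ns: np.ndarray, means: np.ndarray, sds: np.ndarray, alpha: float
) -> AnovaResult:
    k = len(ns)
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0:
        raise ValueError(
            "pooled within-group variance is zero; the F statistic is undefined"
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=f, df_between=df_between, df_within=df_within, p_value=p, alpha=alpha
    )


def anova_oneway(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on raw per-group values."""
    arrs = _validate_groups(groups)
    ns = np.array([g.size for g in arrs])
    means = np.array([g.mean() for g in arrs])
    sds = np.array([g.std(ddof=1) for g in arrs])
    return _anova_from_moments(ns, means, sds, alpha)


def anova_from_summary(
    summaries: Sequence[GroupSummary], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA from printed (n, mean, SD) group summaries.

    Exactly equivalent to :func:`anova_oneway` on any raw data having those
    summaries, since both sums of squares are functions of the moments only.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    return _anova_from_moments(ns, means, sds, alpha)


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """All-pairs Tukey(-Kramer) HSD comparisons at family level ``alpha``."""
    arrs = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match groups")
    ns = np.array([g.size for g in arrs])
    means = np.array([g.mean() for g in arrs])
    k = len(arrs)
    n_total = int(ns.sum())
    df_within = n_total - k
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    if ss_within <= 0:
        raise ValueError(
            "pooled within-group variance is zero; the q statistic is undefined"
        )
    ms_within = ss_within / df_within
    pairs = []
    for i, j in combinations(range(k), 2):
        diff = float(means[i] - means[j])
        se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_within))
        pairs.append(
            TukeyPair(
                label_a=str(labels[i]),
                label_b=str(labels[j]),
                mean_difference=diff,
                q_statistic=float(q),
                p_adjusted=min(1.0, p),
                significant=p < alpha,
            )
        )
    return TukeyResult(pairs=tuple(pairs), alpha=alpha)
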