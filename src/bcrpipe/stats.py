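"""Group-comparison tests and proportion–severity association.

These wrap scipy's implementations behind the handful of tests the analysis
actually uses — two-tailed Student t, paired t, Mann–Whitney, one-way ANOVA
with Tukey HSD — plus Pearson correlation with the least-squares line for
regression-band plots.  Donor is the unit of replication throughout: the
inputs are per-donor values, never per-cell pseudoreplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    PairingError,
    UndefinedStatisticError,
)

TESTS = ("t_two_tailed", "paired_t", "mann_whitney", "anova_tukey")


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # Tukey only: per-pair adjusted p


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between per-donor proportions and disease scores,
    with the least-squares line for regression bands."""

    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float


def compare_groups(values, labels, test: str = "t_two_tailed", *,
                   pair_keys=None, equal_var: bool = True) -> StatResult:
    """Compare ``values`` between the groups named by ``labels``.

    ``paired_t`` additionally needs ``pair_keys`` (e.g. donor ids) and exactly
    two groups; unmatched keys raise :class:`PairingError` listing them.
    ``anova_tukey`` returns the one-way ANOVA F/p plus a pairwise frame with
    family-wise (Tukey HSD) adjusted p-values.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    names = sorted(pd.unique(labels).tolist())
    if len(names) < 2:
        raise InsufficientDataError(f"need >= 2 groups, found {len(names)}")
    groups = [values[labels == g] for g in names]
    if any(len(g) == 0 for g in groups):
        raise InsufficientDataError("a group is empty")

    if test == "t_two_tailed":
        if len(names) != 2:
            raise ValueError("t_two_tailed needs exactly 2 groups")
        t, p = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return StatResult(test, float(t), float(p))

    if test == "paired_t":
        if len(names) != 2:
            raise ValueError("paired_t needs exactly 2 groups")
        if pair_keys is None:
            raise PairingError("paired_t requires pair_keys (e.g. donor ids)")
        keys = np.asarray(list(pair_keys))
        a = {k: v for k, v in zip(keys[labels == names[0]], groups[0])}
        b = {k: v for k, v in zip(keys[labels == names[1]], groups[1])}
        unmatched = sorted(set(a) ^ set(b))
        if unmatched:
            raise PairingError(
                f"unmatched pair key(s) for paired_t: {', '.join(map(str, unmatched))}",
                unmatched=unmatched,
            )
        common = sorted(set(a) & set(b))
        if len(common) < 2:
            raise InsufficientDataError("paired_t needs >= 2 matched pairs")
        t, p = sps.ttest_rel([a[k] for k in common], [b[k] for k in common])
        return StatResult(test, float(t), float(p))

    if test == "mann_whitney":
        if len(names) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        u, p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return StatResult(test, float(u), float(p))

    if test == "anova_tukey":
        f, p = sps.f_oneway(*groups)
        hsd = sps.tukey_hsd(*groups)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    dict(group_a=names[i], group_b=names[j],
                         mean_diff=float(np.mean(groups[i]) - np.mean(groups[j])),
                         p_adjusted=float(hsd.pvalue[i, j]))
                )
        return StatResult(test, float(f), float(p), pairwise=pd.DataFrame(rows))

    raise ValueError(f"unknown test {test!r}; choose from {TESTS}")


def correlate_with_disease(proportions, scores) -> AssociationResult:
    """Pearson r (two-sided p) between per-donor proportions and severity
    scores, plus the least-squares slope/intercept.

    Inputs may be mappings keyed by donor (aligned on shared donors) or
    equal-length sequences.  Needs >= 3 donors and nonzero variance on both
    sides.
    """
    if isinstance(proportions, dict) or isinstance(scores, dict):
        pd_, sd_ = dict(proportions), dict(scores)
        donors = sorted(set(pd_) & set(sd_))
        x = np.array([pd_[d] for d in donors], dtype=float)
        y = np.array([sd_[d] for d in donors], dtype=float)
    else:
        x = np.asarray(list(proportions), dtype=float)
        y = np.asarray(list(scores), dtype=float)
        if x.size != y.size:
            raise ValueError("proportions and scores differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"Pearson correlation needs >= 3 donors, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Pearson correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return AssociationResult(
        n=int(x.size), pearson_r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional switch for correlation dot plots)."""
    return sps.false_discovery_control(np.asarray(list(p_values), dtype=float))
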