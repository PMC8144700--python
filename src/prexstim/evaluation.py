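"""Model evaluation and cohort statistics.

Covers the reporting side of a validation study: confusion counts and
accuracy/sensitivity/specificity with the responder as positive class,
non-parametric two-cohort comparisons (Mann-Whitney for numeric
covariates, Fisher's exact test for binary ones), a two-sample proportion
test for comparing accuracies between validation studies, and Monte-Carlo
power estimation for a one-sample exact-binomial non-inferiority test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

POSITIVE = "responder"
NEGATIVE = "non-responder"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; responder is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(labels) -> np.ndarray:
    out = []
    for v in labels:
        if isinstance(v, str):
            key = v.strip().lower()
            if key in (POSITIVE, "1", "yes", "true"):
                out.append(1)
            elif key in (NEGATIVE, "0", "no", "false"):
                out.append(0)
            else:
                raise InputError(f"unknown label {v!r}")
        else:
            iv = int(v)
            if iv not in (0, 1):
                raise InputError(f"labels must be binary, got {v!r}")
            out.append(iv)
    return np.array(out, dtype=int)


def confusion_matrix(pred, truth) -> ConfusionCounts:
    """Tally predictions against real-life outcomes."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape or len(p) == 0:
        raise InputError("pred and truth must be equal-length, nonempty")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
        tn=int(np.sum((p == 0) & (t == 0))),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Performance:
    """Accuracy/sensitivity/specificity in percent.

    Undefined metrics (zero denominator) are ``None`` rather than 0 or
    100.  ``rounded()`` applies half-away-from-zero rounding to whole
    percent, the convention used for reported figures (66.67 -> 67).
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None

    def rounded(self) -> tuple[int, int | None, int | None]:
        return tuple(
            None if v is None else _round_half_away(v)
            for v in (self.accuracy, self.sensitivity, self.specificity)
        )


def performance(c: ConfusionCounts) -> Performance:
    """Accuracy, sensitivity and specificity (percent) from counts."""
    if c.total == 0:
        raise InputError("cannot evaluate an empty confusion table")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return Performance(acc, sens, spec)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the point-probability rule: the p-value sums the hypergeometric
    probabilities of all tables (with the observed margins) whose point
    probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("need a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InputError("degenerate table: a row or column margin is zero")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney p.

    Exact null distribution when the combined sample is small (<= 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, variant: str = "pooled-z"
) -> float:
    """Two-sided test of H0: p1 = p2 from counts k1/n1 and k2/n2.

    Variants: ``"pooled-z"`` (default z-test with pooled variance),
    ``"pooled-z-cc"`` (Yates continuity correction), ``"fisher"``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n and n > 0):
            raise InputError(f"invalid counts k={k}, n={n}")
    if variant == "fisher":
        return fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
    if variant not in ("pooled-z", "pooled-z-cc"):
        raise ParameterError(f"unknown variant {variant!r}")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    diff = abs(p1 - p2)
    if variant == "pooled-z-cc":
        diff = max(diff - 0.5 * (1 / n1 + 1 / n2), 0.0)
    z = diff / math.sqrt(var)
    return float(2 * stats.norm.sf(z))


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power with its standard error and the exact value."""

    power: float
    mc_se: float
    exact: float
    critical_successes: int | None  # smallest rejecting count, None if never


def binomial_noninferiority_region(n: int, margin: float, alpha: float):
    """Smallest k with P(X >= k | p = margin) <= alpha, or None.

    The one-sided exact binomial test of H0: p <= margin rejects for large
    success counts; its rejection region is the upper tail {X >= k}.
    """
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, margin) <= alpha:
            return k
    return None


def noninferiority_power(
    p_true: float,
    n: int,
    margin: float,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> PowerEstimate:
    """Power of the one-sided exact binomial non-inferiority test.

    Monte-Carlo: draw ``n_sim`` accuracies from Binomial(n, p_true) and
    count how often the exact test rejects H0: p <= margin at level
    *alpha*.  The closed form (the upper binomial tail above the critical
    count) is returned alongside for verification.
    """
    if not (0 < margin < 1):
        raise ParameterError("margin must lie in (0, 1)")
    if not (0 <= p_true <= 1) or n < 1:
        raise ParameterError("need 0 <= p_true <= 1 and n >= 1")
    crit = binomial_noninferiority_region(n, margin, alpha)
    if crit is None:
        exact = 0.0
    else:
        exact = float(stats.binom.sf(crit - 1, n, p_true))
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, p_true, size=n_sim)
    rejected = np.zeros(n_sim, dtype=bool) if crit is None else draws >= crit
    power = float(np.mean(rejected))
    se = math.sqrt(max(power * (1 - power), 1e-12) / n_sim)
    return PowerEstimate(power=power, mc_se=se, exact=exact,
                         critical_successes=crit)


def cohort_summary(table: pd.DataFrame, cohort_col: str = "cohort") -> pd.DataFrame:
    """Two-cohort descriptive summary with per-covariate test p-values.

    Numeric covariates get median and min-max per cohort plus a
    Mann-Whitney p; binary (0/1) covariates get count and percent plus a
    Fisher exact p.  The cohort column must contain exactly two groups.
    """
    if cohort_col not in table.columns:
        raise InputError(f"table lacks the {cohort_col!r} column")
    groups = sorted(table[cohort_col].unique())
    if len(groups) != 2:
        raise InputError(f"need exactly two cohorts, found {groups}")
    ga = table[table[cohort_col] == groups[0]]
    gb = table[table[cohort_col] == groups[1]]
    rows = []
    for col in table.columns:
        if col == cohort_col:
            continue
        series = table[col]
        if not pd.api.types.is_numeric_dtype(series):
            continue
        vals = series.dropna()
        binary = set(vals.unique()).issubset({0, 1})
        a, b = ga[col].dropna(), gb[col].dropna()
        if len(a) == 0 or len(b) == 0:
            raise InputError(f"covariate {col!r} empty in one cohort")
        if binary:
            ka, kb = int(a.sum()), int(b.sum())
            p = fisher_exact([[ka, len(a) - ka], [kb, len(b) - kb]])
            pa = _round_half_away(100 * ka / len(a))
            pb = _round_half_away(100 * kb / len(b))
            rows.append({
                "covariate": col, "kind": "binary",
                f"{groups[0]}": f"{ka} ({pa}%)",
                f"{groups[1]}": f"{kb} ({pb}%)",
                "p_value": p,
            })
        else:
            p = mann_whitney(a.to_numpy(), b.to_numpy())
            rows.append({
                "covariate": col, "kind": "numeric",
                f"{groups[0]}": f"{a.median():g} ({a.min():g}-{a.max():g})",
                f"{groups[1]}": f"{b.median():g} ({b.min():g}-{b.max():g})",
                "p_value": p,
            })
    return pd.DataFrame(rows)
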