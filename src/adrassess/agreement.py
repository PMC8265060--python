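"""Inter-rater measurement-equivalence statistics.

Implements the statistics suite used to validate translated ADR assessment
instruments: exact agreement and extreme disagreement percentages with
truncated Wald intervals, Cohen's kappa and linearly weighted kappa with
Altman interpretation bands, per-category one-vs-rest agreement, and a
two-(or more-)rater Cronbach's alpha over the ordinal scores.

Conventions
-----------
* Proportions are reported on the percentage scale, intervals truncated to
  [0, 100] with the truncation flagged (the published tables apply the same
  "upper bound to 100.00%" rule).
* Kappa standard error uses the simplified Fleiss asymptotic form
  sqrt(Po(1-Po) / (n (1-Pe)^2)); weighted kappa uses the Fleiss–Cohen–Everitt
  (1969) large-sample form.  Alpha intervals use Feldt's F method.
* Degenerate inputs (Pe = 1, zero total-score variance) yield an estimate
  flagged ``defined=False`` rather than an exception, so that a full report
  can always be assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .crosstab import CrossTab, crosstab_from_ratings
from .ratings import RatingMatrix

__all__ = [
    "IntervalEstimate",
    "KappaResult",
    "CategoryAgreement",
    "WeightScheme",
    "ReliabilityReport",
    "linear_weights",
    "quadratic_weights",
    "binary_weights",
    "weight_scheme",
    "wald_interval",
    "exact_agreement",
    "category_agreement",
    "cohen_kappa",
    "weighted_kappa",
    "cronbach_alpha",
    "extreme_disagreement",
    "interpret_kappa",
    "reliability_report",
]


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is requested in strict mode on degenerate data."""


# ---------------------------------------------------------------------------
# Estimates


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with standard error and (possibly truncated) bounds."""

    point: float
    se: float
    lower: float
    upper: float
    level: float = 0.95
    truncated_lower: bool = False
    truncated_upper: bool = False
    defined: bool = True
    note: str | None = None

    def __post_init__(self) -> None:
        if self.defined and not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"bounds do not bracket the point: [{self.lower}, {self.upper}] vs {self.point}"
            )

    @classmethod
    def undefined(cls, note: str, level: float = 0.95) -> "IntervalEstimate":
        nan = float("nan")
        return cls(nan, nan, nan, nan, level=level, defined=False, note=note)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class KappaResult:
    """A kappa estimate together with its Altman interpretation band."""

    estimate: IntervalEstimate
    band: str | None
    scheme: str | None = None  # None for unweighted Cohen's kappa

    def to_dict(self) -> dict:
        return {"estimate": self.estimate.to_dict(), "band": self.band, "scheme": self.scheme}


@dataclass(frozen=True)
class CategoryAgreement:
    """One-vs-rest 2x2 agreement for a single category.

    Counts follow the published layout: ``both_yes`` / ``both_no`` agree on
    presence/absence of the category, ``rater2_only`` and ``rater1_only`` are
    the discordant cells.
    """

    category: str
    both_yes: int
    rater2_only: int
    rater1_only: int
    both_no: int
    estimate: IntervalEstimate

    @property
    def n(self) -> int:
        return self.both_yes + self.rater2_only + self.rater1_only + self.both_no

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "both_yes": self.both_yes,
            "rater2_only": self.rater2_only,
            "rater1_only": self.rater1_only,
            "both_no": self.both_no,
            "estimate": self.estimate.to_dict(),
        }


# ---------------------------------------------------------------------------
# Weight schemes


@dataclass(frozen=True)
class WeightScheme:
    """Symmetric disagreement weights w(i, j) over ordinal scores.

    w(i, i) = 0 and w(i, j) = w(j, i) >= 0.  ``binary`` reduces weighted
    kappa to Cohen's kappa; ``linear`` (the default throughout) is |i - j|.
    """

    name: str
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def matrix(self, scores: Sequence[int]) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        w = self.fn(s[:, None], s[None, :]).astype(float)
        if (np.diag(w) != 0).any() or (w < 0).any() or not np.allclose(w, w.T):
            raise ValueError(f"invalid weight matrix from scheme {self.name!r}")
        return w


def linear_weights() -> WeightScheme:
    return WeightScheme("linear", lambda i, j: np.abs(i - j))


def quadratic_weights() -> WeightScheme:
    return WeightScheme("quadratic", lambda i, j: (i - j) ** 2)


def binary_weights() -> WeightScheme:
    return WeightScheme("binary", lambda i, j: (i != j).astype(float))


def weight_scheme(name: str) -> WeightScheme:
    schemes = {"linear": linear_weights, "quadratic": quadratic_weights, "binary": binary_weights}
    try:
        return schemes[name]()
    except KeyError:
        raise ValueError(f"unknown weight scheme {name!r}; known: {sorted(schemes)}") from None


# ---------------------------------------------------------------------------
# Proportions


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(sps.norm.ppf(1 - (1 - level) / 2))


def wald_interval(successes: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Normal-approximation interval for a proportion, on the % scale,
    truncated to [0, 100] with truncation flagged."""
    if n < 1:
        raise ValueError("wald_interval requires n >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    p = successes / n
    se = math.sqrt(p * (1 - p) / n)
    z = _z(level)
    lo, hi = p - z * se, p + z * se
    trunc_lo, trunc_hi = lo < 0, hi > 1
    return IntervalEstimate(
        point=100 * p,
        se=100 * se,
        lower=100 * max(lo, 0.0),
        upper=100 * min(hi, 1.0),
        level=level,
        truncated_lower=trunc_lo,
        truncated_upper=trunc_hi,
    )


def exact_agreement(crosstab: CrossTab, level: float = 0.95) -> IntervalEstimate:
    """Percentage of cases in which both raters chose the same category."""
    if crosstab.n == 0:
        raise ValueError("exact_agreement requires a non-empty table")
    return wald_interval(crosstab.trace, crosstab.n, level=level)


def category_agreement(
    crosstab: CrossTab, category: str, level: float = 0.95
) -> CategoryAgreement:
    """Dichotomized (one-vs-rest) agreement for a single category."""
    i = crosstab.scale.index(category)  # KeyError -> unknown category
    if crosstab.n == 0:
        raise ValueError("category_agreement requires a non-empty table")
    both_yes = int(crosstab.counts[i, i])
    rater2_only = int(crosstab.row_marginals[i] - both_yes)
    rater1_only = int(crosstab.col_marginals[i] - both_yes)
    both_no = crosstab.n - both_yes - rater2_only - rater1_only
    est = wald_interval(both_yes + both_no, crosstab.n, level=level)
    return CategoryAgreement(category, both_yes, rater2_only, rater1_only, both_no, est)


# ---------------------------------------------------------------------------
# Kappa


def interpret_kappa(value: float) -> str:
    """Altman's qualitative bands; upper-inclusive at 0.20/0.40/0.60/0.80."""
    if value > 1:
        raise ValueError(f"kappa cannot exceed 1, got {value}")
    if value <= 0.20:
        return "poor"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "very good"


def _kappa_interval(k: float, se: float, level: float) -> IntervalEstimate:
    z = _z(level)
    lo, hi = k - z * se, k + z * se
    trunc_hi = hi > 1
    return IntervalEstimate(
        point=k, se=se, lower=lo, upper=min(hi, 1.0), level=level, truncated_upper=trunc_hi
    )


def cohen_kappa(crosstab: CrossTab, level: float = 0.95) -> KappaResult:
    """Chance-corrected nominal agreement between two raters.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed agreement proportion
    and Pe the chance agreement from the marginal products.
    """
    n = crosstab.n
    if n == 0:
        return KappaResult(IntervalEstimate.undefined("empty table"), None)
    p = crosstab.counts / n
    po = float(np.trace(p))
    pe = float(np.sum(p.sum(axis=1) * p.sum(axis=0)))
    if 1 - pe <= 0:
        return KappaResult(
            IntervalEstimate.undefined("degenerate marginals: chance agreement Pe = 1", level),
            None,
        )
    k = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    return KappaResult(_kappa_interval(k, se, level), interpret_kappa(k))


def weighted_kappa(
    crosstab: CrossTab, scheme: WeightScheme | None = None, level: float = 0.95
) -> KappaResult:
    """Weighted kappa over the scale's ordinal scores.

    kappa_w = 1 - sum(w p_obs) / sum(w p_exp), with expected cell
    probabilities from the marginal products.  The linear scheme is the
    default; the binary scheme recovers Cohen's kappa exactly.
    """
    if scheme is None:
        scheme = linear_weights()
    n = crosstab.n
    if n == 0:
        return KappaResult(IntervalEstimate.undefined("empty table"), None, scheme.name)
    w = scheme.matrix(crosstab.scale.scores)
    p = crosstab.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_exp = np.outer(row, col)
    denom = float((w * p_exp).sum())
    if denom <= 0:
        return KappaResult(
            IntervalEstimate.undefined(
                "degenerate marginals: zero expected weighted disagreement", level
            ),
            None,
            scheme.name,
        )
    k = 1 - float((w * p).sum()) / denom

    # Fleiss-Cohen-Everitt large-sample SE, in agreement-weight form
    # v = 1 - w / wmax (wmax > 0 whenever denom > 0).
    wmax = float(w.max())
    v = 1 - w / wmax
    pe_v = float((v * p_exp).sum())
    v_row = v @ col  # v-bar_i. : expected agreement weight given rater-2 category i
    v_col = row @ v  # v-bar_.j
    term = (v - (v_row[:, None] + v_col[None, :]) * (1 - k)) ** 2
    var = (float((p * term).sum()) - (k - pe_v * (1 - k)) ** 2) / (n * (1 - pe_v) ** 2)
    se = math.sqrt(max(var, 0.0))
    return KappaResult(_kappa_interval(k, se, level), interpret_kappa(k), scheme.name)


# ---------------------------------------------------------------------------
# Alpha


def cronbach_alpha(ratings: RatingMatrix, level: float = 0.95) -> IntervalEstimate:
    """Cronbach's alpha across raters' ordinal score vectors.

    alpha = r/(r-1) * (1 - sum of per-rater variances / variance of the
    case totals).  The value is invariant to the variance denominator
    convention; population (1/n) variances are used internally.  The
    confidence interval is Feldt's F-based interval with df (n-1) and
    (n-1)(r-1).
    """
    x = ratings.scores().to_numpy(dtype=float)
    n, r = x.shape
    if r < 2:
        raise ValueError("cronbach_alpha requires at least 2 raters")
    total_var = x.sum(axis=1).var(ddof=0)
    if n < 2 or total_var <= 0:
        return IntervalEstimate.undefined("zero total-score variance", level)
    item_var = x.var(axis=0, ddof=0).sum()
    alpha = float(r / (r - 1) * (1 - item_var / total_var))
    a2 = (1 - level) / 2
    df1, df2 = n - 1, (n - 1) * (r - 1)
    lower = 1 - (1 - alpha) * float(sps.f.ppf(1 - a2, df1, df2))
    upper = 1 - (1 - alpha) * float(sps.f.ppf(a2, df1, df2))
    trunc_hi = bool(upper > 1)
    se = (upper - lower) / (2 * _z(level))  # nominal scale for reporting only
    return IntervalEstimate(
        point=alpha,
        se=float(se),
        lower=float(lower),
        upper=min(float(upper), 1.0),
        level=level,
        truncated_upper=trunc_hi,
    )


# ---------------------------------------------------------------------------
# Extreme disagreement


def extreme_disagreement(
    ratings: RatingMatrix, threshold: int = 2, level: float = 0.95
) -> IntervalEstimate:
    """Percentage of cases whose two ordinal scores differ by MORE than
    ``threshold`` (strict inequality; the published definition is > 2)."""
    if ratings.n_raters != 2:
        raise ValueError(f"extreme_disagreement requires exactly 2 raters, got {ratings.n_raters}")
    if threshold < 0:
        raise ValueError("threshold must be a non-negative integer")
    s = ratings.scores().to_numpy()
    extreme = int((np.abs(s[:, 0] - s[:, 1]) > threshold).sum())
    return wald_interval(extreme, ratings.n_cases, level=level)


# ---------------------------------------------------------------------------
# Full report


@dataclass
class ReliabilityReport:
    """All measurement-equivalence statistics for one tool and rating set."""

    tool_id: str
    n: int
    rater_ids: list[str]
    cronbach_alpha: IntervalEstimate
    cohen_kappa: KappaResult
    weighted_kappa: KappaResult
    exact_agreement: IntervalEstimate
    extreme_disagreement: IntervalEstimate
    extreme_threshold: int
    categories: dict[str, CategoryAgreement] = field(default_factory=dict)
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "tool": self.tool_id,
            "n": self.n,
            "raters": self.rater_ids,
            "level": self.level,
            "cronbach_alpha": self.cronbach_alpha.to_dict(),
            "cohen_kappa": self.cohen_kappa.to_dict(),
            "weighted_kappa": self.weighted_kappa.to_dict(),
            "exact_agreement": self.exact_agreement.to_dict(),
            "extreme_disagreement": {
                "threshold": self.extreme_threshold,
                **self.extreme_disagreement.to_dict(),
            },
            "categories": {c: a.to_dict() for c, a in self.categories.items()},
        }


def reliability_report(
    ratings: RatingMatrix,
    scheme: WeightScheme | None = None,
    level: float = 0.95,
    extreme_threshold: int = 2,
) -> ReliabilityReport:
    """Assemble the complete statistics suite for a two-rater rating matrix.

    Per-category entries are produced for every category of the tool's
    scale, including categories never used by either rater (their one-vs-rest
    agreement is then 100%).
    """
    if scheme is None:
        scheme = linear_weights()
    ct = crosstab_from_ratings(ratings)
    cats = {c: category_agreement(ct, c, level=level) for c in ratings.scale.ids}
    return ReliabilityReport(
        tool_id=ratings.tool_id,
        n=ratings.n_cases,
        rater_ids=ratings.rater_ids,
        cronbach_alpha=cronbach_alpha(ratings, level=level),
        cohen_kappa=cohen_kappa(ct, level=level),
        weighted_kappa=weighted_kappa(ct, scheme=scheme, level=level),
        exact_agreement=exact_agreement(ct, level=level),
        extreme_disagreement=extreme_disagreement(ratings, threshold=extreme_threshold, level=level),
        extreme_threshold=extreme_threshold,
        categories=cats,
        level=level,
    )
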