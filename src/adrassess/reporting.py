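"""Rendering of reliability reports as machine JSON and aligned text.

The text layout mirrors the published results tables: a summary block with
"point (lower–upper)" confidence intervals, and a per-category block of
Yes/No/Total one-vs-rest counts with %EA, CI and SE, including the
truncation footnote marker on intervals clipped at 100%.

Decimal rendering is half-up and locale-independent (dot separator).  The
JSON rendering keeps full-precision numbers and uses no typographic dashes,
so files are bit-stable across platforms.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal

from .agreement import IntervalEstimate, ReliabilityReport


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up)."""
    if math.isnan(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(value: float, ndigits: int = 2) -> str:
    if math.isnan(value):
        return "undefined"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def _interval_cell(est: IntervalEstimate, ndigits: int = 2, point_digits: int | None = None) -> str:
    if not est.defined:
        return f"undefined ({est.note})"
    pd_ = ndigits if point_digits is None else point_digits
    mark = "^a" if est.truncated_upper else ""
    return f"{_fmt(est.point, pd_)} ({_fmt(est.lower, ndigits)}–{_fmt(est.upper, ndigits)}){mark}"


def render_report(report: ReliabilityReport, format: str = "text") -> str:
    """Render a :class:`ReliabilityReport` as "json" or aligned "text"."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, ensure_ascii=False, allow_nan=True)
    if format != "text":
        raise ValueError(f"unknown report format {format!r}; known: ['json', 'text']")

    lines: list[str] = []
    pct = int(round(report.level * 100))
    lines.append(f"Measurement equivalence — {report.tool_id} (n = {report.n})")
    lines.append("")
    label_w = 28
    lines.append(f"{'Scale':<{label_w}}{report.tool_id} ({pct}% CI)")
    rows = [
        ("Cronbach's alpha", _interval_cell(report.cronbach_alpha)),
        ("Cohen's Kappa", _interval_cell(report.cohen_kappa.estimate)),
        (f"Weighted Kappa ({report.weighted_kappa.scheme})",
         _interval_cell(report.weighted_kappa.estimate)),
        ("% Exact Agreement", _interval_cell(report.exact_agreement, point_digits=1)),
        (f"% Extreme Disagreement (>{report.extreme_threshold})",
         _interval_cell(report.extreme_disagreement, point_digits=1)),
    ]
    for name, cell in rows:
        lines.append(f"{name:<{label_w}}{cell}")
    if report.cohen_kappa.band:
        lines.append(f"{'Kappa interpretation':<{label_w}}{report.cohen_kappa.band}"
                     f" (weighted: {report.weighted_kappa.band})")
    lines.append("")
    lines.append("Per-category exact agreement (one vs rest)")
    head = (f"{'Category':<24}{'Both yes':>9}{'R2 only':>9}{'R1 only':>9}{'Both no':>9}"
            f"{'%EA':>8}  {pct}% CI{'':<14}{'SE':>6}")
    lines.append(head)
    any_trunc = False
    for cid, cat in report.categories.items():
        est = cat.estimate
        ci = f"{_fmt(est.lower)}–{_fmt(est.upper)}"
        if est.truncated_upper:
            ci += "^a"
            any_trunc = True
        lines.append(
            f"{cid:<24}{cat.both_yes:>9}{cat.rater2_only:>9}{cat.rater1_only:>9}"
            f"{cat.both_no:>9}{_fmt(est.point):>8}  {ci:<20}{_fmt(est.se):>6}"
        )
    if any_trunc or report.exact_agreement.truncated_upper:
        lines.append("")
        lines.append("^a Upper bound truncated to 100.00% to keep logical coherence")
    return "\n".join(lines)
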