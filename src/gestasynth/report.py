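"""Cohort condition-frequency tabulation and literature comparison.

For each tracked outcome the report gives the number of distinct women
with at least one onset event, the cohort percentage (one decimal,
half-up — matching how such tables are usually printed), and the distance
of the observed percentage from the lower and upper bounds of the
literature prevalence range.  When the literature gives a point value the
difference is computed directly and the upper column is empty.

Sign convention: observed minus reference, for both bounds.
"""

from __future__ import annotations

import decimal
from typing import Optional, Sequence, Union

import pandas as pd

from .demographics import PersonRecord
from .engine import CodedConcept, StateKind
from .pregnancy import CONDITIONS, ReferenceRange, default_reference_ranges

__all__ = ["tabulate", "compare", "build_report", "format_table"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(str(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )


def tabulate(
    cohort: Sequence[PersonRecord],
    conditions: Optional[Sequence[CodedConcept]] = None,
) -> pd.DataFrame:
    """Count distinct women with ≥1 onset event per condition code.

    Returns a frame with columns ``system, code, display, count, fraction,
    percent`` where ``percent`` is the half-up one-decimal cohort
    percentage and ``fraction`` the raw proportion.
    """
    if len(cohort) == 0:
        raise ValueError("cannot tabulate an empty cohort")
    if conditions is None:
        conditions = CONDITIONS
    n = len(cohort)
    counts = {c.code: 0 for c in conditions}
    for record in cohort:
        seen: set[str] = set()
        for event in record.events:
            if event.kind is StateKind.CONDITION_ONSET:
                for code in event.codes:
                    seen.add(code.code)
        for code in seen:
            if code in counts:
                counts[code] += 1
    rows = []
    for concept in conditions:
        count = counts[concept.code]
        rows.append(
            {
                "system": concept.system,
                "code": concept.code,
                "display": concept.display,
                "count": count,
                "fraction": count / n,
                "percent": round_half_up(100.0 * count / n, 1),
            }
        )
    return pd.DataFrame(rows)


def compare(
    observed_percent: float, reference: ReferenceRange
) -> tuple[float, Optional[float]]:
    """Distance of an observed percentage from a literature range.

    Returns ``(observed − lower, observed − upper)``; the second element is
    ``None`` for point references, where the first element is the direct
    difference.  Decimal arithmetic keeps one-decimal inputs exact.
    """
    obs = decimal.Decimal(str(observed_percent))
    diff_lower = float(obs - decimal.Decimal(str(reference.lower)))
    if reference.is_point:
        return diff_lower, None
    diff_upper = float(obs - decimal.Decimal(str(reference.upper)))
    return diff_lower, diff_upper


def build_report(
    cohort: Sequence[PersonRecord],
    references: Optional[Sequence[ReferenceRange]] = None,
) -> pd.DataFrame:
    """Frequency table joined with the literature comparison columns."""
    if references is None:
        references = default_reference_ranges()
    table = tabulate(cohort, [r.condition for r in references])
    ref_by_code = {r.condition.code: r for r in references}
    lowers, uppers, diff_lowers, diff_uppers = [], [], [], []
    for _, row in table.iterrows():
        ref = ref_by_code[row["code"]]
        d_lo, d_hi = compare(row["percent"], ref)
        lowers.append(ref.lower)
        uppers.append(ref.upper)
        diff_lowers.append(d_lo)
        diff_uppers.append(d_hi)
    table["ref_lower"] = lowers
    table["ref_upper"] = uppers
    table["diff_lower"] = diff_lowers
    table["diff_upper"] = diff_uppers
    return table


def format_table(report: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`build_report` output."""
    lines = [
        f"{'code':>16}  {'condition':<44} {'n (%)':>14}  {'literature (%)':>14}  {'difference (%)':>16}"
    ]
    for _, row in report.iterrows():
        if row["ref_lower"] == row["ref_upper"]:
            ref = f"{row['ref_lower']:g}"
            diff = f"{row['diff_lower']:g}"
        else:
            ref = f"{row['ref_lower']:g}-{row['ref_upper']:g}"
            diff = f"{row['diff_lower']:g} to {row['diff_upper']:g}"
        observed = f"{row['count']} ({row['percent']:.1f})"
        lines.append(
            f"{row['code']:>16}  {row['display']:<44} {observed:>14}  {ref:>14}  {diff:>16}"
        )
    return "\n".join(lines)
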