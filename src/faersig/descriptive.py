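"""Baseline-characteristics summaries of a report cohort.

Counts are exact integers; every percentage is 100·count/total rounded
half-up to two decimals (the precision at which such tables are printed), so
each category map is conservative: counts sum to the total and percentages to
100 within rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .reports import (
    AGE_BAND_LABELS,
    OUTCOMES,
    REPORTERS,
    SEXES,
    CaseReport,
)


def percentage(count: int, total: int) -> float:
    """100·count/total, rounded half-up to 2 decimals (exact decimal
    arithmetic, so printed-table rounding is reproduced bit-for-bit)."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _with_pct(counts: Mapping[str, int], total: int) -> dict[str, tuple[int, float]]:
    return {k: (v, percentage(v, total)) for k, v in counts.items()}


@dataclass
class TopDrugs:
    """Ranked drug list with an explicit percentage denominator."""

    entries: list[tuple[str, int, float]]  # (generic, report count, pct)
    denominator: int
    denominator_mode: str  # "reports" | "mentions"


@dataclass
class CohortSummary:
    total_reports: int
    by_age_band: dict[str, tuple[int, float]]
    by_sex: dict[str, tuple[int, float]]
    by_reporter: dict[str, tuple[int, float]]
    by_outcome: dict[str, tuple[int, float]]
    by_year: dict[int, int]
    top_drugs: TopDrugs | None = None

    @classmethod
    def from_counts(
        cls,
        by_age_band: Mapping[str, int],
        by_sex: Mapping[str, int],
        by_reporter: Mapping[str, int],
        by_outcome: Mapping[str, int] | None = None,
        by_year: Mapping[int, int] | None = None,
        top_drugs: TopDrugs | None = None,
    ) -> "CohortSummary":
        """Build the percentage surface from raw category counts.

        Every provided map must sum to the same total (each map covers the
        whole cohort including its unspecified category).
        """
        totals = {sum(by_age_band.values()), sum(by_sex.values()),
                  sum(by_reporter.values())}
        if by_outcome is not None:
            totals.add(sum(by_outcome.values()))
        if len(totals) != 1:
            raise ConfigurationError(
                f"category maps disagree on the cohort total: {sorted(totals)}")
        total = totals.pop()
        if total <= 0:
            raise ConfigurationError("cohort total must be positive")
        return cls(
            total_reports=total,
            by_age_band=_with_pct(by_age_band, total),
            by_sex=_with_pct(by_sex, total),
            by_reporter=_with_pct(by_reporter, total),
            by_outcome=_with_pct(by_outcome, total) if by_outcome else {},
            by_year=dict(by_year) if by_year else {},
            top_drugs=top_drugs,
        )


def summarize_demographics(reports: Sequence[CaseReport],
                           top_n: int = 5,
                           denominator: str = "reports") -> CohortSummary:
    """Full baseline table for a cohort: age band, sex, reporter, outcome
    (all categories present, zero-filled), yearly counts, and the top-N drug
    ranking."""
    if not reports:
        raise ConfigurationError("cannot summarize an empty cohort")
    age = Counter({k: 0 for k in AGE_BAND_LABELS})
    sex = Counter({k: 0 for k in SEXES})
    rep = Counter({k: 0 for k in REPORTERS})
    out = Counter({k: 0 for k in OUTCOMES})
    year: Counter = Counter()
    for r in reports:
        age[r.age_band] += 1
        sex[r.sex] += 1
        rep[r.reporter] += 1
        out[r.outcome] += 1
        year[r.receipt_year] += 1
    years = range(min(year), max(year) + 1)
    by_year = {y: year.get(y, 0) for y in years}
    return CohortSummary.from_counts(
        dict(age), dict(sex), dict(rep), dict(out), by_year,
        top_drugs=top_drugs(reports, top_n, denominator=denominator),
    )


def top_drugs(reports: Sequence[CaseReport], n: int = 5,
              denominator: str = "reports") -> TopDrugs:
    """Most-reported drugs, ranked by report count descending, ties broken
    alphabetically.

    A drug counts once per report however often it is mentioned. The
    percentage denominator is either the number of reports
    (``denominator="reports"``) or the total number of distinct per-report
    drug mentions (``"mentions"``); the choice is carried in the output.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if denominator not in ("reports", "mentions"):
        raise ConfigurationError(
            f"denominator must be 'reports' or 'mentions', got {denominator!r}")
    counts: Counter = Counter()
    for r in reports:
        counts.update(r.drug_labels())
    denom = len(reports) if denominator == "reports" else sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    entries = [(name, cnt, percentage(cnt, denom)) for name, cnt in ranked]
    return TopDrugs(entries=entries, denominator=denom,
                    denominator_mode=denominator)


def yearly_counts(reports: Sequence[CaseReport], event: str,
                  year_range: tuple[int, int] | None = None) -> dict[int, int]:
    """Reports mentioning ``event``, per calendar year, zero-filled over the
    data range (or an explicit range)."""
    counts: Counter = Counter()
    for r in reports:
        if event in r.events:
            counts[r.receipt_year] += 1
    if year_range is None:
        if not reports:
            return {}
        years = [r.receipt_year for r in reports]
        year_range = (min(years), max(years))
    return {y: counts.get(y, 0) for y in range(year_range[0], year_range[1] + 1)}


def outcome_distribution(reports: Sequence[CaseReport],
                         by_year: bool = False) -> pd.DataFrame:
    """Outcome counts and percentages, overall or per year.

    Absolute and percentage views share the same count basis; per-year
    percentages sum to 100 within rounding.
    """
    if not reports:
        raise ConfigurationError("cannot summarize an empty cohort")
    rows = []
    if by_year:
        years = sorted({r.receipt_year for r in reports})
        for y in years:
            sub = [r for r in reports if r.receipt_year == y]
            counts = Counter({k: 0 for k in OUTCOMES})
            counts.update(r.outcome for r in sub)
            for outcome in OUTCOMES:
                rows.append({"year": y, "outcome": outcome,
                             "count": counts[outcome],
                             "pct": percentage(counts[outcome], len(sub))})
    else:
        counts = Counter({k: 0 for k in OUTCOMES})
        counts.update(r.outcome for r in reports)
        for outcome in OUTCOMES:
            rows.append({"outcome": outcome, "count": counts[outcome],
                         "pct": percentage(counts[outcome], len(reports))})
    return pd.DataFrame(rows)


def summary_to_frames(summary: CohortSummary) -> dict[str, pd.DataFrame]:
    """Tidy (category, count, percentage) tables, one per summary block."""
    frames = {}
    for name, mapping in (("age_band", summary.by_age_band),
                          ("sex", summary.by_sex),
                          ("reporter", summary.by_reporter),
                          ("outcome", summary.by_outcome)):
        frames[name] = pd.DataFrame(
            [{"category": k, "count": c, "percentage": p}
             for k, (c, p) in mapping.items()])
    frames["year"] = pd.DataFrame(
        [{"year": y, "count": c} for y, c in summary.by_year.items()])
    if summary.top_drugs is not None:
        frames["top_drugs"] = pd.DataFrame(
            [{"drug": d, "count": c, "percentage": p,
              "denominator": summary.top_drugs.denominator,
              "denominator_mode": summary.top_drugs.denominator_mode}
             for d, c, p in summary.top_drugs.entries])
    return frames
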