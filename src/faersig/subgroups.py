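"""Sex × age subgroup screens and pairwise drug correlations.

The default strata follow the common adult/elderly split used in subgroup
pharmacovigilance screens: adult males and females aged 25–65 (inclusive both
ends) and elderly males and females strictly above 65. Reports aged 18–24 or
with missing age fall in no stratum — the subgroup definition is preserved
as stated rather than patched to be exhaustive.

Within each stratum the contingency background is rebuilt from that stratum's
reports only, and three metrics are tabulated per drug: absolute count (the a
cell), the safety signal, and the relative reporting ratio. Drug profiles
across strata (or across years, via :func:`yearly_metric_matrix`) can then be
correlated pairwise; with only four strata a Pearson r is noisy, so pairs
sharing fewer than three non-missing cells, or with zero variance, are
excluded with a reason instead of being reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .disproportionality import (
    build_contingency,
    compute_rrr,
    compute_safety_signal,
    screen_all,
)
from .errors import ConfigurationError, DataError
from .reports import CaseReport

METRICS = ("absolute_count", "safety_signal", "relative_reporting_ratio")


@dataclass(frozen=True)
class StratumSpec:
    """A sex × age-interval subgroup filter.

    ``age_max=None`` means unbounded above. Bound inclusivity is explicit so
    both closed-closed ([25, 65]) and open-below ((65, inf)) intervals are
    expressible.
    """

    label: str
    sex: str
    age_min: float
    age_max: float | None = None
    min_inclusive: bool = True
    max_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.age_max is not None and not self.age_min < self.age_max:
            raise ConfigurationError(
                f"stratum {self.label!r}: age interval must satisfy low < high"
            )

    def contains(self, sex: str, age_years: float | None) -> bool:
        if age_years is None or sex != self.sex:
            return False
        if self.min_inclusive:
            if age_years < self.age_min:
                return False
        elif age_years <= self.age_min:
            return False
        if self.age_max is not None:
            if self.max_inclusive:
                if age_years > self.age_max:
                    return False
            elif age_years >= self.age_max:
                return False
        return True

    def contains_report(self, report: CaseReport) -> bool:
        return self.contains(report.sex, report.age_years)


def default_strata() -> list[StratumSpec]:
    """The four adult/elderly × male/female subgroups.

    Adult = age 25 to 65 inclusive; elderly = strictly above 65. Ages 18–24
    deliberately fall in no stratum.
    """
    out = []
    for sex in ("male", "female"):
        out.append(StratumSpec(f"adult {sex}", sex, 25.0, 65.0))
        out.append(StratumSpec(f"elderly {sex}", sex, 65.0, None, min_inclusive=False))
    return out


@dataclass
class StratifiedMatrix:
    """Drugs × strata grid of one metric; missing cells are NaN."""

    metric: str
    frame: pd.DataFrame  # index = drugs, columns = stratum labels

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.index)

    @property
    def strata(self) -> list[str]:
        return list(self.frame.columns)


def stratified_metrics(
    reports: Sequence[CaseReport],
    event: str,
    drugs: Sequence[str],
    strata: Sequence[StratumSpec] | None = None,
    role: str | None = None,
) -> dict[str, StratifiedMatrix]:
    """Per-stratum screen: three drugs × strata matrices.

    Each stratum uses its own reports as the contingency background. A stratum
    with zero reports produces an all-missing (NaN) column and a warning.
    """
    if strata is None:
        strata = default_strata()
    _check_disjoint(strata)
    drug_list = list(drugs)
    grids = {m: pd.DataFrame(index=drug_list, columns=[s.label for s in strata],
                             dtype=float) for m in METRICS}
    for spec in strata:
        sub = [r for r in reports if spec.contains_report(r)]
        if not sub:
            warnings.warn(f"stratum {spec.label!r} has no reports; column is missing",
                          stacklevel=2)
            continue  # NaN column stays
        for drug in drug_list:
            table = build_contingency(sub, drug, event, role=role)
            grids["absolute_count"].loc[drug, spec.label] = float(table.a)
            grids["safety_signal"].loc[drug, spec.label] = compute_safety_signal(table)
            grids["relative_reporting_ratio"].loc[drug, spec.label] = compute_rrr(table)
    return {m: StratifiedMatrix(m, g) for m, g in grids.items()}


def _check_disjoint(strata: Sequence[StratumSpec]) -> None:
    probes = [(s, a / 4.0) for s in ("male", "female") for a in range(0, 480)]
    for sex, age in probes:
        hits = [s.label for s in strata if s.contains(sex, age)]
        if len(hits) > 1:
            raise ConfigurationError(f"strata overlap at {sex}, age {age}: {hits}")


def yearly_metric_matrix(
    reports: Sequence[CaseReport],
    event: str,
    drugs: Sequence[str],
    metric: str = "absolute_count",
    role: str | None = None,
) -> StratifiedMatrix:
    """Drugs × years grid of one metric (alternative correlation axis).

    Each calendar year's reports form their own background.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"metric must be one of {METRICS}, got {metric!r}")
    if not reports:
        raise DataError("no reports")
    years = sorted({r.receipt_year for r in reports})
    drug_list = list(drugs)
    grid = pd.DataFrame(index=drug_list, columns=[str(y) for y in years], dtype=float)
    for year in years:
        sub = [r for r in reports if r.receipt_year == year]
        for drug in drug_list:
            table = build_contingency(sub, drug, event, role=role)
            if metric == "absolute_count":
                grid.loc[drug, str(year)] = float(table.a)
            elif metric == "safety_signal":
                grid.loc[drug, str(year)] = compute_safety_signal(table)
            else:
                grid.loc[drug, str(year)] = compute_rrr(table)
    return StratifiedMatrix(metric, grid)


def top_k_per_stratum(
    matrix: StratifiedMatrix, k: int
) -> dict[str, list[tuple[str, float]]]:
    """Per-stratum top-k drugs by the matrix metric, descending.

    Ties break alphabetically; missing cells never rank. ``k`` beyond the drug
    count returns the full ordered list.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    out: dict[str, list[tuple[str, float]]] = {}
    for col in matrix.frame.columns:
        series = matrix.frame[col].dropna()
        ranked = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
        out[col] = [(drug, float(v)) for drug, v in ranked[:k]]
    return out


@dataclass(frozen=True)
class CorrelationPair:
    drug_i: str
    drug_j: str
    n_cells: int
    r: float


def pairwise_drug_correlation(
    matrix: StratifiedMatrix,
    min_shared: int = 3,
    include_self: bool = False,
) -> tuple[list[CorrelationPair], list[tuple[str, str, str]]]:
    """Pearson correlation of every drug pair's metric profile.

    Profiles are the matrix rows; each pair is correlated over the cells
    non-missing in both. Pairs with fewer than ``min_shared`` shared cells or
    zero variance in either profile are returned in the exclusion list with a
    reason. Drug order within a pair is alphabetical (r is symmetric).
    """
    drugs = matrix.drugs
    if len(drugs) < 2 and not include_self:
        raise DataError("need at least two drugs to correlate")
    values = matrix.frame.to_numpy(dtype=float)
    pairs: list[CorrelationPair] = []
    excluded: list[tuple[str, str, str]] = []
    for i in range(len(drugs)):
        j0 = i if include_self else i + 1
        for j in range(j0, len(drugs)):
            di, dj = sorted((drugs[i], drugs[j]))
            x, y = values[i], values[j]
            mask = ~(np.isnan(x) | np.isnan(y))
            n_shared = int(mask.sum())
            if n_shared < min_shared:
                excluded.append((di, dj, f"only {n_shared} shared cells"))
                continue
            xs, ys = x[mask], y[mask]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                excluded.append((di, dj, "zero variance"))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(_sstats.pearsonr(xs, ys).statistic)
            pairs.append(CorrelationPair(di, dj, n_shared, r))
    if matrix.frame.shape[1] < 5 and pairs:
        warnings.warn(
            f"correlations computed over only {matrix.frame.shape[1]} cells per "
            "profile; |r| estimates are noisy", stacklevel=2)
    return pairs, excluded


def rank_negative_pairs(
    pairs: Sequence[CorrelationPair], n: int
) -> list[CorrelationPair]:
    """The n most negatively correlated pairs, ascending in r.

    Ties break on the (drug_i, drug_j) name pair, so the ranking is a total
    order regardless of input order.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    ranked = sorted(pairs, key=lambda p: (p.r, p.drug_i, p.drug_j))
    return list(ranked[:n])


def matrix_to_long_frame(matrices: dict[str, StratifiedMatrix]) -> pd.DataFrame:
    """Heatmap-ready long table: (drug, stratum, metric, value)."""
    rows = []
    for metric, m in matrices.items():
        for drug in m.drugs:
            for stratum in m.strata:
                rows.append({
                    "drug": drug,
                    "stratum": stratum,
                    "metric": metric,
                    "value": m.frame.loc[drug, stratum],
                })
    return pd.DataFrame(rows)


def correlations_to_frame(pairs: Sequence[CorrelationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"drug_i": p.drug_i, "drug_j": p.drug_j, "n_cells": p.n_cells, "r": p.r}
         for p in pairs]
    )


def unstratified_check(
    reports: Sequence[CaseReport], event: str, drugs: Sequence[str],
    role: str | None = None,
):
    """Convenience: the plain (single-background) screen, for consistency
    checks against a single-stratum stratification."""
    return screen_all(reports, event, drugs, role=role)
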