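"""Drug–event 2×2 tables and disproportionality statistics.

For one drug D and one adverse-event preferred term E within a background set
of N deduplicated reports, the contingency table is

    a = reports with D and E        b = reports with D, without E
    c = reports with E, without D   d = reports with neither

with drug margin n1 = a+b, event margin n2 = a+c and expected co-reporting
count under independence E0 = n1*n2/N. Four statistics are computed:

* **ROR** (reporting odds ratio) ``a*d/(b*c)`` with a Wald 95% CI on the log
  scale and a two-sided Fisher exact p-value. When any cell is zero, 0.5 is
  added to all four cells (Haldane–Anscombe) for the estimate and CI, and the
  result is flagged as corrected; the p-value always uses the raw counts.
* **RRR** (relative reporting ratio, the "relative risk" of spontaneous-report
  mining) ``a/E0``.
* **safety signal**: the shrunk log2 observed/expected
  ``log2((a+0.5)/(E0+0.5))``, a signed measure that is 0 when a = E0 and
  finite at a = 0.
* **IC** (BCPNN information component): by default the same shrinkage kernel
  with exact gamma credible bounds — the posterior of the co-reporting rate is
  treated as Gamma(a+1/2, 1) so the 95% interval is
  ``log2(q_Gamma(α; a+1/2) / (E0+1/2))`` at α = 0.025, 0.975. The classical
  closed-form moment approximation with uniform-marginal priors
  (``method="bate1998"``) is selectable.

Three decision rule sets are screened, exactly as commonly printed:

* ``aersmine``: a ≥ 2 and safety signal > 0 and RRR > 2;
* ``ror``: lower 95% Wald limit of the ROR > 1;
* ``bcpnn``: a ≥ 3 and lower 95% credible limit of the IC > 0.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .reports import CaseReport

Z95 = 1.96  # normal multiplier for a 95% interval

IC_METHODS = ("gamma", "bate1998")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event co-reporting counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> int:
        return self.a + self.b

    @property
    def event_margin(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected a under independence: n1*n2/N."""
        if self.n == 0:
            raise DataError("empty contingency table (N=0)")
        return self.drug_margin * self.event_margin / self.n


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # Haldane–Anscombe 0.5 applied


@dataclass
class SignalResult:
    """All metrics and rule-set flags for one drug–event–stratum combination."""

    drug: str
    event: str
    stratum: str
    table: ContingencyTable
    ror: float
    ror_ci: tuple[float, float]
    ror_p: float
    ror_corrected: bool
    rrr: float
    safety_signal: float
    ic: float
    ic_ci: tuple[float, float]
    flags: dict[str, bool] = field(default_factory=dict)


def build_contingency(
    reports: Sequence[CaseReport],
    drug: str,
    event: str,
    role: str | None = None,
) -> ContingencyTable:
    """Count the 2×2 table for ``drug`` × ``event`` over ``reports``.

    ``reports`` IS the background population; pass the full deduplicated set or
    a cohort/stratum subset to choose the background. ``role`` restricts the
    drug side to mentions with that role code (e.g. ``primary_suspect``).
    """
    if not drug or not event:
        raise ConfigurationError("drug and event must be non-empty")
    if len(reports) == 0:
        raise DataError("background is empty")
    a = b = c = d = 0
    for r in reports:
        has_drug = drug in r.drug_labels(role)
        has_event = event in r.events
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with Wald 95% CI and Fisher exact p-value."""
    if table.n == 0:
        raise DataError("empty contingency table (N=0)")
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    ror = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - Z95 * se)
    ci_high = math.exp(log_ror + Z95 * se)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return RorResult(ror, ci_low, ci_high, float(p), corrected)


def point_estimate_from_ci(ci_low: float, ci_high: float) -> float:
    """Recover the Wald point estimate from its CI limits.

    A log-scale Wald interval is symmetric about the log point estimate, so
    the estimate is the geometric mean of the limits. Useful for checking
    published forest plots for internal consistency.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI limits must be positive")
    return math.exp((math.log(ci_low) + math.log(ci_high)) / 2.0)


def compute_rrr(table: ContingencyTable) -> float:
    """Relative reporting ratio a/E0; 0 when a=0, +inf when E0=0 and a>0."""
    if table.a == 0:
        return 0.0
    e = table.expected
    if e == 0:
        return math.inf
    return table.a / e


def compute_safety_signal(table: ContingencyTable) -> float:
    """Signed shrunk log2 observed/expected: log2((a+0.5)/(E0+0.5))."""
    return math.log2((table.a + 0.5) / (table.expected + 0.5))


def compute_ic(
    table: ContingencyTable, method: str = "gamma"
) -> tuple[float, float, float]:
    """Information component and its 95% credible/confidence bounds.

    ``method="gamma"`` (default): IC = log2((a+0.5)/(E0+0.5)); bounds from the
    exact Gamma(a+0.5, 1) quantiles of the numerator.
    ``method="bate1998"``: closed-form posterior moments with uniform-marginal
    priors, interval = E[IC] ± 1.96·sd[IC].
    """
    if method not in IC_METHODS:
        raise ConfigurationError(
            f"unknown IC method {method!r}; supported: {', '.join(IC_METHODS)}"
        )
    a = table.a
    e = table.expected
    if method == "gamma":
        ic = math.log2((a + 0.5) / (e + 0.5))
        q_low, q_high = stats.gamma.ppf([0.025, 0.975], a + 0.5)
        return ic, math.log2(q_low / (e + 0.5)), math.log2(q_high / (e + 0.5))
    # bate1998: Beta/Dirichlet priors alpha1=beta1=1, alpha=beta=2, gamma11=1,
    # with the joint prior scaled so the prior IC expectation is zero.
    n = table.n
    n1 = table.drug_margin
    n2 = table.event_margin
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((n1 + a1) * (n2 + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + g) * (n1 + a1) * (n2 + b1))
    )
    v_ic = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - n1 + al - a1) / ((n1 + a1) * (1 + n + al))
        + (n - n2 + be - b1) / ((n2 + b1) * (1 + n + be))
    ) / math.log(2) ** 2
    sd = math.sqrt(v_ic)
    return e_ic, e_ic - Z95 * sd, e_ic + Z95 * sd


def apply_criteria(result: SignalResult) -> dict[str, bool]:
    """Evaluate the three rule sets with strict inequalities.

    aersmine: a ≥ 2 ∧ safety_signal > 0 ∧ rrr > 2;
    ror:      lower 95% CI limit of ROR > 1;
    bcpnn:    a ≥ 3 ∧ lower 95% IC limit > 0.
    """
    a = result.table.a
    return {
        "aersmine": a >= 2 and result.safety_signal > 0 and result.rrr > 2,
        "ror": result.ror_ci[0] > 1,
        "bcpnn": a >= 3 and result.ic_ci[0] > 0,
    }


def signal_from_table(
    table: ContingencyTable,
    drug: str = "",
    event: str = "",
    stratum: str = "all",
    ic_method: str = "gamma",
) -> SignalResult:
    """Compute every metric and rule flag for one 2×2 table."""
    ror = compute_ror(table)
    ic, ic_lo, ic_hi = compute_ic(table, method=ic_method)
    res = SignalResult(
        drug=drug,
        event=event,
        stratum=stratum,
        table=table,
        ror=ror.ror,
        ror_ci=(ror.ci_low, ror.ci_high),
        ror_p=ror.p,
        ror_corrected=ror.corrected,
        rrr=compute_rrr(table),
        safety_signal=compute_safety_signal(table),
        ic=ic,
        ic_ci=(ic_lo, ic_hi),
    )
    res.flags = apply_criteria(res)
    return res


def _presence_by_label(
    reports: Sequence[CaseReport], role: str | None
) -> dict[str, np.ndarray]:
    """Boolean presence vector per drug label, one pass over the reports."""
    rows: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(reports):
        for label in r.drug_labels(role):
            rows[label].append(i)
    n = len(reports)
    out = {}
    for label, idx in rows.items():
        v = np.zeros(n, dtype=bool)
        v[idx] = True
        out[label] = v
    return out


def screen_all(
    reports: Sequence[CaseReport],
    event: str,
    drugs: Iterable[str] | None = None,
    role: str | None = None,
    ic_method: str = "gamma",
    stratum: str = "all",
) -> list[SignalResult]:
    """Screen every drug against one event over the given background.

    ``drugs=None`` screens all observed drug labels. Results are sorted by ROR
    descending (ties by drug name); no multiple-testing adjustment is applied.
    A drug absent from the background yields an all-zero drug margin and is
    still reported (with the zero-cell correction flagged).
    """
    if len(reports) == 0:
        raise DataError("background is empty")
    presence = _presence_by_label(reports, role)
    if drugs is None:
        drug_list = sorted(presence)
    else:
        drug_list = list(drugs)
        if not drug_list:
            raise ConfigurationError("drug list must be non-empty")
    n = len(reports)
    event_vec = np.fromiter((event in r.events for r in reports), dtype=bool, count=n)
    n_event = int(event_vec.sum())
    results = []
    empty = np.zeros(n, dtype=bool)
    for drug in drug_list:
        vec = presence.get(drug, empty)
        a = int((vec & event_vec).sum())
        b = int(vec.sum()) - a
        c = n_event - a
        d = n - a - b - c
        table = ContingencyTable(a, b, c, d)
        results.append(
            signal_from_table(table, drug=drug, event=event, stratum=stratum,
                              ic_method=ic_method)
        )
    results.sort(key=lambda r: (-r.ror, r.drug))
    return results


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Forest-plot table: one row per screened drug."""
    rows = []
    for r in results:
        rows.append(
            {
                "drug": r.drug,
                "event": r.event,
                "stratum": r.stratum,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.ror,
                "ci_low": r.ror_ci[0],
                "ci_high": r.ror_ci[1],
                "p": r.ror_p,
                "ror_corrected": r.ror_corrected,
                "rrr": r.rrr,
                "safety_signal": r.safety_signal,
                "ic": r.ic,
                "ic_low": r.ic_ci[0],
                "ic_high": r.ic_ci[1],
                "flag_aersmine": r.flags["aersmine"],
                "flag_ror": r.flags["ror"],
                "flag_bcpnn": r.flags["bcpnn"],
            }
        )
    return pd.DataFrame(rows)
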