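"""Reading, assembling, deduplicating and filtering spontaneous reports.

The on-disk dialect is a simplified FAERS-like quarterly layout: one directory
per dataset, four "$"-delimited UTF-8 tables per year-quarter, first line a
header:

* ``DEMO<q>.txt`` — primaryid, caseid, caseversion, event_year, age, age_cod,
  sex, occp_cod
* ``DRUG<q>.txt`` — primaryid, drug_seq, role_cod (PS/SS/C/I), drugname,
  indication
* ``REAC<q>.txt`` — primaryid, pt
* ``OUTC<q>.txt`` — primaryid, outc_cod

``<q>`` is e.g. ``2015Q3``. Backslash is legal inside drugname (combination
products use the backslash-joined convention, e.g.
``ACETAMINOPHEN\\HYDROCODONE BITARTRATE``).

Processing follows the usual spontaneous-report cleaning order: join the four
tables into case reports, drop incomplete reports (no drug or no reaction),
collapse duplicate reports to the latest case version, standardize drug names
through a verbatim→generic mapping, then apply the cohort filter (minimum age,
required event term, required drug role/indication). Every exclusion is
tallied, never silent: kept + excluded always equals the input count.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError
from .reports import ROLES, CaseReport, DrugMention

# ---------------------------------------------------------------------------
# dialect constants
# ---------------------------------------------------------------------------

DELIMITER = "$"

TABLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "caseversion", "event_year", "age",
             "age_cod", "sex", "occp_cod"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "indication"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
}

SEX_TO_CODE = {"female": "F", "male": "M", "unspecified": ""}
CODE_TO_SEX = {v: k for k, v in SEX_TO_CODE.items()}

REPORTER_TO_CODE = {"healthcare_professional": "HP", "consumer": "CN",
                    "other": "OT", "unspecified": ""}
CODE_TO_REPORTER = {v: k for k, v in REPORTER_TO_CODE.items()}

ROLE_TO_CODE = {"primary_suspect": "PS", "secondary_suspect": "SS",
                "concomitant": "C", "interacting": "I"}
CODE_TO_ROLE = {v: k for k, v in ROLE_TO_CODE.items()}

# non_serious gets an explicit NS row; a report with no OUTC row is unspecified
OUTCOME_TO_CODE = {"death": "DE", "life_threatening": "LT",
                   "hospitalization": "HO", "disability": "DS",
                   "other_serious": "OT", "non_serious": "NS"}
CODE_TO_OUTCOME = {v: k for k, v in OUTCOME_TO_CODE.items()}

UNRESOLVED_PREFIX = "UNRESOLVED:"

_WS = re.compile(r"\s+")


def normalize_name(verbatim: str) -> str:
    """Uppercase and collapse internal/leading/trailing whitespace."""
    return _WS.sub(" ", verbatim.strip()).upper()


def primaryid(case_id: str, version: int) -> str:
    """FAERS-style primary key: case id suffixed with the version number."""
    return f"{case_id}{version:02d}"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RejectedRow:
    source: str
    reason: str
    content: str


@dataclass
class RawTables:
    """The four raw string tables with per-row source-file provenance."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rejects: list[RejectedRow] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


def _read_one(path: Path, columns: list[str],
              rejects: list[RejectedRow]) -> pd.DataFrame:
    # The dialect is unquoted, so the field count is exactly the "$" count +1;
    # validate it up front (pandas silently pads/truncates misfit rows).
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DataError(f"{path}: empty file (missing header)")
    header = lines[0].split(DELIMITER)
    if header != columns:
        raise DataError(f"{path}: expected header {columns}, got {header}")
    good: list[list[str]] = []
    for line in lines[1:]:
        if not line:
            continue
        fields = line.split(DELIMITER)
        if len(fields) != len(columns):
            rejects.append(RejectedRow(path.name, "column count", line))
        else:
            good.append(fields)
    df = pd.DataFrame(good, columns=columns, dtype=str)
    df["_source"] = path.name
    df["_row"] = range(len(df))
    return df


def read_quarterly_files(directory: str | Path) -> RawTables:
    """Read every quarter in ``directory`` into four concatenated tables.

    Rows with the wrong column count go to the reject list with a reason; a
    table type with no files at all is a hard error.
    """
    directory = Path(directory)
    rejects: list[RejectedRow] = []
    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in TABLE_COLUMNS}
    for name, columns in TABLE_COLUMNS.items():
        paths = sorted(directory.glob(f"{name}*.txt"))
        if not paths:
            raise DataError(f"missing mandatory table {name} in {directory}")
        for p in paths:
            frames[name].append(_read_one(p, columns, rejects))
    concat = {
        name: pd.concat(fs, ignore_index=True) for name, fs in frames.items()
    }
    return RawTables(demo=concat["DEMO"], drug=concat["DRUG"],
                     reac=concat["REAC"], outc=concat["OUTC"], rejects=rejects)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class AssemblyResult:
    reports: list[CaseReport]
    n_incomplete_no_drug: int = 0
    n_incomplete_no_event: int = 0
    n_collapsed_identical: int = 0  # bit-identical repeated DEMO rows
    rejects: list[RejectedRow] = field(default_factory=list)

    @property
    def n_incomplete(self) -> int:
        return self.n_incomplete_no_drug + self.n_incomplete_no_event


def _iter_rows(df):
    cols = list(df.columns)
    for tup in df.itertuples(index=False, name=None):
        yield dict(zip(cols, tup))


def _parse_age(raw: str) -> float | None:
    if raw == "":
        return None
    return float(raw)


def assemble_reports(tables: RawTables) -> AssemblyResult:
    """Join the four tables into :class:`CaseReport` records.

    Reports lacking any drug or any reaction are excluded and counted as
    incomplete. Bit-identical duplicate rows collapse silently (they carry no
    information); the same primaryid with *conflicting* demographics is
    rejected with a reason. Drug mentions are ordered by drug_seq; duplicate
    reaction terms collapse into the event set.
    """
    result = AssemblyResult(reports=[])

    drugs_by_pid: dict[str, list[tuple[int, DrugMention]]] = {}
    seen_drug_rows: set[tuple] = set()
    for row in _iter_rows(tables.drug):
        key = (row["primaryid"], row["drug_seq"], row["role_cod"],
               row["drugname"], row["indication"])
        if key in seen_drug_rows:
            continue
        seen_drug_rows.add(key)
        role = CODE_TO_ROLE.get(row["role_cod"])
        if role is None:
            result.rejects.append(RejectedRow(row["_source"],
                                              "unknown role code",
                                              DELIMITER.join(map(str, key))))
            continue
        try:
            seq = int(row["drug_seq"])
        except ValueError:
            result.rejects.append(RejectedRow(row["_source"], "bad drug_seq",
                                              DELIMITER.join(map(str, key))))
            continue
        mention = DrugMention(
            verbatim_name=row["drugname"],
            generic_name=None,
            role=role,
            indication=row["indication"] or None,
        )
        drugs_by_pid.setdefault(row["primaryid"], []).append((seq, mention))

    events_by_pid: dict[str, set[str]] = {}
    for row in _iter_rows(tables.reac):
        if row["pt"]:
            events_by_pid.setdefault(row["primaryid"], set()).add(row["pt"])

    outcome_by_pid: dict[str, str] = {}
    for row in _iter_rows(tables.outc):
        outcome = CODE_TO_OUTCOME.get(row["outc_cod"])
        if outcome is None:
            result.rejects.append(RejectedRow(
                row["_source"], "unknown outcome code",
                f"{row['primaryid']}${row['outc_cod']}"))
            continue
        outcome_by_pid.setdefault(row["primaryid"], outcome)

    demo_cols = ["primaryid", "caseid", "caseversion", "event_year", "age",
                 "age_cod", "sex", "occp_cod"]
    seen_demo: dict[str, tuple] = {}
    for row in _iter_rows(tables.demo):
        fields_ = tuple(row[c] for c in demo_cols)
        pid = row["primaryid"]
        if pid in seen_demo:
            if seen_demo[pid] != fields_:
                result.rejects.append(RejectedRow(
                    row["_source"], "conflicting demographics",
                    DELIMITER.join(map(str, fields_))))
            else:
                result.n_collapsed_identical += 1
            continue
        seen_demo[pid] = fields_
        try:
            version = int(row["caseversion"])
            year = int(row["event_year"])
            age = _parse_age(row["age"])
        except ValueError:
            result.rejects.append(RejectedRow(
                row["_source"], "bad numeric field",
                DELIMITER.join(map(str, fields_))))
            continue
        sex = CODE_TO_SEX.get(row["sex"])
        reporter = CODE_TO_REPORTER.get(row["occp_cod"])
        if sex is None or reporter is None:
            result.rejects.append(RejectedRow(row["_source"], "unknown code",
                                              DELIMITER.join(map(str, fields_))))
            continue
        mentions = drugs_by_pid.get(pid)
        if not mentions:
            result.n_incomplete_no_drug += 1
            continue
        events = events_by_pid.get(pid)
        if not events:
            result.n_incomplete_no_event += 1
            continue
        mentions = [m for _, m in sorted(mentions, key=lambda sm: sm[0])]
        result.reports.append(CaseReport(
            case_id=row["caseid"],
            version=version,
            receipt_year=year,
            age_years=age,
            sex=sex,
            reporter=reporter,
            outcome=outcome_by_pid.get(pid, "unspecified"),
            drugs=mentions,
            events=events,
        ))
    return result


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate(reports: Sequence[CaseReport]) -> list[CaseReport]:
    """Keep exactly one report per case id: the highest version.

    Ties break by latest receipt year, then by input (provenance) order with
    the earliest row winning — a documented total order, so the operation is
    deterministic, idempotent, and stable in the order of first appearance.
    """
    best: dict[str, tuple[int, int, CaseReport]] = {}
    order: list[str] = []
    for r in reports:
        key = (r.version, r.receipt_year)
        if r.case_id not in best:
            best[r.case_id] = (*key, r)
            order.append(r.case_id)
        elif key > best[r.case_id][:2]:  # strict: earlier row wins ties
            best[r.case_id] = (*key, r)
    return [best[cid][2] for cid in order]


# ---------------------------------------------------------------------------
# drug-name standardization
# ---------------------------------------------------------------------------


@dataclass
class StandardizationResult:
    reports: list[CaseReport]
    n_mentions: int = 0
    n_resolved: int = 0
    unresolved: Counter = field(default_factory=Counter)

    @property
    def coverage(self) -> float:
        return self.n_resolved / self.n_mentions if self.n_mentions else 1.0


def identity_mapping(names: Iterable[str]) -> dict[str, str]:
    """Mapping that sends each name's normalized form to itself (normalized)."""
    return {normalize_name(n): normalize_name(n) for n in names}


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited verbatim→generic mapping file."""
    mapping = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}: expected two tab-separated columns: {line!r}")
        mapping[normalize_name(parts[0])] = normalize_name(parts[1])
    return mapping


def standardize_drug_names(
    reports: Sequence[CaseReport], mapping: Mapping[str, str]
) -> StandardizationResult:
    """Resolve every verbatim drug name through the mapping.

    Lookup is exact on the case/whitespace-normalized verbatim (no fuzzy
    matching, for reproducibility). Unmapped verbatims get a flagged
    ``UNRESOLVED:`` generic marker and appear once each, with counts, in the
    coverage summary. Input reports are not mutated.
    """
    norm_map = {normalize_name(k): v for k, v in mapping.items()}
    result = StandardizationResult(reports=[])
    for r in reports:
        new = r.copy()
        mentions = []
        for m in new.drugs:
            norm = normalize_name(m.verbatim_name)
            generic = norm_map.get(norm)
            result.n_mentions += 1
            if generic is None:
                result.unresolved[norm] += 1
                generic = UNRESOLVED_PREFIX + norm
            else:
                result.n_resolved += 1
            mentions.append(DrugMention(m.verbatim_name, generic, m.role,
                                        m.indication))
        new.drugs = mentions
        result.reports.append(new)
    return result


# ---------------------------------------------------------------------------
# cohort filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortFilter:
    """The cohort definition: adult age, a required event term, and a
    required drug role/indication combination (both must hold on the same
    drug mention when both are set).

    Missing age cannot be verified against a minimum and is excluded by
    default when ``min_age_years`` is set; ``keep_missing_age=True`` keeps it.
    """

    min_age_years: float | None = 18.0
    required_role: str | None = None
    required_event: str | None = None
    required_indication: str | None = None
    keep_missing_age: bool = False

    def __post_init__(self) -> None:
        if self.min_age_years is not None and self.min_age_years < 0:
            raise ConfigurationError("min_age_years must be >= 0")
        if self.required_role is not None and self.required_role not in ROLES:
            raise ConfigurationError(
                f"required_role must be one of {ROLES}, got {self.required_role!r}")


@dataclass
class FilterResult:
    kept: list[CaseReport]
    tally: dict[str, int]

    @property
    def n_excluded(self) -> int:
        return sum(self.tally.values())


def apply_cohort_filter(
    reports: Sequence[CaseReport], cohort: CohortFilter
) -> FilterResult:
    """Apply the cohort filter, tallying the first failing criterion per
    excluded report (age, then event, then drug role/indication), so that
    kept + Σtally == input count."""
    tally = {"age": 0, "event": 0, "drug": 0}
    kept: list[CaseReport] = []
    want_ind = (normalize_name(cohort.required_indication)
                if cohort.required_indication else None)
    for r in reports:
        if cohort.min_age_years is not None:
            if r.age_years is None:
                if not cohort.keep_missing_age:
                    tally["age"] += 1
                    continue
            elif r.age_years < cohort.min_age_years:
                tally["age"] += 1
                continue
        if cohort.required_event is not None and cohort.required_event not in r.events:
            tally["event"] += 1
            continue
        if cohort.required_role is not None or want_ind is not None:
            def matches(m: DrugMention) -> bool:
                if cohort.required_role is not None and m.role != cohort.required_role:
                    return False
                if want_ind is not None:
                    if m.indication is None:
                        return False
                    if normalize_name(m.indication) != want_ind:
                        return False
                return True

            if not any(matches(m) for m in r.drugs):
                tally["drug"] += 1
                continue
        kept.append(r)
    return FilterResult(kept=kept, tally=tally)
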