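"""Synthetic FAERS-like spontaneous-report generator.

Real spontaneous-report databases cannot be redistributed, so every stage of
this pipeline is exercised on generated data whose structure and marginals
emulate them: configurable sex / age-band / reporter / outcome / year
marginals, a drug vocabulary sampled without replacement per report, and a
per-term independent Bernoulli event model in which a planted drug–event
association multiplies the event's baseline odds by a chosen factor when the
drug is present (optionally only within one demographic stratum).

Because the event model is odds-multiplicative and per-term independent, the
expected 2×2 contingency table of any unrestricted drug–event pair has a
closed form (:func:`expected_contingency`), which serves as the analytic
cross-check for the whole screening stack.

The generator also creates the data problems ingest must solve: a configurable
fraction of near-duplicate reports (half version-incremented, half
bit-identical) and quarterly-file output in the ingest dialect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .ingest import (
    OUTCOME_TO_CODE,
    REPORTER_TO_CODE,
    ROLE_TO_CODE,
    SEX_TO_CODE,
    TABLE_COLUMNS,
    DELIMITER,
    primaryid,
)
from .reports import (
    AGE_BAND_LABELS,
    NOT_SPECIFIED_BAND,
    OUTCOMES,
    REPORTERS,
    SEXES,
    CaseReport,
    DrugMention,
)
from .subgroups import StratumSpec

#: Uniform sampling range (years) for an age drawn within each band; chosen
#: strictly inside the band's classification interval so a value rounded to
#: two decimals still classifies into the band it was drawn from.
AGE_DRAW_RANGES = {
    "0-1 Month": (0.0, 0.08),
    "2 Months-2 Years": (0.17, 2.99),
    "3-11 Years": (3.0, 11.99),
    "12-17 Years": (12.0, 17.99),
    "18-64 Years": (18.0, 64.99),
    "65-85 Years": (65.0, 85.99),
    "More than 85 Years": (86.0, 100.99),
}


@dataclass(frozen=True)
class PlantedSignal:
    """A controlled drug–event association.

    ``effect`` multiplies the event's baseline odds when the drug is present
    on a report (1 = no association). ``restrict_to`` limits the effect to
    reports inside one sex × age stratum.
    """

    drug: str
    event: str
    effect: float
    restrict_to: StratumSpec | None = None

    def __post_init__(self) -> None:
        if not self.effect > 0:
            raise ConfigurationError(
                f"planted_signals: effect must be > 0, got {self.effect}")


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic dataset.

    Probability maps must each sum to 1 (within 1e-9). Drug vocabulary entries
    are (generic name, sampling weight); each report draws its drug count
    uniformly from ``drugs_per_report`` and then that many distinct drugs by
    weighted sampling without replacement. Event vocabulary entries are
    (preferred term, baseline probability); a baseline probability of 1 marks
    a term present on every report, which guarantees reports are complete.
    """

    n_reports: int
    drug_vocabulary: list[tuple[str, float]]
    event_vocabulary: list[tuple[str, float]]
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    sex_proportions: dict[str, float] = field(default_factory=dict)
    age_band_proportions: dict[str, float] = field(default_factory=dict)
    reporter_proportions: dict[str, float] = field(default_factory=dict)
    year_range: tuple[int, int] = (2004, 2023)
    year_weights: dict[int, float] = field(default_factory=dict)
    outcome_proportions: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    drugs_per_report: tuple[int, int] = (1, 3)
    indication_term: str | None = "POSTOPERATIVE ANALGESIA"
    indication_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be a positive integer")
        if not self.drug_vocabulary:
            raise ConfigurationError("drug_vocabulary must be non-empty")
        if not self.event_vocabulary:
            raise ConfigurationError("event_vocabulary must be non-empty")
        for name, w in self.drug_vocabulary:
            if w < 0:
                raise ConfigurationError(
                    f"drug_vocabulary: weight for {name!r} must be non-negative")
        for name, p in self.event_vocabulary:
            if not 0 <= p <= 1:
                raise ConfigurationError(
                    f"event_vocabulary: baseline probability for {name!r} "
                    "must be in [0,1]")
        drug_names = {d for d, _ in self.drug_vocabulary}
        event_names = {e for e, _ in self.event_vocabulary}
        for s in self.planted_signals:
            if s.drug not in drug_names:
                raise ConfigurationError(
                    f"planted_signals: drug {s.drug!r} not in drug_vocabulary")
            if s.event not in event_names:
                raise ConfigurationError(
                    f"planted_signals: event {s.event!r} not in event_vocabulary")
        _check_probability_map("sex_proportions", self.sex_proportions, SEXES)
        _check_probability_map("age_band_proportions", self.age_band_proportions,
                               AGE_BAND_LABELS)
        _check_probability_map("reporter_proportions", self.reporter_proportions,
                               REPORTERS)
        _check_probability_map("outcome_proportions", self.outcome_proportions,
                               OUTCOMES)
        lo, hi = self.year_range
        if lo > hi:
            raise ConfigurationError("year_range: low must be <= high")
        years = tuple(range(lo, hi + 1))
        _check_probability_map("year_weights",
                               {str(y): w for y, w in self.year_weights.items()},
                               tuple(map(str, years)))
        if not 0 <= self.duplicate_rate <= 1:
            raise ConfigurationError("duplicate_rate must be in [0, 1]")
        klo, khi = self.drugs_per_report
        if not 1 <= klo <= khi:
            raise ConfigurationError(
                "drugs_per_report: need 1 <= low <= high")
        if khi > len(self.drug_vocabulary):
            raise ConfigurationError(
                "drugs_per_report: high exceeds drug_vocabulary size")
        if not 0 <= self.indication_rate <= 1:
            raise ConfigurationError("indication_rate must be in [0, 1]")


def _check_probability_map(field_name: str, mapping: Mapping[str, float],
                           allowed: tuple[str, ...]) -> None:
    if not mapping:
        raise ConfigurationError(f"{field_name} must be non-empty")
    for key, p in mapping.items():
        if key not in allowed:
            raise ConfigurationError(
                f"{field_name}: unknown category {key!r} (allowed: {allowed})")
        if p < 0:
            raise ConfigurationError(
                f"{field_name}: probability for {key!r} must be non-negative")
    total = sum(mapping.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"{field_name}: probabilities sum to {total!r}, expected 1")


def default_config(n_reports: int = 10_000, seed: int = 0,
                   duplicate_rate: float = 0.05) -> GeneratorConfig:
    """Study-condition defaults.

    Demographic marginals follow the published baseline table of a large
    dizziness reporting cohort (sex 61.92/31.27/6.81, the eight age bands in
    their observed proportions, reporter mix dominated by consumers); the
    yearly weights rise to a 2015 peak and then plateau; the outcome mix is
    dominated by non-serious reports. The drug vocabulary covers common
    postoperative-analgesia agents with planted dizziness associations on the
    drugs reported as strong signals (amitriptyline, clonazepam, ketamine).
    One guaranteed event term (baseline 1.0) makes every report complete.
    """
    age_counts = {
        "0-1 Month": 98, "2 Months-2 Years": 279, "3-11 Years": 2545,
        "12-17 Years": 6286, "18-64 Years": 213999, "65-85 Years": 118117,
        "More than 85 Years": 10276, "Not Specified": 147276,
    }
    age_total = sum(age_counts.values())
    reporter_counts = {"healthcare_professional": 177851, "consumer": 292090,
                       "other": 2, "unspecified": 28933}
    rep_total = sum(reporter_counts.values())
    years = range(2004, 2024)
    raw_w = {y: (y - 2003.0 if y <= 2015 else 9.0) for y in years}
    wsum = sum(raw_w.values())
    return GeneratorConfig(
        n_reports=n_reports,
        drug_vocabulary=[
            ("BUPIVACAINE", 0.12), ("MORPHINE", 0.10), ("LIDOCAINE", 0.10),
            ("ACETAMINOPHEN\\HYDROCODONE BITARTRATE", 0.08),
            ("GABAPENTIN", 0.08), ("HYDROCODONE", 0.06), ("KETAMINE", 0.05),
            ("ROPIVACAINE", 0.05), ("MIDAZOLAM", 0.05), ("PROPOFOL", 0.05),
            ("ADALIMUMAB", 0.05), ("REMIFENTANIL", 0.04), ("ONDANSETRON", 0.04),
            ("TRAMADOL", 0.04), ("PARACETAMOL", 0.04), ("CLONAZEPAM", 0.03),
            ("AMITRIPTYLINE", 0.02),
        ],
        event_vocabulary=[
            ("PAIN", 1.0), ("DIZZINESS", 0.01), ("NAUSEA", 0.08),
            ("HEADACHE", 0.06), ("VOMITING", 0.05), ("PRURITUS", 0.03),
            ("SOMNOLENCE", 0.03),
        ],
        planted_signals=[
            PlantedSignal("AMITRIPTYLINE", "DIZZINESS", 8.0),
            PlantedSignal("CLONAZEPAM", "DIZZINESS", 6.0),
            PlantedSignal("KETAMINE", "DIZZINESS", 4.0),
        ],
        sex_proportions={"female": 0.6192, "male": 0.3127,
                         "unspecified": 0.0681},
        age_band_proportions={k: v / age_total for k, v in age_counts.items()},
        reporter_proportions={k: v / rep_total
                              for k, v in reporter_counts.items()},
        year_range=(2004, 2023),
        year_weights={y: w / wsum for y, w in raw_w.items()},
        outcome_proportions={
            "non_serious": 0.50, "hospitalization": 0.18, "other_serious": 0.12,
            "death": 0.04, "life_threatening": 0.03, "disability": 0.03,
            "unspecified": 0.10,
        },
        duplicate_rate=duplicate_rate,
        drugs_per_report=(1, 3),
        indication_term="POSTOPERATIVE ANALGESIA",
        indication_rate=0.2,
        seed=seed,
    )


def _draw_categorical(rng: np.random.Generator, mapping: Mapping, n: int):
    cats = list(mapping.keys())
    probs = np.asarray(list(mapping.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return cats, idx


def generate_reports(config: GeneratorConfig) -> list[CaseReport]:
    """Draw exactly ``n_reports`` reports (duplicates are injected separately).

    Demographics are drawn independently per report from the configured
    marginals; ages are uniform within the drawn band (rounded to 2 decimals,
    missing in the ``Not Specified`` band). Each report carries k distinct
    drugs (k uniform in ``drugs_per_report``) drawn by weighted sampling
    without replacement, with one primary suspect chosen uniformly among them
    (remaining mentions are secondary suspect or concomitant at random); the
    primary suspect carries the indication marker with ``indication_rate``.
    Each event term is included with probability
    odds·θ/(1+odds·θ) where odds = p/(1−p) of the baseline probability and θ
    is the product of the applicable planted effects. Deterministic given the
    config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    sex_cats, sex_idx = _draw_categorical(rng, config.sex_proportions, n)
    band_cats, band_idx = _draw_categorical(rng, config.age_band_proportions, n)
    rep_cats, rep_idx = _draw_categorical(rng, config.reporter_proportions, n)
    out_cats, out_idx = _draw_categorical(rng, config.outcome_proportions, n)
    year_cats, year_idx = _draw_categorical(rng, config.year_weights, n)

    ages = np.full(n, np.nan)
    for bi, band in enumerate(band_cats):
        if band == NOT_SPECIFIED_BAND:
            continue
        lo, hi = AGE_DRAW_RANGES[band]
        mask = band_idx == bi
        ages[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), 2)

    names = [d for d, _ in config.drug_vocabulary]
    weights = np.asarray([w for _, w in config.drug_vocabulary], dtype=float)
    weights = weights / weights.sum()
    V = len(names)
    klo, khi = config.drugs_per_report
    k = rng.integers(klo, khi + 1, size=n)
    # Gumbel top-k == successive weighted sampling without replacement
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw[None, :] + rng.gumbel(size=(n, V))
    order = np.argsort(-keys, axis=1, kind="stable")
    sel_mask = np.arange(V)[None, :] < k[:, None]
    presence = np.zeros((n, V), dtype=bool)
    presence[np.arange(n)[:, None], order] = sel_mask

    ps_pos = rng.integers(0, k)  # position of the primary suspect in the draw
    other_role = rng.integers(0, 2, size=(n, V))  # 0=secondary_suspect 1=concomitant
    ind_draw = rng.random(n)

    sex_arr = np.asarray([sex_cats[i] for i in sex_idx], dtype=object)
    event_names = [e for e, _ in config.event_vocabulary]
    name_index = {d: i for i, d in enumerate(names)}
    include = np.zeros((len(event_names), n), dtype=bool)
    for j, (pt, p) in enumerate(config.event_vocabulary):
        if p >= 1.0:
            include[j, :] = True
            continue
        if p == 0.0:
            continue
        odds = p / (1.0 - p)
        theta = np.ones(n)
        for s in config.planted_signals:
            if s.event != pt:
                continue
            applies = presence[:, name_index[s.drug]].copy()
            if s.restrict_to is not None:
                in_stratum = np.fromiter(
                    (s.restrict_to.contains(sx, None if np.isnan(a) else float(a))
                     for sx, a in zip(sex_arr, ages)),
                    dtype=bool, count=n)
                applies &= in_stratum
            theta[applies] *= s.effect
        pe = odds * theta / (1.0 + odds * theta)
        include[j, :] = rng.random(n) < pe

    reports: list[CaseReport] = []
    for i in range(n):
        ki = int(k[i])
        sel = order[i, :ki]
        mentions = []
        for pos, j in enumerate(sel):
            if pos == ps_pos[i]:
                role = "primary_suspect"
                indication = (config.indication_term
                              if config.indication_term is not None
                              and ind_draw[i] < config.indication_rate else None)
            else:
                role = "secondary_suspect" if other_role[i, j] == 0 else "concomitant"
                indication = None
            mentions.append(DrugMention(
                verbatim_name=names[j], generic_name=names[j], role=role,
                indication=indication))
        events = {event_names[j] for j in range(len(event_names))
                  if include[j, i]}
        age = None if np.isnan(ages[i]) else float(ages[i])
        reports.append(CaseReport(
            case_id=str(100_000_000 + i),
            version=0,
            receipt_year=int(year_cats[year_idx[i]]),
            age_years=age,
            sex=sex_cats[sex_idx[i]],
            reporter=rep_cats[rep_idx[i]],
            outcome=out_cats[out_idx[i]],
            drugs=mentions,
            events=events,
        ))
    return reports


def inject_duplicates(reports: Sequence[CaseReport], duplicate_rate: float,
                      seed: int) -> list[CaseReport]:
    """Append round(rate·n) near-duplicate reports.

    Half of the duplicates (at random) increment the case version, the other
    half are bit-identical copies — both flavors occur in real spontaneous
    databases and exercise both deduplication branches. The original list
    order is preserved; deterministic given the seed.
    """
    if not 0 <= duplicate_rate <= 1:
        raise ConfigurationError("duplicate_rate must be in [0, 1]")
    n = len(reports)
    m = round(duplicate_rate * n)
    out = list(reports)
    if m == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    bump = rng.random(m) < 0.5
    for i, b in zip(idx, bump):
        dup = reports[int(i)].copy()
        if b:
            dup.version += 1
        out.append(dup)
    return out


def _quarter(case_id: str) -> int:
    return zlib.crc32(case_id.encode()) % 4 + 1


def write_quarterly_files(reports: Sequence[CaseReport],
                          directory: str | Path,
                          year_range: tuple[int, int] | None = None,
                          ) -> dict[str, int]:
    """Write the four-table dialect partitioned by year-quarter.

    The quarter of a report is a stable hash of its case id. When
    ``year_range`` is given, header-only files are emitted for every quarter
    in that range even without data. Returns {filename: data-row count}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    quarters: set[tuple[int, int]] = set()
    if year_range is not None:
        quarters |= {(y, q) for y in range(year_range[0], year_range[1] + 1)
                     for q in (1, 2, 3, 4)}
    by_quarter: dict[tuple[int, int], list[CaseReport]] = {}
    for r in reports:
        key = (r.receipt_year, _quarter(r.case_id))
        by_quarter.setdefault(key, []).append(r)
        quarters.add(key)

    manifest: dict[str, int] = {}
    for year, q in sorted(quarters):
        tag = f"{year}Q{q}"
        rows: dict[str, list[str]] = {t: [] for t in TABLE_COLUMNS}
        for r in by_quarter.get((year, q), ()):
            pid = primaryid(r.case_id, r.version)
            age = "" if r.age_years is None else f"{r.age_years:.2f}"
            age_cod = "YR" if r.age_years is not None else ""
            rows["DEMO"].append(DELIMITER.join([
                pid, r.case_id, str(r.version), str(r.receipt_year), age,
                age_cod, SEX_TO_CODE[r.sex], REPORTER_TO_CODE[r.reporter]]))
            for seq, m in enumerate(r.drugs, start=1):
                rows["DRUG"].append(DELIMITER.join([
                    pid, str(seq), ROLE_TO_CODE[m.role], m.verbatim_name,
                    m.indication or ""]))
            for pt in sorted(r.events):
                rows["REAC"].append(DELIMITER.join([pid, pt]))
            if r.outcome != "unspecified":
                rows["OUTC"].append(DELIMITER.join(
                    [pid, OUTCOME_TO_CODE[r.outcome]]))
        for name, columns in TABLE_COLUMNS.items():
            path = directory / f"{name}{tag}.txt"
            body = DELIMITER.join(columns) + "\n"
            if rows[name]:
                body += "\n".join(rows[name]) + "\n"
            try:
                path.write_text(body, encoding="utf-8")
            except OSError as exc:  # pragma: no cover - depends on filesystem
                raise OSError(f"failed writing {path}: {exc}") from exc
            manifest[path.name] = len(rows[name])
    return manifest


# ---------------------------------------------------------------------------
# closed-form expectation oracle
# ---------------------------------------------------------------------------


def _draw_set_probabilities(weights: np.ndarray, kmax: int
                            ) -> list[dict[frozenset, float]]:
    """P(first s draws form exactly set S) for successive weighted sampling
    without replacement, for every S up to size kmax. Exact recursion:
    f(S) = Σ_{j∈S} f(S∖{j}) · w_j / (1 − W_{S∖{j}})."""
    levels: list[dict[frozenset, float]] = [{frozenset(): 1.0}]
    for _ in range(kmax):
        nxt: dict[frozenset, float] = {}
        for prev, p_prev in levels[-1].items():
            rem = 1.0 - sum(weights[j] for j in prev)
            for j in range(len(weights)):
                if j in prev:
                    continue
                s = prev | {j}
                nxt[s] = nxt.get(frozenset(s), 0.0) + p_prev * weights[j] / rem
        levels.append({frozenset(s): p for s, p in nxt.items()})
    return levels


def expected_contingency(config: GeneratorConfig, drug: str, event: str
                         ) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) for one drug–event pair.

    Exact under the generative model: enumerates every possible drug set with
    its sampling probability and applies the odds-multiplicative event model.
    Only supports planted signals without a stratum restriction on the target
    event (a restricted effect's expectation depends on the demographic mix).
    Independent of the sampling path — used as the analytic cross-check.
    """
    config.validate()
    relevant = [s for s in config.planted_signals if s.event == event]
    if any(s.restrict_to is not None for s in relevant):
        raise NotImplementedError(
            "expected_contingency does not support stratum-restricted signals")
    names = [d for d, _ in config.drug_vocabulary]
    if drug not in names:
        raise ConfigurationError(f"drug {drug!r} not in drug_vocabulary")
    baseline = dict(config.event_vocabulary)
    if event not in baseline:
        raise ConfigurationError(f"event {event!r} not in event_vocabulary")
    p0 = baseline[event]
    weights = np.asarray([w for _, w in config.drug_vocabulary], dtype=float)
    weights = weights / weights.sum()
    name_index = {d: i for i, d in enumerate(names)}
    klo, khi = config.drugs_per_report
    levels = _draw_set_probabilities(weights, khi)
    pk = 1.0 / (khi - klo + 1)
    di = name_index[drug]
    a = b = c = d = 0.0
    for kk in range(klo, khi + 1):
        for s, p_set in levels[kk].items():
            if p0 >= 1.0:
                pe = 1.0
            elif p0 == 0.0:
                pe = 0.0
            else:
                odds = p0 / (1.0 - p0)
                theta = 1.0
                for sig in relevant:
                    if name_index[sig.drug] in s:
                        theta *= sig.effect
                pe = odds * theta / (1.0 + odds * theta)
            w = pk * p_set
            if di in s:
                a += w * pe
                b += w * (1.0 - pe)
            else:
                c += w * pe
                d += w * (1.0 - pe)
    n = config.n_reports
    return a * n, b * n, c * n, d * n
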