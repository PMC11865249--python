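"""Shared fixtures: a report factory and generator configurations whose
expected behaviour has a closed analytic form."""

from __future__ import annotations

import pytest

from faersig.reports import CaseReport, DrugMention
from faersig.subgroups import StratumSpec
from faersig.synthetic import GeneratorConfig, PlantedSignal

# A guaranteed event term keeps every generated report complete.
ALWAYS_EVENT = "PAIN"
TARGET_EVENT = "DIZZINESS"


def make_report(
    case_id: str = "c1",
    version: int = 0,
    year: int = 2015,
    age: float | None = 40.0,
    sex: str = "female",
    reporter: str = "consumer",
    outcome: str = "non_serious",
    drugs: tuple[str, ...] = ("DRUGA",),
    events: tuple[str, ...] = (TARGET_EVENT,),
    role: str = "primary_suspect",
    indication: str | None = None,
) -> CaseReport:
    mentions = [
        DrugMention(d, d, role if i == 0 else "concomitant",
                    indication if i == 0 else None)
        for i, d in enumerate(drugs)
    ]
    return CaseReport(case_id=case_id, version=version, receipt_year=year,
                      age_years=age, sex=sex, reporter=reporter,
                      outcome=outcome, drugs=mentions, events=set(events))


@pytest.fixture
def report_factory():
    return make_report


def _base_marginals() -> dict:
    return dict(
        sex_proportions={"female": 0.45, "male": 0.45, "unspecified": 0.10},
        age_band_proportions={"18-64 Years": 0.60, "65-85 Years": 0.30,
                              "Not Specified": 0.10},
        reporter_proportions={"consumer": 0.7, "healthcare_professional": 0.3},
        year_range=(2010, 2012),
        year_weights={2010: 0.3, 2011: 0.4, 2012: 0.3},
        outcome_proportions={"non_serious": 0.8, "hospitalization": 0.2},
    )


def oracle_config(n: int = 50_000, seed: int = 0, effect: float = 10.0,
                  drug_weight: float = 0.005, baseline: float = 0.01,
                  planted: bool = True) -> GeneratorConfig:
    """One planted drug (DRUGX) against nine fillers; small sampling weight
    and baseline so the relative reporting ratio tracks the planted odds
    factor closely. Expected tables come from expected_contingency."""
    fill = (1.0 - drug_weight) / 9.0
    signals = [PlantedSignal("DRUGX", TARGET_EVENT, effect)] if planted else []
    return GeneratorConfig(
        n_reports=n,
        drug_vocabulary=[("DRUGX", drug_weight)]
        + [(f"FILLER{i}", fill) for i in range(9)],
        event_vocabulary=[(ALWAYS_EVENT, 1.0), (TARGET_EVENT, baseline)],
        planted_signals=signals,
        drugs_per_report=(1, 2),
        duplicate_rate=0.0,
        indication_rate=0.0,
        seed=seed,
        **_base_marginals(),
    )


#: (drug, sampling weight, event, planted odds factor) for the recovery runs.
#: Each signal gets its own event term: signals sharing one event would
#: inflate that event's margin and bias every other signal's relative
#: reporting ratio downward. Weights shrink as the effect grows so the
#: expected ratio stays close to the planted factor (logistic saturation and
#: background contamination both scale with drug prevalence × effect).
RECOVERY_SIGNALS = [
    ("DRUG_E2", 0.04, "EVENT_E2", 2.0),
    ("DRUG_E5", 0.02, "EVENT_E5", 5.0),
    ("DRUG_E10", 0.0075, "EVENT_E10", 10.0),
]


def recovery_config(seed: int, n: int = 50_000) -> GeneratorConfig:
    """Three planted effects (2, 5, 10), one per event, at n = 50,000."""
    used = sum(w for _, w, _, _ in RECOVERY_SIGNALS)
    fill = (1.0 - used) / 7.0
    return GeneratorConfig(
        n_reports=n,
        drug_vocabulary=[(d, w) for d, w, _, _ in RECOVERY_SIGNALS]
        + [(f"FILLER{i}", fill) for i in range(7)],
        event_vocabulary=[(ALWAYS_EVENT, 1.0)]
        + [(e, 0.01) for _, _, e, _ in RECOVERY_SIGNALS],
        planted_signals=[PlantedSignal(d, e, eff)
                         for d, _, e, eff in RECOVERY_SIGNALS],
        drugs_per_report=(1, 3),
        duplicate_rate=0.0,
        indication_rate=0.0,
        seed=seed,
        **_base_marginals(),
    )


def null_config(seed: int, n: int = 20_000, n_drugs: int = 40,
                n_events: int = 25) -> GeneratorConfig:
    """No planted associations; 40 drugs × 25 events gives 1,000 pairs with
    every margin comfortably above 20 at n = 20,000."""
    return GeneratorConfig(
        n_reports=n,
        drug_vocabulary=[(f"NULLDRUG{i:02d}", 1.0 / n_drugs)
                         for i in range(n_drugs)],
        event_vocabulary=[(ALWAYS_EVENT, 1.0)]
        + [(f"EVENT{i:02d}", 0.01) for i in range(n_events)],
        planted_signals=[],
        drugs_per_report=(1, 3),
        duplicate_rate=0.0,
        indication_rate=0.0,
        seed=seed,
        **_base_marginals(),
    )


def stratum_config(seed: int, n: int = 50_000) -> GeneratorConfig:
    """One strong association planted only in the adult-male stratum.

    The event baseline (0.03) and drug weight (0.05) are set so each null
    stratum expects ~15 co-reports: large enough that its relative reporting
    ratio concentrates near 1 and a signal-level value (>2) there would be a
    >3.5-sigma fluctuation, while the planted stratum sits well above 2.
    """
    adult_male = StratumSpec("adult male", "male", 25.0, 65.0)
    fill = (1.0 - 0.05) / 9.0
    return GeneratorConfig(
        n_reports=n,
        drug_vocabulary=[("STRATDRUG", 0.05)]
        + [(f"FILLER{i}", fill) for i in range(9)],
        event_vocabulary=[(ALWAYS_EVENT, 1.0), (TARGET_EVENT, 0.03)],
        planted_signals=[PlantedSignal("STRATDRUG", TARGET_EVENT, 8.0,
                                       restrict_to=adult_male)],
        drugs_per_report=(1, 2),
        duplicate_rate=0.0,
        indication_rate=0.0,
        seed=seed,
        **_base_marginals(),
    )
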