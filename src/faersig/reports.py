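"""Core report containers for spontaneous adverse-event data.

A :class:`CaseReport` is one deduplicated spontaneous report: who reported it
(demographics, reporter type), when (receipt year), which drugs were involved
and in which role, which adverse-event preferred terms were reported, and the
worst outcome. Categorical vocabularies mirror the FAERS enumerations at the
granularity this pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SEXES = ("female", "male", "unspecified")
REPORTERS = ("healthcare_professional", "consumer", "other", "unspecified")
ROLES = ("primary_suspect", "secondary_suspect", "concomitant", "interacting")
OUTCOMES = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "other_serious",
    "non_serious",
    "unspecified",
)

#: Age bands used for baseline summaries. Each entry is
#: (label, classification low, classification high) in years, half-open
#: [low, high); the last band is open-ended. Missing age maps to the
#: "Not Specified" band.
AGE_BANDS: tuple[tuple[str, float, float | None], ...] = (
    ("0-1 Month", 0.0, 1.0 / 12.0),
    ("2 Months-2 Years", 1.0 / 12.0, 3.0),
    ("3-11 Years", 3.0, 12.0),
    ("12-17 Years", 12.0, 18.0),
    ("18-64 Years", 18.0, 65.0),
    ("65-85 Years", 65.0, 86.0),
    ("More than 85 Years", 86.0, None),
)

AGE_BAND_LABELS = tuple(label for label, _, _ in AGE_BANDS) + ("Not Specified",)

NOT_SPECIFIED_BAND = "Not Specified"


def band_from_age(age_years: float | None) -> str:
    """Map an age in years to its summary band; ``None`` → ``Not Specified``."""
    if age_years is None:
        return NOT_SPECIFIED_BAND
    if age_years < 0:
        raise ValueError(f"age_years must be non-negative, got {age_years}")
    for label, low, high in AGE_BANDS:
        if high is None or age_years < high:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class DrugMention:
    """One drug named on a report.

    ``generic_name`` is ``None`` until name standardization has run; an
    unmapped verbatim keeps an ``UNRESOLVED:`` marker afterwards. ``indication``
    optionally carries a free-text context marker (e.g. the
    postoperative-analgesia indication).
    """

    verbatim_name: str
    generic_name: str | None = None
    role: str = "primary_suspect"
    indication: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class CaseReport:
    """One spontaneous report version.

    ``events`` is a set of preferred terms; ``age_band`` is derived from
    ``age_years`` and is ``Not Specified`` exactly when age is missing.
    """

    case_id: str
    version: int = 0
    receipt_year: int = 0
    age_years: float | None = None
    sex: str = "unspecified"
    reporter: str = "unspecified"
    outcome: str = "unspecified"
    drugs: list[DrugMention] = field(default_factory=list)
    events: set[str] = field(default_factory=set)

    @property
    def age_band(self) -> str:
        return band_from_age(self.age_years)

    def drug_labels(self, role: str | None = None) -> set[str]:
        """Distinct drug labels on this report (generic name when resolved,
        normalized verbatim otherwise), optionally restricted to one role."""
        out = set()
        for m in self.drugs:
            if role is not None and m.role != role:
                continue
            out.add(m.generic_name if m.generic_name is not None else m.verbatim_name)
        return out

    def copy(self) -> "CaseReport":
        """Deep-enough copy: fresh drug list and event set."""
        return replace(self, drugs=list(self.drugs), events=set(self.events))
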