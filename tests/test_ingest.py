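"""Reading, assembly, deduplication, name standardization and cohort
filtering."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.errors import DataError
from faersig.ingest import (
    UNRESOLVED_PREFIX,
    CohortFilter,
    RawTables,
    apply_cohort_filter,
    assemble_reports,
    deduplicate,
    identity_mapping,
    normalize_name,
    read_quarterly_files,
    standardize_drug_names,
)
from faersig.synthetic import generate_reports, inject_duplicates, write_quarterly_files

from conftest import TARGET_EVENT, make_report, oracle_config


def _write(tmp_path, name, lines):
    (tmp_path / name).write_text("\n".join(lines) + "\n", encoding="utf-8")


HEADERS = {
    "DEMO": "primaryid$caseid$caseversion$event_year$age$age_cod$sex$occp_cod",
    "DRUG": "primaryid$drug_seq$role_cod$drugname$indication",
    "REAC": "primaryid$pt",
    "OUTC": "primaryid$outc_cod",
}


def _write_quarter(tmp_path, tag="2015Q1", demo=(), drug=(), reac=(), outc=()):
    _write(tmp_path, f"DEMO{tag}.txt", [HEADERS["DEMO"], *demo])
    _write(tmp_path, f"DRUG{tag}.txt", [HEADERS["DRUG"], *drug])
    _write(tmp_path, f"REAC{tag}.txt", [HEADERS["REAC"], *reac])
    _write(tmp_path, f"OUTC{tag}.txt", [HEADERS["OUTC"], *outc])


def test_header_only_files_give_empty_tables_and_no_rejects(tmp_path):
    _write_quarter(tmp_path)
    tables = read_quarterly_files(tmp_path)
    for name in ("demo", "drug", "reac", "outc"):
        assert len(tables.table(name)) == 0
    assert tables.rejects == []


def test_missing_mandatory_table_is_a_hard_error(tmp_path):
    _write_quarter(tmp_path)
    (tmp_path / "REAC2015Q1.txt").unlink()
    with pytest.raises(DataError, match="REAC"):
        read_quarterly_files(tmp_path)


@pytest.mark.parametrize("bad_row", [
    "c100$c1$0$2015$40.00$YR$F",          # too few fields
    "c100$c1$0$2015$40.00$YR$F$CN$extra",  # too many fields
])
def test_wrong_column_count_goes_to_reject_list(tmp_path, bad_row):
    _write_quarter(tmp_path, demo=[bad_row])
    tables = read_quarterly_files(tmp_path)
    assert len(tables.rejects) == 1
    assert tables.rejects[0].reason == "column count"
    assert len(tables.demo) == 0


def test_complete_single_case_assembles_fully(tmp_path):
    _write_quarter(
        tmp_path,
        demo=["c100$c1$0$2015$40.00$YR$F$CN"],
        drug=["c100$1$PS$MORPHINE$POSTOPERATIVE ANALGESIA"],
        reac=[f"c100${TARGET_EVENT}", "c100$NAUSEA"],
        outc=["c100$HO"],
    )
    result = assemble_reports(read_quarterly_files(tmp_path))
    assert len(result.reports) == 1
    r = result.reports[0]
    assert (r.case_id, r.version, r.receipt_year) == ("c1", 0, 2015)
    assert r.age_years == 40.0 and r.sex == "female" and r.reporter == "consumer"
    assert r.outcome == "hospitalization"
    assert r.events == {TARGET_EVENT, "NAUSEA"}
    assert r.drugs[0].verbatim_name == "MORPHINE"
    assert r.drugs[0].indication == "POSTOPERATIVE ANALGESIA"


def test_report_without_reactions_is_excluded_and_counted(tmp_path):
    _write_quarter(
        tmp_path,
        demo=["c100$c1$0$2015$40.00$YR$F$CN"],
        drug=["c100$1$PS$MORPHINE$"],
    )
    result = assemble_reports(read_quarterly_files(tmp_path))
    assert result.reports == []
    assert result.n_incomplete_no_event == 1


def test_conflicting_demographics_for_same_primaryid_are_rejected(tmp_path):
    _write_quarter(
        tmp_path,
        demo=["c100$c1$0$2015$40.00$YR$F$CN",
              "c100$c1$0$2015$41.00$YR$F$CN"],
        drug=["c100$1$PS$MORPHINE$"],
        reac=[f"c100${TARGET_EVENT}"],
    )
    result = assemble_reports(read_quarterly_files(tmp_path))
    assert len(result.reports) == 1  # first row wins
    assert any(rej.reason == "conflicting demographics"
               for rej in result.rejects)


def test_identical_duplicate_rows_collapse_silently(tmp_path):
    row = "c100$c1$0$2015$40.00$YR$F$CN"
    _write_quarter(tmp_path, demo=[row, row],
                   drug=["c100$1$PS$MORPHINE$", "c100$1$PS$MORPHINE$"],
                   reac=[f"c100${TARGET_EVENT}"])
    result = assemble_reports(read_quarterly_files(tmp_path))
    assert len(result.reports) == 1
    assert len(result.reports[0].drugs) == 1
    assert result.rejects == []


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def test_dedup_keeps_highest_version():
    reports = [make_report(case_id="x", version=v) for v in (0, 1, 2)]
    out = deduplicate(reports)
    assert len(out) == 1 and out[0].version == 2


def test_dedup_without_duplicates_is_order_stable_identity():
    reports = [make_report(case_id=f"c{i}") for i in range(5)]
    assert deduplicate(reports) == reports


def test_dedup_is_idempotent():
    reports = [make_report(case_id="a", version=1),
               make_report(case_id="b"),
               make_report(case_id="a", version=0)]
    once = deduplicate(reports)
    assert deduplicate(once) == once


def test_dedup_tie_breaks_by_year_then_first_occurrence():
    newer = make_report(case_id="a", version=1, year=2020)
    older = make_report(case_id="a", version=1, year=2018)
    assert deduplicate([older, newer]) == [newer]
    # equal (version, year): earliest provenance wins
    first = make_report(case_id="a", version=1, year=2020, sex="male")
    assert deduplicate([first, newer]) == [first]


def test_dedup_removes_exactly_injected_duplicates():
    reports = generate_reports(oracle_config(n=500, seed=31))
    with_dups = inject_duplicates(reports, 0.2, seed=4)
    assert len(with_dups) == 600
    assert len(deduplicate(with_dups)) == 500


# ---------------------------------------------------------------------------
# name standardization
# ---------------------------------------------------------------------------


def test_normalization_uppercases_and_collapses_whitespace():
    assert normalize_name("  amitriptyline ") == "AMITRIPTYLINE"
    assert normalize_name("fat\t emulsions") == "FAT EMULSIONS"


def test_mapping_resolves_combination_product_with_backslash():
    reports = [make_report(drugs=("APAP/HYDROCODONE",))]
    mapping = {"APAP/HYDROCODONE": "ACETAMINOPHEN\\HYDROCODONE BITARTRATE"}
    out = standardize_drug_names(reports, mapping)
    assert out.reports[0].drugs[0].generic_name == \
        "ACETAMINOPHEN\\HYDROCODONE BITARTRATE"
    assert out.coverage == 1.0


def test_unmapped_verbatim_keeps_unresolved_marker_and_is_summarized():
    reports = [make_report(case_id="1", drugs=("XYZZY",)),
               make_report(case_id="2", drugs=("XYZZY", "MORPHINE"))]
    out = standardize_drug_names(reports, {"MORPHINE": "MORPHINE"})
    assert out.reports[0].drugs[0].generic_name == UNRESOLVED_PREFIX + "XYZZY"
    assert out.unresolved == {"XYZZY": 2}
    assert out.n_resolved == 1


def test_standardize_does_not_mutate_input():
    reports = [make_report(drugs=("morphine",))]
    standardize_drug_names(reports, identity_mapping(["morphine"]))
    assert reports[0].drugs[0].generic_name == "morphine"  # factory default


# ---------------------------------------------------------------------------
# cohort filter
# ---------------------------------------------------------------------------


def test_minor_is_excluded_by_adult_age_filter():
    reports = [make_report(case_id="minor", age=17.0),
               make_report(case_id="adult", age=18.0)]
    result = apply_cohort_filter(reports, CohortFilter(min_age_years=18.0))
    assert [r.case_id for r in result.kept] == ["adult"]
    assert result.tally["age"] == 1


def test_missing_age_excluded_unless_kept_by_policy():
    reports = [make_report(age=None)]
    strict = apply_cohort_filter(reports, CohortFilter(min_age_years=18.0))
    assert strict.kept == [] and strict.tally["age"] == 1
    lenient = apply_cohort_filter(
        reports, CohortFilter(min_age_years=18.0, keep_missing_age=True))
    assert len(lenient.kept) == 1


def test_unset_filter_is_identity():
    reports = [make_report(case_id=f"c{i}", age=None) for i in range(4)]
    result = apply_cohort_filter(reports, CohortFilter(min_age_years=None))
    assert result.kept == reports
    assert result.n_excluded == 0


def test_role_and_indication_must_match_on_the_same_mention():
    match = make_report(case_id="m", indication="Postoperative  analgesia")
    wrong_role = make_report(case_id="r", role="concomitant",
                             indication="POSTOPERATIVE ANALGESIA")
    no_ind = make_report(case_id="n")
    f = CohortFilter(min_age_years=None, required_role="primary_suspect",
                     required_indication="POSTOPERATIVE ANALGESIA")
    result = apply_cohort_filter([match, wrong_role, no_ind], f)
    assert [r.case_id for r in result.kept] == ["m"]
    assert result.tally["drug"] == 2


def test_filter_recovers_planted_indication_count():
    cfg = oracle_config(n=2_000, seed=17)
    cfg.indication_rate = 0.25
    reports = generate_reports(cfg)
    planted = sum(any(m.indication == cfg.indication_term for m in r.drugs)
                  for r in reports)
    result = apply_cohort_filter(
        reports, CohortFilter(min_age_years=None,
                              required_indication=cfg.indication_term))
    assert len(result.kept) == planted


@settings(max_examples=50, derandomize=True)
@given(ages=st.lists(st.one_of(st.none(),
                               st.floats(0, 100, allow_nan=False)),
                     min_size=1, max_size=30),
       min_age=st.floats(0, 90, allow_nan=False))
def test_filter_conserves_report_count(ages, min_age):
    reports = [make_report(case_id=str(i), age=a) for i, a in enumerate(ages)]
    result = apply_cohort_filter(reports, CohortFilter(min_age_years=min_age))
    assert len(result.kept) + result.n_excluded == len(reports)


def test_full_ingest_roundtrip_is_identity_on_clean_data(tmp_path):
    """write → read → assemble → standardize → deduplicate leaves a
    duplicate-free synthetic report set untouched."""
    cfg = oracle_config(n=150, seed=23)
    reports = generate_reports(cfg)
    write_quarterly_files(reports, tmp_path)
    assembled = assemble_reports(read_quarterly_files(tmp_path))
    names = [d for d, _ in cfg.drug_vocabulary]
    restored = standardize_drug_names(assembled.reports,
                                      identity_mapping(names)).reports
    deduped = deduplicate(restored)
    assert sorted(deduped, key=lambda r: r.case_id) == \
        sorted(reports, key=lambda r: r.case_id)
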