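"""2×2 construction, the four signal statistics, rule sets, and the screen."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig.disproportionality import (
    ContingencyTable,
    apply_criteria,
    build_contingency,
    compute_ic,
    compute_ror,
    compute_rrr,
    compute_safety_signal,
    point_estimate_from_ci,
    screen_all,
    signal_from_table,
)
from faersig.errors import ConfigurationError, DataError
from faersig.synthetic import generate_reports

from conftest import TARGET_EVENT, make_report, recovery_config

cells = st.integers(min_value=1, max_value=60)


def test_contingency_margins_and_expected():
    t = ContingencyTable(2, 5, 10, 495)
    assert t.n == 512
    assert t.drug_margin == 7 and t.event_margin == 12
    assert t.expected == pytest.approx(7 * 12 / 512)


def test_build_contingency_partitions_four_archetypes():
    reports = [
        make_report(case_id="1", drugs=("D",), events=("E",)),
        make_report(case_id="2", drugs=("D",), events=("X",)),
        make_report(case_id="3", drugs=("O",), events=("E",)),
        make_report(case_id="4", drugs=("O",), events=("X",)),
    ]
    t = build_contingency(reports, "D", "E")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_build_contingency_respects_role_filter():
    reports = [make_report(case_id="1", drugs=("D",), role="concomitant",
                           events=("E",)),
               make_report(case_id="2", drugs=("D",), events=("E",))]
    t = build_contingency(reports, "D", "E", role="primary_suspect")
    assert (t.a, t.c) == (1, 1)


def test_event_on_every_report_gives_degenerate_margin():
    reports = [make_report(case_id="1", drugs=("D",)),
               make_report(case_id="2", drugs=("O",))]
    t = build_contingency(reports, "D", TARGET_EVENT)
    assert t.b == 0 and t.d == 0


def test_empty_background_is_an_error():
    with pytest.raises(DataError):
        build_contingency([], "D", "E")


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------


def test_balanced_table_has_unit_ror_with_ci_straddling_one():
    r = compute_ror(ContingencyTable(10, 10, 10, 10))
    assert r.ror == 1.0
    assert r.ci_low < 1 < r.ci_high
    assert not r.corrected


def test_ror_example_against_direct_arithmetic():
    r = compute_ror(ContingencyTable(2, 5, 10, 500))
    assert r.ror == pytest.approx(20.0)
    se = math.sqrt(1 / 2 + 1 / 5 + 1 / 10 + 1 / 500)
    assert se == pytest.approx(math.sqrt(0.802))
    assert r.ci_low == pytest.approx(20 * math.exp(-1.96 * se), rel=1e-9)
    assert r.ci_high == pytest.approx(20 * math.exp(1.96 * se), rel=1e-9)
    assert r.ci_low == pytest.approx(3.457, abs=0.02)
    assert r.ci_high == pytest.approx(115.7, abs=0.5)
    assert 0 < r.p < 0.05


def test_zero_cell_triggers_haldane_correction_flag():
    r = compute_ror(ContingencyTable(0, 5, 10, 500))
    assert r.corrected
    assert math.isfinite(r.ror) and r.ror > 0


def test_point_estimate_recovered_from_wald_limits():
    r = compute_ror(ContingencyTable(7, 93, 31, 869))
    assert point_estimate_from_ci(r.ci_low, r.ci_high) == \
        pytest.approx(r.ror, rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(a=cells, b=cells, c=cells, d=cells)
def test_ror_transposition_and_inversion(a, b, c, d):
    base = compute_ror(ContingencyTable(a, b, c, d)).ror
    transposed = compute_ror(ContingencyTable(a, c, b, d)).ror
    swapped = compute_ror(ContingencyTable(b, a, d, c)).ror
    assert transposed == pytest.approx(base, rel=1e-12)
    assert swapped == pytest.approx(1 / base, rel=1e-12)


@settings(max_examples=200, derandomize=True)
@given(a=st.integers(0, 60), b=cells, c=cells, d=cells)
def test_wald_symmetry_holds_even_when_corrected(a, b, c, d):
    r = compute_ror(ContingencyTable(a, b, c, d))
    mid = math.exp((math.log(r.ci_low) + math.log(r.ci_high)) / 2)
    assert mid == pytest.approx(r.ror, rel=1e-9)


# ---------------------------------------------------------------------------
# RRR and safety signal
# ---------------------------------------------------------------------------


def test_proportional_rows_give_unit_rrr():
    assert compute_rrr(ContingencyTable(2, 8, 20, 80)) == pytest.approx(1.0)


def test_rrr_example_and_edge_cases():
    assert compute_rrr(ContingencyTable(2, 5, 10, 495)) == \
        pytest.approx(2 / (7 * 12 / 512), rel=1e-12)
    assert compute_rrr(ContingencyTable(2, 5, 10, 495)) == \
        pytest.approx(12.19, abs=0.01)
    assert compute_rrr(ContingencyTable(0, 5, 10, 495)) == 0.0
    # E >= a^2/N > 0 whenever a > 0, so a drug-and-event-only table is the
    # closest degenerate case: rrr = a*N/(n1*n2) stays finite
    assert compute_rrr(ContingencyTable(3, 0, 0, 5)) == \
        pytest.approx(3 * 8 / 9, rel=1e-12)


def test_safety_signal_zero_iff_observed_equals_expected():
    assert compute_safety_signal(ContingencyTable(10, 10, 10, 10)) == 0.0
    t = ContingencyTable(2, 5, 10, 495)
    assert compute_safety_signal(t) == \
        pytest.approx(math.log2(2.5 / (t.expected + 0.5)), rel=1e-12)
    assert compute_safety_signal(t) == pytest.approx(1.91, abs=0.01)
    assert compute_safety_signal(ContingencyTable(0, 50, 50, 50)) < 0


@settings(max_examples=200, derandomize=True)
@given(a=st.integers(0, 60), b=cells, c=cells, d=cells)
def test_ror_strictly_increases_in_a_at_fixed_off_cells(a, b, c, d):
    t0 = ContingencyTable(a, b, c, d)
    t1 = ContingencyTable(a + 1, b, c, d)
    assert compute_ror(t1).ror > compute_ror(t0).ror


@settings(max_examples=200, derandomize=True)
@given(a=st.integers(0, 60), b=st.integers(2, 60), c=st.integers(2, 60),
       d=cells)
def test_all_statistics_strictly_increase_in_a_at_fixed_margins(a, b, c, d):
    """Shifting one report from the discordant cells into agreement
    (a+1, b-1, c-1, d+1) keeps every margin fixed and must strictly raise
    all four statistics. (At fixed b,c,d the observed/expected family is
    not monotone, because E grows superlinearly in a.)"""
    t0 = ContingencyTable(a, b, c, d)
    t1 = ContingencyTable(a + 1, b - 1, c - 1, d + 1)
    assert compute_ror(t1).ror > compute_ror(t0).ror
    assert compute_rrr(t1) > compute_rrr(t0)
    assert compute_safety_signal(t1) > compute_safety_signal(t0)
    assert compute_ic(t1)[0] > compute_ic(t0)[0]
    assert compute_ic(t1)[1] > compute_ic(t0)[1]  # lower credible bound too


# ---------------------------------------------------------------------------
# IC
# ---------------------------------------------------------------------------


def test_ic_near_zero_at_large_sample_independence():
    for method in ("gamma", "bate1998"):
        ic, lo, hi = compute_ic(ContingencyTable(1000, 1000, 1000, 1000),
                                method=method)
        assert abs(ic) < 0.01
        assert lo < 0 < hi


def test_default_ic_equals_safety_signal():
    t = ContingencyTable(8, 92, 192, 9708)
    assert compute_ic(t)[0] == compute_safety_signal(t)


def test_ic_credible_bounds_match_monte_carlo():
    """The exact gamma credible bounds agree with 10^6 posterior draws."""
    t = ContingencyTable(8, 92, 192, 9708)  # a=8, E=2
    _, lo, hi = compute_ic(t)
    rng = np.random.default_rng(123)
    draws = np.log2(rng.gamma(t.a + 0.5, size=1_000_000) / (t.expected + 0.5))
    mc_lo, mc_hi = np.quantile(draws, [0.025, 0.975])
    assert lo == pytest.approx(mc_lo, abs=0.02)
    assert hi == pytest.approx(mc_hi, abs=0.02)


def test_ic_interval_orders_and_brackets_point():
    for table in (ContingencyTable(5, 20, 30, 400),
                  ContingencyTable(0, 20, 30, 400)):
        for method in ("gamma", "bate1998"):
            ic, lo, hi = compute_ic(table, method=method)
            assert lo <= ic <= hi


def test_unknown_ic_method_lists_supported_ones():
    with pytest.raises(ConfigurationError, match="gamma.*bate1998"):
        compute_ic(ContingencyTable(1, 1, 1, 1), method="nope")


# ---------------------------------------------------------------------------
# rule sets
# ---------------------------------------------------------------------------


def _result(a=5, signal=1.0, rrr=3.0, ror_low=2.0, ic_low=0.5):
    res = signal_from_table(ContingencyTable(a, 10, 10, 100))
    res.safety_signal = signal
    res.rrr = rrr
    res.ror_ci = (ror_low, 100.0)
    res.ic_ci = (ic_low, 5.0)
    return res


@pytest.mark.parametrize("kwargs, ruleset, expected", [
    (dict(a=2, signal=0.1, rrr=2.01), "aersmine", True),
    (dict(a=1, signal=5.0, rrr=50.0), "aersmine", False),
    (dict(a=5, signal=0.0, rrr=50.0), "aersmine", False),
    (dict(a=5, signal=1.0, rrr=2.0), "aersmine", False),
    (dict(ror_low=1.0), "ror", False),
    (dict(ror_low=1.0000001), "ror", True),
    (dict(a=3, ic_low=0.23), "bcpnn", True),
    (dict(a=2, ic_low=0.23), "bcpnn", False),
    (dict(a=3, ic_low=-0.10), "bcpnn", False),
    (dict(a=3, ic_low=0.0), "bcpnn", False),
])
def test_rule_boundaries_are_strict_as_printed(kwargs, ruleset, expected):
    flags = apply_criteria(_result(**kwargs))
    assert flags[ruleset] is expected


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------


def test_screen_single_drug_is_singleton():
    reports = [make_report(case_id="1", drugs=("D",), events=(TARGET_EVENT,)),
               make_report(case_id="2", drugs=("D",), events=("X",))]
    results = screen_all(reports, TARGET_EVENT, drugs=["D"])
    assert len(results) == 1 and results[0].drug == "D"


def test_screen_sorts_by_ror_descending():
    cfg = recovery_config(seed=1, n=5000)
    results = screen_all(generate_reports(cfg), "EVENT_E5")
    rors = [r.ror for r in results]
    assert rors == sorted(rors, reverse=True)


def test_strongly_planted_drugs_carry_top_rrr_ranks():
    """Three drugs with planted odds factors >= 8 on the same event must
    occupy the top three relative-reporting-ratio ranks of the screen."""
    from faersig.synthetic import GeneratorConfig, PlantedSignal
    from conftest import ALWAYS_EVENT, _base_marginals

    planted = [("HOTDRUG_A", 8.0), ("HOTDRUG_B", 9.0), ("HOTDRUG_C", 10.0)]
    fill = (1.0 - 3 * 0.01) / 7.0
    cfg = GeneratorConfig(
        n_reports=50_000,
        drug_vocabulary=[(d, 0.01) for d, _ in planted]
        + [(f"FILLER{i}", fill) for i in range(7)],
        event_vocabulary=[(ALWAYS_EVENT, 1.0), (TARGET_EVENT, 0.01)],
        planted_signals=[PlantedSignal(d, TARGET_EVENT, e)
                         for d, e in planted],
        drugs_per_report=(1, 3),
        duplicate_rate=0.0,
        indication_rate=0.0,
        seed=2,
        **_base_marginals(),
    )
    results = screen_all(generate_reports(cfg), TARGET_EVENT)
    by_rrr = sorted(results, key=lambda r: -r.rrr)
    assert {r.drug for r in by_rrr[:3]} == {d for d, _ in planted}


def test_screen_empty_drug_list_rejected():
    with pytest.raises(ConfigurationError):
        screen_all([make_report()], TARGET_EVENT, drugs=[])
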