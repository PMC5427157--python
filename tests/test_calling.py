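"""Cq parsing, control validation and duplicate-well calling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import join_rows, pipeline_calls
from gmoscreen import calling, simulate as sim
from gmoscreen.calling import NO_AMP, CallingConfig, call_duplicates
from gmoscreen.plates import build_default_layout

CQ = st.one_of(st.none(), st.floats(0.5, 45))


@pytest.mark.parametrize(
    "cq1,cq2,expected",
    [
        (25.1, 25.3, "D"),
        (NO_AMP, NO_AMP, "ND"),
        (32.0, NO_AMP, "S"),
        (44.9, NO_AMP, "S"),
        (20.0, 44.0, "D"),  # one late replicate alone does not make a suspect
    ],
)
def test_call_duplicates_rules(cq1, cq2, expected):
    call, _ = call_duplicates(cq1, cq2)
    assert call == expected


def test_late_window_gives_suspect_with_note():
    call, notes = call_duplicates(38.5, 39.2, CallingConfig(suspect_cq_min=34))
    assert call == "S"
    assert any("late" in n for n in notes)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(cq1=CQ, cq2=CQ)
def test_call_duplicates_symmetric(cq1, cq2):
    assert call_duplicates(cq1, cq2) == call_duplicates(cq2, cq1)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(cq1=CQ, cq2=CQ, t1=st.floats(30, 45), t2=st.floats(30, 45))
def test_detection_monotone_in_threshold(cq1, cq2, t1, t2):
    """Raising detect_cq_max never turns a D into an ND."""
    lo, hi = sorted((t1, t2))
    call_lo, _ = call_duplicates(cq1, cq2, CallingConfig(detect_cq_max=lo))
    call_hi, _ = call_duplicates(cq1, cq2, CallingConfig(detect_cq_max=hi))
    if call_lo == "D":
        assert call_hi != "ND"
    if call_hi == "ND":
        assert call_lo == "ND"


@pytest.fixture(scope="module")
def simulated_table(matrix, tmp_path_factory):
    layout = build_default_layout(11)
    comps = [sim.SampleComposition(i, "soy") for i in range(1, 12)]
    rows = sim.simulate_run(comps, layout, matrix, sim.CqModel(), seed=5)
    path = tmp_path_factory.mktemp("cq") / "cq.tsv"
    sim.write_cq_table(rows, path)
    return layout, path


def test_parse_full_export(simulated_table):
    layout, path = simulated_table
    joined = calling.parse_cq_table(path, layout)
    assert len(joined) == 768
    sample_rows = [j for j in joined if j.assignment.role.value == "sample"]
    assert len(sample_rows) == 704  # 11 samples x 2 isolations x 32 assays
    assert len(joined) - len(sample_rows) == 64  # 32 positive + 32 water controls


def test_parse_errors(simulated_table, tmp_path):
    layout, path = simulated_table
    text = path.read_text()
    bad = tmp_path / "unknown_well.tsv"
    bad.write_text(text + "3\tZ99\t30.0\n")
    with pytest.raises(ValueError, match="Z99"):
        calling.parse_cq_table(bad, layout)
    dup = tmp_path / "dup.tsv"
    dup.write_text(text + text.splitlines()[1] + "\n")
    with pytest.raises(ValueError, match="duplicate"):
        calling.parse_cq_table(dup, layout)
    token = tmp_path / "token.tsv"
    token.write_text(text.replace("Undetermined", "oops", 1))
    with pytest.raises(ValueError, match="oops"):
        calling.parse_cq_table(token, layout)


def test_validate_controls_nominal_and_failures(matrix):
    layout = build_default_layout(1)
    comps = [sim.SampleComposition(1, "soy")]
    rows = sim.simulate_run(comps, layout, matrix, sim.CqModel(), seed=1)
    joined = join_rows(rows, layout)
    outcomes = calling.validate_controls(joined, layout)
    assert all(o.valid for o in outcomes.values())
    assert all(o.positive_control_cq is not None for o in outcomes.values())

    # positive control fails to amplify
    failed = [
        j if not (j.assignment.role.value == "positive_control"
                  and j.assignment.assay == "P-35S")
        else calling.JoinedWell(
            calling.WellResult(j.result.plate_index, j.result.well, NO_AMP), j.assignment
        )
        for j in joined
    ]
    assert not calling.validate_controls(failed, layout)["P-35S"].positive_control_ok

    # NTC amplifies late: contamination
    dirty = [
        j if not (j.assignment.role.value == "no_template_control"
                  and j.assignment.assay == "T-nos")
        else calling.JoinedWell(
            calling.WellResult(j.result.plate_index, j.result.well, 38.0), j.assignment
        )
        for j in joined
    ]
    outcome = calling.validate_controls(dirty, layout)["T-nos"]
    assert not outcome.ntc_ok
    assert any("contamination" in n for n in outcome.notes)

    with pytest.raises(ValueError, match="missing"):
        calling.validate_controls(joined[:-1], layout)


def test_profile_non_gmo_soy(matrix):
    layout = build_default_layout(1)
    calls = pipeline_calls([sim.SampleComposition(1, "soy")], layout, matrix, seed=3)
    profile = calls.calls[1]
    assert len(profile) == 32
    assert profile["Soy Lec"].call == "D"
    assert profile["Plant actin"].call == "D"
    for assay in matrix.assays:
        assert profile[assay].call == "ND"


def test_profile_event_sample_matches_matrix(matrix):
    """A GTS 40-3-2 sample is detected on exactly that event's element set."""
    layout = build_default_layout(1)
    comp = sim.SampleComposition(1, "soy", events={"GTS 40-3-2 soy": 0.05})
    calls = pipeline_calls([comp], layout, matrix, seed=11)
    detectable = matrix.detectable("GTS 40-3-2 soy")
    for assay in matrix.assays:
        expected = "D" if assay in detectable else "ND"
        assert calls.calls[1][assay].call == expected, assay


def test_single_replicate_flagged(matrix):
    layout = build_default_layout(1)
    comps = [sim.SampleComposition(1, "soy")]
    rows = sim.simulate_run(comps, layout, matrix, sim.CqModel(), seed=2)
    kept = [
        (p, w, cq) for (p, w, cq) in rows
        if not (layout.lookup(p, w).role.value == "sample"
                and layout.lookup(p, w).isolation == 2)
    ]
    calls = calling.call_sample_profile(join_rows(kept, layout), layout)
    for ac in calls.calls[1].values():
        assert "single replicate only" in ac.notes
    assert calls.calls[1]["Soy Lec"].call == "D"


def test_invalid_run_annotated(matrix):
    layout = build_default_layout(1)
    comps = [sim.SampleComposition(1, "soy")]
    rows = sim.simulate_run(comps, layout, matrix, sim.CqModel(), seed=2)
    broken = [
        (p, w, NO_AMP if (layout.lookup(p, w).role.value == "positive_control"
                          and layout.lookup(p, w).assay == "bar") else cq)
        for (p, w, cq) in rows
    ]
    calls = calling.call_sample_profile(join_rows(broken, layout), layout)
    assert any(n.startswith("invalid-run") for n in calls.calls[1]["bar"].notes)
    assert not calls.controls["bar"].valid


def test_call_table_round_trip(matrix, tmp_path):
    layout = build_default_layout(2)
    comps = [
        sim.SampleComposition(1, "soy"),
        sim.SampleComposition(2, "maize", events={"MON810 maize": 0.05}),
    ]
    calls = pipeline_calls(comps, layout, matrix, seed=9, sigma=0.1)
    path = tmp_path / "calls.tsv"
    calling.write_call_table(calls, path)
    again = calling.read_call_table(path)
    for sid, per_assay in calls.calls.items():
        for assay, ac in per_assay.items():
            assert again[sid][assay].call == ac.call
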