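"""Candidate prediction, element explanation, masking and workflow decisions."""

import random

import pytest

from gmoscreen import inference
from gmoscreen.catalog import AuthorisationStatus
from gmoscreen.inference import (
    DONOR_CAVEAT,
    EXPLAINED,
    UNEXPLAINED,
    candidate_events,
    crops_present,
    decide_workflow,
    explain,
    interpret_sample,
    masking_check,
)

SEVEN = ["P-35S", "P-FMV", "T-nos", "Cry1A(b)", "Cry1A.105", "Cry2Ab2", "I-rAct1"]


def make_calls(matrix, assays, detected=(), suspect=()):
    calls = {a: "ND" for a in assays}
    for a in detected:
        calls[a] = "D"
    for a in suspect:
        calls[a] = "S"
    return calls


@pytest.fixture
def worked_example_calls(matrix, assays):
    """The two-event worked example: all seven elements plus maize taxon marker."""
    return make_calls(matrix, assays, detected=SEVEN + ["Maize HMG", "Plant actin"])


def test_crops_present(matrix, assays):
    calls = make_calls(matrix, assays, detected=["Soy Lec", "Plant actin"])
    report = crops_present(calls, assays)
    assert report.crops == {"soy"}
    assert report.plant_material_confirmed

    calls = make_calls(matrix, assays, detected=["Plant actin"])
    report = crops_present(calls, assays)
    assert report.crops == set()
    assert report.ungated == {"cotton", "potato"}

    report = crops_present(make_calls(matrix, assays), assays)
    assert any("DNA quality" in w for w in report.warnings)


def test_worked_example_candidates(worked_example_calls, matrix, assays):
    report = candidate_events(worked_example_calls, matrix, assays)
    names = report.candidate_names
    assert "MON89034 maize" in names and "MON810 maize" in names
    # soy events are crop-gated out, with the reason recorded
    assert any("crop gate" in reason for name, reason in report.excluded
               if name.endswith("soy"))
    assert set(names).isdisjoint(n for n, _ in report.excluded)


def test_no_detection_yields_always_test_only(matrix, assays):
    calls = make_calls(matrix, assays, detected=["Soy Lec", "Plant actin"])
    report = candidate_events(calls, matrix, assays)
    assert report.candidates == []
    # zero-coverage events of present (soy) and ungated (cotton) crops
    assert set(report.always_test) == {
        "CV127 soy", "DP305423 soy", "DP356043 soy", "GHB614 cotton",
    }


def test_strict_candidates_subset_of_lenient(matrix, assays):
    rng = random.Random(123)
    screening = list(matrix.assays)
    for _ in range(100):
        detected = [a for a in screening if rng.random() < 0.3]
        calls = make_calls(matrix, assays,
                           detected=detected + ["Maize HMG", "Soy Lec", "Canola FatA",
                                                "Rice SPS", "Sugar beet GS",
                                                "Plant actin"])
        strict = set(candidate_events(calls, matrix, assays, "strict").candidate_names)
        lenient = set(candidate_events(calls, matrix, assays, "lenient").candidate_names)
        assert strict <= lenient


def test_suspect_counts_as_detected_for_candidacy(matrix, assays):
    calls = make_calls(matrix, assays, detected=["Maize HMG", "Plant actin", "P-35S"],
                       suspect=["Cry1A(b)"])
    names = candidate_events(calls, matrix, assays).candidate_names
    assert "MON810 maize" in names


def test_explain_worked_example(worked_example_calls, matrix, assays):
    report = explain(worked_example_calls, matrix, {"MON89034 maize": "detected"},
                     "gmo_labelled", assays=assays)
    assert set(report.statuses) == set(SEVEN)
    assert all(s == EXPLAINED for s in report.statuses.values())
    assert not report.unknown_gmo_indicated
    assert report.required_next_tests == []


def test_explain_set_difference_oracle(worked_example_calls, matrix, assays):
    """With only MON810 confirmed, the unexplained set is the matrix set-difference."""
    cand = candidate_events(worked_example_calls, matrix, assays)
    results = {name: "not_detected" for name in cand.candidate_names}
    results["MON810 maize"] = "detected"
    report = explain(worked_example_calls, matrix, results, "gmo_labelled",
                     candidates=cand)
    expected_unexplained = set(SEVEN) - matrix.detectable("MON810 maize")
    open_assays = {a for a, s in report.statuses.items() if s != EXPLAINED}
    assert open_assays == expected_unexplained
    assert report.unknown_gmo_indicated  # every candidate tested, elements left over


def test_explain_vacuous_when_nothing_detected(matrix, assays):
    calls = make_calls(matrix, assays, detected=["Soy Lec", "Plant actin"])
    report = explain(calls, matrix, {}, "gmo_labelled", assays=assays)
    assert report.statuses == {}
    assert not report.unknown_gmo_indicated


def test_indicator_waits_for_untested_candidates(worked_example_calls, matrix, assays):
    report = explain(worked_example_calls, matrix, {}, "gmo_labelled", assays=assays)
    assert not report.unknown_gmo_indicated
    assert "MON89034 maize" in report.required_next_tests


def test_donor_caveat_softens_but_still_counts(matrix, assays):
    calls = make_calls(matrix, assays, detected=["Maize HMG", "Plant actin", "nptII"])
    cand = candidate_events(calls, matrix, assays)
    results = {name: "not_detected" for name in cand.candidate_names}
    report = explain(calls, matrix, results, "gmo_labelled", candidates=cand)
    assert report.statuses["nptII"] == DONOR_CAVEAT
    assert any("donor organisms" in a for a in report.annotations)
    assert report.unknown_gmo_indicated


def test_unverified_positive_explains_with_warning(matrix, assays):
    # Bt63's rice actin promoter cell is "(+)": explanation is downgraded
    calls = make_calls(matrix, assays,
                       detected=["Rice SPS", "Plant actin", "P-Rice actin", "T-nos",
                                 "Cry1Ab/Ac", "nptII"])
    report = explain(calls, matrix, {"Bt63 rice construct": "detected"},
                     "gmo_labelled", assays=assays)
    assert report.statuses["P-Rice actin"] == inference.EXPLAINED_UNVERIFIED
    assert report.statuses["T-nos"] == EXPLAINED


def test_masking_worked_example(matrix):
    masked = masking_check({"MON89034 maize"}, matrix)
    assert "MON810 maize" in masked
    assert masking_check(set(), matrix) == []


def test_masking_matches_bruteforce_oracle(matrix):
    rng = random.Random(99)
    names = matrix.event_names

    def oracle(confirmed):
        union = set()
        for c in confirmed:
            union |= matrix.detectable(c)
        return sorted(
            e for e in names
            if e not in confirmed and matrix.detectable(e)
            and matrix.detectable(e) <= union
        )

    for _ in range(40):
        confirmed = set(rng.sample(names, rng.randint(1, 4)))
        assert masking_check(confirmed, matrix) == oracle(confirmed)


def test_explanation_monotone_in_confirmed_events(matrix, assays):
    rng = random.Random(2024)
    screening = list(matrix.assays)
    names = matrix.event_names
    rank = {UNEXPLAINED: 0, DONOR_CAVEAT: 0, inference.EXPLAINED_UNVERIFIED: 1,
            EXPLAINED: 2}
    for _ in range(60):
        detected = [a for a in screening if rng.random() < 0.4]
        calls = make_calls(matrix, assays, detected=detected + ["Plant actin"])
        confirmed = rng.sample(names, rng.randint(0, 3))
        extra = rng.choice(names)
        base = explain(calls, matrix, {e: "detected" for e in confirmed},
                       "gmo_labelled", assays=assays)
        more = explain(calls, matrix,
                       {e: "detected" for e in set(confirmed) | {extra}},
                       "gmo_labelled", assays=assays)
        for assay, status in base.statuses.items():
            assert rank[more.statuses[assay]] >= rank[status]


def test_workflow_directives(worked_example_calls, matrix, assays):
    cand = candidate_events(worked_example_calls, matrix, assays)

    done = explain(worked_example_calls, matrix, {"MON89034 maize": "detected"},
                   "gmo_labelled", candidates=cand)
    assert decide_workflow("gmo_labelled", cand, done).status == "complete"

    pending = explain(worked_example_calls, matrix, {}, "non_gmo_labelled",
                      candidates=cand)
    directive = decide_workflow("non_gmo_labelled", cand, pending)
    assert directive.status == "test_events"
    assert len([a for a in directive.actions if a.startswith("test event")]) == len(
        cand.candidate_names
    )

    all_neg = explain(worked_example_calls, matrix,
                      {n: "not_detected" for n in cand.candidate_names},
                      "gmo_labelled", candidates=cand)
    directive = decide_workflow("gmo_labelled", cand, all_neg)
    assert directive.status == "unknown_gmo"
    assert any("orthogonal" in a for a in directive.actions)


def test_non_gmo_mode_demands_quantification(worked_example_calls, matrix, assays):
    cand = candidate_events(worked_example_calls, matrix, assays)
    results = {n: "not_detected" for n in cand.candidate_names}
    results["MON89034 maize"] = "detected"
    rep = explain(worked_example_calls, matrix, results, "non_gmo_labelled",
                  candidates=cand)
    directive = decide_workflow("non_gmo_labelled", cand, rep)
    assert any("0.9%" in a and "MON89034" in a for a in directive.actions)


def test_candidate_ordering_by_authorisation_severity(matrix, assays):
    """Unauthorised candidates outrank authorised ones regardless of name order."""
    for ev in matrix.events:
        if ev.name == "MON810 maize":
            object.__setattr__(ev, "authorisation_status", AuthorisationStatus.AUTHORISED)
        if ev.name == "Bt176 maize":
            object.__setattr__(ev, "authorisation_status", AuthorisationStatus.UNAUTHORISED)
    try:
        calls = make_calls(matrix, assays,
                           detected=["Maize HMG", "Plant actin", "P-35S", "Cry1A(b)",
                                     "T-35S", "bar"])
        names = candidate_events(calls, matrix, assays).candidate_names
        assert names.index("Bt176 maize") < names.index("MON810 maize")
    finally:
        for ev in matrix.events:
            if ev.name in ("MON810 maize", "Bt176 maize"):
                object.__setattr__(ev, "authorisation_status", AuthorisationStatus.UNKNOWN)


def test_engine_never_claims_stack_identity(worked_example_calls, matrix, assays):
    """Stacks produce union patterns: the engine may hint, never identify."""
    interp = interpret_sample(
        1, worked_example_calls, matrix, assays,
        {"MON89034 maize": "detected", "MON810 maize": "detected"}, "gmo_labelled",
    )
    from gmoscreen.reporting import interpretation_dict

    payload = interpretation_dict(interp)
    assert not any("stack" in key for key in payload)
    assert any("stack" in a for a in payload["annotations"])
    assert all("stack" not in e for e in payload["confirmed_events"])


def test_invalid_run_blocks_interpretation(matrix, assays):
    from gmoscreen.calling import AssayCall

    calls = {a: "ND" for a in assays}
    calls["P-35S"] = AssayCall(1, "P-35S", "D", 30.0, 30.1, ["invalid-run: NTC"])
    with pytest.raises(ValueError, match="run controls failed"):
        interpret_sample(1, calls, matrix, assays)
    interp = interpret_sample(1, calls, matrix, assays, allow_invalid_runs=True)
    assert any("failed run controls" in a
               for a in interp.explanation_report.annotations)
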