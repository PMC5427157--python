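"""Decision logic of the screening module: from calls to candidate events,
element explanation and the unknown-GMO indicator.

Given one sample's 32 D/ND/S calls the engine

1. derives which crops are present from the endogenous (taxon) assays,
2. predicts which catalogued GMO events may be present ("possibly present GMO
   event" lane): in strict mode an event is a candidate only if *every* assay
   it is known to trigger was detected, in lenient mode if at least one was,
3. once event-specific test results are entered, checks that every detected
   element/construct is explained by at least one confirmed event,
4. flags the sample as indicating an unknown unauthorised GMO when a detected
   element remains unexplained after all candidates have been tested, and
5. reports which catalogued events a confirmed set would mask (their whole
   detectable footprint is contained in the confirmed events' union, so their
   presence would change no screening call — e.g. MON810 behind MON89034).

Suspect (S) calls count as detected throughout: for ruling events in and for
demanding explanation.  That is the conservative choice with respect to
missing an unauthorised GMO.  Stacked events produce the union pattern of
their components; the engine therefore never claims to identify a stack and
only ever annotates the possibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .catalog import (
    AssayCategory,
    STATUS_SEVERITY,
    SpecificityMatrix,
    SpecificityState,
    expected_elements,
    zero_coverage_events,
)

__all__ = [
    "CandidateReport",
    "CropReport",
    "ExplanationReport",
    "SampleInterpretation",
    "WorkflowDirective",
    "candidate_events",
    "crops_present",
    "decide_workflow",
    "explain",
    "interpret_sample",
    "masking_check",
]

DETECTED_CALLS = ("D", "S")
#: Crops screened without a dedicated taxon assay; their events bypass crop gating.
UNGATED_CROPS = ("cotton", "potato")

EXPLAINED = "explained"
EXPLAINED_UNVERIFIED = "explained_unverified"
UNEXPLAINED = "unexplained"
DONOR_CAVEAT = "donor_caveat"


@dataclass
class CropReport:
    crops: set
    ungated: set
    plant_material_confirmed: bool
    warnings: list = field(default_factory=list)


@dataclass
class CandidateReport:
    crop_report: CropReport
    candidates: list  # (event name, basis: frozenset of supporting detected assays)
    always_test: list  # zero-coverage events of present/ungated crops
    excluded: list  # (event name, reason)
    mode: str = "strict"

    @property
    def candidate_names(self) -> list:
        return [name for name, _ in self.candidates]


@dataclass
class ExplanationReport:
    statuses: dict  # detected assay -> explained | explained_unverified | unexplained | donor_caveat
    explaining_events: dict  # detected assay -> frozenset of confirmed events citing it
    unknown_gmo_indicated: bool
    required_next_tests: list
    confirmed_events: list
    annotations: list = field(default_factory=list)

    @property
    def unexplained(self) -> list:
        return sorted(
            a for a, s in self.statuses.items() if s in (UNEXPLAINED, DONOR_CAVEAT)
        )


@dataclass
class WorkflowDirective:
    status: str  # complete | test_events | unknown_gmo
    actions: list = field(default_factory=list)
    notes: list = field(default_factory=list)


def _detected(calls: Mapping) -> set:
    return {a for a, c in calls.items() if _call_of(c) in DETECTED_CALLS}


def _call_of(call) -> str:
    return getattr(call, "call", call)


def crops_present(calls: Mapping, assays: Mapping) -> CropReport:
    """Crops whose endogenous assay is D or S, plus the actin DNA-quality flag.

    Cotton and potato have no taxon assay among the 32 methods and are always
    returned as "ungated" — their events cannot be excluded on crop grounds.
    """
    crops: set = set()
    actin_call = "ND"
    for name, assay in assays.items():
        if assay.category is not AssayCategory.ENDOGENOUS or name not in calls:
            continue
        call = _call_of(calls[name])
        if assay.crop_scope == "all-plants":
            actin_call = call
        elif call in DETECTED_CALLS:
            crops.add(assay.crop_scope)
    report = CropReport(
        crops=crops,
        ungated=set(UNGATED_CROPS),
        plant_material_confirmed=actin_call in DETECTED_CALLS,
    )
    if actin_call not in DETECTED_CALLS:
        report.warnings.append(
            "plant actin not detected: DNA quality/quantity questionable"
        )
    return report


def _severity_key(matrix: SpecificityMatrix, name: str, basis_size: int):
    status = matrix.event(name).authorisation_status
    return (STATUS_SEVERITY[status], -basis_size, name)


def candidate_events(
    calls: Mapping,
    matrix: SpecificityMatrix,
    assays: Mapping,
    mode: str = "strict",
) -> CandidateReport:
    """The "possibly present GMO event" lane.

    strict (default): an event is a candidate iff its crop gate passes and every
    assay of its detectable set was called D or S — appropriate for a complete
    32-assay screen, where a clean ND on an expected element rules the event
    out.  lenient: one supporting detection suffices — for degraded samples.
    Unverified expected-positives ("(+)" cells) are never binding: an ND on
    them excludes nothing.  Zero-coverage events of present (or ungated) crops
    are listed under ``always_test`` regardless of any call.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    crop_report = crops_present(calls, assays)
    detected = _detected(calls)
    zero = set(zero_coverage_events(matrix))
    candidates = []
    always_test = []
    excluded = []
    for event in matrix.events:
        gate_ok = event.crop in crop_report.crops or event.crop in crop_report.ungated
        if event.name in zero:
            if gate_ok:
                always_test.append(event.name)
            continue
        if not gate_ok:
            excluded.append(
                (event.name, f"crop gate: {event.crop} endogenous assay not detected")
            )
            continue
        det = matrix.detectable(event.name)
        hits = det & detected
        if mode == "strict":
            missing = [a for a in matrix.assays if a in det and a not in detected]
            if missing:
                excluded.append((event.name, f"expected element not detected: {missing[0]}"))
            else:
                candidates.append((event.name, frozenset(det)))
        else:
            if hits:
                candidates.append((event.name, frozenset(hits)))
            else:
                first = next(a for a in matrix.assays if a in det)
                excluded.append((event.name, f"expected element not detected: {first}"))
    candidates.sort(key=lambda item: _severity_key(matrix, item[0], len(item[1])))
    always_test.sort(key=lambda name: _severity_key(matrix, name, 0))
    return CandidateReport(crop_report, candidates, always_test, excluded, mode)


def explain(
    calls: Mapping,
    matrix: SpecificityMatrix,
    event_results: Mapping,
    label_mode: str = "gmo_labelled",
    candidates: CandidateReport | None = None,
    assays: Mapping | None = None,
) -> ExplanationReport:
    """Explanation status of every detected non-endogenous assay.

    *event_results* maps event name to ``"detected"``/``"not_detected"`` from
    event-specific PCR.  A detected assay is explained when a confirmed event
    carries it as ``+``/``+*``; a ``(+)`` cell explains only with an
    "unverified" downgrade.  Unexplained donor-organism targets (nptII, T-g7,
    T-E9, rice actin promoter/intron, CaMV) keep a softened annotation but
    still count toward the unknown-GMO indicator — the indicator only fires
    once every remaining candidate has been tested.
    """
    if label_mode not in ("gmo_labelled", "non_gmo_labelled"):
        raise ValueError(f"unknown label mode {label_mode!r}")
    for name in event_results:
        matrix.event(name)  # raises on unknown event
    if candidates is None:
        if assays is None:
            raise ValueError("explain() needs either a CandidateReport or the assay catalogue")
        candidates = candidate_events(calls, matrix, assays)

    confirmed = sorted(n for n, r in event_results.items() if r == "detected")
    detected_assays = [a for a in matrix.assays if a in _detected(calls)]
    statuses: dict = {}
    explaining: dict = {}
    annotations: list = []
    for assay in detected_assays:
        by_state = {
            st: {e for e in confirmed if matrix.state(e, assay) is st}
            for st in (
                SpecificityState.POS,
                SpecificityState.CROSS_REACT,
                SpecificityState.EXP_POS_UNVERIFIED,
            )
        }
        firm = by_state[SpecificityState.POS] | by_state[SpecificityState.CROSS_REACT]
        if firm:
            statuses[assay] = EXPLAINED
            explaining[assay] = frozenset(firm)
            if by_state[SpecificityState.CROSS_REACT] and not by_state[SpecificityState.POS]:
                annotations.append(
                    f"{assay}: explained via sequence-similarity cross-reaction "
                    f"({', '.join(sorted(by_state[SpecificityState.CROSS_REACT]))})"
                )
        elif by_state[SpecificityState.EXP_POS_UNVERIFIED]:
            statuses[assay] = EXPLAINED_UNVERIFIED
            explaining[assay] = frozenset(by_state[SpecificityState.EXP_POS_UNVERIFIED])
            annotations.append(
                f"{assay}: explanation rests on an unverified expected-positive"
            )
        elif assay in matrix.donor_caveat_assays:
            statuses[assay] = DONOR_CAVEAT
            explaining[assay] = frozenset()
            annotations.append(
                f"{assay}: unexplained, but the target occurs in donor organisms; "
                "a non-GMO origin is possible"
            )
        else:
            statuses[assay] = UNEXPLAINED
            explaining[assay] = frozenset()

    untested = [n for n in candidates.candidate_names if n not in event_results]
    open_assays = [a for a, s in statuses.items() if s in (UNEXPLAINED, DONOR_CAVEAT)]
    unknown_indicated = bool(open_assays) and not untested
    if label_mode == "gmo_labelled":
        required = list(untested) if open_assays else []
    else:
        required = list(untested)

    if "CaMV" in detected_assays and "P-35S" in detected_assays:
        annotations.append(
            "CaMV positive: the P-35S signal may derive from the virus rather than a GMO"
        )
    if len(confirmed) > 1:
        annotations.append(
            "multiple events confirmed: screening cannot distinguish a stacked event "
            "from a mixture; similar event Cq values may hint at a stack"
        )
    return ExplanationReport(
        statuses=statuses,
        explaining_events=explaining,
        unknown_gmo_indicated=unknown_indicated,
        required_next_tests=required,
        confirmed_events=confirmed,
        annotations=annotations,
    )


def masking_check(confirmed_events: Iterable[str], matrix: SpecificityMatrix) -> list:
    """Catalogued events whose presence the confirmed set would completely mask.

    An absent event E is maskable when its detectable footprint is non-empty and
    contained in the union footprint of the confirmed events: adding E to the
    sample would change no screening call, so screening alone can never reveal
    it.  Zero-coverage events are excluded here — they are invisible always,
    not masked by anything, and surface through ``always_test`` instead.
    """
    confirmed = set(confirmed_events)
    union = expected_elements(confirmed, matrix)
    out = []
    for name in matrix.event_names:
        if name in confirmed:
            continue
        det = matrix.detectable(name)
        if det and det <= union:
            out.append(name)
    return sorted(out)


def decide_workflow(
    label_mode: str,
    candidate_report: CandidateReport,
    explanation_report: ExplanationReport,
) -> WorkflowDirective:
    """Next laboratory step for one sample.

    GMO-labelled samples stop as soon as every detected element is explained;
    otherwise the remaining candidates are listed, and once none remain the
    unknown-unauthorised-GMO indication demands orthogonal identification
    (e.g. sequencing).  Non-GMO-labelled samples must test every candidate and
    quantify every confirmed event against the 0.9% labelling threshold
    (quantification itself is outside this module).
    """
    rep = explanation_report
    open_assays = [a for a, s in rep.statuses.items() if s in (UNEXPLAINED, DONOR_CAVEAT)]
    always = [e for e in candidate_report.always_test if e not in rep.confirmed_events]
    notes = []
    if always:
        notes.append(
            "events without screening coverage require direct event tests: "
            + ", ".join(always)
        )
    if label_mode == "gmo_labelled":
        if not open_assays:
            return WorkflowDirective("complete", [], notes)
        if rep.required_next_tests:
            return WorkflowDirective(
                "test_events",
                [f"test event {e}" for e in rep.required_next_tests],
                notes,
            )
        return WorkflowDirective(
            "unknown_gmo",
            ["unknown unauthorised GMO indicated; orthogonal identification "
             "(e.g. NGS) required"],
            notes + [f"unexplained: {', '.join(sorted(open_assays))}"],
        )
    # non-GMO labelled: every candidate must be tested, every hit quantified
    actions = [f"test event {e}" for e in rep.required_next_tests]
    for e in rep.confirmed_events:
        actions.append(f"quantify {e} against the 0.9% labelling threshold")
    if rep.unknown_gmo_indicated:
        actions.append(
            "unknown unauthorised GMO indicated; orthogonal identification required"
        )
        return WorkflowDirective("unknown_gmo", actions, notes)
    if rep.required_next_tests:
        return WorkflowDirective("test_events", actions, notes)
    return WorkflowDirective("complete", actions, notes)


@dataclass
class SampleInterpretation:
    """Everything the reporting layer needs about one sample."""

    sample_id: int
    label_mode: str
    calls: dict  # assay -> AssayCall (or bare call string)
    candidate_report: CandidateReport
    explanation_report: ExplanationReport
    workflow: WorkflowDirective
    masked_events: list
    event_results: dict = field(default_factory=dict)


def interpret_sample(
    sample_id: int,
    calls: Mapping,
    matrix: SpecificityMatrix,
    assays: Mapping,
    event_results: Mapping | None = None,
    label_mode: str = "gmo_labelled",
    mode: str = "strict",
    allow_invalid_runs: bool = False,
) -> SampleInterpretation:
    """Run the whole engine for one sample's calls.

    Calls carrying an ``invalid-run`` note (failed run controls) abort the
    interpretation unless *allow_invalid_runs* is set, in which case they are
    used as-is and the annotation propagates.
    """
    invalid = [
        a for a, c in calls.items()
        if any(n.startswith("invalid-run") for n in getattr(c, "notes", []))
    ]
    if invalid and not allow_invalid_runs:
        raise ValueError(
            f"run controls failed for assay(s) {sorted(invalid)}; "
            "re-run or pass allow_invalid_runs=True"
        )
    event_results = dict(event_results or {})
    cand = candidate_events(calls, matrix, assays, mode=mode)
    expl = explain(calls, matrix, event_results, label_mode, candidates=cand)
    if invalid:
        expl.annotations.append(
            "interpretation includes assays with failed run controls: "
            + ", ".join(sorted(invalid))
        )
    workflow = decide_workflow(label_mode, cand, expl)
    masked = masking_check(expl.confirmed_events, matrix) if expl.confirmed_events else []
    return SampleInterpretation(
        sample_id=sample_id,
        label_mode=label_mode,
        calls=dict(calls),
        candidate_report=cand,
        explanation_report=expl,
        workflow=workflow,
        masked_events=masked,
        event_results=event_results,
    )
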