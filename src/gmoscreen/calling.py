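"""Per-well Cq ingestion, run-control validation and duplicate-well calling.

The thermocycler exports one Cq value per well (or a no-amplification marker).
This module joins that long-format table to the plate layout, checks each
assay's positive sensitivity control and no-template control, and collapses the
two isolations of every sample into a single call per (sample, assay):

``D``  both replicates amplified at or below the detection threshold;
``ND`` neither replicate amplified;
``S``  anything in between — discordant replicates, or concordant but late
       amplification (the suspect window), which in practice flags trace-level
       signals such as the low-level CRM cross-contaminations observed between
       Cq 34 and 40.

The run defines 45 cycles, so 45 is the default detection bound; the suspect
window onset of Cq 34 mirrors the observed trace-contamination range.  Both are
configuration, not measured constants: the underlying protocol never states a
numeric D/ND/S rule and leaves it to the analyst's module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

from .plates import PlateLayout, WellAssignment, WellRole

__all__ = [
    "NO_AMP",
    "AssayCall",
    "CallingConfig",
    "ControlOutcome",
    "ScreenCalls",
    "WellResult",
    "call_duplicates",
    "call_sample_profile",
    "parse_cq_table",
    "validate_controls",
    "write_call_table",
    "read_call_table",
]

#: Canonical in-memory marker for "no amplification within the run".
NO_AMP = None


@dataclass(frozen=True)
class CallingConfig:
    max_cycles: float = 45.0
    detect_cq_max: float = 45.0
    suspect_cq_min: float = 34.0
    no_amp_tokens: tuple = ("", "N/A", "Undetermined", "NO_AMP", "NoAmp")
    #: proceed with inference despite failed run controls (calls stay annotated)
    allow_invalid_runs: bool = False

    def parse_cq(self, token: str):
        token = token.strip()
        if token in self.no_amp_tokens:
            return NO_AMP
        try:
            cq = float(token)
        except ValueError:
            raise ValueError(f"Cq token {token!r} is neither numeric nor a no-amp marker")
        if not 0 < cq <= self.max_cycles:
            raise ValueError(f"Cq {cq} outside (0, {self.max_cycles}]")
        return cq

    def amplified(self, cq) -> bool:
        return cq is not NO_AMP and cq <= self.detect_cq_max

    def late(self, cq) -> bool:
        return cq is not NO_AMP and self.suspect_cq_min < cq <= self.detect_cq_max


@dataclass(frozen=True)
class WellResult:
    plate_index: int
    well: str
    cq: float | None  # None = no amplification


@dataclass(frozen=True)
class JoinedWell:
    """A well result joined to its layout assignment."""

    result: WellResult
    assignment: WellAssignment


@dataclass(frozen=True)
class ControlOutcome:
    assay: str
    positive_control_ok: bool
    ntc_ok: bool
    positive_control_cq: float | None = None
    notes: tuple = ()

    @property
    def valid(self) -> bool:
        return self.positive_control_ok and self.ntc_ok


@dataclass
class AssayCall:
    sample_id: int
    assay: str
    call: str  # D | ND | S
    cq1: float | None = None
    cq2: float | None = None
    notes: list = field(default_factory=list)


@dataclass
class ScreenCalls:
    """All per-sample calls of one screening run plus its control outcomes."""

    calls: dict  # sample_id -> {assay: AssayCall}
    controls: dict  # assay -> ControlOutcome

    def profile(self, sample_id: int) -> dict:
        return {assay: ac.call for assay, ac in self.calls[sample_id].items()}


def parse_cq_table(path, layout: PlateLayout, config: CallingConfig | None = None) -> list:
    """Read a delimited (plate, well, cq) table and join it to the layout.

    Returns a list of :class:`JoinedWell`.  Rows naming wells outside the layout,
    duplicated wells, and unparseable Cq tokens raise ``ValueError`` with the
    plate/well coordinates; wells of the layout missing from the file are
    tolerated here and surface later as missing replicates.
    """
    config = config or CallingConfig()
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
        rows = [
            r for r in csv.reader(fh, delimiter=delimiter)
            if r and not r[0].startswith("#")
        ]
    if not rows:
        raise ValueError(f"{path}: empty Cq table")
    header = [h.strip().lower() for h in rows[0]]
    try:
        i_plate, i_well, i_cq = header.index("plate"), header.index("well"), header.index("cq")
    except ValueError:
        raise ValueError(f"{path}: header must name plate, well and cq columns") from None
    joined = []
    seen = set()
    for lineno, rec in enumerate(rows[1:], start=2):
        rec = rec + [""] * (len(header) - len(rec))
        plate, well = int(rec[i_plate]), rec[i_well].strip()
        if (plate, well) in seen:
            raise ValueError(f"{path}:{lineno}: duplicate row for plate {plate} well {well}")
        seen.add((plate, well))
        try:
            assignment = layout.lookup(plate, well)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if isinstance(assignment, str):  # EMPTY marker
            raise ValueError(
                f"{path}:{lineno}: plate {plate} well {well} is empty in the layout"
            )
        try:
            cq = config.parse_cq(rec[i_cq])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        joined.append(JoinedWell(WellResult(plate, well, cq), assignment))
    return joined


def validate_controls(
    joined: Iterable[JoinedWell],
    layout: PlateLayout,
    config: CallingConfig | None = None,
) -> dict:
    """Per-assay control outcomes; a missing control well raises ``ValueError``.

    The positive sensitivity control must amplify within the detection bound
    (it carries 0.1% GMO / ~25 copies, so failure means the method lost
    sensitivity); the no-template control must stay negative — any NTC signal,
    however late, is flagged as contamination.
    """
    config = config or CallingConfig()
    pos: dict = {}
    ntc: dict = {}
    for jw in joined:
        if jw.assignment.role is WellRole.POSITIVE_CONTROL:
            pos[jw.assignment.assay] = jw.result.cq
        elif jw.assignment.role is WellRole.NO_TEMPLATE_CONTROL:
            ntc[jw.assignment.assay] = jw.result.cq
    outcomes = {}
    for assay in layout.assays:
        if assay not in pos:
            raise ValueError(f"positive-control well for assay {assay!r} missing from results")
        if assay not in ntc:
            raise ValueError(f"no-template-control well for assay {assay!r} missing from results")
        pos_ok = config.amplified(pos[assay])
        ntc_ok = ntc[assay] is NO_AMP
        notes = []
        if not pos_ok:
            notes.append("positive sensitivity control failed to amplify")
        if not ntc_ok:
            notes.append(f"no-template control amplified (Cq {ntc[assay]:g}): contamination")
        outcomes[assay] = ControlOutcome(assay, pos_ok, ntc_ok, pos[assay], tuple(notes))
    return outcomes


def call_duplicates(cq1, cq2, config: CallingConfig | None = None) -> tuple:
    """Collapse two replicate Cq values into (call, notes); symmetric in its inputs.

    A numeric Cq above ``detect_cq_max`` counts as not amplified.
    """
    config = config or CallingConfig()
    amp1, amp2 = config.amplified(cq1), config.amplified(cq2)
    if amp1 and amp2:
        if config.late(cq1) and config.late(cq2):
            return "S", ["late Cq in both replicates (suspect window)"]
        return "D", []
    if not amp1 and not amp2:
        return "ND", []
    return "S", ["discordant replicates"]


def call_sample_profile(
    joined: Iterable[JoinedWell],
    layout: PlateLayout,
    config: CallingConfig | None = None,
) -> ScreenCalls:
    """One D/ND/S call per (sample, assay), with control outcomes propagated.

    Samples with a single available replicate are called from that replicate
    alone and flagged; assays whose run controls failed keep their calls but
    carry an ``invalid-run`` note (inference refuses them unless overridden).
    """
    config = config or CallingConfig()
    joined = list(joined)
    controls = validate_controls(joined, layout, config)
    per_sample: dict = {}
    by_key: dict = {}
    for jw in joined:
        a = jw.assignment
        if a.role is WellRole.SAMPLE:
            by_key.setdefault((a.sample_id, a.assay), {})[a.isolation] = jw.result.cq

    n_samples = layout.n_samples
    for sample_id in range(1, n_samples + 1):
        calls = {}
        for assay in layout.assays:
            reps = by_key.get((sample_id, assay), {})
            cq1, cq2 = reps.get(1), reps.get(2)
            notes: list
            if 1 in reps and 2 in reps:
                call, notes = call_duplicates(cq1, cq2, config)
            elif not reps:
                call, notes = "S", ["no wells measured for this sample/assay"]
            else:
                only = cq1 if 1 in reps else cq2
                if config.amplified(only):
                    call = "S" if config.late(only) else "D"
                else:
                    call = "ND"
                notes = ["single replicate only"]
            if not controls[assay].valid:
                notes = notes + ["invalid-run: " + "; ".join(controls[assay].notes)]
            calls[assay] = AssayCall(sample_id, assay, call, cq1, cq2, notes)
        per_sample[sample_id] = calls
    return ScreenCalls(per_sample, controls)


# ---------------------------------------------------------------------------
# call-table serialization (sample, assay, call, cq1, cq2, notes)

_CALL_COLUMNS = ["sample", "assay", "call", "cq1", "cq2", "notes"]


def write_call_table(calls: ScreenCalls, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_CALL_COLUMNS)
        for sample_id in sorted(calls.calls):
            for ac in calls.calls[sample_id].values():
                writer.writerow(
                    [
                        ac.sample_id, ac.assay, ac.call,
                        "" if ac.cq1 is None else f"{ac.cq1:.2f}",
                        "" if ac.cq2 is None else f"{ac.cq2:.2f}",
                        "; ".join(ac.notes),
                    ]
                )


def read_call_table(path) -> dict:
    """sample_id -> {assay: AssayCall} from a table written by :func:`write_call_table`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if rows[0] != _CALL_COLUMNS:
        raise ValueError(f"{path}: unexpected call-table header {rows[0]}")
    out: dict = {}
    for rec in rows[1:]:
        rec = rec + [""] * (len(_CALL_COLUMNS) - len(rec))
        sample_id = int(rec[0])
        if rec[2] not in ("D", "ND", "S"):
            raise ValueError(f"{path}: invalid call {rec[2]!r}")
        out.setdefault(sample_id, {})[rec[1]] = AssayCall(
            sample_id, rec[1], rec[2],
            float(rec[3]) if rec[3] else None,
            float(rec[4]) if rec[4] else None,
            [n for n in rec[5].split("; ") if n],
        )
    return out
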