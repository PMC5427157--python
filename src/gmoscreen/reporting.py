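"""Per-sample interpretation sheets and the cross-sample summary (LIMS export).

The published module's colour semantics are mapped to explicit status tokens so
plain-text exports carry the same information; spreadsheet output applies
colours as presentation only.  Tokens used in the call lane status column:

``EXPLAINED`` / ``EXPLAINED_UNVERIFIED`` / ``UNEXPLAINED`` / ``DONOR_CAVEAT``
for detected screening targets, ``EXPECTED_POS`` for not-detected targets that
a current candidate would be expected to trigger, ``EXPECTED_NEG`` otherwise,
and ``ENDOGENOUS`` for the taxon/actin lane.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .catalog import AssayCategory, SpecificityMatrix
from .inference import SampleInterpretation

__all__ = [
    "SummaryTable",
    "build_summary",
    "interpretation_dict",
    "parse_sample_sheet",
    "render_sample_sheet",
]

_STATUS_COUNT_COLUMNS = [
    "n_unauthorised", "n_unknown_status", "n_expired", "n_low_level", "n_authorised",
]
_STATUS_TO_COLUMN = {
    "unauthorised": "n_unauthorised",
    "unknown": "n_unknown_status",
    "expired": "n_expired",
    "low_level_619_2011": "n_low_level",
    "authorised": "n_authorised",
}


def _call_fields(call):
    if hasattr(call, "cq1"):
        return call.cq1, call.cq2, call.call
    return None, None, call


def render_sample_sheet(
    interp: SampleInterpretation,
    matrix: SpecificityMatrix,
    assays: dict,
    format: str = "text",
):
    """One sample's analysis sheet: call lane, candidate lane, event results.

    ``format="text"`` returns a tab-delimited multi-section string;
    ``format="xlsx"`` returns an ``openpyxl`` workbook with the same content
    (colours are presentation only).
    """
    if format == "xlsx":
        return _sheet_workbook(interp, matrix, assays)
    if format != "text":
        raise ValueError(f"unknown sheet format {format!r}")
    expl = interp.explanation_report
    expected_pos = set()
    for name, basis in interp.candidate_report.candidates:
        expected_pos |= set(basis)
    lines = [f"# sample {interp.sample_id} ({interp.label_mode})", "[calls]",
             "assay\tcq1\tcq2\tcall\tstatus"]
    for assay_name in list(assays) if assays else list(interp.calls):
        if assay_name not in interp.calls:
            continue
        cq1, cq2, call = _call_fields(interp.calls[assay_name])
        if assays and assays[assay_name].category is AssayCategory.ENDOGENOUS:
            status = "ENDOGENOUS"
        elif assay_name in expl.statuses:
            status = expl.statuses[assay_name].upper()
        elif assay_name in expected_pos:
            status = "EXPECTED_POS"
        else:
            status = "EXPECTED_NEG"
        lines.append(
            f"{assay_name}\t{'' if cq1 is None else f'{cq1:.2f}'}"
            f"\t{'' if cq2 is None else f'{cq2:.2f}'}\t{call}\t{status}"
        )
    lines += ["[events]", "event\tauthorisation\tcandidate\tbasis\tresult"]
    results = dict(interp.event_results)
    candidate_basis = dict(interp.candidate_report.candidates)
    listed = list(dict.fromkeys(
        list(candidate_basis) + interp.candidate_report.always_test + sorted(results)
    ))
    for name in listed:
        event = matrix.event(name)
        cand = "X" if name in candidate_basis else (
            "always-test" if name in interp.candidate_report.always_test else ""
        )
        basis = ",".join(sorted(candidate_basis.get(name, ())))
        lines.append(
            f"{name}\t{event.authorisation_status.value}\t{cand}\t{basis}"
            f"\t{results.get(name, '')}"
        )
    lines += ["[workflow]", f"status\t{interp.workflow.status}"]
    for action in interp.workflow.actions:
        lines.append(f"action\t{action}")
    lines.append(f"unknown_gmo_indicated\t{expl.unknown_gmo_indicated}")
    for note in expl.annotations + interp.workflow.notes:
        lines.append(f"note\t{note}")
    if interp.masked_events:
        lines.append("masked_by_confirmed\t" + ", ".join(interp.masked_events))
    return "\n".join(lines) + "\n"


def parse_sample_sheet(text: str) -> dict:
    """Recover the call lane (assay -> call) from a text sheet."""
    calls = {}
    in_calls = False
    for line in text.splitlines():
        if line.startswith("["):
            in_calls = line.strip() == "[calls]"
            continue
        if not in_calls or line.startswith("#") or line.startswith("assay\t"):
            continue
        fields = line.split("\t")
        if len(fields) >= 4:
            calls[fields[0]] = fields[3]
    return calls


def _sheet_workbook(interp, matrix, assays):
    from openpyxl import Workbook
    from openpyxl.styles import PatternFill

    fills = {
        "EXPLAINED": PatternFill("solid", start_color="C6EFCE"),
        "EXPLAINED_UNVERIFIED": PatternFill("solid", start_color="E2EFDA"),
        "UNEXPLAINED": PatternFill("solid", start_color="FFC7CE"),
        "DONOR_CAVEAT": PatternFill("solid", start_color="FFEB9C"),
        "EXPECTED_POS": PatternFill("solid", start_color="D8E4BC"),
        "EXPECTED_NEG": PatternFill("solid", start_color="FFFFCC"),
    }
    wb = Workbook()
    ws = wb.active
    ws.title = f"sample {interp.sample_id}"
    text = render_sample_sheet(interp, matrix, assays, format="text")
    for row in text.splitlines():
        ws.append(row.split("\t"))
        status = row.split("\t")[-1]
        if status in fills:
            ws.cell(row=ws.max_row, column=5).fill = fills[status]
    return wb


@dataclass
class SummaryTable:
    """One row per sample, fixed column order; serializes losslessly to TSV."""

    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.frame.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, path) -> "SummaryTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def to_xlsx(self, path) -> None:
        self.frame.to_excel(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def build_summary(
    interpretations: list,
    matrix: SpecificityMatrix,
    assays: dict,
) -> SummaryTable:
    """Cross-sample table: 32 call columns + event results + status counts + workflow."""
    assay_order = list(assays)
    designs = {tuple(sorted(i.calls)) for i in interpretations}
    if len(designs) > 1:
        raise ValueError("interpretations stem from different assay designs")
    records = []
    for interp in interpretations:
        expl = interp.explanation_report
        rec = {"sample": str(interp.sample_id), "label_mode": interp.label_mode}
        for assay_name in assay_order:
            call = interp.calls.get(assay_name, "")
            rec[assay_name] = _call_fields(call)[2] if call != "" else ""
        rec["candidates"] = "|".join(interp.candidate_report.candidate_names)
        rec["always_test"] = "|".join(interp.candidate_report.always_test)
        rec["events_tested"] = "|".join(
            f"{e}:{r}" for e, r in sorted(interp.event_results.items())
        )
        counts = dict.fromkeys(_STATUS_COUNT_COLUMNS, 0)
        for e in expl.confirmed_events:
            counts[_STATUS_TO_COLUMN[matrix.event(e).authorisation_status.value]] += 1
        rec.update({k: str(v) for k, v in counts.items()})
        rec["workflow"] = interp.workflow.status
        rec["unknown_gmo"] = str(expl.unknown_gmo_indicated)
        records.append(rec)
    columns = (
        ["sample", "label_mode"] + assay_order
        + ["candidates", "always_test", "events_tested"]
        + _STATUS_COUNT_COLUMNS + ["workflow", "unknown_gmo"]
    )
    frame = pd.DataFrame.from_records(records, columns=columns) if records else \
        pd.DataFrame(columns=columns)
    return SummaryTable(frame.astype(str) if records else frame)


def interpretation_dict(interp: SampleInterpretation) -> dict:
    """Machine-readable per-sample summary (the CLI's JSON payload)."""
    expl = interp.explanation_report
    return {
        "sample_id": interp.sample_id,
        "label_mode": interp.label_mode,
        "crops_present": sorted(interp.candidate_report.crop_report.crops),
        "plant_material_confirmed":
            interp.candidate_report.crop_report.plant_material_confirmed,
        "calls": {a: _call_fields(c)[2] for a, c in interp.calls.items()},
        "candidates": interp.candidate_report.candidate_names,
        "always_test": interp.candidate_report.always_test,
        "excluded": [list(item) for item in interp.candidate_report.excluded],
        "element_status": dict(expl.statuses),
        "confirmed_events": expl.confirmed_events,
        "required_next_tests": expl.required_next_tests,
        "unknown_gmo_indicated": expl.unknown_gmo_indicated,
        "workflow": {"status": interp.workflow.status, "actions": interp.workflow.actions},
        "masked_by_confirmed": interp.masked_events,
        "annotations": expl.annotations,
    }
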