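"""Assay and GMO-event catalogues and the element/construct specificity matrix.

The matrix approach to GMO screening runs a battery of element-, construct- and
virus-targeted qPCR methods on a sample and infers which transformation events may
be present from the combination of detected targets.  The central data structure is
the specificity matrix: one row per GMO event, one column per non-endogenous
screening assay, each cell holding one of six experimentally determined states
(detected, not detected, present-but-divergent, cross-reactive, and the two
unverified expectations).

All bundled tables are plain TSV files under :mod:`gmoscreen.data`, transcribed
from the published screening strategy; :func:`load_bundled_matrix` additionally
cross-validates the transcription against hard prose anchors (the MON89034/MON810
element sets and the seven events without any detectable screening element) so a
corrupted data file cannot silently drive inference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "AssayCategory",
    "AuthorisationStatus",
    "CROPS",
    "DONOR_CAVEAT_ASSAYS",
    "DetectableSets",
    "GMOEvent",
    "MatrixParseError",
    "ScreeningAssay",
    "SpecificityMatrix",
    "SpecificityState",
    "ValidationReport",
    "expected_detectable",
    "expected_elements",
    "load_assays",
    "load_bundled_matrix",
    "load_matrix",
    "load_genome_sizes",
    "load_positive_controls",
    "load_reference_materials",
    "validate_matrix",
    "write_matrix",
    "zero_coverage_events",
]

#: Crops appearing as matrix rows.
CROPS = ("soy", "maize", "canola", "potato", "cotton", "rice", "sugar beet")

#: Assays whose target also occurs in naturally occurring donor organisms
#: (nptII in E. coli, T-g7 from Agrobacterium tumefaciens, T-E9 from pea,
#: the rice actin promoter/intron from rice, CaMV as a plant virus).  A positive
#: signal on these may have a non-GMO origin and is annotated accordingly.
DONOR_CAVEAT_ASSAYS = frozenset(
    {"nptII", "T-g7 (T-ORF1)", "T-E9", "P-Rice actin", "I-rAct1", "CaMV"}
)

_IUPAC = set("ACGTRYSWKMBDHVN")

#: Elements whose joint detection the worked screening example revolves around.
MON89034_ELEMENTS = frozenset(
    {"P-35S", "P-FMV", "T-nos", "Cry1A(b)", "Cry1A.105", "Cry2Ab2", "I-rAct1"}
)
N_ZERO_COVERAGE = 7


class MatrixParseError(ValueError):
    """Raised for malformed catalogue or matrix files, citing the offending cell."""


class AssayCategory(str, Enum):
    ENDOGENOUS = "endogenous"
    ELEMENT = "element"
    CONSTRUCT = "construct"
    VIRUS = "virus"


class AuthorisationStatus(str, Enum):
    AUTHORISED = "authorised"
    LOW_LEVEL_619_2011 = "low_level_619_2011"
    EXPIRED = "expired"
    UNAUTHORISED = "unauthorised"
    UNKNOWN = "unknown"


#: Ordering used when ranking candidate events for follow-up testing: the more
#: severe the potential non-compliance, the earlier the event is listed.  Events
#: of unknown status are ranked right after unauthorised ones (conservative).
STATUS_SEVERITY = {
    AuthorisationStatus.UNAUTHORISED: 0,
    AuthorisationStatus.UNKNOWN: 1,
    AuthorisationStatus.EXPIRED: 2,
    AuthorisationStatus.LOW_LEVEL_619_2011: 3,
    AuthorisationStatus.AUTHORISED: 4,
}


class SpecificityState(Enum):
    """Six-valued outcome of a screening assay run against a reference material."""

    POS = "+"
    NEG = "-"
    SEQ_DIVERGENT = "X"
    CROSS_REACT = "+*"
    EXP_POS_UNVERIFIED = "(+)"
    EXP_NEG_UNVERIFIED = ""

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpecificityState":
        sym = symbol.strip().replace("–", "-").replace("−", "-")
        for state in cls:
            if state.value == sym:
                return state
        raise MatrixParseError(f"unknown specificity symbol {symbol!r}")

    @property
    def detectable(self) -> bool:
        """Whether the assay fires on an event in this state.

        A cross-reactive signal (``+*``) is a real amplification and therefore
        counts as detectable for both candidacy and explanation; a divergent
        element (``X``) is present in the genome but never amplifies.
        """
        return self in (SpecificityState.POS, SpecificityState.CROSS_REACT)


@dataclass(frozen=True)
class ScreeningAssay:
    """One of the 32 qPCR methods, with primer/probe metadata from the protocol."""

    name: str
    category: AssayCategory
    crop_scope: str | None
    forward_primer: str
    reverse_primer: str
    probe: str
    primer_conc_nM: float
    probe_conc_nM: float
    reference: str = ""

    def __post_init__(self) -> None:
        for label, seq in (
            ("forward_primer", self.forward_primer),
            ("reverse_primer", self.reverse_primer),
            ("probe", self.probe),
        ):
            if not seq:
                raise MatrixParseError(f"assay {self.name!r}: empty {label}")
            bad = set(seq.upper()) - _IUPAC
            if bad:
                raise MatrixParseError(
                    f"assay {self.name!r}: non-IUPAC characters {sorted(bad)} in {label}"
                )
        if self.primer_conc_nM <= 0 or self.probe_conc_nM <= 0:
            raise MatrixParseError(f"assay {self.name!r}: concentrations must be > 0")


@dataclass(frozen=True)
class GMOEvent:
    """A transformation event (unique insert) in one of the seven matrix crops."""

    name: str
    crop: str
    authorisation_status: AuthorisationStatus = AuthorisationStatus.UNKNOWN
    reference_material: str | None = None

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise MatrixParseError(
                f"event {self.name!r}: crop {self.crop!r} not one of {CROPS}"
            )


class DetectableSets(NamedTuple):
    """Assays expected to fire on an event, split by verification status."""

    detectable: frozenset
    unverified: frozenset


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class SpecificityMatrix:
    """Event x assay grid of specificity states plus the event catalogue."""

    def __init__(
        self,
        assays: Iterable[str],
        events: Iterable[GMOEvent],
        cells: dict,
        donor_caveat_assays: frozenset = DONOR_CAVEAT_ASSAYS,
    ) -> None:
        self.assays = list(assays)
        self.events = list(events)
        self.cells = dict(cells)
        self.donor_caveat_assays = frozenset(donor_caveat_assays) & set(self.assays)
        self._by_name = {e.name: e for e in self.events}
        if len(self._by_name) != len(self.events):
            raise MatrixParseError("duplicate event name in matrix")
        if len(set(self.assays)) != len(self.assays):
            raise MatrixParseError("duplicate assay name in matrix")
        for ev in self.events:
            for assay in self.assays:
                if (ev.name, assay) not in self.cells:
                    raise MatrixParseError(
                        f"missing cell for event {ev.name!r}, assay {assay!r}"
                    )

    # -- queries ---------------------------------------------------------

    def event(self, name: str) -> GMOEvent:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown GMO event {name!r}") from None

    @property
    def event_names(self) -> list:
        return [e.name for e in self.events]

    def state(self, event: str, assay: str) -> SpecificityState:
        self.event(event)
        if assay not in self.assays:
            raise KeyError(f"unknown screening assay {assay!r}")
        return self.cells[(event, assay)]

    def detectable(self, event: str) -> frozenset:
        """Assays with a real signal (``+`` or ``+*``) on this event."""
        self.event(event)
        return frozenset(a for a in self.assays if self.cells[(event, a)].detectable)

    def unverified_positive(self, event: str) -> frozenset:
        self.event(event)
        return frozenset(
            a
            for a in self.assays
            if self.cells[(event, a)] is SpecificityState.EXP_POS_UNVERIFIED
        )

    def divergent(self, event: str) -> frozenset:
        """Assays whose target is present in the event but never amplifies."""
        self.event(event)
        return frozenset(
            a
            for a in self.assays
            if self.cells[(event, a)] is SpecificityState.SEQ_DIVERGENT
        )

    def events_detected_by(self, assay: str) -> frozenset:
        if assay not in self.assays:
            raise KeyError(f"unknown screening assay {assay!r}")
        return frozenset(
            e.name for e in self.events if self.cells[(e.name, assay)].detectable
        )

    def restricted_to(self, event_names: Iterable[str]) -> "SpecificityMatrix":
        keep = [self.event(n) for n in event_names]
        cells = {
            (e.name, a): self.cells[(e.name, a)] for e in keep for a in self.assays
        }
        return SpecificityMatrix(self.assays, keep, cells, self.donor_caveat_assays)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpecificityMatrix):
            return NotImplemented
        return (
            self.assays == other.assays
            and self.events == other.events
            and self.cells == other.cells
            and self.donor_caveat_assays == other.donor_caveat_assays
        )


# ---------------------------------------------------------------------------
# spec-level operations


def expected_detectable(event: str, matrix: SpecificityMatrix) -> DetectableSets:
    """Assays expected to fire on *event*, with unverified expectations separate."""
    return DetectableSets(matrix.detectable(event), matrix.unverified_positive(event))


def expected_elements(events: Iterable[str], matrix: SpecificityMatrix) -> frozenset:
    """Union of detectable assays over a set of events (the screening footprint)."""
    out: set = set()
    for ev in events:
        out |= matrix.detectable(ev)
    return frozenset(out)


def zero_coverage_events(matrix: SpecificityMatrix) -> list:
    """Events none of whose elements the screening set can detect, sorted by name.

    These always require direct event-specific testing: screening can neither
    suggest nor exclude them.
    """
    return sorted(n for n in matrix.event_names if not matrix.detectable(n))


def check_prose_anchors(matrix: SpecificityMatrix) -> list:
    """Verify the bundled transcription against hard facts stated in prose.

    Returns a list of failure strings (empty when all anchors hold).  Applied to
    the shipped matrix at load time; a failing anchor means the data file was
    corrupted or mis-transcribed, not that a sample is unusual.
    """
    failures = []

    def _has(name: str) -> bool:
        return name in matrix._by_name

    for required in ("MON89034 maize", "MON810 maize", "CV127 soy"):
        if not _has(required):
            failures.append(f"event {required!r} missing from matrix")
    if failures:
        return failures

    mon89034 = matrix.detectable("MON89034 maize")
    mon810 = matrix.detectable("MON810 maize")
    if mon89034 != MON89034_ELEMENTS:
        failures.append(
            "MON89034 detectable set != the seven worked-example elements: "
            f"{sorted(mon89034)}"
        )
    if not mon810 >= {"P-35S", "Cry1A(b)"}:
        failures.append(f"MON810 must detect P-35S and Cry1A(b); got {sorted(mon810)}")
    if not mon810 <= mon89034:
        failures.append("MON810 detectable set not a subset of MON89034's (masking premise)")
    if matrix.detectable("CV127 soy"):
        failures.append("CV127 soy should have no detectable screening element")
    zero = zero_coverage_events(matrix)
    if len(zero) != N_ZERO_COVERAGE:
        failures.append(
            f"expected {N_ZERO_COVERAGE} zero-coverage events, found {len(zero)}: {zero}"
        )
    return failures


def validate_matrix(
    matrix: SpecificityMatrix,
    assays: dict | None = None,
    anchors: bool = False,
) -> ValidationReport:
    """Structural invariants as violations; screening-coverage issues as warnings.

    With *assays* (name -> :class:`ScreeningAssay`), also checks that matrix
    columns are known non-endogenous assays and that every event's crop has an
    endogenous assay or is covered only by the all-plants actin control (true
    for cotton and potato).
    """
    report = ValidationReport()
    seen = set()
    for ev in matrix.events:
        if ev.name in seen:
            report.violations.append(f"duplicate event row {ev.name!r}")
        seen.add(ev.name)
        if ev.crop not in CROPS:
            report.violations.append(f"event {ev.name!r}: unknown crop {ev.crop!r}")

    if assays is not None:
        endo_crops = {
            a.crop_scope
            for a in assays.values()
            if a.category is AssayCategory.ENDOGENOUS and a.crop_scope != "all-plants"
        }
        for col in matrix.assays:
            if col not in assays:
                report.violations.append(f"matrix column {col!r} not in assay catalogue")
            elif assays[col].category is AssayCategory.ENDOGENOUS:
                report.violations.append(
                    f"endogenous assay {col!r} must not be a matrix column"
                )
        for crop in {e.crop for e in matrix.events}:
            if crop not in endo_crops and crop not in ("cotton", "potato"):
                report.violations.append(
                    f"crop {crop!r} has neither an endogenous assay nor actin-only coverage"
                )

    for name in zero_coverage_events(matrix):
        report.warnings.append(
            f"{name}: no detectable screening element; event-specific testing required"
        )
    for ev in matrix.events:
        n = len(matrix.detectable(ev.name))
        if n == 1:
            report.warnings.append(
                f"{ev.name}: only one detectable screening element; little redundancy"
            )
    if anchors:
        report.violations.extend(check_prose_anchors(matrix))
    return report


# ---------------------------------------------------------------------------
# I/O


def _data_path(name: str) -> Path:
    return Path(resources.files("gmoscreen.data") / name)


def _read_tsv(path) -> list:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    return rows


def load_assays(path=None) -> dict:
    """Load the assay catalogue (bundled by default) as name -> ScreeningAssay."""
    path = _data_path("assays.tsv") if path is None else path
    rows = _read_tsv(path)
    header = rows[0]
    out: dict = {}
    for i, row in enumerate(rows[1:], start=2):
        rec = dict(zip(header, row))
        name = rec["name"]
        if name in out:
            raise MatrixParseError(f"{path}:{i}: duplicate assay {name!r}")
        out[name] = ScreeningAssay(
            name=name,
            category=AssayCategory(rec["category"]),
            crop_scope=rec.get("crop_scope") or None,
            forward_primer=rec["fwd"],
            reverse_primer=rec["rev"],
            probe=rec["probe"],
            primer_conc_nM=float(rec["primer_nM"]),
            probe_conc_nM=float(rec["probe_nM"]),
            reference=rec.get("reference", ""),
        )
    n_endo = sum(1 for a in out.values() if a.category is AssayCategory.ENDOGENOUS)
    n_virus = sum(1 for a in out.values() if a.category is AssayCategory.VIRUS)
    if n_endo != 7 or n_virus != 1:
        raise MatrixParseError(
            f"assay catalogue must carry 7 endogenous + 1 virus assay, got {n_endo}/{n_virus}"
        )
    return out


def load_matrix(path, reference_materials: dict | None = None) -> SpecificityMatrix:
    """Parse a specificity-matrix TSV (event, crop, status, then one assay per column)."""
    rows = _read_tsv(path)
    header = rows[0]
    if header[:3] != ["event", "crop", "status"]:
        raise MatrixParseError(f"{path}: header must start with event/crop/status")
    assay_cols = header[3:]
    events: list = []
    cells: dict = {}
    for i, row in enumerate(rows[1:], start=2):
        # csv drops nothing, but guard short rows (trailing empty cells are legal)
        row = row + [""] * (len(header) - len(row))
        if len(row) > len(header):
            raise MatrixParseError(f"{path}:{i}: {len(row)} fields, expected {len(header)}")
        name, crop, status = row[0], row[1], row[2]
        ref = (reference_materials or {}).get(name)
        try:
            event = GMOEvent(name, crop, AuthorisationStatus(status), ref)
        except ValueError as exc:
            raise MatrixParseError(f"{path}:{i}: {exc}") from None
        for assay, symbol in zip(assay_cols, row[3:]):
            try:
                cells[(name, assay)] = SpecificityState.from_symbol(symbol)
            except MatrixParseError:
                raise MatrixParseError(
                    f"{path}:{i}: invalid symbol {symbol!r} for event {name!r}, "
                    f"assay {assay!r}"
                ) from None
        events.append(event)
    return SpecificityMatrix(assay_cols, events, cells)


def write_matrix(matrix: SpecificityMatrix, path) -> None:
    """Serialize a matrix back to the TSV layout accepted by :func:`load_matrix`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["event", "crop", "status"] + list(matrix.assays))
        for ev in matrix.events:
            writer.writerow(
                [ev.name, ev.crop, ev.authorisation_status.value]
                + [matrix.cells[(ev.name, a)].value for a in matrix.assays]
            )


def load_reference_materials(path=None) -> dict:
    """event name -> supplier code for the certified reference materials."""
    path = _data_path("reference_materials.tsv") if path is None else path
    rows = _read_tsv(path)
    header = rows[0]
    out = {}
    for row in rows[1:]:
        rec = dict(zip(header, row))
        out[rec["event"]] = rec["supplier_code"]
    return out


def load_genome_sizes(path=None) -> dict:
    """crop -> haploid (1C) genome mass in picograms."""
    path = _data_path("genome_1C.tsv") if path is None else path
    return {r[0]: float(r[1]) for r in _read_tsv(path)[1:]}


@dataclass(frozen=True)
class PositiveControl:
    assay: str
    material: str
    kind: str  # event_crm | non_gmo_crop | virus
    event: str | None
    crop: str | None


def load_positive_controls(path=None) -> dict:
    """assay name -> PositiveControl describing its sensitivity-control material."""
    path = _data_path("positive_controls.tsv") if path is None else path
    rows = _read_tsv(path)
    header = rows[0]
    out = {}
    for row in rows[1:]:
        row = row + [""] * (len(header) - len(row))
        rec = dict(zip(header, row))
        out[rec["assay"]] = PositiveControl(
            assay=rec["assay"],
            material=rec["material"],
            kind=rec["kind"],
            event=rec.get("event") or None,
            crop=rec.get("crop") or None,
        )
    return out


def load_bundled_matrix() -> SpecificityMatrix:
    """Load the shipped specificity matrix, enforcing the prose anchors."""
    matrix = load_matrix(_data_path("specificity_matrix.tsv"), load_reference_materials())
    failures = check_prose_anchors(matrix)
    if failures:
        raise MatrixParseError(
            "bundled specificity matrix failed transcription anchors: "
            + "; ".join(failures)
        )
    return matrix
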