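"""Eight-plate, 96-well layout for screening 11 samples in duplicate.

Each plate carries four PCR mixes (screening methods); each method occupies a
24-well block: 11 samples x 2 independent DNA isolations, one positive
sensitivity control (0.1% GMO or 25 copies) and one no-template (water) control.
The published figure fixes the block content but not machine coordinates, so
this module's coordinate convention is normative for the artifact: block *m*
(1-4) occupies columns 3(m-1)+1 .. 3m, filled column-major (A1, B1, ... H1,
A2, ...), in the order sample 1-1, 1-2, 2-1, ... 11-2, positive control,
no-template control.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .catalog import _data_path, _read_tsv

__all__ = [
    "MixRecipe",
    "PlateLayout",
    "WellAssignment",
    "WellRole",
    "build_layout",
    "build_default_layout",
    "copies_per_reaction",
    "export_plate_map",
    "import_plate_map",
    "load_plate_methods",
    "well_name",
]

ROWS = "ABCDEFGH"
N_COLUMNS = 12
WELLS_PER_BLOCK = 24
MAX_SAMPLES = 11
EMPTY = "empty"


class WellRole(str, Enum):
    SAMPLE = "sample"
    POSITIVE_CONTROL = "positive_control"
    NO_TEMPLATE_CONTROL = "no_template_control"


@dataclass(frozen=True)
class WellAssignment:
    plate_index: int
    well: str
    assay: str
    role: WellRole
    sample_id: int | None = None
    isolation: int | None = None
    control_material: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.plate_index <= 8:
            raise ValueError(f"plate index {self.plate_index} out of range 1..8")
        _well_index(self.well)  # validates the coordinate
        if self.role is WellRole.SAMPLE:
            if self.sample_id is None or self.isolation is None:
                raise ValueError("sample wells need sample_id and isolation")
            if not 1 <= self.sample_id <= MAX_SAMPLES or self.isolation not in (1, 2):
                raise ValueError(
                    f"sample_id {self.sample_id}/isolation {self.isolation} out of range"
                )
        elif self.sample_id is not None or self.isolation is not None:
            raise ValueError("only sample wells carry sample_id/isolation")
        if (self.role is WellRole.POSITIVE_CONTROL) != (self.control_material is not None):
            raise ValueError("positive-control wells (exactly) carry a control material")


@dataclass(frozen=True)
class MixRecipe:
    """Per-well reaction recipe: 20 uL mix + 5 uL DNA at 10 ng/uL = 25 uL."""

    assay: str
    mix_volume_uL: float = 20.0
    dna_volume_uL: float = 5.0
    dna_concentration_ng_per_uL: float = 10.0

    @property
    def total_uL(self) -> float:
        return self.mix_volume_uL + self.dna_volume_uL

    @property
    def dna_mass_ng(self) -> float:
        return self.dna_volume_uL * self.dna_concentration_ng_per_uL


def well_name(row: int, col: int) -> str:
    return f"{ROWS[row]}{col + 1}"


def _well_index(well: str) -> tuple:
    if len(well) < 2 or well[0] not in ROWS:
        raise ValueError(f"invalid well coordinate {well!r}")
    try:
        col = int(well[1:])
    except ValueError:
        raise ValueError(f"invalid well coordinate {well!r}") from None
    if not 1 <= col <= N_COLUMNS:
        raise ValueError(f"invalid well coordinate {well!r}")
    return ROWS.index(well[0]), col - 1


def _block_wells(mix: int) -> list:
    """The 24 coordinates of mix block 1..4, column-major within its 3 columns."""
    first_col = 3 * (mix - 1)
    return [well_name(r, c) for c in range(first_col, first_col + 3) for r in range(8)]


class PlateLayout:
    def __init__(self, assignments: Iterable[WellAssignment], methods_per_plate: dict):
        self.assignments = list(assignments)
        self.methods_per_plate = {p: list(ms) for p, ms in methods_per_plate.items()}
        self._index = {}
        for a in self.assignments:
            key = (a.plate_index, a.well)
            if key in self._index:
                raise ValueError(f"well {a.well} assigned twice on plate {a.plate_index}")
            self._index[key] = a

    @property
    def assays(self) -> list:
        return [m for p in sorted(self.methods_per_plate) for m in self.methods_per_plate[p]]

    @property
    def n_samples(self) -> int:
        return max((a.sample_id for a in self.assignments if a.sample_id), default=0)

    def lookup(self, plate_index: int, well: str) -> WellAssignment | str:
        """The assignment at a coordinate, or the ``"empty"`` marker."""
        if not 1 <= plate_index <= max(self.methods_per_plate, default=0):
            raise KeyError(f"plate {plate_index} out of range")
        _well_index(well)
        return self._index.get((plate_index, well), EMPTY)

    def wells_for(self, assay: str) -> list:
        return [a for a in self.assignments if a.assay == assay]

    def sample_wells(self, sample_id: int, assay: str) -> list:
        return [
            a
            for a in self.assignments
            if a.role is WellRole.SAMPLE and a.sample_id == sample_id and a.assay == assay
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateLayout):
            return NotImplemented
        return (
            self.assignments == other.assignments
            and self.methods_per_plate == other.methods_per_plate
        )


def load_plate_methods(path=None) -> dict:
    """plate index -> ordered list of the four assay names, from the bundled table."""
    path = _data_path("plate_methods.tsv") if path is None else path
    rows = _read_tsv(path)
    out: dict = {}
    for rec in rows[1:]:
        plate, _mix, assay = int(rec[0]), int(rec[1]), rec[2]
        out.setdefault(plate, []).append(assay)
    return out


def build_layout(
    n_samples: int,
    methods_table: dict,
    controls_table: dict,
) -> PlateLayout:
    """Deterministic plate layout for *n_samples* (<= 11) over the given method plan.

    *controls_table* maps assay name to its positive-control material (either a
    plain string or an object with a ``material`` attribute).  Control wells keep
    their fixed positions (23rd/24th well of each block) regardless of how many
    samples are loaded; unused sample wells stay empty.
    """
    if not 1 <= n_samples <= MAX_SAMPLES:
        raise ValueError(f"n_samples must be 1..{MAX_SAMPLES}, got {n_samples}")
    assignments = []
    for plate in sorted(methods_table):
        methods = methods_table[plate]
        if len(methods) != 4:
            raise ValueError(f"plate {plate} carries {len(methods)} assays, expected 4")
        for mix, assay in enumerate(methods, start=1):
            if assay not in controls_table:
                raise ValueError(f"assay {assay!r} has no positive-control material")
            material = controls_table[assay]
            material = getattr(material, "material", material)
            wells = _block_wells(mix)
            for s in range(1, n_samples + 1):
                for iso in (1, 2):
                    assignments.append(
                        WellAssignment(
                            plate, wells[2 * (s - 1) + iso - 1], assay,
                            WellRole.SAMPLE, sample_id=s, isolation=iso,
                        )
                    )
            assignments.append(
                WellAssignment(
                    plate, wells[22], assay, WellRole.POSITIVE_CONTROL,
                    control_material=material,
                )
            )
            assignments.append(
                WellAssignment(plate, wells[23], assay, WellRole.NO_TEMPLATE_CONTROL)
            )
    return PlateLayout(assignments, methods_table)


def build_default_layout(n_samples: int = MAX_SAMPLES) -> PlateLayout:
    """The bundled 8-plate / 32-method design."""
    from .catalog import load_positive_controls

    return build_layout(n_samples, load_plate_methods(), load_positive_controls())


def copies_per_reaction(dna_mass_ng: float, gmo_fraction: float, genome_1C_pg: float) -> int:
    """Haploid genome-equivalent copies of GMO DNA in one PCR well.

    ``floor(dna_mass_ng * 1000 * gmo_fraction / genome_1C_pg)``; at 50 ng and
    0.1% this gives the protocol's sensitivity-control levels of 44 copies for
    soy (1C = 1.13 pg), 18 for maize (2.725 pg) and 43 for canola (1.15 pg).
    The true copy number in real material additionally depends on zygosity,
    which this arithmetic deliberately ignores.
    """
    if dna_mass_ng <= 0 or genome_1C_pg <= 0 or gmo_fraction <= 0:
        raise ValueError("dna_mass_ng, gmo_fraction and genome_1C_pg must be positive")
    if gmo_fraction > 1:
        raise ValueError("gmo_fraction is a mass fraction in 0..1")
    return math.floor(dna_mass_ng * 1000.0 * gmo_fraction / genome_1C_pg)


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = ["plate", "well", "assay", "role", "sample_id", "isolation", "control_material"]


def export_plate_map(layout: PlateLayout, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS)
        for a in layout.assignments:
            writer.writerow(
                [
                    a.plate_index, a.well, a.assay, a.role.value,
                    a.sample_id if a.sample_id is not None else "",
                    a.isolation if a.isolation is not None else "",
                    a.control_material or "",
                ]
            )


def import_plate_map(path) -> PlateLayout:
    rows = _read_tsv(path)
    if rows[0] != _COLUMNS:
        raise ValueError(f"{path}: unexpected plate-map header {rows[0]}")
    assignments = []
    methods: dict = {}
    for lineno, rec in enumerate(rows[1:], start=2):
        rec = rec + [""] * (len(_COLUMNS) - len(rec))
        try:
            a = WellAssignment(
                plate_index=int(rec[0]),
                well=rec[1],
                assay=rec[2],
                role=WellRole(rec[3]),
                sample_id=int(rec[4]) if rec[4] else None,
                isolation=int(rec[5]) if rec[5] else None,
                control_material=rec[6] or None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        assignments.append(a)
        plate_methods = methods.setdefault(a.plate_index, [])
        if a.assay not in plate_methods:
            plate_methods.append(a.assay)
    layout = PlateLayout(assignments, methods)
    for plate, ms in methods.items():
        if len(ms) != 4:
            raise ValueError(f"{path}: plate {plate} carries {len(ms)} assays, expected 4")
    for assay in layout.assays:
        roles = [a.role for a in layout.wells_for(assay)]
        if WellRole.POSITIVE_CONTROL not in roles or WellRole.NO_TEMPLATE_CONTROL not in roles:
            raise ValueError(f"{path}: assay {assay!r} lacks a control well")
    return layout
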