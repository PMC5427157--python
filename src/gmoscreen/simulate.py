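"""Synthetic per-well Cq data for arbitrary sample compositions.

The generator emulates what the screening run measures, not how PCR works:
each well receives an expected template copy number computed with the same
genome-equivalent arithmetic the protocol uses for its sensitivity controls
(50 ng DNA per well, haploid 1C genome masses), the realised copy number is
Poisson-sampled (the dominant stochastic effect near the detection limit),
amplification is all-or-nothing at >= 1 copy, and the Cq follows a standard
log-linear calibration (default: Cq 40 at a single copy, 3.32 cycles per
10-fold — perfect doubling) plus optional Gaussian replicate noise.  There is
no per-copy efficiency, inhibition or extraction-yield model: the published
methods detect below 20 copies, so near-single-copy sensitivity is the
realistic null, and the simple model keeps every downstream expectation
analyzable.  Zygosity is ignored throughout, as in the control arithmetic.

Compositions may also carry ``unknown_elements`` — screening targets injected
at a given mass fraction without any catalogued event behind them — which is
how an unknown unauthorised GMO enters a synthetic sample.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .catalog import (
    AssayCategory,
    SpecificityMatrix,
    load_assays,
    load_genome_sizes,
    load_positive_controls,
)
from .plates import PlateLayout, WellRole, copies_per_reaction

__all__ = [
    "CqModel",
    "Fixture",
    "SampleComposition",
    "expected_copies",
    "fixture_names",
    "load_scenario",
    "make_fixture",
    "simulate_run",
    "simulate_well",
    "write_cq_table",
]

DNA_MASS_NG = 50.0  # 5 uL at 10 ng/uL per well


@dataclass(frozen=True)
class SampleComposition:
    """Mass-fraction make-up of one sample's DNA."""

    sample_id: int
    crop_background: str
    events: dict = field(default_factory=dict)  # event name -> mass fraction
    contamination: dict = field(default_factory=dict)  # event name -> trace fraction
    unknown_elements: dict = field(default_factory=dict)  # assay name -> fraction

    def __post_init__(self) -> None:
        fractions = list(self.events.values()) + list(self.contamination.values()) \
            + list(self.unknown_elements.values())
        if any(f < 0 for f in fractions):
            raise ValueError("fractions must be >= 0")
        if sum(self.events.values()) + sum(self.contamination.values()) > 1:
            raise ValueError("event + contamination fractions exceed 1")

    @property
    def background_fraction(self) -> float:
        return 1.0 - sum(self.events.values()) - sum(self.contamination.values())

    def event_fractions(self) -> dict:
        out = dict(self.events)
        for ev, f in self.contamination.items():
            out[ev] = out.get(ev, 0.0) + f
        return out


@dataclass(frozen=True)
class CqModel:
    """Log-linear Cq calibration with Poisson template sampling."""

    intercept_cq: float = 40.0  # Cq at a single template copy
    slope: float = 3.32  # cycles per log10(copies); 3.32 = 100% efficiency
    sigma_cq: float = 0.0  # replicate noise SD in cycles
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.sigma_cq < 0:
            raise ValueError("slope must be > 0 and sigma_cq >= 0")


def _crop_fraction(composition: SampleComposition, crop: str, matrix: SpecificityMatrix) -> float:
    total = composition.background_fraction if composition.crop_background == crop else 0.0
    for ev, f in composition.event_fractions().items():
        if matrix.event(ev).crop == crop:
            total += f
    return total


def expected_copies(
    composition: SampleComposition,
    assay: str,
    matrix: SpecificityMatrix,
    genome_sizes: dict | None = None,
    dna_mass_ng: float = DNA_MASS_NG,
) -> dict:
    """Expected copies per well of a screening target, per contributing event.

    Only events whose matrix state is a real signal (``+``/``+*``) contribute;
    a sequence-divergent element (``X``) is present in the DNA but contributes
    zero detectable copies.  Copy numbers use the event crop's 1C mass with the
    protocol's floor arithmetic.
    """
    genome_sizes = genome_sizes or load_genome_sizes()
    out = {}
    for ev, fraction in composition.event_fractions().items():
        if fraction <= 0:
            continue
        if not matrix.state(ev, assay).detectable:
            continue
        crop = matrix.event(ev).crop
        if crop not in genome_sizes:
            raise KeyError(f"no 1C genome size for crop {crop!r}")
        out[ev] = copies_per_reaction(dna_mass_ng, fraction, genome_sizes[crop])
    return out


def _well_lambda(
    composition: SampleComposition,
    assay_name: str,
    assays: dict,
    matrix: SpecificityMatrix,
    genome_sizes: dict,
) -> float:
    """Total expected template copies in one well of *assay_name*."""
    assay = assays[assay_name]
    if assay.category is AssayCategory.ENDOGENOUS:
        if assay.crop_scope == "all-plants":
            fractions = {composition.crop_background: composition.background_fraction}
            for ev, f in composition.event_fractions().items():
                crop = matrix.event(ev).crop
                fractions[crop] = fractions.get(crop, 0.0) + f
            return sum(
                dna_copies(f, genome_sizes[c]) for c, f in fractions.items() if f > 0
            )
        frac = _crop_fraction(composition, assay.crop_scope, matrix)
        return dna_copies(frac, genome_sizes[assay.crop_scope]) if frac > 0 else 0.0
    lam = float(sum(expected_copies(composition, assay_name, matrix, genome_sizes).values()))
    frac = composition.unknown_elements.get(assay_name, 0.0)
    if frac > 0:
        lam += copies_per_reaction(
            DNA_MASS_NG, frac, genome_sizes[composition.crop_background]
        )
    return lam


def dna_copies(fraction: float, genome_1C_pg: float, dna_mass_ng: float = DNA_MASS_NG) -> int:
    return copies_per_reaction(dna_mass_ng, fraction, genome_1C_pg) if fraction > 0 else 0


def simulate_well(lam: float, model: CqModel, rng: np.random.Generator):
    """Cq for one well at expected copy number *lam*, or ``None`` for no signal."""
    if lam <= 0:
        return None
    copies = rng.poisson(lam)
    if copies == 0:
        return None
    cq = model.intercept_cq - model.slope * math.log10(copies)
    if model.sigma_cq > 0:
        cq += rng.normal(0.0, model.sigma_cq)
    return max(cq, 1.0)


def _control_lambda(assignment, assays, matrix, controls, genome_sizes) -> float:
    """Expected copies in a positive-control well (0.1% GMO / 25-copy level)."""
    ctrl = controls[assignment.assay]
    assay = assays[assignment.assay]
    if assay.category is AssayCategory.ENDOGENOUS:
        # endogenous target: the full 50 ng of the material's crop DNA
        return dna_copies(1.0, genome_sizes[ctrl.crop])
    if ctrl.kind == "virus":
        return 25.0
    return float(copies_per_reaction(DNA_MASS_NG, 0.001, genome_sizes[ctrl.crop]))


def simulate_run(
    compositions: list,
    layout: PlateLayout,
    matrix: SpecificityMatrix,
    cq_model: CqModel | None = None,
    seed: int | None = None,
    assays: dict | None = None,
    genome_sizes: dict | None = None,
    controls: dict | None = None,
    ntc_contamination: dict | None = None,
) -> list:
    """Simulate every assigned well of *layout*; returns (plate, well, cq) tuples.

    Fully reproducible from *seed* (falls back to ``cq_model.seed``).  Positive
    controls are simulated from their assigned materials at the 0.1%/25-copy
    level; no-template controls stay negative unless *ntc_contamination* maps
    an assay to an expected copy number (contamination scenario).
    """
    cq_model = cq_model or CqModel()
    assays = assays or load_assays()
    genome_sizes = genome_sizes or load_genome_sizes()
    controls = controls or load_positive_controls()
    by_sample = {c.sample_id: c for c in compositions}
    if len(by_sample) != len(compositions):
        raise ValueError("duplicate sample_id in compositions")
    if len(by_sample) < layout.n_samples:
        missing = sorted(set(range(1, layout.n_samples + 1)) - set(by_sample))
        raise ValueError(f"compositions missing for sample(s) {missing}")
    rng = np.random.default_rng(cq_model.seed if seed is None else seed)
    rows = []
    for a in layout.assignments:
        if a.role is WellRole.SAMPLE:
            lam = _well_lambda(by_sample[a.sample_id], a.assay, assays, matrix, genome_sizes)
        elif a.role is WellRole.POSITIVE_CONTROL:
            lam = _control_lambda(a, assays, matrix, controls, genome_sizes)
        else:
            lam = float((ntc_contamination or {}).get(a.assay, 0.0))
        rows.append((a.plate_index, a.well, simulate_well(lam, cq_model, rng)))
    return rows


def write_cq_table(rows: list, path) -> None:
    """Write simulated wells in the long format the calling module consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["plate", "well", "cq"])
        for plate, well, cq in rows:
            writer.writerow([plate, well, "Undetermined" if cq is None else f"{cq:.3f}"])


def load_scenario(path) -> list:
    """Read sample compositions from a YAML scenario file.

    Layout::

        samples:
          1: {background: soy}
          2: {background: maize, events: {"MON89034 maize": 0.10}}
          3: {background: soy, unknown_elements: {"Cry1F": 0.05}}
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = []
    for sid, entry in sorted(doc["samples"].items()):
        out.append(
            SampleComposition(
                sample_id=int(sid),
                crop_background=entry["background"],
                events=dict(entry.get("events", {})),
                contamination=dict(entry.get("contamination", {})),
                unknown_elements=dict(entry.get("unknown_elements", {})),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bundled end-to-end scenarios with known ground truth


@dataclass(frozen=True)
class Fixture:
    name: str
    compositions: tuple
    label_mode: str
    event_results: dict  # entered after screening, as the workflow prescribes
    expected: dict  # ground truths the scenario is constructed to exhibit


_FIXTURES = {}


def _register(fx: Fixture) -> None:
    _FIXTURES[fx.name] = fx


_register(
    Fixture(
        name="non_gmo_soy",
        compositions=(SampleComposition(1, "soy"),),
        label_mode="non_gmo_labelled",
        event_results={},
        expected={
            "calls": {"Soy Lec": "D", "Plant actin": "D", "P-35S": "ND", "T-nos": "ND"},
            "candidates": [],
            "unknown_gmo_indicated": False,
        },
    )
)

_register(
    Fixture(
        name="mon89034_mon810_masking",
        compositions=(
            SampleComposition(
                1, "maize",
                events={"MON89034 maize": 0.10, "MON810 maize": 0.05},
            ),
        ),
        label_mode="gmo_labelled",
        event_results={"MON89034 maize": "detected"},
        expected={
            "calls": {
                "Maize HMG": "D", "P-35S": "D", "P-FMV": "D", "T-nos": "D",
                "Cry1A(b)": "D", "Cry1A.105": "D", "Cry2Ab2": "D", "I-rAct1": "D",
            },
            "candidates_include": ["MON89034 maize", "MON810 maize"],
            "unknown_gmo_indicated": False,
            "workflow_status": "complete",
            "masked_includes": ["MON810 maize"],
        },
    )
)

_register(
    Fixture(
        name="unknown_gmo",
        compositions=(
            SampleComposition(
                1, "soy",
                events={"GTS 40-3-2 soy": 0.05},
                unknown_elements={"Cry1F": 0.05},
            ),
        ),
        label_mode="gmo_labelled",
        event_results={"GTS 40-3-2 soy": "detected"},
        expected={
            "calls": {"Cry1F": "D", "P-35S": "D", "ctp4/CP4-epsps": "D"},
            "candidates_include": ["GTS 40-3-2 soy"],
            "unknown_gmo_indicated": True,
            "workflow_status": "unknown_gmo",
            "unexplained_includes": ["Cry1F"],
        },
    )
)

_register(
    Fixture(
        name="trace_contamination",
        compositions=(
            SampleComposition(
                1, "cotton",
                events={"MON1445 cotton": 0.5},
                contamination={"MON531 cotton": 0.0005},
            ),
        ),
        label_mode="gmo_labelled",
        event_results={"MON1445 cotton": "detected", "MON531 cotton": "detected"},
        expected={
            # ~10 copies of MON531 put Cry1Ab/Ac in the late-Cq suspect window
            "calls": {"P-35S": "D", "P-FMV": "D", "nptII": "D", "Cry1Ab/Ac": "S"},
            "candidates_include": ["MON531 cotton"],
            "unknown_gmo_indicated": False,
        },
    )
)


def fixture_names() -> list:
    return sorted(_FIXTURES)


def make_fixture(name: str) -> Fixture:
    """A bundled scenario with its expected downstream truths."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}") from None
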