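# Methods

## The screening model

The package encodes a matrix-approach GMO screen: a sample is tested with 32
TaqMan qPCR methods — 7 endogenous taxon assays (soy Lec, maize HMG, canola
FatA, rice SPS, sugar beet GS, wheat Wx-1, and plant actin as an all-species
DNA-quality control), 24 element/construct assays and one CaMV assay — and the
combination of detected targets is interpreted against an experimentally
determined specificity matrix over 60 GMO events in seven crops.

A matrix cell takes one of six states. `+` (detected) and `+*` (detected
through sequence similarity) are *real signals*: they make an assay part of an
event's detectable footprint, for both candidate prediction and element
explanation; `+*` additionally propagates a cross-reaction annotation. `X`
(element present but sequence-divergent) never fires and therefore contributes
nothing to candidacy or explanation — it is carried as an annotation only.
`(+)` (expected positive, unverified for lack of reference material) is
non-binding: a clean ND on such an assay never excludes the event, and it can
explain a detected element only with an explicit "unverified" downgrade. Empty
cells (expected negative, unverified) are treated as negative.

### Candidate prediction

Strict mode (default): an event is "possibly present" iff its crop gate passes
and *every* assay in its detectable footprint was called D or S. The strategy
is built on a complete 32-assay screen, where a clean ND on an expected element
is strong evidence of absence; strictness is what makes the candidate lane
informative. Lenient mode (one supporting detection suffices) exists for
degraded samples. Suspect (S) calls count as detected in both modes — the
conservative choice with respect to missing an unauthorised GMO. Crops whose
taxon assay is ND have their events excluded (with the reason recorded); cotton
and potato have no taxon assay among the 32 and always bypass the gate. Events
with an empty detectable footprint ("zero coverage", seven in the bundled
matrix) can never be ruled in or out by screening and are returned under
`always_test` whenever their crop is present or ungated.

### Explanation and the unknown-GMO indicator

After event-specific testing, each detected non-endogenous assay is *explained*
if at least one confirmed event carries it as `+`/`+*`. Unexplained assays
whose targets also occur in donor organisms (nptII, T-g7/T-ORF1, T-E9, the
rice actin promoter and intron, CaMV) receive a softened `donor_caveat`
status; they still count toward the indicator, because a donor-organism origin
is a possibility, not an explanation. The unknown-unauthorised-GMO indicator
fires exactly when unexplained (or donor-caveat) detections remain *and* no
untested candidates are left — as long as candidates remain untestable
explanations, the workflow demands those tests instead. CaMV positivity
additionally annotates any P-35S detection as possibly virus-derived.

### Masking

An absent event is *maskable* by a set of confirmed events when its non-empty
detectable footprint is contained in their union: its presence would change no
screening call. The check is a direct subset test over the matrix (and is
verified in the tests against an exhaustive oracle). The canonical case: after
confirming MON89034 (P-35S, P-FMV, T-nos, Cry1A(b), Cry1A.105, Cry2Ab2,
I-rAct1), MON810 (P-35S, Cry1A(b)) is invisible. Stacked events produce the
union pattern of their components; the engine never claims stack
identification and only emits a similar-Cq hint as an annotation when more
than one event is confirmed.

### Workflow modes

GMO-labelled samples stop once every detected element is explained (so some
authorised events, like the masked MON810, are deliberately never tested);
otherwise the remaining candidates are listed, and when none remain the
unknown-GMO indication demands orthogonal identification (e.g. sequencing).
Non-GMO-labelled samples must test *every* candidate, and every confirmed
event carries a "quantify against the 0.9% labelling threshold" action;
quantification itself is out of scope.

## Calling rules

The thermocycler runs 45 cycles; Cq values are consumed as exported (baseline
and threshold setting are upstream). Defaults, all configurable in
`CallingConfig`:

| parameter        | default | unit   | rationale                                   |
|------------------|---------|--------|---------------------------------------------|
| `max_cycles`     | 45      | cycles | the run length                              |
| `detect_cq_max`  | 45      | cycles | amplification anywhere within the run counts |
| `suspect_cq_min` | 34      | cycles | observed onset of trace-contamination signals (Cq 34–40) |

Both replicates amplified at or below `detect_cq_max` → **D**, unless both fall
in the late window (`suspect_cq_min`, `detect_cq_max`] → **S** with a late-Cq
note; neither amplified → **ND**; discordant replicates → **S**. The underlying
protocol never states a numeric D/ND/S rule — these defaults are artifact
decisions, documented as such. Single-replicate calls are computed from the one
available well and flagged. Positive sensitivity controls (0.1% GMO or 25
copies per assay per run) must amplify and water controls must not; failing
assays keep their sample calls but carry an `invalid-run` note, and
interpretation refuses them without an explicit override.

## Copy arithmetic

`copies_per_reaction(mass_ng, fraction, 1C_pg) = floor(mass_ng · 1000 ·
fraction / 1C_pg)`. Floor rounding reproduces the protocol's three printed
control levels exactly (44 soy / 18 maize / 43 canola at 50 ng, 0.1%). The
1C values 1.13, 2.725 and 1.15 pg are the protocol's own; rice 0.50, cotton
2.33, potato 0.85, sugar beet 0.714 and wheat 17.33 pg are standard plant
genome-size compilation values needed only by the simulator. True copy numbers
additionally depend on zygosity, which the whole strategy (and this package)
deliberately ignores.

## The synthetic-run generator

The simulator emulates what the run measures, not PCR mechanism. Per well:
expected copies λ are computed from the sample composition with the arithmetic
above (per contributing event; `X` cells contribute zero); the realised copy
number is Poisson(λ) — the dominant stochastic effect near the detection
limit; amplification is all-or-nothing at ≥ 1 copy (the methods' verified LODs
below 20 copies justify near-single-copy sensitivity); and
Cq = 40 − 3.32·log₁₀(copies) + N(0, σ²), i.e. Cq 40 at one copy and perfect
doubling, σ defaulting to 0 (library) or 0.15 cycles (CLI). Positive-control
wells are simulated from their assigned materials at the 0.1%/25-copy level,
water controls stay negative unless a contamination scenario is enabled. Runs
are fully reproducible from a seed.

Compositions may include an `unknown_elements` mapping (assay → mass fraction)
that injects a screening target with no catalogued event behind it — this is
how an unknown unauthorised GMO enters a synthetic sample, and what the
bundled `unknown_gmo` fixture uses.

What the generator does **not** model: PCR efficiency differences, inhibition,
extraction yield and fragmentation, zygosity, fluorescence curves, and
instrument-specific Cq estimation. Passing tests therefore demonstrate the
correctness of the calling and inference logic under a clean, analyzable null —
not robustness to every failure mode of real feed matrices.

## Bundled data and transcription caveats

The assay catalogue (primers, probes, final concentrations), the plate
distribution (4 methods × 8 plates), the positive-control assignments, the
reference-material catalogue and the specificity matrix ship as TSV files under
`gmoscreen/data/` with provenance notes in their headers. The published
rendering of the specificity table is typographically fragile, so the loader
cross-validates the transcription against hard prose anchors at import time
(`load_bundled_matrix`): the MON89034/MON810 element sets and subset relation,
and exactly seven zero-coverage events. `validate-data` exposes the same gate
on user-edited files; a failing anchor is a packaging/data error, never a
sample property. Cells that could not be transcribed unambiguously are encoded
with the unverified states. Authorisation statuses are configuration, not
measurement: the shipped file defaults every event to `unknown` (except
DAS59132/E32, documented as unauthorised), and candidate ordering ranks
severity as unauthorised > unknown > expired > low-level (619/2011) >
authorised — a reporting convenience, not a protocol rule.

One shipped-data deviation: the protocol text names MON810 maize as the
positive-control material for the CP4-epsps and ctp4/CP4-epsps methods, but
MON810 carries neither target; the control table assigns GTS 40-3-2 soy (which
carries both) instead.

## Problem sizes and numerical choices

The property tests run the engine on randomised profiles (1000 for explanation
monotonicity), recover 1–3 implanted events per sample across 200 simulated
samples at ≥ 25 copies with σ = 0, and calibrate Poisson dropout on 1000 wells
against exp(−λ) within three standard errors — sizes chosen so the full suite
completes in seconds while keeping the binomial checks well-powered. Ties in
candidate ordering are broken by (authorisation severity, supporting
detections desc, name); well blocks are filled column-major in fixed sample
order, making layouts byte-identical across runs.

## Known limitations

- The matrix covers the 60 events with available reference materials at the
  time of transcription; unlisted events are invisible to candidacy (though
  their elements still surface as unexplained detections).
- Event quantification (0.9% / 0.1% compliance) is intentionally out of scope;
  the workflow only emits the requirement.
- No in-silico PCR: specificity is data, not prediction from primer sequences.
- Stacked events are indistinguishable from mixtures by design of the method.
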