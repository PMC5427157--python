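# gmoscreen

Matrix-approach qPCR screening of feed and food samples for authorised and
**unauthorised GMOs** — as a tested Python library plus command-line tool.

## The problem

EU enforcement laboratories must establish which GMO events a sample contains,
including events for which no authorisation exists. Testing every catalogued
event with its event-specific PCR is impractical, so routine laboratories first
screen with a battery of *element* and *construct* qPCR methods (promoters such
as P-35S and P-FMV, terminators such as T-nos, coding sequences such as
*cry1A(b)* or *CP4-epsps*, and construct junctions such as ctp4/CP4-epsps) and
use a **specificity matrix** — which assays fire on which event, determined
experimentally against certified reference materials — to infer the candidate
events. For GMO-labelled samples an *extended* screen pays off twice: fewer
event tests are needed, and any detected element that no identified event can
account for is an **indication of an unknown unauthorised GMO**.

`gmoscreen` implements that whole screening strategy:

- a validated, machine-readable catalogue of the 32 screening methods
  (7 endogenous taxon assays, 24 element/construct assays, 1 CaMV assay),
  the 60-event specificity matrix with its six cell states
  (`+`, `-`, `X`, `+*`, `(+)`, empty), reference materials and positive
  sensitivity controls;
- the deterministic eight-plate, 96-well layout (11 samples × 2 isolations
  + positive control + water control for each of 4 methods per plate);
- duplicate-well Cq calling into **D / ND / S** (detected / not detected /
  suspect) with run-control validation;
- the inference engine: crops present, candidate events ("possibly present GMO
  event" lane), element explanation after event-specific testing, masking
  analysis, and the unknown-unauthorised-GMO indicator, in GMO-labelled or
  non-GMO-labelled mode;
- a synthetic-run generator (Poisson single-copy dropout, log-linear Cq model)
  so the entire pipeline is testable end to end without instrument data;
- sample sheets and a cross-sample summary table (LIMS export), and a CLI.

## Worked example

A maize sample screens positive on exactly P-35S, P-FMV, T-nos, Cry1A(b),
Cry1A.105, Cry2Ab2 and I-rAct1 (plus the maize taxon and plant-actin assays).

```python
import gmoscreen as g
from gmoscreen import inference

matrix, assays = g.load_bundled_matrix(), g.load_assays()
calls = {a: "ND" for a in assays}
for a in ["P-35S", "P-FMV", "T-nos", "Cry1A(b)", "Cry1A.105", "Cry2Ab2",
          "I-rAct1", "Maize HMG", "Plant actin"]:
    calls[a] = "D"

interp = inference.interpret_sample(
    1, calls, matrix, assays,
    event_results={"MON89034 maize": "detected"}, label_mode="gmo_labelled",
)
print(interp.candidate_report.candidate_names)
print(interp.workflow.status, interp.explanation_report.unknown_gmo_indicated)
print(interp.masked_events)
```

prints

```
['MON89034 maize', 'MON810 maize', '3272 maize', '5307 maize', 'MIR604 maize']
complete False
['3272 maize', '5307 maize', 'MIR604 maize', 'MON810 maize']
```

Both MON89034 and MON810 are candidates (MON810's whole detectable footprint —
P-35S and Cry1A(b) — lies inside the detected set). Confirming MON89034 alone
explains **all seven** detected elements, so in GMO-labelled mode the workflow
is `complete`: MON810 is never tested, and the masking report makes the
consequence explicit — MON810 (and the T-nos-only events) could be present
without changing a single screening call. Had an element remained unexplained
after all candidates were tested, the unknown-GMO indicator would have fired
instead.

The sensitivity-control arithmetic is exposed directly: at 50 ng DNA per well,
a 0.1% GMO control corresponds to

```python
g.copies_per_reaction(50, 0.001, 1.13)   # 44 copies (soy,   1C = 1.13 pg)
g.copies_per_reaction(50, 0.001, 2.725)  # 18 copies (maize, 1C = 2.725 pg)
g.copies_per_reaction(50, 0.001, 1.15)   # 43 copies (canola, 1C = 1.15 pg)
```

## Command line

```sh
gmoscreen validate-data                        # check the shipped tables + anchors
gmoscreen layout --samples 11 --out platemap.tsv
gmoscreen simulate --scenario scen.yaml --layout platemap.tsv --seed 3 --out cq.tsv
gmoscreen call --cq cq.tsv --layout platemap.tsv --out calls.tsv
gmoscreen infer --calls calls.tsv --event-results er.tsv --out interp.json
gmoscreen report --calls calls.tsv --event-results er.tsv --out summary.tsv --xlsx summary.xlsx
```

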