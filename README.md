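# pulsefate

Single-cell quantification of cell cycle-dependent responses to pulsed
platinum chemotherapy in lung adenocarcinoma cultures: clonal-colour
tracking, FUCCI-based fate classification, DNA-damage focus counting and
size gating — all driven by a synthetic-data engine with exact ground
truth, so every stage is testable without microscope data.

## Who this is for

Labs that follow drug-treated cells by time-lapse microscopy and need
reproducible, scriptable versions of the common quantification steps:

- **Clonal outgrowth** (`pulsefate.clonal`). Cells co-transduced with red,
  green and blue lentiviral vectors carry a heritable colour code. The
  pipeline mirrors the standard image workflow — rolling-paraboloid
  background subtraction, disc mean filtering, regional-maximum cell
  detection, disc-ROI sampling of the raw image, extreme-value filtering —
  then quantises each cell's mean (R, G, B) into 8x8x8 = 512 fixed-range
  colour classes, keeps the 64 most represented colours, and calls a
  *positive clone* for every colour exceeding 0.1% of the population.
  Diversity is summarised as richness, Shannon index H = -sum p_i ln p_i
  and evenness H / ln(richness).
- **Single-cell fate ontology** (`pulsefate.fates`). FUCCI traces
  (mCherry-hCdt1 red = G1, mVenus-hGeminin green = S/G2/M, overlap =
  G1/S) are thresholded into per-frame phase calls with run-length
  hysteresis. Divisions are annotated NEBD/anaphase events or a
  morphology proxy (>= 40% one-frame nuclear-area drop with a green
  reset). Each 72 h track is classified as PROLIF (>= 2 divisions),
  SINGLE_DIV, G2_EXIT (prolonged S/G2 arrest resolved into a G1-like red
  state without mitosis), G1 arrest before/after mitosis, death
  before/after mitosis, or persistent S/G2 arrest.
- **DNA-damage and replication foci** (`pulsefate.foci`). Foci are
  connected components above a per-nucleus robust threshold
  (median + k * 1.4826 * MAD), with areas in um^2, the <5 / 5-15 / >15
  foci-per-cell classes, and S sub-staging from the PCNA pattern
  (dispersed small = early S, mid-radial annulus = mid S, few large
  peripheral = late S).
- **Stable/enlarged gating** (`pulsefate.morpho`). The gate is a high
  quantile (default 97.5%) of the untreated-control nuclear-area
  distribution; treated cells above it are ENLARGED.
- **Synthetic ground truth** (`pulsefate.synthetic`). Generators for all
  of the above: Poisson-integration/lognormal-expression colour mixes and
  rendered 16-bit images; scripted FUCCI trajectories realising exact
  per-fate allocations; a phase-structured population simulator whose
  untreated steady state holds 70-80% of cells in G1 and whose
  p53-proficient pulse response resolves into a >90% red population by
  day 7; and focus-kinetics series (~100-focus bursts after G1 exposure,
  <20 under undamaged replication, G1 nuclear bodies up to 5 um^2).

## Worked example

```python
from pulsefate.synthetic import (LentiMixModel, make_lenti_population,
                                 make_fucci_cohort, reference_allocations)
from pulsefate import clonal
from pulsefate.fates import classify_fate, aggregate_cohort

# clonal colours in a 10,000-cell untreated control
model = LentiMixModel(seed=7)
pop = make_lenti_population(model, 10_000)
recs = pop.rename(columns={"r": "mean_r", "g": "mean_g", "b": "mean_b"})
assigned, clones = clonal.analyze_rgb_table(recs, low_quantile=None,
                                            high_quantile=None)
print(f"positive clones: {clones.n_positive}")
print(f"top-64 coverage: {clones.coverage:.3f}")

# fates of 50 cells pulsed in G1 (release from palbociclib)
tracks = make_fucci_cohort(reference_allocations()["palbo_G1"], n=50, seed=11)
calls = [classify_fate(t) for t in tracks]
table, divisions = aggregate_cohort(calls)
print(table.to_string(index=False))
```

prints

```
positive clones: 64
top-64 coverage: 1.000
condition       fate  count  fraction
      all    G2_EXIT     40      0.80
      all SINGLE_DIV      7      0.14
      all SG2_ARREST      3      0.06
```

i.e. the calibrated control resolves into 64 positive clonal colours, and
a G1-pulsed cohort is dominated by G2-exit, with 7/50 cells completing a
single division and none dividing twice.

A command-line layer wraps the same functions:
`pulsefate simulate fucci --condition thy_lateS --out cohort/`,
`pulsefate fates classify --tracks cohort/tracks.csv --events
cohort/events.csv --out fates/`, and likewise `pulsefate clones analyze`,
`pulsefate foci analyze`, `pulsefate size gate`.

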