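# quiescore

Cell-state scoring for quiescence and senescence from a three-marker panel.

Non-cycling (G0) states are not one condition but a continuum: cells enter
reversible quiescence through transitional stages, and after irreparable
stress they drift into senescence through transitional stages of their own.
`quiescore` implements the marker-combination rule that resolves these
stages from three per-cell readouts — the proliferation marker **Ki67**,
phosphorylated ribosomal protein S6 (**pRPS6**, a proxy for active protein
synthesis), and **SA-β-gal** activity (a lysosomal stress/senescence
marker) — and wraps it in a complete, reproducible analysis pipeline for
bench scientists and image-analysis developers working with mesenchymal
stromal cells or similar cultures.

## The classification rule

Each cell receives three binary calls; the triple maps onto seven states:

| Ki67 | pRPS6 | SA-β-gal | state |
|------|-------|----------|-------|
| + | + | − | cycling |
| + | − | − | G0-entry (shutting down protein synthesis on the way into quiescence) |
| − | − | − | G0 (quiescent) |
| − | + | − | G0-alert (protein synthesis resumed before Ki67 re-expression) |
| + | + | + | stressed (acute, potentially recoverable) |
| + | − | + | pre-senescent (early route) |
| − | − | + | pre-senescent (late-entry route) |
| − | + | + | senescent |

The package provides:

* `phenotypes` / `gating` — the classification rule itself, plus
  reproducible positivity gating: a two-component Gaussian mixture on log
  intensity thresholded at the equal-density (posterior 0.5) point, with a
  robust negative-control fence for markers that have no positive
  population.
* `presets` / `simulate` / `render` — synthetic per-cell tables,
  DNA-content event lists and 4-channel pseudo-micrographs for two
  built-in designs (serum starvation/re-supplementation: AP, S1–S3, Q,
  T1–T3, P; H₂O₂ stress: AP, SEN1–SEN5), anchored to published
  time-course percentages.
* `imaging` — DAPI nucleus segmentation (Otsu + distance-transform
  watershed) and per-cell intensity measurement.
* `dna` — DNA-content histogram simulation and a constrained-mixture fit
  (`DnaMixtureModel(...).fit()` → results object with `summary()`)
  recovering G1/G0, S and G2/M fractions.
* `stats` — per-timepoint proportions with Wilson intervals, the
  ≥500-cells counting rule, and reference-timepoint t-tests with
  Bonferroni correction.
* a `quiescore` CLI (`simulate | quantify | classify | report | all`).

## Worked example

```python
from quiescore import run_timepoint, Phenotype

point = run_timepoint("Q", n_cells=2000, seed=1)  # simulate, gate, classify, count
for s in Phenotype:
    if point.percentage(s) > 0:
        print(f"{s.value:12s} {point.percentage(s):5.1f}%")
```

```
cycling        2.5%
g0_entry      36.5%
g0            47.8%
g0_alert      13.2%
pre_senescent  0.1%
```

At the quiescence endpoint Q nearly half the population is in full G0 and
cycling cells have almost vanished — the simulated experiment recovers the
preset's anchored composition (47.9% G0, 2.7% cycling) to within sampling
and gating error; the stray 0.1% pre-senescent calls are the false-positive
rate of the SA-β-gal fence gate.

The DNA-content side, statsmodels-style:

```python
from quiescore import build_preset, simulate_dna_content
from quiescore.dna import DnaMixtureModel

hist = simulate_dna_content(build_preset("AP").cycle_fractions,
                            n_events=5000, cv=0.05, seed=1)
print(DnaMixtureModel(hist).fit().summary())
```

```
DNA-content mixture fit
======================================
events                  5000
G1 peak location      100.06
shared CV             0.0503
G1/G0 fraction        0.7358
S fraction            0.1821
G2/M fraction         0.0822
residual RMS           4.709
```

The asynchronously proliferating preset (73.0% G1/G0, 19.0% S, 8.0% G2/M)
is recovered from 5000 simulated events to within ~1 percentage point.

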