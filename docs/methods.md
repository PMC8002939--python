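# Methods

## The classification model

The core of the package is a deterministic, total function from the
binary triple (Ki67, pRPS6, SA-β-gal) to seven cell states.  SA-β-gal
splits the population into a healthy branch (cycling, G0-entry, G0,
G0-alert) and a stress branch (stressed, pre-senescent, senescent); within
each branch Ki67 × pRPS6 resolves the stages.  Two triples — Ki67+/pRPS6−
and Ki67−/pRPS6−, both SA-β-gal+ — map to the single pre-senescent state;
the route is retained as a sub-code (`early` / `late_entry`) because the
two represent different moments of the entry into senescence (Ki67 still
detectable vs. already lost).  The labels are turning points on a
continuum, not fixed compartments: the model assumes nothing about
dynamics between timepoints and none is simulated.

## Positivity gating

Published percentages of "positive" cells are produced by visual scoring.
To make that decision reproducible the package fits a two-component
Gaussian mixture to the log intensities of each marker across cells and
places the threshold where the two weighted component densities are equal
(the posterior-0.5 boundary, located by bracketing + Brent root-finding
between the component means).  A call is `intensity > threshold`; ties
are negative, the conservative choice that avoids inflating positivity.

Degeneracy is decided by two checks: the 2-component fit must beat a
1-component fit on BIC (a plain Gaussian split in half by EM passes any
naive separation test, because each half receives a small scale), and the
component separation must exceed 1.0 pooled standard deviation.  A
degenerate fit raises a gating failure.  The pipeline's fallback for a
unimodal marker is a robust negative-control fence — median + 3·1.4826·MAD
on log intensity — the standard cytometry rule that calls only upper
outliers positive.  A median-quantile fallback was considered and
rejected: a marker with no positive population (SA-β-gal in every healthy
timepoint) would have half the population called positive, which is
scientifically meaningless.  Quantile and fixed-threshold gating remain
available and configurable.

## Condition presets and the completion rule

Each of the 14 timepoints (AP, S1–S3, Q, T1–T3, P; SEN1–SEN5) carries a
full state-proportion vector, per-marker intensity parameters and paired
cycle fractions.  Published percentages are anchored exactly:

* healthy design — AP: cycling 42.0%, G0 16.0%; Q: cycling 2.7%,
  G0 47.9%, G0-alert 13.3%; T1: G0-alert 52.4%; P: cycling 36.9%;
* stress design — SA-β-gal-positive totals 54.0% (SEN1), 30.0% (SEN2),
  63.0% (SEN5);
* cycle fractions — AP: 73.0% G1/G0, 19.0% S; S1: 4.3% S; P: 15.3% S.

Everything else is filled by a deterministic completion rule: anchored
values are fixed; each unanchored state gets a provisional weight by
linear interpolation of its own anchors over the timepoint index
(nearest-anchor extrapolation at the ends; a state never anchored in the
design gets the uniform share); provisional weights are rescaled to the
unanchored mass.  In the stress design the anchored quantity is the
SA-β-gal-positive *total*; its split across stressed/pre-senescent/
senescent, and the split of the negative remainder, are authored constants
chosen to follow the qualitative time course (acute stress dominating at
SEN1 and decaying, senescence programs rising through SEN4–SEN5).
Unanchored entries are plausible placeholders, not measurements, and are
deliberately excluded from every quantitative check.

One internal inconsistency had to be resolved.  At Q the anchored marker
percentages force G0-entry = 36.1% (the healthy states partition unity in
a generative model), so G0-entry + G0 + G0-alert = 97.3% — but the
measured G1/G0 peak at Q is 93.5%.  The original counts were made
per-marker in different microscope fields and need not partition unity;
a generative preset must.  The package keeps the marker anchors and the
constraint that G0-like states fit inside the G1/G0 peak, and sets Q's
cycle fractions to (97.8% G1/G0, 0.4% S, 1.8% G2/M) — consistent with an
essentially empty S-phase at full starvation.  The Q cycle fractions are
not used in any anchored comparison.

## Intensity model

Per marker, negative and positive populations are log-normal with a
2.0 natural-log separation at 0.35 log-scale (≈5.7σ apart) — clean enough
that a human scorer would agree with the gate, which is the regime the
published percentages were produced in.  Separation and scale are
configurable for robustness experiments; at the default the full
generate → gate → classify chain reproduces each anchored percentage to
within sampling error (binomial SE ≈ 1.1 pp at n = 2000), and at zero
noise exactly (multinomial error only).  DAPI is a single log-normal
population (location 5.3, scale 0.20): DNA content plays no role in the
marker classification.

## Rendering and image quantification

Fields default to 1024×1024 px at 0.65 µm/px with elliptical nuclei of
5–9 µm radius, placed by rejection sampling (centre distance ≥ 0.95 of
the summed radii, so slight touching occurs but packing failures raise a
layout error).  DAPI and Ki67 fill the nucleus; pRPS6 is a perinuclear
band (extending 1 px into the nucleus so blurring does not hollow its
inner edge); SA-β-gal is a wider flat cytoplasmic disc standing in for
the chromogenic precipitate on an inverted-brightfield optical-density
channel.  Channels are blurred (σ 0.6 px) and carry Poisson shot noise
plus Gaussian read noise (σ 2).

Segmentation is Otsu thresholding of the smoothed DAPI channel followed
by a distance-transform watershed and a size filter; border-touching and
size-outlier nuclei are flagged and excluded from counting, preventing
biased partial measurements.  Per-cell intensities are medians — over a
1-px-eroded nucleus mask (Ki67, DAPI) or a 3-px annulus (pRPS6,
SA-β-gal) — with the per-channel background (median of non-cell pixels)
subtracted and floored at ε = 10⁻³.  The median was chosen over the mean
because it is insensitive to boundary partial-volume pixels and to
spill-over from a neighbour's cytoplasmic signal; at the default geometry
the render → segment → measure → gate → classify round trip agrees with
generator truth for ≥95% of unflagged cells.

What the synthetic images do **not** emulate: uneven illumination,
chromatic aberration, out-of-focus cells, apoptotic debris, confluent
sheets, or stain-to-stain spectral bleed-through.  Passing round-trip
tests therefore demonstrate that the measurement chain is self-consistent,
not that it is robust to every real-microscopy artefact.

## DNA-content model and fit

Events follow the classic single-cell DNA distribution: G1/G0 ~
N(μ, cv·μ), G2/M ~ N(2μ, 2cv·μ) (ploidy doubling, shared cv), S ~
Uniform(μ, 2μ) convolved with the same measurement kernel, binned over
[0, 3μ] in 240 bins (μ = 100 arbitrary units).  The fit is least squares
of the same shape against the binned histogram with five free parameters
(μ, cv, three non-negative phase amplitudes normalised to fractions);
the G2/M-at-2μ constraint and the shared cv keep the problem well-posed
at 5000 events.  Initialisation takes μ from the smoothed histogram mode
and the amplitude split from the mass within ±25% of μ and 2μ; a mode in
the top third of the axis (no room for a G2/M peak) raises a fit error.
S-phase is a single broadened rectangle rather than a multi-compartment
model — sufficient for fraction recovery, which is the only quantity
used.  Doublets, debris and sub-G1 apoptotic events are not modelled.
Recovery is within 0.5 pp of the generating fractions on the analytic
(noise-free) histogram and within 2 pp per fraction on simulated event
lists at n = 5000, cv = 0.05.

## Time-course statistics

Percentages are computed per timepoint from pooled classified cells; the
≥500-cells counting floor is enforced as a flagged verdict (under-powered
points are reported, never silently dropped).  Single-proportion
uncertainty uses the Wilson score interval.  Timepoint comparisons mirror
the donor-replicate design (three donors by default): a pooled-variance
two-sample t-test of each timepoint against the chosen reference on
donor-level percentages — not pooled cells, which would overstate the
effective n — with Bonferroni correction over the family of non-reference
timepoints and the usual star convention (p < 0.05/0.01/0.001).  An
omnibus one-way ANOVA gate before the pairwise tests is implemented but
off by default, since published figure captions star pairwise
comparisons directly.  A mixed-effects variance model for continuous
outcomes is out of scope: no model structure is specified for it.

## Problem sizes and seeds

Default working scales — 2000 cells per timepoint for marker
percentages, 5000 events at cv 0.05 for DNA fits, 3 fields of ≤60–150
cells for image round-trips — were chosen so every anchored quantity's
sampling error is several times smaller than the 2-pp comparison band.
All randomness flows from a single master seed through fixed-offset
per-timepoint streams (`numpy` `default_rng` seed sequences), so any
timepoint can be regenerated in isolation and rendered tables are
byte-identical across reruns.

## Known limitations

* Unanchored preset entries (e.g. the G0-entry curve, the SEN3/SEN4
  splits) are deterministic placeholders; conclusions about those
  sub-populations cannot be drawn from this package.
* The gating model assumes log-normal intensity populations; heavily
  skewed or multimodal real stains may need the quantile or fixed gate.
* The renderer's simplified cell geometry means segmentation performance
  on real micrographs will be worse than the round-trip figures suggest.
* No apoptosis, no doublets, no inter-timepoint dynamics.
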