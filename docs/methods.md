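# Methods

## Signal model and extraction

A transit is modelled as `v(t) = V0 − g(t)·[ΔB + ΔW·m(t)] + ε(t)`: a
unit-peak Gaussian envelope `g` (σ = duration/6, so the nominal duration
spans ±3σ) scaling a constant body occlusion ΔB plus a wing occlusion
ΔW·m(t), with `m` a nonnegative periodic waveform normalised to peak 1.
`m` is built as a cosine fundamental plus aligned harmonics (defaults: two
harmonics at relative amplitudes 0.5 and 0.25), shifted and scaled so its
minimum over a period is 0 — i.e. at some stroke phase the wings occlude
nothing. The generator refuses non-physical specs (total depth exceeding
the baseline, sampling below the Nyquist rate of the highest harmonic).

**Detection.** The trace is smoothed (5 ms moving average) and compared to
`median × (1 − threshold)` with a 2% default threshold. Runs below
threshold are merged when separated by less than one period of the slowest
in-band wingbeat (1/10 Hz = 100 ms): a slow flapper lifts the signal above
threshold within each stroke, and without merging a single transit
fragments into per-stroke pulses. Only after merging is the 10 ms minimum
duration applied; events longer than 1 s are truncated and flagged rather
than dropped. Consequence: two genuinely distinct transits closer than
100 ms would merge — acceptable at realistic event rates.

**Baseline.** `V0` is the median of the flanking windows (half the segment
duration, ≥10 ms, each side). The flank abuts the sub-threshold transit
tail, so on noiseless synthetic data `V0` lands within a few mV of truth
rather than exactly on it; the median makes the estimate robust to drift
and to neighbouring events.

**Spectral extraction.** The segment is detrended with a degree-8
polynomial — enough flexibility to absorb a Gaussian-like envelope, far
too little to track any in-band oscillation (an in-band component
completes ≥1 cycle over any accepted segment; a degree-8 polynomial has at
most 9 extrema) — then Hann-windowed, zero-padded 4×, and transformed.
Peaks in 10–900 Hz must exceed 5× the in-band median magnitude, have
prominence 3× that median, and reach 2% of the envelope's own spectral
magnitude (the below-band maximum of the un-detrended spectrum). The last,
absolute criterion is what rejects smooth dips: a droplet's only in-band
content is the monotone shoulder of its envelope lobe plus detrending
residue, orders of magnitude below the envelope scale, whereas genuine
wing modulation is commensurate with it. The fundamental is the
lowest-frequency candidate peak such that every taller candidate lies
within 10% of an integer multiple; this keeps a 1.2×-taller second
harmonic from capturing the estimate. The peak location is refined by
quadratic interpolation on log magnitude (bias < 0.01 Hz on noiseless
tones; the round-trip tolerance of 2 Hz is dominated by envelope leakage,
not interpolation).

**Levels.** Both in-transit levels apply a 10%-minimum averaging rule to
the wing-cycle envelopes: `Vw` averages the lowest decile of per-cycle
minima (deepest occlusion), `VB` the lowest decile of per-cycle maxima
(wings edge-on, body only). Cycles are local extrema spaced ≥0.8 wingbeat
periods. Averaging the lowest decile of *raw samples* instead would mix
envelope depths across the transit and biases the wing cross-section by
~20%; the per-cycle-envelope reading reproduces closed-form cross-sections
to within 2% for ≥50 Hz wingbeats (at 25 Hz a transit holds too few cycles
for the decile to be meaningful — levels there carry a few-percent
envelope-discretisation bias). Without resolvable cycles (no modulation)
both levels fall back to the raw lowest decile and coincide.

**Cross-sections.** `σw = (V0 − Vw)/V0 × A`, `σB = (V0 − VB)/V0 × A`. The
beam area defaults to a 50.8 mm diameter flat-top circle (2026.8 mm²); σ
values scale linearly with `A`, the ratio `σw/(σw+σB)` does not — which is
why clustering uses the ratio.

## Clustering and model selection

Features are `(wingbeat frequency, wing-to-body ratio)`, each standardised
to zero mean and unit variance — raw frequency spans hundreds of Hz while
the ratio spans less than one, and unstandardised fits would be driven by
frequency alone. GMM (full covariance, 10 restarts, tolerance 1e-4 by
default) and K-means are fitted independently for k = 1..10. K-means has
no likelihood, so its BIC uses the equal-spherical-variance Gaussian
convention (pooled within-cluster variance, k−1 + kd + 1 parameters),
making the two curves comparable.

The cluster count is the knee of the BIC curve: normalise both axes to
[0, 1] and take the point farthest from the chord joining the endpoints,
with two guards — if the global minimum is at k = 1 no split helps and
there is no elbow, and the knee is only accepted at or before the global
minimum (a bend in the rising, penalty-dominated tail is not a knee). Ties
break toward smaller k. A curve nowhere farther than 0.05 (normalised)
from the chord is flagged as elbow-free. The knee rule presumes the
successive BIC drops are of comparable size; when one split dominates
(e.g. components strung along a line with one huge gap) the knee lands
early regardless of the true component count — an inherent property of
chord-based knee detection, shared by this implementation.

Events are hard-assigned by maximum posterior responsibility of the GMM at
the selected k, and clusters are relabelled 1..k by ascending mean
frequency so labels are stable across runs and seeds.

## Thermal analysis

Per cluster, events are binned into half-open `[t, t+0.5)` °C intervals
anchored at the integer grid. Events below 10 °C are omitted (insect
flight is rare there and the sparse bins fluctuate strongly), as are bins
with fewer than 20 events. The slope ± SE comes from unweighted OLS of the
bin means on bin centers; bin counts are retained so a weighted variant is
possible, but the unweighted fit is the default — refitting the five
reference (frequency, slope) pairs reproduces the published-style
coefficients only without weights. A cluster's "mean frequency" is the fit
evaluated at 20 °C, not the grand mean over all temperatures (the two
differ because event rates are temperature-weighted).

The cross-cluster model `s(f) = a f² + b f` is an unweighted least-squares
fit with no constant term: a hypothetical 0 Hz flapper has no thermal
response, so `c = 0` and the correction at the reference temperature is
exactly the identity. On the five reference pairs this yields
`a ≈ −3.60e-5`, `b ≈ 0.0372`. The correction
`f + s(f)·(T_ref − T)` uses the slope at the *measured* frequency; the
inverse shift with the same `s(f_initial)` is exact, and the quadratic has
a vertex near 516 Hz beyond which predicted slopes decline — corrections
far above ~700 Hz extrapolate outside the fitted range and negative
corrected frequencies are flagged.

## Synthetic campaign generator

Event-level campaigns draw, per event: a cluster (probability ∝ weight), a
temperature, a frequency `mean_freq_ref + slope·(T − 20) + N(0, freq_sd)`,
a ratio from a clipped normal, and a body cross-section from a lognormal
around 20 mm² (wing cross-section follows from the ratio). Temperatures
default to a uniform base over 10–38 °C re-weighted by flight activity
∝ (T − 10)⁺ (exponent 1), qualitatively emulating the near-absence of
flight below 10 °C; an optional diurnal-seasonal model generates a
minute-cadence weather series (seasonal + diurnal cycles + AR(1) noise)
over an eight-month deployment window and samples event times from it.

The default five-cluster population uses the field-calibrated means
(50.51, 100.42, 171.33, 290.71, 525.58 Hz at 20 °C) and slopes (2.02,
3.66, 5.10, 7.69, 9.63 Hz/°C), equal weights, ratio centers (0.80, 0.45,
0.35, 0.30, 0.25). Within-cluster spreads are not field-measured
quantities; they were fixed at design time to `freq_sd = 4%` of the
cluster mean and `ratio_sd = 0.008` so that the generating structure is
identifiable: the slopes × the 28 °C range make adjacent clusters overlap
intrinsically in marginal frequency, so the ratio axis must carry the
separation. With broader ratio spreads (0.02–0.05) hard assignment leaks a
fraction of a percent of events between neighbouring clusters; because a
contaminating event sits ~100 Hz from its host cluster's trend at the same
temperature, even that leakage biases binned slopes by many standard
errors. Passing recovery tests under these defaults therefore demonstrates
pipeline correctness on an identifiable population, not robustness to
heavily overlapping field data, where hard-assignment bias is a real
effect the corrected user should expect.

## Desk-scale problem sizes

Simulated campaigns use 50,000 events (tests that only need structure use
5,000–20,000), BIC sweeps in heavy tests and the acceptance script use 2
restarts at tolerance 1e-3 (library defaults remain 10 and 1e-4), and
replicate counts are 5–10 per property. These sizes were chosen so the
whole suite runs in minutes on one core while leaving every acceptance
margin wide.

## Known limitations

* No optical physics beyond additive occlusion depths (no diffraction,
  beam profile, melanisation or angular effects).
* Hard GMM assignment biases per-cluster thermal fits when clusters
  overlap; soft (responsibility-weighted) fits are not implemented.
* The correction is population-general by construction; species-specific
  thermal responses (including negative or zero slopes reported for some
  bees) are deliberately out of scope.
* Level estimation degrades below ~50 Hz wingbeat where a ≤1 s transit
  contains too few stroke cycles.
* The weather generator is a caricature (two cosines + AR noise) intended
  for schema and plumbing tests, not climate realism.
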