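# wingbeat

Analysis pipeline for optical insect-monitoring sensors: extract wingbeat
frequencies and optical cross-sections from transit signals, cluster the
insect population, quantify how each cluster's wingbeat frequency rises
with air temperature, and derive a general temperature correction.

## Who this is for

Bistatic optical (and acoustic) entomological sensors record thousands of
insect passages per day as dips in a received light intensity. The wingbeat
frequency retrieved from each dip is a workhorse feature for clustering and
coarse taxonomic sorting — but it drifts with air temperature, smearing the
clusters. This package implements the full chain from raw voltage traces to
a frequency-dependent temperature correction, plus a synthetic-data
generator so every stage can be validated against known ground truth
without field data.

## The model

An insect crossing the beam produces a transit signal with a roughly
Gaussian envelope, amplitude-modulated by the wing stroke. From the
background level `V0` and the in-transit wing/body levels `Vw`, `VB`
(each estimated by averaging the lowest 10% of the respective wing-cycle
envelope), the optical extinction cross-sections are

    sigma_w = (V0 - Vw) / V0 * A        sigma_B = (V0 - VB) / V0 * A

with `A` the beam cross-sectional area, and the beam-invariant shape
feature is the wing-to-body ratio `sigma_w/b = sigma_w / (sigma_w +
sigma_B)`. The wingbeat frequency is the fundamental of the detrended
transit spectrum (the lowest prominent peak whose taller peers are integer
multiples of it — the fundamental need not be the tallest peak).

Events are clustered in the `(frequency, ratio)` plane with a Gaussian
mixture model and K-means fitted independently; the cluster count is chosen
where the BIC-versus-k curve bends (elbow by maximal distance to chord,
k = 1..10). Per cluster, mean frequency is computed in 0.5 °C temperature
bins (observations below 10 °C omitted) and fitted linearly, giving a
thermal slope `s` in Hz/°C. Across clusters the slope grows with the
cluster's frequency; fitting `s(f) = a f² + b f` (no constant) yields the
general correction

    f_corrected = f_initial + (a f_initial² + b f_initial) (T_ref - T)

which shifts any measured frequency to its expected value at the reference
temperature `T_ref = 20 °C`.

## Worked example

```python
import dataclasses, wingbeat as wb

cfg = wb.PipelineConfig(
    clustering=wb.ClusteringConfig(restarts=2, tol=1e-3),
    simulation=dataclasses.replace(wb.CampaignSpec(), n_events=50_000),
)
res = wb.run_pipeline(cfg, seed=1)
for cid, ft in sorted(res["fits"].items()):
    print(f"cluster {cid}: {ft.mean_freq_at_ref:7.2f} Hz at 20 C, "
          f"slope {ft.slope:+.3f} +/- {ft.slope_se:.3f} Hz/C")
m = res["model"]
print(f"model: a={m.a:.4g} b={m.b:.4g}")
print("f=100 Hz at T=25 C ->", round(float(wb.correct_frequency(100.0, 25.0, m)), 2))
```

prints

```
cluster 1:   50.59 Hz at 20 C, slope +2.013 +/- 0.003 Hz/C
cluster 2:  100.39 Hz at 20 C, slope +3.659 +/- 0.006 Hz/C
cluster 3:  171.36 Hz at 20 C, slope +5.094 +/- 0.012 Hz/C
cluster 4:  290.79 Hz at 20 C, slope +7.669 +/- 0.016 Hz/C
cluster 5:  525.06 Hz at 20 C, slope +9.701 +/- 0.034 Hz/C
model: a=-3.536e-05 b=0.03697
f=100 Hz at T=25 C -> 83.28
```

The simulated campaign draws 50,000 events from a five-cluster population
(cluster means 50.5–525.6 Hz at 20 °C, thermal slopes 2.02–9.63 Hz/°C,
temperatures 10–38 °C); the pipeline re-identifies the five clusters from
the data alone, recovers each cluster's slope within a few standard errors,
and refits the quadratic correction. A measured 100 Hz event at 25 °C is
corrected to 83.3 Hz at the 20 °C reference (its thermal slope of
~3.36 Hz/°C acts over −5 °C).

The same stages are scriptable from a shell:

```bash
wingbeat simulate events --n 50000 --seed 1 --out events.csv
wingbeat cluster --events events.csv --seed 1 --out clustered.csv
wingbeat fit-thermal --events clustered.csv --out fits.json
wingbeat correct --events clustered.csv --model fits.json --out corrected.csv
# or end-to-end, with every artifact and a run report:
wingbeat run-all --seed 1 --out rundir/
```

Waveform-level processing (`wingbeat simulate waveforms`, `wingbeat
extract`) covers the upstream stage: transit detection, insect/non-insect
classification (duration window 10 ms – 1 s, spectral content in
10–900 Hz), and per-event feature extraction at the instrument's 30,517 Hz
sampling rate.

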