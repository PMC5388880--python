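# neurovasc

Quantitative analysis of neurovascular function for two-photon bolus
tracking, cortical electrophysiology and vascular immunofluorescence —
with synthetic-data generators that provide fully known ground truth for
every analysis chain.

## Who this is for

Labs studying cerebrovascular reactivity and neuronal network function in
rodent models of neurodegeneration typically combine three data streams:

1. **Bolus tracking.** A fluorescent dextran bolus is injected while a
   two-photon microscope line-scans cortical microvessels (~20 ms/line,
   11–13 s scans). Each vessel's fluorescence transient is modeled with
   the gamma-variate function

   `F(t) = b + A (t − t0)^α exp(−(t − t0)/β)`  for `t > t0`,

   whose peak sits at `TTP = t0 + αβ` — the time-to-peak from the
   injection trigger. Cerebrovascular reactivity is the percent TTP
   shortening under a hypercapnic (CO₂) challenge,
   `100·(TTPₙ − TTPₕ)/TTPₙ`. When flow rises by a factor `k`, the
   *dispersion* of transit times across the network contracts by `k`;
   regressing hypercapnic on normocapnic TTP with orthogonal (Deming)
   regression therefore gives a slope of `1/k`, and the network flow
   change is `100·(1/slope − 1)` percent.

2. **Theta–gamma phase–amplitude coupling (PAC).** From 20 kHz local
   field potentials, the Canolty composite-signal modulation index
   `MI = |mean(a_t · e^{iφ_t})|` couples the gamma envelope `a_t` to the
   theta phase `φ_t`, evaluated over a grid of four 1 Hz theta bins
   (4–8 Hz) × 4 Hz gamma bins (30–138 Hz), tested against a circular
   time-shift surrogate null with Bonferroni correction.

3. **Morphometry.** Pixel- and surface-ratio measures on confocal masks:
   mural-cell coverage (desmin/lectin pixels), detachment (pixels in
   cells touching no other cell), parenchymal plaque load (amyloid pixels
   per ROI area, discarding components under ~100 µm²), and vascular
   amyloid load (percent of vessel surface).

No raw animal data ship with this package. The `synthetic` module
generates all three streams with known ground truth, so every estimator
is validated by parameter recovery.

## Worked example

```python
from neurovasc.synthetic import BolusCohortConfig, generate_bolus_cohort
from neurovasc.pipeline import cohort_to_records
from neurovasc.flow import network_flow_change

cfg = BolusCohortConfig(flow_change_true=74.0, seed=3)   # 147 vessels
pairs, truth = generate_bolus_cohort(cfg)                # paired traces
records = cohort_to_records(pairs, truth)                # fit every trace
fit = network_flow_change(records, n_boot=2000, seed=1)
print(f"flow change {fit.flow_change:.1f}% "
      f"(CI {fit.ci_low:.1f} to {fit.ci_high:.1f})")
```

prints

```
flow change 75.4% (CI 70.4 to 81.5)
```

The cohort was generated with a true hypercapnic flow increase of 74%:
each vessel's normocapnic TTP is drawn around its type mean, the
hypercapnic TTP contracts the deviation by `k = 1.74`, and white noise is
added to every fluorescence sample. The chain — gamma-variate fits on 294
noisy traces, per-type mean-centering, Deming regression, inverse slope —
recovers the truth within the animal-level bootstrap CI.

The same pattern runs end to end from the shell:

```bash
neurovasc run --experiment vascular --seed 3 --out results/
neurovasc simulate-lfp --coupling-depth 0.8 --out lfp.h5
neurovasc pac --lfp lfp.h5 --seed 11 --out comod.json
```

The numbered scripts under `analysis/` reproduce the full narrative —
simulate both cohorts, fit, infer flow changes and reactivity tables,
run the PAC contrast and the morphometry suite — writing their tables
under `results/`.

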