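# petquant

Quantification and test–retest reliability analysis of dynamic small-animal
PET time–activity data.

`petquant` is aimed at preclinical imaging groups that quantify reversible
radioligand binding in rodents — for example tracers for mutant-huntingtin
aggregates in knock-in Huntington-disease mouse models — from regional
time–activity curves (TACs) and an image-derived input function (IDIF),
without arterial sampling. It covers the full analysis chain:

* **Input function** — a whole-blood curve is converted to the
  metabolite-corrected plasma-parent input
  `C_p(t) = C_wb(t) · (r0 + r1 t) · f(t)`, where the plasma-to-whole-blood
  ratio is a linear fit and the intact-parent fraction
  `f(t) = a1 e^(−μ1 t) + a2 e^(−μ2 t)` a biexponential fit to discrete blood
  samples (5/15/30/60/90 min).
* **Kinetics** — the reversible two-tissue compartment model (2TCM) with
  rate constants `K1, k2, k3, k4` and blood-volume fraction `vB`, fitted by
  weighted nonlinear least squares with seeded multi-start; Logan graphical
  analysis whose late-time slope estimates the total volume of distribution
  `V_T = (K1/k2)(1 + k3/k4)`; scan-truncation time-stability of `V_T`; and
  `SUV = C̄[100–120 min] / (dose/weight)`.
* **Reliability** — per-animal rTRV `= 100·(test − retest)/mean`, aTRV
  `= |rTRV|`, Bland–Altman bias and 1.96·SD limits of agreement, and a
  variance-component ICC `= σ²_animal / Σ positive components` from a
  restricted-maximum-likelihood mixed model.
* **Planning** — genotype percent differences and Cohen's *d*, one-tailed
  two-sample sample-size calculation via the noncentral-*t* distribution,
  Pearson/Spearman agreement, and a 4PL curve for the `V_T` decline with
  injected mass.
* **Synthetic data** — a first-class generator producing input functions,
  parent fractions, noisy frame-averaged TACs on the 45-frame / 120-min
  schedule, and multi-animal test–retest cohorts with known ground truth, so
  every stage is testable against a recoverable target.

## Worked example

```python
import petquant as pq

schedule = pq.make_standard_frame_schedule()          # 45 frames, 120 min
input_fn = pq.simulate_input()                        # bolus + metabolite correction
truth    = pq.TwoTcmParams(K1=0.3, k2=0.15, k3=0.075, k4=0.03, vB=0.03)
tac      = pq.simulate_tac(truth, input_fn, schedule,
                           pq.NoiseSpec(scale=0.05, seed=7), region="striatum")

# express everything in kBq/mL for a 4.1 MBq injection into a 28 g mouse
scale     = 4.1 * 1000.0 / 28.0
tac_kbq   = pq.TacTable(schedule, tac.values * scale)
input_kbq = pq.InputFunction(input_fn.times, input_fn.whole_blood * scale,
                             input_fn.plasma_parent * scale)

fit   = pq.fit_2tcm(tac_kbq, input_kbq, "striatum")
logan = pq.logan_vt(tac_kbq, input_kbq, "striatum", t_star=30.0)
suv   = pq.compute_suv(tac_kbq, 4.1, 28.0, "striatum")
```

prints, via the obvious format strings:

```
true V_T      : 7.000 mL/cm^3
2TCM V_T      : 6.939   (K1=0.296, k2=0.159, k3=0.081, k4=0.030, vB=0.024)
Logan V_T     : 6.686   (t*=30 min, r2=0.9996, 18 points)
SUV 100-120   : 1.021 g/mL  (4 frames)
n per group at d=7.48: 2
```

The 2TCM fit recovers the generative `V_T = 7.0` within 1% despite frame
noise; the Logan slope sits a few percent lower — the well-known downward
bias of the linearization — while remaining tightly rank-correlated with the
compartmental estimate; the SUV of ~1 g/mL reflects near-unity normalized
uptake in the late window; and a Cohen's *d* of 7.48 needs only 2 animals
per group at α = 0.05 and 80% power (one-tailed). The last line is
`pq.sample_size_two_sample_t(pq.PowerSpec(d=7.48))`.

A complete study runs from the shell:

```sh
petquant simulate study/ --n-per-genotype 8 --seed 1
petquant run config.yaml        # paths + policy; see petquant.StudyConfig
```

which writes per-scan kinetics reports, a Table-style reliability report
(rTRV/aTRV by genotype, ICC per region and metric), group statistics and a
power table, all as tab-separated files with the config and seed logged.

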