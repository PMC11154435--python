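# spikeval

**Validation calculus for GC-MS spiking experiments in oral-fluid drug
testing.**

`spikeval` is for bioanalytical chemists validating a quantitative GC-MS
(or LC-MS) method against spiking designs: it computes the matrix effect,
extraction recovery, process efficiency, and collection-device
pad-transfer recovery — each in absolute and internal-standard-normalized
form — plus signal-to-noise detection limits and the real-sample
marker-window assessment used to judge whether an oral-fluid collection
device is fit for distinguishing coca-leaf consumption from cocaine use.
A seeded synthetic-data generator emulates the spiking designs with known
ground truth, so every statistic the package reports can be verified by
algebraic identity and parameter recovery.

## The statistics

The classic three-set design prepares, per analyte and level:

* **A** — neat standard in solvent,
* **B** — blank matrix extracted first, spiked *after* extraction,
* **C** — matrix spiked *before* extraction,

(with device counterparts B_Q/C_Q collected through an absorbent-pad
device). With Ā, B̄, C̄ the replicate-group mean areas:

| statistic | formula | measures |
|---|---|---|
| matrix effect | ME% = (B̄/Ā − 1)·100 | signal enhancement (+) or suppression (−) by co-extracted matrix |
| extraction recovery | RE% = C̄/B̄·100 | true extraction loss; matrix effect cancels |
| process efficiency | RA% = C̄/Ā·100 | overall apparent yield |
| pad recovery | R% = (Tube a)/(Tube b)·100 | analyte released from the device pad into its buffer |

The three are linked by the consistency identity
**RA = (1 + ME%/100) × RE%** (because C/A = (B/A)·(C/B)); `spikeval`
reports the residual of this identity for every cell as an internal
cross-check. Each statistic also has an IS-normalized variant computed on
per-injection area/IS ratios, which shows how much a deuterated internal
standard compensates (and how "artificially" high normalized recoveries
can run when it over-compensates). Cells are flagged when |ME| > 25% or
CV > 15% (20% near the LOQ). `nd` (not detectable, S/N < 3) is a
censoring state distinct from zero and from missing, and it propagates:
any nd replicate censors its group, and any nd group mean censors its
ratio.

LOD and LOQ are taken off the tested level grid: the lowest levels at
which every replicate reaches S/N ≥ 3 and ≥ 10 respectively.

## Worked example

```python
import spikeval as sv

# simulate the full two-arm spiking design with known ground truth
truth = sv.paper_like_truth(seed=1)          # enhancement, SPE losses, pad retention
table, truth_record = sv.simulate_experiment(truth, sv.default_design(), seed=1)

results = sv.ValidationStudy(table).fit()
print(results.metric("ME", "CUS", "drooling", 10.0))   # 101.0...
print(truth_record["expected"]["CUS"]["ME_pct"])       # 100.0
print(results.identity_residuals["identity_residual"].max())  # ~2.8e-14
print(results.summary()[:400])
```

```
101.00977678590866
100.0
2.842170943040401e-14
== ME — drooling arm ==
conc        EME         EME-d3      CUS         TRO         COC         COC-d3      t-CIN
10          -6 (27.1%)  14 (11.3%)  101 (5.8%)  25 (5.7%)   6 (9.2%)    22 (17.3%)  48 (16.1%)
```

The simulated cuscohygrine matrix effect (101%) recovers the generating
enhancement factor 2.0 (ME = 100%) within replicate noise, and the
identity residual confirms that ME, RE and RA were computed consistently
from the same group means. The same grid carries the IS-normalized
variants, guideline flags, and nd-censored device-arm cells for the polar
analytes that the pad retains.

The identity is also useful on its own, e.g. reconstructing a process
efficiency from reported ME and RE values:

```python
>>> sv.matuszewski_identity(16, 35)   # ME 16%, RE 35%
40.599999999999994
```

A command-line interface wraps the same pipeline:

```sh
spikeval simulate --seed 7 --out-dir out/        # peak_table.csv + truth.json
spikeval validate --input out/peak_table.csv --out-dir out/
spikeval limits --input sn.csv --out-dir out/    # LOD/LOQ grid from replicate S/N
spikeval realsample --input real.csv --out-dir out/  # marker-window assessment
```

## Layout

* `spikeval.table` / `spikeval.analytes` — long-format peak-area tables, the
  analyte panel (SIM ions, logP, IS assignments), nd-aware CSV I/O
* `spikeval.metrics` — the ratio statistics, identity, and guideline flags
* `spikeval.study` — `ValidationStudy` / `ValidationResults` report layer
* `spikeval.calibration` — OLS slope comparison, S/N, LOD/LOQ
* `spikeval.simulate` — ground-truth generator (tables, traces, time courses)
* `spikeval.realsample` — external-standard ratios and marker windows
* `spikeval.cli` — the `spikeval` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
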