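# Methods

## Scope and model

`spikeval` implements the validation calculus for quantitative GC-MS
spiking experiments on oral fluid: the three-set matrix-effect/recovery
design, pad-transfer recovery for absorbent-pad collection devices,
S/N-based detection limits over discrete spiked levels, and the
real-sample marker-window criterion. The target application is the panel
of coca-leaf alkaloids — hygrine (HYG), cuscohygrine (CUS), ecgonine
methyl ester (EME), tropacocaine (TRO), cocaine (COC) and
trans-cinnamoylcocaine (t-CIN) — analyzed with deuterated internal
standards (COC-d3, EME-d3) and proadifen (SKF) as an external standard,
but every statistic is generic to any analyte panel.

### Statistics

With Ā, B̄, C̄ the arithmetic means of the replicate peak areas of the
neat standard (A), post-extraction spike (B) and pre-extraction spike
(C):

* ME% = (B̄/Ā − 1)·100 — signed; positive is enhancement. In GC-MS,
  enhancement is the typical direction: matrix constituents occupy active
  sites in the liner/column that would otherwise adsorb analyte, so more
  analyte reaches the detector when matrix is present. The effect varies
  between injections, which is why its CV matters as much as its mean.
* RE% = C̄/B̄·100 — true extraction recovery. Dividing C by B (not A)
  cancels the matrix effect; a "recovery" above 100% computed as C/A is a
  symptom of that mistake, not an actual yield.
* RA% = C̄/Ā·100 — process efficiency (apparent recovery).
* R% = mean(Tube a)/mean(Tube b)·100 — pad-transfer recovery: the same
  spiked oral fluid either loaded onto the device pad then eluted into
  buffer (Tube a) or added directly to buffer (Tube b).

ME% here is *enhancement-style*; the classical consistency identity uses
the *ratio-style* matrix effect B/A. `matuszewski_identity` converts
explicitly: RA = (1 + ME%/100)·RE%, which is exact algebra
(C/A = (B/A)·(C/B)) when all three statistics come from the same group
means. The report computes the residual of this identity for every
process-efficiency cell; it should be at machine precision, and a
nonzero residual flags inconsistent aggregation (e.g. values pooled over
different days).

Normalized variants divide each injection's analyte area by the IS area
of the *same* injection before averaging, then form the identical ratios.
A same-molecule deuterated IS that co-varies with its analyte drives
ME_n to 0 and RE_n to 100% regardless of the true extraction loss — which
is precisely why absolute-area recoveries must be reported alongside
normalized ones. Analytes lacking their own deuterated analogue (CUS,
TRO, t-CIN, HYG) are normalized by a surrogate IS and annotated as such
in the grid, since surrogate compensation is structurally imperfect.

### Aggregation rules

* Metrics are ratios of group means, not means of per-replicate ratios:
  the design establishes one mean response per set and no per-injection
  pairing between sets. The reported CV% of a metric is the CV of the
  per-replicate numerator values (dividing by the constant denominator
  mean leaves CV unchanged); n is the numerator replicate count.
* `nd` (not detectable, S/N < 3) is a censoring state, distinct from zero
  and from a missing cell. One nd replicate censors its group mean; one
  censored group mean censors every ratio built on it. Reports never mix
  nd with numbers inside a cell. A normalized cell whose IS is unusable
  (nd or zero) in every injection is likewise nd — the set exists, the
  normalization is impossible — whereas a set with no records at all is
  "not computed" with a reason.
* Cells replicated on several days are evaluated per day and reported as
  a min–max range with the mean of the per-day values as the point value;
  identity residuals are only attached to single-day cells, where the
  algebra is exact.
* Guideline flags use strict inequalities: |ME| > 25%, CV > 15%
  (> 20% for levels at or below `near_loq_max_conc`, default 10 ng/mL).
  An ME of exactly −25% is not flagged. These limits come from the
  LC-MS/MS validation guidelines; there are no GC-MS-specific ones.
* Report rendering rounds to integer percent (one decimal below 1 in
  magnitude); CSV/JSON outputs keep full precision.

### Detection limits

S/N is (peak-window maximum − baseline)/SD(noise window), with the
baseline the mean of a declared noise window of at least 20 points
disjoint from the peak. SD-based noise was chosen over peak-to-peak
because it is stable and testable; the definition is confined to
`signal_to_noise` so an alternative can be swapped in. A zero noise SD
returns an infinite-S/N sentinel. LOD/LOQ are the lowest *tested* levels
at which **all** replicates reach S/N ≥ 3 / ≥ 10 — grid values, never
interpolated, and the all-replicates rule is the conservative choice
among all/any/mean, which the reporting convention does not specify.
Because S/N ≥ 10 implies S/N ≥ 3 at the same level, LOD ≤ LOQ always
holds where both are defined.

Calibration comparison uses unweighted OLS with a free intercept
(`scipy.stats.linregress`) on at least three distinct levels;
`slope_ratio_recovery` is 100·slope_a/slope_b for same-analyte,
same-response-mode fits. Weighted regression (1/x, 1/x²) and
back-calculation of unknowns are out of scope.

### Real samples and the marker window

Volunteer samples are quantified only as analyte/SKF area ratios (SKF is
added after extraction, so it tracks injection response without
extraction or collection losses). Detection calls use S/N < 3 → nd, with
the boundary S/N = 3 counted as detected ("less than 3" defines nd). The
marker-window criterion asks, per collection arm: at every time point
where COC is positive, is at least one leaf marker (HYG or CUS) still
detected? The COC confirmation cut-off is defined in ng/mL (default
8 ng/mL), but ratio-quantified samples cannot be mapped to
concentration without a calibration the design does not include, so the
assessment takes a `cutoff_equivalent_ratio`; its default (`None`) treats
every *detected* COC point as positive, the conservative choice. Raising
the cutoff shrinks the positive set, so a failing arm can only flip to
passing, never the reverse. HYG participates in detection calls only —
it has no commercial standard (it is identified from coca-leaf extract)
and never enters a quantitative metric.

## The synthetic-data generator

`simulate_experiment` generates the full two-arm design with known truth:

| mechanism | model | default |
|---|---|---|
| response | area = RF·conc, RF per analyte | RF = 1000 area/(ng/mL) |
| matrix enhancement | multiplicative gain E, lognormal per injection | mean 1.05–2.0 by analyte, CV 10% |
| extraction loss | fraction `extraction_efficiency` in pre-extraction sets | 0.40–0.50 by analyte |
| pad retention | retained = 1/(1 + exp(s·(logP − m))) | m = 1.5, s = 4 |
| censoring | device-arm areas below a threshold → nd | 4000 area units |
| injection noise | lognormal, unit mean | CV 10% |
| IS coupling | IS gain = E^`is_coupling` of its analyte's injection | 1.0 |

Replicate counts, levels (default 10/20/50/500 ng/mL), arms, sets and
days are all overridable through `DesignSpec`. IS areas are generated at
the 15 ng/mL IS spiking level and pass through the same set-dependent
extraction/pad factors as a pre-extraction-spiked analyte (the IS is
added before processing), with the matrix term E^is_coupling; this is
what makes a same-molecule IS with full coupling compensate exactly
(ME_n = 0, RE_n = 100% noise-free) while a surrogate IS does not.

The default ("paper-like") truth profile is *illustrative, not fitted*:
it was chosen once for qualitative agreement with the observed patterns —
strong erratic enhancement for CUS and t-CIN, mild for EME/TRO/COC,
device-arm censoring of the polar analytes (EME logP −0.23, CUS 0.72) at
low levels while COC/TRO/t-CIN (logP ≈ 2.6–2.7) survive, recoveries
around 40–50%. Noise is multiplicative lognormal because areas are
positive and dispersion is relative; the enhancement is drawn per
injection, not per batch, reflecting how unpredictable active-site
effects are between injections.

What the generator does **not** emulate: chromatographic peak-shape
chemistry, SPE kinetics, carryover, heteroscedastic weighting regimes,
real buffer-interference chemistry (the censor threshold is a free
parameter, not an estimate — consequently some observed nd patterns,
like a device-arm post-extraction IS dropout, are outside the model),
and pharmacokinetic realism of the coca-tea time course (first-order
decay per analyte from configurable t=0 ratios is a design template for
testing window logic, not a PK model; its decay constants were set so
the drooling arm keeps its markers at 120 min while a strongly
attenuated device arm does not, mirroring the volunteer pattern).
Passing tests therefore certify the *calculus* — identities, censoring
propagation, threshold logic, estimator consistency — on data whose
generating mechanisms are plausible but idealized; they are not evidence
about any particular instrument.

Traces from `simulate_trace` are a Gaussian peak over white noise with a
tight ±2σ peak window; the S/N of such a trace is biased slightly above
height/SD because it takes a maximum over the window — tests account for
that bias rather than hiding it.

## Numerical and design choices

* Group CVs use the sample SD (n − 1): triplicate/sextuplicate groups are
  samples, and the convention is not otherwise pinned down.
* Set A (neat standard) is arm-independent: both arms' metrics reference
  the same neat-standard means, and the generator emits it once.
* TRO's IS assignment differs between reporting contexts
  (EME-d3 vs COC-d3 in different tables); the packaged panel assigns
  COC-d3 and the assignment is overridable per analyte.
* HYG and SKF ship with estimated logP values (0.8, 5.2); no published
  value exists, the numbers only feed the simulator's retention curve,
  and neither analyte enters a validation statistic.
* Zero denominators raise an explicit undefined-ratio error rather than
  returning infinities; nd never silently becomes 0 or ∞.
* One seeded `numpy` generator per simulate call; no global RNG state.
  Identical (truth, design, seed) triples give bitwise-identical tables.
* Problem sizes in the test suite (2000-injection expectation checks,
  30–40 replicate studies for estimator convergence, 1000 randomized
  S/N maps) were sized to make the statistical assertions sharp at
  3-standard-error tolerances while keeping the suite fast.

## Known limitations

* The per-replicate pairing of set-A injections with matrix injections
  is not modeled (the design does not define one), so normalized metrics
  compare group means of ratios, not paired differences.
* Multi-day cells report ranges; no pooled between-day variance
  component is estimated.
* The marker-window assessment emits flags, not verdicts: detecting leaf
  markers confirms coca-leaf consumption but cannot rule out concurrent
  illicit cocaine use, and benzoylecgonine (which requires derivatization
  for GC-MS) is outside scope.
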