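# Methods

## Decision problem and model structure

`cariesim` evaluates two screening strategies for proximal caries on
posterior teeth of an initially 12-year-old individual, followed in
discrete annual cycles over a 66-year horizon (the mean remaining tooth
lifetime):

* **dentist_no_ai** — annual visual-tactile examination plus a bitewing
  radiograph every second year, read by the dentist alone;
* **dentist_with_ai** — the same schedule, with the radiograph
  additionally read by a convolutional-network classifier that charges
  a per-application fee (4–12 euros) and whose accuracy depends on the
  fraction of the labelled image corpus used to train it (10%, 25%,
  50%, 100%).

Each tooth is an independent Markov microsimulation with one proximal
lesion at most. Untreated disease progresses one stage per cycle at
most: `SOUND → E2 → D1 → D2–D3` (inner-enamel, outer-dentin,
mid/deep-dentin lesion depths). Detected initial lesions (E2, D1) are
arrested by resin infiltration (`ARRESTED`, which may fail back to D1);
detected advanced lesions (D2–D3) enter the restorative cascade

```
RESTORED --(k-th failure)--> CROWNED --(failure)--> crown replaced once
   --(failure)--> ROOT_FILLED --> RETREATED_NONSURG --> RETREATED_SURG
   --(failure)--> EXTRACTED_IMPLANT   (absorbing)
```

Endodontic complications can strike restored or crowned teeth directly
(annual hazard, preempting the same-cycle failure draw). Extraction
with an implant-supported crown is absorbing: the natural tooth is
gone, retention accrual stops, and no further costs arise.

**Within-cycle order** (fixed for reproducibility): examination fees →
examination → treatment decision → natural progression →
treated-state failure hazards. A tooth restored in a cycle is exposed
to failure hazards in that same cycle; a lesion arrested in a cycle can
lose its arrest in that same cycle. Effectiveness is the count of
cycles entered with the natural tooth in situ (no half-cycle
correction); costs are discounted at 3%/year by the whole-year index of
the cycle in which they occur. Retention years are not discounted:
the health outcome is reported on its natural scale.

## Diagnostic model

Accuracy is lesion-depth-specific. Initial lesions are radiograph-only
(visual-tactile sensitivity for E2/D1 is structurally zero and
validated as such); advanced lesions can additionally be found
visual-tactilely, combined with the radiographic read by logical OR.
Sound and arrested surfaces can be falsely flagged with probability
1 − specificity; a false-positive call is acted on — as a restoration
with probability `fp_advanced_share` (default 0.2), otherwise as an
infiltration — which is the mechanism by which imperfect specificity
causes real harm (a sound tooth dragged into the restorative cascade).
Treated teeth are not re-diagnosed, but examination fees continue while
the tooth is in situ. "Biannual" visual-tactile examination is mapped
to one examination per annual cycle, the model's finest time step, and
charged once per cycle.

## Parameters and uncertainty

All inputs live in a `ParameterSet`; the base-case PSA marks as
uncertain:

| parameter | distribution | why |
|---|---|---|
| AI fee per application | uniform(4, 12) € | stated deployment-cost band |
| cohort risk profile | low/high, p = 0.5 each | maximum uncertainty about where the AI is deployed |
| training-data fraction | uniform over {10, 25, 50, 100}% | value-of-data question; each fraction carries its own accuracy band |
| AI accuracy per fraction | uniform, half-width 0.02–0.064 shrinking with data | cross-validation spread narrows with data |
| transition probabilities | uniform (sparse evidence) / triangular (better-studied failure rates) | standard PSA practice |

Parameters are drawn independently (no correlation structure is
asserted). A draw outside a probability's [0, 1] bound raises an error;
clamping would silently distort the distribution. Dentist and
visual-tactile accuracy are fixed point values in the base case.

## Synthetic parameter generator and calibration

Rather than hard-coding the parameter estimates of any one clinical
setting, the package ships a generator (`cariesim.synthetic`) that
emulates the *structure* such inputs must have and is calibrated to a
reference result pattern. Its defaults are the package's reference
conditions:

* **Learning curve.** Accuracy(f) = floor + (asymptote − floor)·(1 −
  e^(−6f)) per metric; uncertainty half-width 0.02 + 0.06·e^(−6f).
  With rate 6 the 10%→25% step carries most of the gain and gains are
  marginal beyond 50%, the signature behaviour of data-hungry image
  classifiers; a rate too shallow to put the largest gain on the first
  step is rejected at construction. Floors/asymptotes: sensitivity
  E2 0.48→0.65, D1 0.62→0.82, D2–D3 0.80→0.95; specificity 0.92→0.975.
  The AI is thus more sensitive than the dentist reader (0.25/0.40/0.70,
  specificity 0.97) at every fraction, but less specific until roughly
  half the data are used — so in mostly sound (low-risk) mouths a
  sparsely trained AI loses money on false positives plus its fee,
  while in high-risk mouths its sensitivity advantage dominates.
* **Risk profiles.** Low risk: initial prevalence (sound, E2, D1,
  D2–D3) = (0.85, 0.08, 0.05, 0.02), baseline hazards. High risk:
  (0.30, 0.30, 0.24, 0.16) with onset/progression hazards ×2.2.
* **Hazards** (annual, low-risk baseline): onset 0.03; E2→D1 0.25;
  D1→D2–D3 0.30; arrest failure 0.02; restoration failure 0.06 (crown
  after 3 failures, repair/replace split 50/50); crown failure 0.05;
  endodontic complication 0.03; root-filling failure 0.07; nonsurgical
  retreatment failure 0.12; surgical retreatment failure 0.15.
  Magnitudes follow the restorative-dentistry literature (median
  restoration survival ≈ 10–15 y, slow but nonzero late-cascade
  attrition).
* **Costs** (euros, German mixed public–private payer scale): exams 4
  (visual-tactile) and 6 (radiograph) per cycle; infiltration 90;
  composite restoration 140 (repair 70, replacement 140); crown and
  crown replacement 600; root canal 550; nonsurgical/surgical
  retreatment 600/650; extraction 100; implant-supported crown 2400.
  The AI fee is charged in full on every radiograph cycle.

Calibration was a single campaign: starting from the literature-scale
first guesses above, the learning-curve floors, risk-profile contrast
and cascade costs were adjusted until the simulated pattern showed the
intended qualitative structure — base-case AI dominant; sparsely
trained AI more costly in low-risk cohorts; risk profile the most
valuable single piece of information, training amount second, AI fee
worthless — and then frozen. Under these conditions the base case
yields mean retention ≈ 60.2 y (no AI) vs ≈ 62.1 y (AI) and mean
discounted lifetime costs ≈ 870 € vs ≈ 825 €.

**What the generator does not emulate.** Real bitewing imagery and
reader behaviour (the accuracy values are curve outputs, not measured
operating points); correlation between parameters; dentists deviating
from AI advice; secondary caries as a distinct failure mode;
patient-level mortality or multi-tooth interactions. Passing tests
therefore demonstrate that the *pipeline* — simulation, economics, and
VOI estimators — behaves correctly under realistic conditions, not that
these parameter values describe any particular population.

## Economic and value-of-information estimators

* **NMB.** NMB(λ) = λ·e − c per strategy and draw, with e in retention
  years, c in discounted euros, λ the willingness to pay per retention
  year (grid 0–100 €, step 1).
* **CEAC.** Fraction of draws in which a strategy attains the strictly
  highest NMB; exact ties split their vote equally, so acceptability
  sums to one across strategies at every λ.
* **ICER.** Reported as Δc/Δe only in the trade-off quadrants;
  "dominant"/"dominated" labels otherwise; Δe = 0 is labelled, never
  divided by. CE-plane boundary convention: Δe = 0 counts as more
  effective, Δc = 0 as less costly.
* **EVPI.** mean over draws of max-strategy NMB, minus max over
  strategies of mean NMB. For a fixed draw set this is a convex,
  piecewise-linear function of λ.
* **EVPPI.** Single-loop conditional-mean estimator: draws are grouped
  by the sampled value of the target parameter (exactly for the
  discrete risk profile and training fraction; 10 quantile bins for the
  continuous AI fee), the best strategy is chosen per group on
  group-mean NMB, and the frequency-weighted mean of the group maxima
  is compared with the best marginal strategy. Unbiased for discrete
  parameters; chosen over nested two-level Monte Carlo because the
  base-case uncertain parameters are low-cardinality or scalar. Note
  the max operator gives these estimators a positive small-sample bias,
  so small EVPPIs should be read against their bootstrap errors.
* **Uncertainty.** Nonparametric bootstrap over draws (default 200
  resamples) attaches a standard error to every VOI point. VOI is
  reported per individual, on the same per-tooth scale as costs.

## Randomness and reproducibility

All randomness descends from one root seed through
`numpy.random.SeedSequence` spawning: per PSA draw, one child stream
samples the parameters and another drives the simulation. Every chance
event a tooth can face in a cycle has a dedicated pre-drawn uniform
variate (a horizon × 7 block per tooth), and by default both strategies
within a draw consume the *same* block (common random numbers), so
incremental cost/effect estimates are differenced over identical chance
histories and their Monte Carlo variance drops sharply. Reruns with the
same seed are bit-identical; independent streams per strategy are a
config switch.

## Problem sizes

Reference runs use 1,000 teeth per cohort; headline analyses in the
acceptance script use 1,000 PSA draws × 400 teeth plus deterministic
4,000-tooth scenario cohorts, and the test suite uses 1,000 draws × 250
teeth for its end-to-end checks — sizes at which the documented
qualitative pattern resolves well beyond its Monte Carlo error. The
degenerate edge cases (certain detection, certain failure, zero
hazards) are checked against exact hand traces and a closed-form
geometric-phase retention expectation.

## Known limitations

One lesion per tooth; no surface-level anatomy or adjacent-tooth
effects; implant is terminal (no implant failure); treated teeth are
not re-screened for new primary lesions (new disease on a restored
tooth is subsumed in the failure hazards); exam fees are modelled
per tooth, so mouth-level fee sharing is out of scope; cost-utility
(QALY) analysis and population-scale or sample-information VOI are not
implemented.
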