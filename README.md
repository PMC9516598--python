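# cariesim

Does letting an AI read bitewing radiographs pay off — and how much is
it worth to *know* the things we are unsure about before deciding?

`cariesim` is a health-economic simulation package for proximal caries
screening on posterior teeth. It compares two strategies over a tooth's
lifetime: routine dentist diagnostics (annual visual-tactile exam,
biennial bitewing radiograph) with and without a convolutional-network
caries detector assisting the radiograph read. The AI is more sensitive
than the average dentist reader — increasingly so the more data it was
trained on — but charges a fee per application and, when trained on
little data, produces more false positives. Whether it saves money and
teeth depends on the population's caries risk, the training-data
amount, and the fee: exactly the uncertainties the package quantifies.

It is written for health-economics and dental-informatics researchers
who need a reproducible, scriptable pipeline rather than a GUI
modelling tool: every stage is a library call with a seeded RNG, and a
thin CLI chains them.

## Model and analysis in brief

* **Markov microsimulation.** Each of 1,000 independent teeth walks
  through annual cycles over a 66-year horizon: `SOUND → E2 → D1 →
  D2–D3` if untreated; infiltration arrests detected initial lesions;
  detected advanced lesions enter the restorative cascade (restoration
  → crown → root canal → retreatments → extraction + implant,
  absorbing). Effectiveness is tooth retention years; costs (euros,
  German payer scale) are discounted at 3%/year.
* **PSA.** Parameters are drawn from uniform/triangular distributions —
  notably the AI fee U(4, 12) €, an equiprobable low/high risk profile,
  and the training-data fraction {10, 25, 50, 100}% with its
  fraction-specific accuracy band — and the cohort is resimulated per
  draw with common random numbers across strategies.
* **Cost-effectiveness.** Incremental cost Δc and effect Δe per draw;
  ICER with dominance labels; CE-plane quadrant shares; acceptability
  curves from net monetary benefit, NMB(λ) = λ·e − c.
* **Value of information.**
  EVPI(λ) = E_θ[max_s NMB_s(θ)] − max_s E_θ[NMB_s(θ)], and
  single-loop conditional-mean EVPPI per parameter (risk profile,
  training fraction, AI fee), with bootstrap standard errors.

See `docs/methods.md` for assumptions, parameter defaults and their
rationale, estimator details, and limitations.

## Worked example

```sh
cariesim make-fixture --out params.yaml --seed 0
cariesim psa --params params.yaml --n-draws 300 --n-teeth 300 --seed 7 --out results
cariesim cea --results results --out results
cariesim voi --results results --out results
```

The PSA stage prints the per-strategy summary (mean and 2.5–97.5
percentiles of per-draw cohort means):

```
       strategy  mean_cost  cost_p2_5  cost_p97_5  mean_effect  effect_p2_5  effect_p97_5
  dentist_no_ai 877.763273 534.776896 1292.304745    60.159544    54.839833     63.988167
dentist_with_ai 822.505060 497.655194 1183.748513    62.117967    57.963000     65.296417
```

AI screening retains teeth about two years longer (62.1 vs 60.2 y) at
lower mean lifetime cost (823 vs 878 €). The CEA stage locates the
incremental pairs on the cost-effectiveness plane:

```
{
  "delta_cost_mean": -55.258213292902774,
  "delta_effect_mean": 1.9584222222222232,
  "icer": "dominant",
  "quadrant_shares": {
    "more_costly_more_effective": 0.2833333333333333,
    "more_costly_less_effective": 0.04666666666666667,
    "less_costly_more_effective": 0.67,
    "less_costly_less_effective": 0.0
  }
}
```

so AI dominates (cheaper *and* more effective) in 67% of draws, though
28% of draws buy the extra retention at extra cost — the decision
uncertainty that VOI prices. The VOI stage prints the λ = 0 values
(euros per individual, bootstrap SE):

```
           parameter     value   stderr
                 all 24.429646 2.901453
ai_training_fraction  7.111537 3.155654
        risk_profile  7.464270 3.880631
             ai_cost  2.070214 1.946057
```

Eliminating *all* parameter uncertainty is worth ≈ 24 € per individual;
knowing the population's risk profile or the accuracy the training data
will buy is worth a few euros each; knowing the AI fee is worth
essentially nothing (its value shrinks toward zero as the draw count
grows — at 1,000 draws it is ≈ 1 €, within its bootstrap error of
zero). `cariesim report --results results` reprints the summary table
from saved files, and `--help` on any subcommand lists the knobs
(horizon, cohort size, λ grid, bootstrap count, strategy selection).

All numbers above are what these exact commands print; rerunning them
with the same seeds reproduces them byte for byte.

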