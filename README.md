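# cadcea

Cost-effectiveness modelling of diagnostic imaging strategies for suspected
obstructive coronary artery disease (CAD).

For a patient with stable chest pain, a clinician can wait (no imaging),
order a noninvasive test — cardiovascular magnetic resonance (CMR),
single-photon emission computed tomography (SPECT), or coronary CT
angiography (CCTA) — or go straight to invasive coronary angiography (ICA).
Each choice trades test costs, false positives sent to ICA, and false
negatives left untreated, against downstream major adverse cardiovascular
events (MACE). `cadcea` quantifies those tradeoffs for payers, guideline
writers and health-economics researchers: it projects lifetime discounted
costs and quality-adjusted life-years (QALYs) for the five strategies,
turns them into ICERs, net monetary benefit (NMB) and value classes, and
fits a fast linear *cost-effectiveness calculator* (metamodel) that
emulates the full simulation so users can plug in local prices, accuracy
estimates and disease prevalence.

## Model

* **Diagnostic year** — the cohort (prevalence π) is split by a test with
  sensitivity *se* and specificity *sp* into TP = π·se, FN = π(1−se),
  FP = (1−π)(1−sp), TN = (1−π)·sp. Positives undergo ICA (a perfect
  reference test); confirmed CAD receives medical therapy plus
  revascularization (CABG/PCI mix) for a configurable fraction. 58% of
  false negatives return with escalating symptoms within the first year and
  experience the same pathway as true positives.
* **Markov cohort model** — annual cycles over four health states (no MACE,
  one MACE, >1 MACE, death), tagged by status (no CAD, treated CAD,
  untreated CAD). First-MACE risk depends on status; recurrent events occur
  at a multiplier of the status rate; every event carries a case-fatality
  risk; background mortality follows an age-interpolated life table. QALYs
  weight life-years by utilities (0.84 event-free, 0.78 after MACE); costs
  combine procedures, therapy, and acute ($14,500 default) plus chronic
  ($3,400/yr) MACE costs; both streams are discounted at 3%/yr.
* **CEA metrics** — pairwise ICER = Δcost/ΔQALY with dominance markers, the
  efficiency frontier with extended dominance, NMB = WTP·QALY − cost
  (default WTP $100,000/QALY), ACC/AHA value classes (<$50k high,
  $50–150k intermediate, >$150k low value per QALY).
* **Calculator (metamodel)** — probabilistic sensitivity analysis samples
  20 parameters (beta for probabilities/utilities, gamma for costs, 15% CV)
  and evaluates each draw through the engine; ten OLS regressions (the
  no-imaging QALY/cost plus incremental QALY/cost of each strategy vs no
  imaging) are fitted with backward elimination at p < 0.05 and validated
  on held-out draws via adjusted r² and percentage deviation.
* **Threshold analysis** — bisection on the incremental NMB of two
  strategies as one input varies, against either engine.

Three scenarios transcribed from published US analyses ship with the
package (`ge_us`, `genders_us`, `genders_plus_ge_accuracy`), plus a curated
15-study literature-review table with its summary tabulations. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
cadcea run --scenario ge_us
```

prints the five-strategy comparison under the packaged US base case
(CAD prevalence 32.4%, age 62.5):

```
scenario: ge_us  engine: markov  WTP: 100,000/QALY
  strategy       cost   qaly icer_vs_reference           nmb  value_class           frontier
no_imaging 17,408.712 12.554         reference 1,237,965.238                     on_frontier
     spect 21,358.422 12.637        47,204.068 1,242,382.836         high extended_dominated
       cmr 22,037.727 12.660        43,512.181 1,243,974.657         high        on_frontier
      ccta 22,677.038 12.661        48,971.389 1,243,454.879         high        extended_dominated
       ica 23,978.086 12.673        54,958.680 1,243,349.160 intermediate        on_frontier
```

Reading: doing nothing is cheapest but forgoes ~0.11 discounted QALYs per
patient versus CMR; CMR buys those QALYs at ≈ $43,500 each (high-value
care) and achieves the highest NMB at $100,000/QALY, while SPECT and CCTA
are extended-dominated (a mix of the neighbouring strategies delivers their
QALYs for less). The same library calls are available in Python
(`load_scenario`, `evaluate_all`, `results_table`).

Train and use the calculator, then ask how expensive CMR could become
before CCTA wins:

```bash
cadcea psa-train --scenario ge_us --n-train 20000 --n-test 1000 --seed 1 --out mm.json
cadcea threshold --scenario ge_us --param cmr_cost --lo 807 --hi 10000 \
    --strategy-a cmr --strategy-b ccta --engine markov
```

The threshold command reports a break-even CMR price of ≈ $1,327 (1.64× the
$807 base case) at $100,000/QALY.

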