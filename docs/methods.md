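# Methods

## Decision problem and model structure

The package evaluates five diagnostic strategies for a cohort with
suspected obstructive CAD: no imaging, CMR, SPECT, CCTA, and immediate ICA.
The model has two stages.

**Diagnostic year (cycle 0).** A noninvasive test partitions the cohort by
true disease status and test result (TP/FN/FP/TN). Test-positives undergo
ICA, modelled as a perfect reference test (sensitivity = specificity = 1;
ICA complications are not modelled). ICA-confirmed disease receives medical
therapy plus revascularization for a fraction of patients
(`revascularization_fraction`, split `cabg_share` CABG / remainder PCI).
False positives incur the ICA cost and are then managed as disease-free. A
fraction `fn_return_prob` (default 0.58) of untreated diseased patients —
false negatives, and in the no-imaging arm all diseased patients — returns
with escalating symptoms within the first year, undergoes ICA and receives
the same treatment as true positives. This crossover applies in year 1
only; thereafter untreated CAD persists with elevated MACE risk. The
immediate-ICA strategy sends the entire cohort to ICA and treats exactly
the prevalent fraction. Year-0 rewards are the full procedure costs plus
one year of medical therapy for the treated, and one undiscounted year at
the event-free utility for everyone (MACE incidence starts with the first
Markov cycle, i.e. events during the work-up year are not modelled
separately from year-1 events).

**Markov cohort model (annual cycles to the horizon).** Four health states
— no MACE history, one MACE, more than one MACE, death — with the alive
states tagged by status: no CAD, treated CAD, untreated CAD. MACE is a
single lumped composite (cardiovascular death, nonfatal MI, unstable-angina
or heart-failure hospitalization). Per cycle, first events occur at a
status-specific annual probability; recurrent events (from the MACE-history
states) at `recurrent_mace_multiplier` times that rate, capped at 1;
survivors of an event from "one MACE" move to ">1 MACE"; every event is
fatal with probability `mace_case_fatality`; background all-cause mortality
(linear interpolation of an age-indexed table) then applies to all alive
states; death is absorbing. Occupancy is conserved to machine precision by
construction, and the engine is fully vectorized so a parameter batch of
tens of thousands of draws runs in one pass.

**Rewards and discounting.** Cycle length is one year with rewards accrued
at cycle start and no half-cycle correction; cycle *t* (the diagnostic year
being *t* = 0) is discounted by (1 + r)^−t, so the first cycle is
undiscounted. QALYs weight occupancy by `utility_no_mace` (0.84) or
`utility_mace` (0.78, both MACE-history states). Costs per cycle: medical
therapy for treated-CAD occupants every year alive, the chronic MACE cost
for occupants of MACE states, and the acute MACE cost for every event in
the cycle it occurs (the "entry cycle"), including fatal events. The
simulation runs from the cohort age to `horizon_age` (default 100, a
lifetime horizon).

## Default parameters

Published inputs carried by the packaged scenarios (test profiles,
prevalence, age, procedure costs, utilities, chronic MACE cost, 3%
discount rate, $100,000/QALY WTP, the 58% return rule) are flagged
`published` in the scenario files. Remaining fields are package defaults,
flagged `source: default`:

| parameter | default | rationale |
|---|---|---|
| acute (first-year) MACE cost | $14,500 | midpoint of the commonly cited $11,000–18,000 range |
| SPECT profile | se 0.70 / sp 0.75 / $550 | mid-range literature estimates for perfusion SPECT |
| medical therapy | $1,200/yr | generic secondary-prevention regimen |
| revascularization fraction | 0.60 | share of confirmed CAD revascularized rather than managed medically alone |
| CABG share | 0.30 | CABG vs PCI mix in revascularized patients |
| first-MACE risk, untreated CAD | 0.060/yr | untreated obstructive CAD composite-event rates |
| first-MACE risk, treated CAD | 0.025/yr | treatment cuts event risk roughly in half or better |
| first-MACE risk, no CAD | 0.006/yr | background event rate in chest-pain patients without obstructive CAD |
| recurrent-event multiplier | 2.0 | post-event patients at roughly doubled risk |
| MACE case fatality | 0.15 | composite including CV death |
| life table | abridged, ages 40–105 | approximates a contemporary US all-cause period table, interpolated |

These cohort parameters were chosen once from typical secondary-prevention
epidemiology so that the base-case lifetime discounted QALYs of a
62.5-year-old US cohort land near published values (the packaged `ge_us`
no-imaging arm yields 12.55). Currency is a label (default USD); no
inflation adjustment or currency conversion is performed.

## Probabilistic sensitivity analysis

Twenty parameters are sampled: prevalence; sensitivity, specificity and
cost of each modality; ICA/CABG/PCI costs; both utilities; acute and
chronic MACE costs; the three first-MACE probabilities. Probabilities and
utilities get beta distributions (method of moments from the scenario mean
and a coefficient of variation, default 15%); costs get gamma (shape
1/CV²); any parameter may be overridden or held fixed, and parameters at a
degenerate mean (0 or 1) are fixed automatically. Age, discount rate,
pathway fractions and the remaining cohort parameters are fixed per draw.

Draws are independent across parameters and records, except that rows
violating two modelled orderings are redrawn (conditioning the joint
distribution on the ordered region): the MACE-state utility may not exceed
the event-free utility, and treated-CAD MACE risk may not exceed
untreated-CAD risk. Without this, roughly a third of draws would assert
that surviving a MACE *improves* quality of life, and the dominance
property of a perfect free test (incremental QALYs ≥ 0 in every draw)
fails. The conditioning shifts the means of those four parameters away
from their scenario values; the other sixteen match their configured means
to Monte-Carlo error. All sampling derives from a single seeded
`numpy.random.Generator`, so (scenario, settings, seed) fully determines
every record; non-finite draws would be logged by index and abort the run
above a 0.1% failure rate.

Each draw yields ten outputs: the no-imaging lifetime discounted QALY and
cost, and the incremental QALY and cost versus no imaging for CMR, SPECT,
CCTA and immediate ICA.

## Metamodel (cost-effectiveness calculator)

One OLS regression per output on main effects of the sampled parameters —
deliberately no interactions or polynomial terms, keeping the calculator a
transparent linear form. Variable selection is backward elimination
per output: refit, drop the regressor with the largest p ≥ 0.05 (ties
broken by name, so the procedure is order-deterministic), repeat until all
retained coefficients are significant; the intercept is always kept, and a
single-shot pruning variant is available. Regressors whose standardized
coefficient is at floating-point rounding level are treated as
insignificant regardless of their nominal p-value; this makes exact-fit
(zero-residual) training data behave sensibly. Rank-deficient designs
raise an error naming the collinear columns.

Validation on held-out records reports, per output, the adjusted r² and
the **percentage deviation**, defined here in the external-calibration
sense: 100 × (mean prediction − mean observation)/mean observation. At the
default held-out size of 1,000 records this metric carries a sampling
noise floor of a few tenths of a percent for the incremental-QALY outputs,
whose coefficients of variation are large (treatment benefit is a product
of prevalence, risk gaps and utility gaps); on large held-out sets the
bias component is well under 0.5%, consistent with OLS unbiasedness.
Metamodels serialize to versioned JSON with named coefficients; loading
validates the schema version and that retained regressors are known.

## Threshold analysis

`find_threshold` bisects the incremental NMB of two strategies as a
function of one scalar input (any sampled parameter, or a dotted scenario
path when using the Markov engine) to a relative tolerance of 1e-4, after
screening monotonicity on a 10-point grid (a warning is issued if the NMB
difference changes sign more than once; bisection then returns one root).
Either engine may be used; the metamodel engine is fast and mirrors
calculator use, the Markov engine serves as confirmation. Under the
packaged US base case the CMR-vs-CCTA break-even CMR price is ≈ 1.6× its
base value at $100,000/QALY.

## CEA conventions

Pairwise comparisons: dominated/dominant markers use weak dominance (equal
QALYs at higher cost is dominated); when both deltas are negative the
ratio is reported in the reference-favouring direction rather than as a
negative number. Value classes take the closed interval
[$50,000, $150,000]/QALY as intermediate. The frontier removes weakly
dominated strategies, then iteratively removes nodes whose sequential ICER
strictly exceeds the next one (exactly collinear points therefore stay on
the frontier with equal adjacent ICERs); exact-duplicate cost/QALY points
are treated as one frontier node.

## Literature-review module

The packaged CSV transcribes a 15-study review of CMR-for-CAD
cost-effectiveness analyses; `summarize` reproduces its tabulations
(counts and integer percentages per attribute level) with arbitrary record
filters, e.g. restricting to the 13 cost-per-QALY/life-year studies.
Set-valued attributes (settings, comparators, key drivers) can tally to
more than the study count; single-valued attributes always sum to the
filtered total. Transcription disambiguations are noted in the module
docstring.

## What the synthetic experiments do and do not show

PSA records are generated by this package's own engine, so emulator
validation demonstrates that a sparse linear calculator can track *this*
Markov model across realistic joint input uncertainty — held-out adjusted
r² ≥ 0.94 for all ten outputs at 20,000 training draws — not that it would
track a differently parameterized model equally well. The engine omits
test-related harms (radiation, contrast), echocardiography/PET
comparators, sex-specific test performance, correlated parameter
uncertainty, and within-year event timing (no half-cycle correction);
costs are unit-agnostic and not inflation-adjusted. Default problem sizes
used throughout the documentation and validation runs are 20,000 training
/ 1,000 held-out records, which one CPU completes in a few minutes;
the calculator's configuration object defaults to the larger 100,000-draw
training set for production fits.
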