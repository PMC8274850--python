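# Methods

This note records the model as implemented, the defaults and why they were
chosen, and what the synthetic setting can and cannot show.

## Natural history

Each person is simulated in continuous age. Other-cause death is sampled
by inverse transform from a Gompertz–Makeham life table,
S(a) = exp(−λa − (α/β)(e^{βa} − 1)) with λ = 5·10⁻⁴ /y, α = 2.8·10⁻⁵ /y,
β = 0.095 /y, chosen so that life expectancy at birth is ≈ 78 y (77.9 y on
the annual grid) and S(110) < 10⁻³ — US-like longevity. Survival is
interpolated log-linearly within years (piecewise-constant hazard), which
makes quantile lookup the exact inverse of evaluation.

Precursor lesions arise by a non-homogeneous Poisson process with
piecewise-constant annual rate μ(a), sampled by cumulative-hazard
inversion. Each lesion advances independently through its precursor states
with exponential dwell times; on leaving state k it becomes preclinical
cancer with probability pₖ, otherwise it moves to the next state, stalling
benignly after the last. Preclinical cancer turns clinical after an
exponential sojourn; a clinical stage is drawn, then an exponential
stage-specific survival time. A person's cancer death is the earliest
potential cancer death among lesions whose clinical onset precedes the
death age current at that point; observed death is the minimum of that and
other-cause death. Lesion paths are kept latently up to the table horizon
so that screening can cancel or reveal them without re-simulation.

Default disease parameters are synthetic stand-ins (the calibrated rates
of established screening models are not public) with realistic gross
behaviour:

* colorectal-like: μ(a) = 6·10⁻⁴·e^{0.04a} from age 20 (≈ 30–40% lifetime
  chance of any adenoma), dwells 8/6/5 y, pₖ = (0.01, 0.04, 0.20), sojourn
  4 y, stage mix (0.20, 0.30, 0.30, 0.20) with survival means
  (25, 12, 5, 1.5) y. About 3.3% are clinically diagnosed and 2.4% die of
  the cancer unscreened.
* esophageal-like (reflux-symptom males): Barrett onset
  μ(a) = 1.2·10⁻³·e^{0.015a} from 25, dwells 12/5/3 y,
  pₖ = (0.02, 0.08, 0.35), sojourn 3 y, poorer stage mix and survival.

### Mortality scaling

For a relative risk RR of other-cause morbidity, residual survival is
scaled proportional-hazards style: S*(a|c) = [S(a)/S(c)]^{RR}. The
multiplier applies from first precursor onset (configurable to lifelong).
Implementation detail that matters for variance reduction: the baseline
draw's conditional survival level v = S(ocd₀)/S(onset) is re-used and
re-inverted at exponent RR, so RR = 1 reproduces the baseline draw exactly
and death ages vary smoothly and monotonically with RR under common
random numbers.

Cohorts enter at 40 (colorectal) or 60 (esophageal) conditional on being
alive and free of diagnosed cancer at entry (rejection sampling; the
rejected fraction is < 1%).

## Screening

100% adherence (standard for strategy comparisons of this kind).
Scheduled exams run from start to stop age at the given interval,
truncated at death and abandoned at clinical diagnosis. At each contact,
each extant lesion is detected with state-specific sensitivity
(colonoscopy 0.75/0.85/0.95 by adenoma size, 0.95 preclinical; endoscopy
0.85–0.95; cytosponge is a primary test whose positives are confirmed by
endoscopy, so its effective sensitivity is the product). Detected
precursors are removed at the invasive test's removal cost — endoscopic
therapy in the esophageal model — cancelling their future path; the person
then enters surveillance at 3 y (any most-advanced-state lesion) or 5 y
(otherwise), continuing while exams stay clean, up to the stop age.
Detected preclinical cancer is diagnosed at the contact age with a
stage-shifted distribution and survival re-drawn from the shifted stage,
using a reserved per-person random stream so the no-screening arm is
untouched. Lesion-free persons test falsely positive at 1 − specificity
(cost only). Colonoscopy/endoscopy carry a small complication probability
with a cost and a 0.01-QALY lump; no complication mortality.

Common random numbers: streams are keyed by (seed, person, purpose) with
purposes natural-history, screening, stage-shift; nothing is keyed by
strategy or scenario, so arms and RR grid cells are paired person by
person.

## Population inputs

Expenditure and utility observations are one (age, value, weight) triple
per age 18–85, weights proportional to a US-like population pyramid
(4·10⁶·e^{−0.018·max(a−50,0)}). Truth curves: expenditures
500·e^{0.04a} $/person-year (≈ $1,100 at 20 to ≈ $15,000 at 85, the convex
rise of survey data) with $400 Gaussian noise; utility 0.9686 − 0.0027a
(0.92 at 18 to ≈ 0.74 at 85) with 0.015 noise, clipped to (0, 1].

Fitting is weighted nonlinear least squares (residuals √wᵢ·(yᵢ − f(aᵢ))),
Levenberg–Marquardt from a moment-based start plus four deterministic
perturbations (×0.5…×2), tolerances 10⁻¹⁴; the best converged start wins
and the achieved weighted SSE is stored. Supported forms: exponential,
linear, quadratic, logistic. Fitted curves extrapolate flat outside the
observed age range — deliberate, to keep exponential costs bounded at
ages 85+ — and utility curves clip to [0, 1].

## Economics

Discounting is continuous at rate r from cohort entry:
PV = x·(1+r)^{−(a−entry)}. Continuous accruals are integrated with
16-point Gauss–Legendre quadrature on each segment between regime
breakpoints (entry, first lesion onset, diagnosis, end of the cancer
decrement window, curve domain edges, death); the integrand is smooth
within segments, so this is exact to machine precision for practical
purposes, and the QALY = LY − disutility decomposition holds identically
node by node. A zero rate reproduces undiscounted sums exactly.

Quality weight and background cost follow the scenario rules given in the
README. Persons who never develop a lesion always use the unscaled
(RR = 1) background values; with background switched on these cancel in
increments between arms except through differential survival. Negative
quality weights (possible at extreme RR and old age) clip at 0. Cancer
care: stage-specific treatment cost ($30k–$120k) at diagnosis, $60k
terminal cost at cancer death, 0.12 utility decrement for 3 years after
diagnosis, $1,000/$800/$250 per colonoscopy/endoscopy/cytosponge, small
per-test disutility lumps. These magnitudes are synthetic; they are set so
that colorectal screening has a modest positive net cost (keeping ACERs
finite across the scenario grid) while esophageal screening is roughly an
order costlier per person screened.

Scenario semantics: the default scenario has no background costs or
disutility and average mortality. Every other cell includes all three
components at the population average and scales the named subset by RR, so
all single-component series and the combined series coincide at RR = 1
(represented once as the "average" cell).

## Decision layer

Frontier: sort by cost; remove strongly dominated points (another point no
costlier and no less effective, one inequality strict; exact duplicates
keep the lexicographically smallest label); then repeatedly remove the
point whose incoming pairwise ICER is ≥ its outgoing one, until ICERs
strictly increase — equivalent to the upper-left convex envelope, which
the tests verify against subset-enumeration on a thousand random
instances. The least costly remaining point is the reference; a
cost-saving screening strategy can therefore dominate "no screening"
itself. Cost-saving ACERs are reported as a label, never as a negative
ratio. Frontiers are computed on discounted values.

The published per-strategy table ships as a text fixture; its esophageal
cost cells are read as $ thousands per 1000 men — the only reading
consistent with the printed ICERs (e.g. 976.2k/32.4 ≈ 30.1k). ICERs
recomputed from the printed, rounded cells match the printed ICERs to
≈ 1% in the median; cells whose printed cost increment has only one
significant digit (e.g. $0.06M) are rounding-limited and can deviate by
~10%.

## Problem sizes and determinism

Defaults used by the analysis drivers and tests: 10,000–20,000 persons per
cohort for sweeps, 100,000 for the cohort-integration validation, 2,000
for shared unit-test fixtures. At these sizes the paired (common random
number) comparisons that the conclusions rest on — ACER dose-response,
superadditivity, frontier stability — are far outside Monte-Carlo noise.
Every stream derives from one master seed; re-running any entry point with
the same seed is bit-identical.

## Validation against independent oracles

* Lifetime clinical incidence and cancer mortality of the microsimulation
  match deterministic integration of the same competing-risks process
  (lesion-level CTMC kinetics convolved with the Poisson onset rate,
  marginalized over the life table) within 3 Monte-Carlo SE at n = 10⁵.
* The frontier algorithm equals brute-force dominance-by-definition on
  random instances; the weighted fit beats a coarse grid search and
  recovers noise-free truth to < 10⁻⁶ relative error.
* RR = 1 sampling reproduces the life table (KS test, α = 0.01).

## What the synthetic setting does and does not show

Passing tests establish the correctness of the machinery — the simulator,
the accounting identities, the dominance algebra — and reproduce the
published decision layer exactly where it is reproducible (the printed
table) plus the qualitative findings (dose-response of the ACER in RR,
superadditivity of the combined scenario, frontier robustness). They do
not reproduce the absolute LY/QALY/cost magnitudes of the calibrated
models behind the published strategy table: those depend on calibrated
natural-history parameters and care costs that are not public. Synthetic
parameters were chosen once for realism, not tuned to match printed
magnitudes. Other known simplifications: exponential dwell/sojourn times
(memoryless), no cure fraction in stage survival, only the first clinical
diagnosis is costed, no screening-related mortality, 100% adherence, and
the synthetic esophageal model makes once-only screening cost-saving under
default assumptions where the published calibrated model has it at a
positive net cost.
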