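# Methods

## Decision problem and model structure

The package evaluates ivosidenib (500 mg daily, oral) against two
chemotherapy comparators — mFOLFOX and 5-FU/LV, both intravenous — for
previously treated *IDH1*-mutant advanced intrahepatic cholangiocarcinoma,
from the payer perspective of Taiwan's NHIA, with all costs in 2022 NT$.

A partitioned survival model with three states (progression-free PF,
post-progression PP, dead) derives occupancy directly from each arm's OS
and PFS curves: PF(t) = min(PFS(t), OS(t)), PP(t) = OS(t) − PF(t),
dead(t) = 1 − OS(t). The min() cap handles independently estimated curves
that cross; occupancy then conserves to 1 at every boundary by
construction. There are no transition probabilities — that is the point of
the PSM: it needs only the two marginal curves each trial publishes, at the
price of ignoring the PF→death vs PF→PP split (a Markov cross-check would
need patient-level data, which none of the source trials release).

Cycles are monthly (1/12 year — the annual cost bookkeeping of the input
table resolves the month-vs-28-day ambiguity) over a 10-year horizon, by
which point every arm's OS is below 1 %, so the horizon is effectively
lifetime. Costs and health outcomes are discounted at 3 %/year.

## Survival inputs

All six OS/PFS curves are log-normal (meanlog, sdlog) on a time scale of
months; exp(meanlog) matches the trials' reported median survivals in
months, which fixes the unit. Each parameter carries a standard error, a
95 % CI used as its deterministic range, and a normal PSA distribution.

The survival module implements the six families standard in
health-technology-assessment extrapolation. Parameterisations: exponential
(rate), Weibull (shape, scale), Gompertz (shape, rate — negative shape
allowed, giving a survival plateau that is acceptable over a finite
horizon), log-logistic (shape, scale), log-normal (meanlog, sdlog), and the
generalised gamma in the (mu, sigma, Q) form used in extrapolation
practice, with Q → 0 recovering the log-normal. Fitting maximises the
right-censored log-likelihood (events contribute log f, censored records
log S) with Nelder-Mead plus L-BFGS-B from several documented starts on a
log-transformed scale for positive parameters; standard errors come from
the inverse observed information (central-difference Hessian at the
optimum, natural scale). Model selection minimises AIC, with BIC as the
tiebreak and a separately reported BIC winner plus a disagreement flag.
The fitter is cross-checked against lifelines on shared families in the
test suite.

Hybrid curves equal the trial KM up to a user-chosen cutoff and a
parametric tail rescaled by KM(cutoff)/S(cutoff) beyond it, making the
curve continuous at the junction. Rescaling (rather than splicing the raw
parametric values) is a design choice: it preserves the KM information at
the junction and avoids a discontinuity. The cutoff is an explicit argument
because no single trial-period end applies to all arms.

## Pseudo-IPD reconstruction

The reconstruction inverts the product-limit calculation given digitized
(time, survival) coordinates and the numbers-at-risk table. Within each
risk-table interval a censoring count is iterated: censor times spread
uniformly, event counts at each digitized step chosen so the running
product-limit estimate tracks the digitized probability (the comparison is
against the *reconstructed* KM, so rounding self-corrects rather than
accumulates), and the censoring count updated until the implied number at
risk at the next risk-table time matches the published one. When the total
event count is reported, a final pass increases censoring in the last
interval to absorb an event excess; an event deficit is never manufactured.
Records still at risk after the last digitized time are censored there, so
the record count equals the initial number at risk. Digitized probabilities
are monotonized (cumulative minimum) on input to absorb digitization
jitter. On synthetic trials (n = 300, two censoring levels, five seeds,
0.25-month digitization grid, jitter SD 0.003) the reconstructed KM tracks
the original within 0.02 everywhere; that tolerance is an engineering
choice, since no numeric criterion is standard.

## Accrual

Discounted person-time is the trapezoid integral of occupancy times the
continuous discount factor (1+r)^(−t) on the cycle grid — equivalent to a
half-cycle-corrected discrete sum; halving the grid moves the shipped
curves' integrals by < 0.05 %, and the monthly grid sits within 0.1 % of a
10×-finer oracle. Accrual rates:

- PF costs: annual medication cost × price multiplier + annual
  non-medication cost (treatment runs until progression);
- PP costs: annual supportive-care cost (NT$497,710/year — the annual
  figure reconciles the published cost decomposition; a per-cycle figure
  printed elsewhere does not, and is unused);
- PF utility: 0.76 minus the IV-administration disutility 0.025 for the
  two infusion arms only, minus the AE disutility 0.16 weighted by the
  arm's per-cycle grade ≥ 3 AE proportion (0.192 / 0.048 / 0.013). This
  assignment is the only one that reproduces the published PF QALYs
  (0.48 / 0.33 / 0.26) from the inputs;
- PP utility: 0.68; life-years are the same person-times with weight 1.

## Cost-calibrated person-times

The published analysis was built on hybrid curves whose digitized
coordinates are not public. Pure-parametric person-times match the
chemotherapy arms well (mFOLFOX PF ≈ 0.456 y) but understate ivosidenib's
PF time (its log-normal PFS implies ≈ 5.7 discounted months where the
published costs imply ≈ 7.8). Because accrual is linear — cost = rate ×
person-years — the published PF-state and overall costs invert exactly:
pf_years = PF cost / (medication + non-medication rate), pp_years =
(overall − PF cost) / supportive rate. `fit(calibrate_from_costs=True)`
uses these person-times; everything downstream (QALYs, ICERs, INMBs, price
and conversion-factor and LY scenarios, DSA, PSA) is then recomputed by the
engine. Horizon scenarios are the one analysis that genuinely needs the
survival layer and are refused in calibrated mode.

## Scenarios

- **Price grid**: the intervention's medication cost is scaled by 0.9 down
  to 0.4. The ICER is affine in the multiplier, so the grid is an exact
  arithmetic progression (a property the tests assert).
- **Conversion factor** (0.9): Taiwan's point-based fee system can value a
  reimbursement point below NT$1. The factor is applied to both PF
  non-medication and PP supportive-care rates — both are point-valued
  non-medication claims. The source is ambiguous on whether supportive care
  is included; with both scaled, one comparator's published scenario ICER
  reproduces to < 0.01 % and the other differs by ≈ 0.7 %, so the
  both-scaled reading is kept and the second row is not asserted
  numerically.
- **Horizons** of 5 and 15 years (survival layer required).
- **Life-years as effectiveness**: metric switch only; costs unchanged.

## Sensitivity analysis

DSA moves one parameter at a time to the ends of its range (survival
parameters: 95 % CI; costs/utilities/disutilities: ±25 %; discount rate:
0–0.05). Parameters without a tabulated range (comparator medication
costs, the exchange rate, per-arm AE proportions) are skipped; an
``include`` argument can restrict or extend the varied set. The base-case
utilities must satisfy u_pp ≤ u_pf, but sensitivity excursions may cross
them (the PF utility's own lower range, 0.57, lies below the base PP
utility), so the ordering is validated at configuration load and not
re-imposed during DSA/PSA evaluations.

PSA draws every distribution-carrying parameter independently per
iteration (normal for survival parameters — meanlog and sdlog
independently, as only marginal SEs are published; gamma(shape, rate) for
costs, parameterised so the mean α/λ matches the base values; beta for
utilities and the AE disutility; uniform for the exchange rate), rebuilds
the model and records each arm's discounted cost, QALYs and LYs. The
intervention's medication price is a currency conversion of a foreign list
price, so it varies only through the exchange-rate draw (proportional to
rate/29.81); the conversion factor enters only its own scenario. Draws
producing an invalid model are rejected and redrawn, with the count
reported. Runs are reproducible bit-for-bit given the seed. The default is
1,000 iterations.

CEAC reports, per willingness-to-pay value, the fraction of iterations in
which each strategy has the highest net monetary benefit, with ties split
equally so columns sum to 1. EVPI per person is mean(max-strategy NMB) −
max(mean NMB), non-negative by construction; pairwise decision quantities
(the intervention against one comparator) use the two-strategy subset of
the iteration table.

## Synthetic data

The generator emulates what the pipeline assumes about real trials:
log-normal event times with the configured parameters, a comonotone OS/PFS
pair (one shared uniform, PFS truncated at OS — the simplest joint model
with the right marginals and ordering), uniform accrual over 12 months,
administrative censoring at study end (24 months of follow-up by default),
KM digitization on a 0.25-month grid with truncated-normal jitter, and
exact risk tables every 3 months. It does not emulate treatment crossover,
informative censoring, reporting granularity of published figures, or
between-trial population differences — so passing round-trip and recovery
tests demonstrates the algorithms are correct under the model's own
assumptions, not that the published curves themselves are recoverable.

Default problem sizes — n = 300 per synthetic arm for reconstruction
round-trips, n = 2,000 for parameter-recovery checks, 1,000 PSA
iterations — were chosen once as realistic for trials and models of this
kind and give comfortably stable results.

## Known limitations

- The PSM structure cannot separate pre-progression mortality from
  progression; the published analysis shares this limit.
- Life-year totals reported by the engine are the self-consistent
  discounted person-times implied by the cost decomposition; one published
  LY row is mutually inconsistent with the published costs and LY ICERs
  and is deliberately not targeted.
- PSA probabilities of cost-effectiveness under price cuts depend on the
  unavailable hybrid curves; the package asserts the robust qualitative
  properties (first quadrant, monotonicity in price) rather than the
  published percentages.
- Survival draws in calibrated mode perturb costs/utilities only; with a
  user-supplied hybrid curve they perturb the extrapolated tail.
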