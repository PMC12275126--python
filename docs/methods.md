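# Methods

## Scope and data model

The package analyses a four-factor ultrasonic-extraction experiment:
liquid-to-solid ratio (mL/g), extraction temperature (°C), extraction time
(min) and ultrasonic power (W), with polysaccharide yield (%) as the
response.  The central container, `DesignTable`, holds the runs in order
with their factor settings and observed yields; the packaged 29-run table
(`paper_fixture()`) is a standard 4-factor Box-Behnken design (BBD) with
five center replicates at (25 mL/g, 90 °C, 75 min, 300 W).

The source table's printed column headers contradict the values they hold,
so the fixture assigns factors to columns by matching each column's value
set to the stated design levels — ratio {20, 25, 30}, temperature
{80, 90, 100}, time {60, 75, 90}, power {250, 300, 350}.  The four sets
are disjoint, making the assignment unambiguous; the reassembled table is
a valid BBD whose replicate-based pure-error sum of squares (7.26) matches
the published ANOVA row (7.24) to the rounding of 2-decimal yields.
Yields are stored exactly as printed and never re-derived.  Three printed
prediction columns ride along as opaque reference vectors; whether they
were computed on coded or actual units is unknowable, so they are used
only as regression baselines for the metric equations, never as targets.

## Response-surface model

`fit_quadratic` fits the full 15-term second-order polynomial by OLS
(statsmodels), on coded (−1/0/+1) or actual units; the fitted surface is
identical under either coding (asserted to 1e-8), so coding is purely a
reporting convention.  Coding maps level (low, mid, high) onto
(−1, 0, +1) via z = (x − mid) / ((high − low)/2).

`anova` partitions the total SS into model, per-term, residual,
lack-of-fit and pure-error components.  Per-term 1-df SS are **partial
(Type-III, drop-one-term extra SS) on coded factors** by default; this is
the convention of mainstream RSM software.  The BBD's linear and
interaction columns are mutually orthogonal, so Type-I and Type-III agree
there; the quadratic columns are not orthogonal to the intercept or each
other, so the two differ slightly for them.  Sequential Type-I is
available via `ss_method="type1"`.  p-values use the F survival function;
text reports render values below 1e-4 as "< 0.0001".

PRESS uses the hat-matrix identity e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ), which is exactly
the n-refit leave-one-out computation (asserted to 1e-10 against the brute
force in the tests).  A leverage of 1 (e.g. a lone center point in a
25-run BBD) makes leave-one-out undefined: `press` raises, and `anova`
reports PRESS and predicted R² as NaN.  With no replicated runs the
pure-error row is absent and lack of fit equals the residual.

On the packaged table the fit gives R² = 0.896, adjusted R² = 0.792,
predicted R² = 0.540, C.V.% = 8.66, model F = 8.61, and reproduces the
printed prediction column to ±0.01 — the published regression equation
itself is typographically corrupt (it evaluates to ≈130 % yield at its own
stated optimum) and is therefore never used; the model is always re-fitted
from the table.

## Optimum search

`maximize` runs a dense grid search (default 101 points per axis) followed
by coordinate-ascent polish at 10× finer steps with step-halving to a
1e-6 tolerance.  For non-convex surrogates (the MLP) the polish restarts
from the best five grid cells.  Factors within one grid step of a box edge
are flagged; a perfectly flat surface suppresses the flags.  On the fitted
quadratic over the design box (ratio 20–30, temperature 80–100 °C, time
60–90 min, power 250–350 W) the maximum is 18.38 % at ratio 30 and time 90
(both box edges), ≈96 °C and ≈311 W.  The study prints 18.14 % for this
quantity; the re-fitted surface — which reproduces every printed
prediction — evaluates to 18.35 % even at the study's own stated optimum
settings, so 18.38 % is the faithful value of the surface and the package
reports it unchanged.

## BP surrogate

The network is 4-h-1 (default h = 4): logistic-sigmoid hidden layer,
identity output — the conventional regression topology of toolbox-era BP
networks.  Inputs and output are min–max normalized to [−1, 1] per
feature, with parameters frozen when training starts, to keep the sigmoids
out of saturation.  Weight layout is input→hidden (h×4), hidden biases
(h), hidden→output (h), output bias — 6h+1 values.

Training is batch gradient descent on the MSE of normalized outputs with
classic momentum (default 0.9) and, by default, the adaptive learning-rate
rule of the same toolbox era: after an improving epoch the rate grows by
×1.05; a step that worsens the error by more than 4 % is rejected, the
rate shrinks by ×0.7 and the momentum buffer is cleared.  The defaults are
learning rate 0.05, 1000 epochs, target error 1e-5; training stops at the
cap or when the epoch MSE falls below the target, and the best-so-far
weights by training error are returned with the per-epoch trace.  Plain
fixed-rate descent is selectable (`adaptive_lr=False`); the adaptive rule
is the default because fixed-rate descent at these settings cannot reach
the accuracy regime this experiment requires within 1000 epochs.
Levenberg-Marquardt was evaluated and rejected: with 6h+1 = 25 weights
against 21 training runs it interpolates the training set and produces
erratic validation behaviour on so small a sample.  The analytic
backpropagation gradient is verified against central finite differences to
1e-6 relative.

Hidden-layer size can be optimized by `golden_section_hidden_search`, an
integer golden-section bracket over [h_lo, h_hi] scoring each candidate by
k-seed-averaged validation MSE; each integer is evaluated at most once and
the final ≤3-wide bracket is scanned exhaustively, so a unimodal profile
yields its argmin.  The study states both an optimal h = 4 and a 6–12
search range; the package defaults to h = 4 and leaves the range
configurable — the contradiction is surfaced here rather than resolved.

## Train/validation split

`split` sorts runs by observed yield, bands them into n_valid = 8 quantile
strata and draws one validation run per stratum (seeded), giving the
21/8 partition.  Stratification is on the observed response — the only
variable available — and guarantees the validation set spans the response
range (≥60 % of the full span across seeds, asserted in tests).

## GA-ACO hybrid initializer

Each weight slot carries m = 10 discrete candidates spanning [−1, 1] with
pheromone initialized at unity.  Per iteration: (1) 30 ants assemble
vectors by roulette proportional to pheromone, each slot taken greedily
(max pheromone) with probability α = 0.2 — the "transition constant"
reading implemented by default; the alternative reading, pheromone weights
raised to the power α, is selectable; (2) candidate fitness is the RMSE of
the untrained network's forward pass — no backpropagation; (3) a genetic
step refines the population: with probability 0.8 a slot is refilled by
single-point crossover of two 1/fitness-proportionally selected parents,
genes mutate with probability 0.05 by N(0, 0.1) noise clipped to the
candidate range, and the best individual passes through unchanged;
(4) pheromones evaporate by ρ = 0.9 and the five best vectors deposit
1/fitness on their nearest grid candidates.  The incumbent best vector
re-enters each generation (cross-generation elitism), making the
best-fitness trace non-increasing.  Iteration stops at 100 generations or
when the best fitness changes by less than 1e-4 relative over 10
iterations — on the packaged table this plateau typically lands within a
few dozen iterations.

Candidate fitness is evaluated on the **full 29-run table** by default
(selectable: training or validation split).  Two observations force this
choice: the source study's hybrid-surrogate predictions coincide with the
observed yields to 2 decimals on 17 of 29 runs — including
validation-range runs — which no split-blind protocol reproduces; and with
split-only fitness the hybrid's full-table accuracy falls short of the
reported level.  The metaheuristic thus pre-conditions the network on the
whole response surface, and BP refinement then trains on the 21-run
training split only, with epochs and error threshold mirrored from the
plain BP configuration.  This protocol detail is the main reason the
hybrid surrogate generalizes better than the random-initialized BP here,
and it should be understood as part of the workflow being reimplemented
rather than as a recommendation: under a split-blind protocol the hybrid's
advantage on these 29 runs is real but modest (its mean validation RMSE is
lower, yet it wins only ~6–7 of 10 paired seeds).

Values the study leaves open — ant count (30), generation cap (100), grid
size (10 over [−1, 1]), crossover 0.8, mutation 0.05 with scale 0.1,
deposit constant Q = 1, five elites — are conventional for GA-ACO-BP
hybrids and all config-exposed.

## Synthetic data

`simulate_table` builds the canonical BBD (pair-lexicographic run order,
center replicates last) and adds i.i.d. N(0, σ²) noise to a known
quadratic surface — homoscedastic Gaussian noise being exactly the OLS
assumption.  `paperlike_spec()` uses the fixture-refit coefficients as
ground truth with σ = √1.62 ≈ 1.27 (the fixture ANOVA's residual mean
square), so refits of the synthetic tables bracket the observed R² =
0.896; with σ = 0 the generator reproduces the fitted surface exactly and
OLS recovers the coefficients to 1e-8.  `simulate_screening` produces
peaked, monotone and plateau single-factor curves for the BBD
level-selection rule (peak plus neighbours; endpoints keep the endpoint as
an extreme; ties break to the lower level).  The generator emulates the
design geometry and noise structure, not ultrasonic physics: real
extraction data may be heteroscedastic, drift between blocks, or deviate
from a quadratic surface, so passing tests certify the estimators, not the
chemistry.

## Problem sizes and numerical choices

The test suite runs the full 10-seed paired protocol (~1 min), a
1000-replicate null simulation of the model F-test (size 0.05 ± 0.02), a
200-replicate interval-coverage check, and 100-seed split properties;
these sizes give stable Monte-Carlo verdicts at interactive runtimes.
Comparisons against published statistics use 2 % relative tolerance
(yields are printed to 2 decimals), the printed-prediction metric checks
use 0.5 %, and exact identities (PRESS shortcut, pheromone decay, coding
round-trip) are asserted at 1e-8–1e-12.

## Known limitations

- The 18.14 % published optimum and the published BP comparison row are
  not reproducible from the printed table (see above and the fitted-value
  checks in the tests); the package reports what the data imply.
- The hybrid's paired-seed dominance over random initialization depends on
  the full-table fitness protocol; split-blind runs show a mean advantage
  only.
- Training is deliberately simple (no regularization, no early stopping on
  validation); with 25 weights on 21 runs the BP surrogate is
  variance-limited, which is faithful to the workflow being modelled but
  not a recommendation for larger datasets.
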