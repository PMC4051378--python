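# Methods

## Uniform designs

`generate_uniform_table` builds U_n(n^s) tables by the good-lattice-point
construction: for a generator vector h of integers coprime with n, run i
(0-based) takes level `(i*h_j mod n) + 1` in column j. Every candidate
generator set (all combinations of the coprime integers; a seeded
subsample past 20 000 candidates) is scored by the centered
L2-discrepancy of the points `(level - 0.5)/n` in the unit cube, using
Hickernell's closed form, and the minimiser is returned; ties break to the
lexicographically smallest generator so generation is reproducible.
Levels map to physical units linearly and endpoint-inclusively:
`value = minimum + (level - 1) * (maximum - minimum)/(n_levels - 1)`.
This reproduces all five factor columns of the packaged 15-run dataset
exactly (starch step 1 g/L, NaNO3 0.1 g/L, inoculum 0.5 %, pH 0.5, time
12 h).

Two caveats. First, the construction used by the original design software
is unknown, so the packaged table's particular run-to-level assignment is
shipped verbatim rather than regenerated; the generator only guarantees a
valid, low-discrepancy U_n(n^s). Second, lattice designs can exactly
alias monomials of the full quadratic model: the discrepancy-optimal
U_15(15^5) produced here (generator (1,2,4,7,13)) spans only rank 12 of
the 14 columns needed by the 13-term dry-weight model. Discrepancy
measures spread, not model identifiability; when a design is destined for
quadratic-surface fitting it should be checked with `validate_design` and
a rank check on the intended term matrix. The packaged table is full rank
for both published term sets.

## Quadratic response surface

Candidate terms are the s linear, s pure-quadratic and s(s-1)/2 pairwise
interaction monomials. Fitting is ordinary least squares via QR
(`numpy.linalg.lstsq`) with column equilibration — monomials such as
time² reach 5.2e4 while coefficients sit near 1e-5, and equilibration
keeps the solve accurate to ~1e-13 relative on noise-free data.
Diagnostics: multiple correlation R = sqrt(1 - SSE/SST), overall F with
(k, n-k-1) degrees of freedom and its upper-tail p-value, and the
Durbin-Watson statistic of the residuals in run order. Near-saturated
fits (a single residual degree of freedom, as in the 15-run/13-term
published models) are allowed with a warning; rank-deficient term
matrices raise an error naming the collinear columns (pivoted QR).

Stepwise selection is forward entry with backward elimination on partial
F-tests (defaults alpha_enter 0.05, alpha_remove 0.10). Entry stops when
no candidate's p-value clears the threshold, when another term would
exhaust the residual degrees of freedom, or when the fit is already exact
to working precision (SSE below 1e-12 of SST); at an exact fit, terms
whose removal keeps the fit exact are pruned as redundant. Two behaviours
are worth knowing. (1) One-term-at-a-time entry cannot pick up a centered
parabola over a range far from zero (x and x² must enter jointly), so
symmetric interior-peak surfaces may select nothing at conventional
thresholds; surfaces with strong marginal trends are recovered exactly
from noise-free data. (2) The published 13-term equations are
near-saturated and cannot arise from partial-F stepwise at conventional
thresholds on 15 runs (the defaults keep 0 terms for the algicidal ratio
and 2 for dry weight); published equations are therefore reproduced by
the fixed-term OLS path, and stepwise agreement is treated as an
observation, not a contract.

`maximize_polynomial` scans a dense grid (21 points per axis by default,
chunked to bound memory) and polishes the best few points with bounded
L-BFGS-B; it is deterministic and the argmax may legitimately sit on the
box boundary. Factors absent from the model are reported as
unconstrained rather than assigned a fabricated optimum.

The algicidal ratio lives on fraction scale internally (0.8957, displayed
as 89.57 %): the published algicidal-ratio equation evaluates to ~1.03 at
its published optimum, which only reads correctly as 103 % on that scale.
Model predictions may exceed 1; observations never do.

## Network surrogate

The surrogate is a 5-h-1 perceptron: sigmoid hidden layer, and a sigmoid
(saturating) output unit by default. Inputs are min-max scaled to [0,1]
and the target to [0.1, 0.9]; the target interval leaves the output unit
in its responsive range (no saturation at the data extremes) and, because
the inverse scaling maps (0,1) to a band only 12.5 % beyond the observed
response range, bounds what the surrogate can predict anywhere in the
box. That bounded extrapolation is the property that makes the surrogate
trustworthy for condition search: a linear output unit, also available
via `output_activation="linear"`, extrapolates far above the observed
range at box corners and is the better choice only when the response is
genuinely unbounded.

Training is batch gradient descent with momentum (defaults lr 0.05,
momentum 0.9) and a variable learning rate: the rate grows 5 % per
improving epoch and, when the error jumps more than 4 %, the step is
retracted, the rate shrinks by 0.7 and the momentum buffer resets.
Fixed-rate descent (`adaptive=False`) is kept for reference but plateaus
roughly two orders of magnitude above the adaptive trainer on the 15-run
dataset. Defaults: 2000 epochs maximum, goal MSE 1e-6 (scaled space) —
reached on the packaged data from GA initialisation for every seed tried.
Divergence (non-finite loss) raises with the last finite epoch.

Structure selection (`hidden_neuron_scan`) follows the repeated-split
protocol: for each hidden size, 13 of the 15 runs train the network and 2
test it, replicated (10 by default) with fresh seeded splits and
initialisations; the 2-norms of training- and test-residual vectors are
averaged in scaled output space and the recommended size minimises mean
prediction error. Scan error magnitudes depend on the trainer and the
scaling convention, so they are comparable within a scan but not across
implementations; the scan's output shape (sizes 3..12, training and
prediction columns) is the reproducible part.

## Genetic algorithm

One real-coded GA serves both stages. Selection is roulette on linear
rank weights (best rank weight = population size), which handles
minimisation, maximisation and negative fitness uniformly; crossover is
whole-arithmetic on consecutive pairs (offspring alpha*a + (1-alpha)*b,
alpha ~ U(0,1)); mutation is non-uniform per gene: a step toward a
randomly chosen bound scaled by (1 - r^(1 - t/T)), coarse in early
generations and refining toward zero in late ones. Uniform-reset
mutation is available (`mutation="uniform"`) but cannot refine interior
optima at the protocol's settings: against the deterministic grid oracle
on the known dry-weight polynomial its worst gap over 20 seeds is ~2e-3,
versus 4e-5 for the non-uniform default. One elite individual survives
unchanged per generation, making the best-fitness trace non-worsening by
construction; every individual is clipped to bounds before evaluation,
and a non-finite fitness raises immediately, identifying the individual.

Stage defaults follow the protocol: weights stage maxgen 50, population
20, pcross 0.8, pmutation 0.05, genes bounded to [-3, 3] (sigmoid units
saturate beyond that on unit-scaled inputs); conditions stage maxgen 100,
population 80, pcross 0.4, pmutation 0.05, genes bounded by the factor
box. The GA's best weight vector seeds a subsequent full BP run by
default (the usual GA-BP coupling); `refine_bp=False` keeps the raw GA
weights for the alternative reading of the protocol.

## Synthetic data generator

`generate_synthetic` emulates the study's data-generating situation: a
quadratic polynomial with interactions (the ground-truth surface),
optionally squashed through L*tanh(y/L) to mimic an assay with a ceiling
(an algicidal ratio cannot meaningfully exceed 100 %), plus additive
Gaussian noise, sampled on a U_n design over the five packaged factor
ranges. Default noise scales mimic the real responses: sd 0.01 on
dry-weight-like responses, 0.05 on fraction-scale bioassay responses.
Measurements are floored at zero (a dry-weight assay cannot read
negative) and the exact ground-truth vector is returned alongside the
dataset for recovery tests.

What passing on synthetic data does not show: real fermentations have
run-to-run biological variability that is neither Gaussian nor
independent of the mean, responses interact with factors outside the
design (dissolved oxygen, salinity), and the true surface is not a
quadratic. The generator validates the machinery — term recovery,
optimum recovery, noise sensitivity — not the biology.

## Verification arithmetic

`verification_metrics` computes improvement over control,
(experimental - control)/control * 100, and prediction error,
|predicted - experimental|/experimental * 100, from a prediction, an
experimental mean and a control mean on a shared scale. The packaged
verification constants reproduce every derived percentage in the
verification table from its own raw entries; the table's GA-ANN
dry-weight standard deviation (0.072) is stored verbatim although it is
likely a misprint of 0.0072, being anomalously large against its mean
(0.2165) and every other sd in the table.

## Known limitations

- The trainer is first-order; a Levenberg-Marquardt trainer would reach
  the 1e-6 goal in far fewer epochs and with different scan-error
  magnitudes. Scan tables are comparable within this implementation only.
- Good-lattice-point designs are chosen by discrepancy alone and can
  alias quadratic monomials (see above); check identifiability before
  fitting saturated models on generated designs.
- The GA is a single-population generational scheme; no niching or
  multi-objective support.
- Stepwise selection inherits the usual myopia of one-term-at-a-time
  partial-F methods; it is a baseline, not a model-discovery guarantee.
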