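# Methods

## Models

Three well-stirred reaction networks are built declaratively (species,
stoichiometric change vectors, analytic propensities):

**Simple signaling cascade.** An input x (a step: x(t) = 0 for t < 0, x(t) =
X+ for t >= 0, in nM) converts an inactive factor Y1* to its active form Y1
through the bilinear-in-input propensity theta_x * x * y1*; Y1 reverts at
theta_y1 * y1 and both forms degrade at the common rate gamma_y1* = gamma_y1.
Y1 activates transcription of the output mRNA My2 through the Hill propensity

    f1(y1) = beta_m2* + beta_m2 * y1^n1 / (y1^n1 + y1_0^n1),

and the protein Y2 is translated at beta_y2 * my2.  With the shipped
`table1` rate constants (all in s^-1, copy numbers in molecules per cell) the
stationary totals are beta_y1*/gamma_y1* = 1492.5 molecules of Y1* + Y1, a
basal My2 of beta_m2*/gamma_m2 = 10 and basal Y2 of 100, and saturating-input
maxima of (beta_m2* + beta_m2)/gamma_m2 = 200.7 mRNAs and 2007 proteins.

**Global (extrinsic) variability.** A birth/death species G (birth beta_g,
death gamma_g * G, stationary law Poisson with mean gbar = beta_g/gamma_g,
coefficient of variation 1/sqrt(gbar)) multiplies every protein-creation
propensity by G/gbar, so translation rates keep their nominal means but
fluctuate with G.  Cell-to-cell spread in G then emulates cell-to-cell
differences in translation capacity; gamma_g sets its correlation time.

**Synthetic estradiol circuit.** The same cascade preceded by an mRNA step:
M1 (transcript of the constitutive ADH1-driven transcription factor) is
produced at

    beta_m1*(x) = beta_m1 * [(1 - alpha_x) + alpha_x * xe^nx / (xe^nx + x^nx)],

a modest estradiol-dependent repression (equal to beta_m1 at x = 0; the flag
`adh1_estradiol_dependence=False` restores a plain constant, the control
variant).  Y1* and a fluorescent reporter Y1r are both translated from M1 at
beta_y1*; Y1r has its own degradation rate (a six-hour half-life scale,
gamma_y1r = gamma_y2 = 4.63e-5 s^-1, taken verbatim from the parameter
table).  Two shipped parameterizations: `table2` (global model, used with
gbar = 42 and gamma_g = 3e-6 as the slow-global-fluctuation, "SGF",
configuration) and `table3` (purely intrinsic model, no G, with a much lower
translation rate and y1_0 = 1).

The printed form of beta_m1*(x) admits two parenthesizations; the one above
is adopted because it is the only grouping that behaves as a repression with
baseline beta_m1 at zero estradiol.

A note on output scale: the global-model circuit reaches a stationary mean
y2 of about 560 molecules at 100 nM estradiol, while the intrinsic model
reaches about 2750.  The often-quoted "about 2500 molecules" maximum is
therefore a property of the intrinsic parameter set; since the fluorescence
gain is an arbitrary per-channel constant, none of the dimensionless results
(noise, normalized dose responses, MI) depend on it.

## Moment propagation (affine CME closure)

The chemical master equation is closed at second order by expanding each
propensity to first order about the instantaneous mean z(t).  Means then
follow the deterministic rate equations dz/dt = S^T a(z) and the covariance
obeys dC/dt = A C + C A^T + B with A = S^T J(z), B = S^T diag(a(z)) S, where
S stacks the change vectors and J is the analytic propensity Jacobian.  For
networks whose propensities are affine in the state the closure is exact;
tests verify birth/death transients against the closed form to 1e-8 relative
and a two-stage (mRNA/protein) network against the classic Fano-factor
expression 1 + beta_p/(gamma_m + gamma_p).

Numerics: the mean ODE (independent of C) is solved first with LSODA and the
analytic Jacobian; the covariance flow - linear in C given z(t) - is then
solved with BDF supplying its exact Kronecker-structured Jacobian
A (+) A.  This split matters in practice: a naive joint integration
collapses to sub-second steps when fast activation modes (theta_y1 = 1.5/s)
ride on slow synthesis rates (1e-5 to 1e-8/s).  Default tolerances are
rtol = 1e-8 and atol = 1e-10 for means; the covariance stage anchors its
absolute tolerance to the state magnitude (0.01 * rtol * max|C0|, with
1e-11 as a lower bound) because stationary covariances here are O(10^3-10^4)
molecules^2.  Covariances are symmetrized at every output time; transient
negative means (possible in the linearized flow) are clipped to zero inside
propensity evaluation only, never in the state.  The covariance stays
positive semi-definite (minimum eigenvalue >= -1e-8 * trace) along all
shipped scenarios.

Stationary states are computed directly: the mean fixed point by a root
solve (falling back to relaxation integration if the root leaves the
physical orthant) and the covariance from the continuous Lyapunov equation
A C + C A^T + B = 0.  A pure-integration route (drift criterion 1e-9 /s
relative, capped at ten slowest relaxation times) is retained as
`method="integrate"` and agrees with the direct solve to the accuracy its
own criterion implies (~1e-4 relative).

Known limitation (quantified, see Validation): at few-molecule occupancy of
the Hill input the first-order expansion of f1 underestimates E[f1(y1)]
(Jensen gap of y^1.5 under near-Poisson spread), which biases downstream
means by ~10 % at low estradiol doses in the circuit models.

## Distribution reconstruction

Scalar conditional laws p(y, t | x+) are reconstructed from (mu, C) by the
printed family rule: negative binomial when mu < 3 sqrt(C) (moment-matched:
r = mu^2/(C - mu), p = mu/C), normal when mu >= 3 sqrt(C), with the Poisson
limit when the NB regime demands sub-Poissonian variance (C <= mu) and a
point mass for the degenerate zero state.  The switch is heuristic: at the
boundary mu = 3 sqrt(C) the moment-matched NB tends to a shape-9 gamma
(skewness 2/3), so NB and normal never coincide exactly there
(max-normalized sup distance plateaus near 0.164); well inside the normal
regime the families agree closely.  Joint observables are always modelled as
multivariate normals, consistent with the high-copy regime where joint
computations are performed.

## Mutual information

The channel is step amplitude -> snapshot readout at time t, with the input
uniform over [0, Xmax].  Implementation: moments are propagated at the
sampled doses (the 12-well estradiol series 100*(2/3)^(c-1) nM plus 0 nM, or
a geometric series over 0-250 nM for the cascade), linearly interpolated in
dose, and the continuous uniform input realized as a fine equally-weighted
dose grid (501 points by default; doubling the grid changes the reported MI
by < 0.1 %).  For scalar observables the MI sum runs over the natural
integer support of molecule counts - the channel is genuinely discrete, and
at output SDs of order one molecule the count quantization (variance 1/12)
is a real, physical reduction of the channel fidelity.  Joint observables
use per-dose (multivariate) normal conditionals evaluated by Gauss-Hermite
quadrature of the mixture cross-entropy; conditionals are floored at one
molecule^2 of variance (count granularity).

**Measured-fluorescence channel.** The synthetic-circuit MI figures refer to
fluorescence measurements, not bare molecule counts.  The measured channel
adds an autofluorescence background per channel: means shift by the
background mean and variances grow by its variance.  The default background
is calibrated from the model itself, implementing the observation that the
early y2 signal strongly overlaps autofluorescence: background mean = model
y2 mean at t = 65 min at the top dose (74.3 molecules-equivalent for the
SGF model, 326 for the intrinsic model), SD = mean/3; the reporter channel,
driven by a strong constitutive promoter, gets 5 % of its pre-stimulus mean.
These constants were fixed by this calibration rule, not fitted.  On this
channel the SGF population MI rises from 0.33 bits at 65 min to a plateau of
0.92-0.98 bits at 330/580 min, the single-cell (S1) value is 1.66 bits at
580 min, and the intrinsic model's measured y2 noise ratio between 165 and
580 min is 1.71; the bare molecular channel gives 1.27-1.29 bits, 2.20 bits
and 1.47 respectively.

**How many experiments (N).** MI is recomputed for nested geometric dose
sets of increasing size N; for each consecutive triple the ratio
r = (MI_N - MI_{N-1})/(MI_{N-1} - MI_{N-2}) extrapolates the limit
MI_inf = MI_N + r (MI_N - MI_{N-1})/(1 - r) (Aitken form; guarded for
constant sequences and |r| >= 1), and the first N within 1 % of MI_inf is
accepted.  For the cascade at t = 750 min the criterion accepts N = 5 and
the sequence is flat to four digits by N = 13, comfortably inside the
N <= 20 envelope.

**Population decompositions.**  Initial regimes: S1/S2/S3 are point states
with G at gbar, gbar -/+ sqrt(gbar) and the other species at their
conditional stationary means; Sg pins G at gbar but keeps the intrinsic
conditional covariance; "heterogeneous" is the full stationary population.
"One standard deviation away" is applied to G, inducing the corresponding
offsets in the readout marginals.  The slow-variable decomposition
(conditioning on G) uses an integer G grid carrying Poisson(gbar) weights
(coverage 1 - 1e-9 by default, or the heaviest n nodes renormalized).
During G-conditioned propagation the G birth/death reactions are frozen
(pinned); this idealizes the slow-fluctuation limit and makes the identity

    I(x; [y, G]) = E_G[ I(x; y | G) ]

exact up to quadrature (verified to < 1e-4 bits at gamma_g = 3e-8 when the
joint side represents p(y, G | x) as the G-mixture of locally-Gaussian
components; a single joint Gaussian smears the curved (y, G) ridge and loses
~0.2 bits, and unpinned G drift over the experiment costs a further ~0.3
bits by making the recorded G an imperfect readout of the cell's state -
both effects are available behind flags).  A one-node grid degenerates to
the G = gbar subpopulation, i.e. the Sg regime - not the point state S1,
whose conditioning is strictly more informative.  The diversity metric
I(y; G, t | x+) is small but nonzero at t = 0 because the pre-stimulus
output level is itself G-coupled through translation.

**Joint reporter/output MI.** I(x; [y1r, y2], t) uses bivariate normal
conditionals; the chain-rule route I(x; y1r) + E[I(x; y2 | y1r)] (analytic
Gaussian conditionals, posterior input weights on a y1r grid) agrees with
the direct 2-D quadrature to ~1e-7 bits at the default orders.  The
mean-equalization transform sets the reporter mean at every dose to its
zero-dose value while rescaling the variance (preserving SD/mean) and the
cross-covariance (preserving correlation), enforcing I(x; y1r) = 0 exactly.

## Stochastic-simulation oracle

A Gillespie direct-method sampler (numba-compiled inner loop, pure-Python
fallback) provides statistically exact CME sample paths for any network,
reproducible from a seed via per-run substreams.  Heterogeneous initial
states are sampled per species from the stationary family-rule marginals
conditioned on a Poisson-drawn G (cross-species intrinsic correlations are
not reproduced by this recipe).  Distribution comparisons smooth the
empirical sample and the model law with the same Gaussian kernel (default
bandwidth half the model SD) before max-normalizing, so kernel bias cancels
and residual disagreement is location/shape error plus sampling noise.

## Validation results the tests compute

* Moments vs SSA, heterogeneous SGF circuit at the top dose (100 nM,
  t = 580 min, n = 2000): means agree to 2.4 % (y2) and < 0.3 % (all other
  species); SDs to < 1 %.
* Moments vs SSA at low doses (S1 init, t = 580): the closure's Hill-input
  bias shifts the y2 location by ~0.27 SD at 8.78 nM (max-normalized sup
  distance 0.16, n = 5000); the global-variable distribution agrees to
  sup distance 0.046, at the Monte-Carlo noise floor.  This is the affine
  scheme's intrinsic low-copy limitation, not an implementation artifact.
* The cascade ensemble means at a moderate dose agree with the closure
  within 3 standard errors; the long-run occupancy of the G birth/death
  process passes a chi-squared test against Poisson(50) at alpha = 0.01.

## Synthetic cytometry generator

Emulates the two-reporter flow experiment: >= 3000 cells per well-time,
twelve wells, five sampling times, fresh cells at every sampling (cytometry
is destructive, so no per-cell correlation across times is generated).  SGF
variant: each cell's G is a Poisson(42) draw frozen over the experiment; its
(y1r, y2) pair is sampled from the G-conditional bivariate law (conditional
moments computed on an integer-G grid of spacing 2 and interpolated - the
moments are nearly linear in G over a unit step).  Fast-global variant
(gamma_g = 3e-4): G decorrelates within a protein lifetime, cells are
exchangeable, and readouts are drawn from the unconditional population law.
Intrinsic variant: single propagation per dose.  At low copy number the two
channels are sampled independently from their family-rule marginals; the
neglected residual intrinsic cross-correlation is small next to the shared
factors already conditioned on.  Autofluorescence is added per channel as
above; gains default to 1.  Optional knobs (off by default, qualitative
emulations only): a first-order fluorophore maturation delay and a
multiplicative cell-size factor are *not* modelled; the generator reproduces
size-normalized fluorescence directly.

What the generator does not emulate: cytometer gating artifacts, spectral
spillover, the mCherry dynamic-range limit, pipetting/dilution variation
across wells, and any real-data deviation from the reaction-network model
itself.  Passing generator-based tests therefore demonstrates internal
consistency of model + estimator, not correctness on real cytometry data.

Classifier: the regime call uses the y2 noise-ratio insets.  Slow-global if
the late-time noise ratios noise(t)/noise(580) at the top dose lie within
0.15 of 1 (measured: 0.91/0.95 for SGF).  Otherwise the
background-corrected signal (background estimated from the zero-dose well)
is tested for Poissonian scaling across time - a purely intrinsic circuit
predicts the 165-to-580-min signal noise ratio to equal
sqrt(mean_580/mean_165) - and called intrinsic when the measured ratio is
at least 1.45 and matches that prediction within 25 % (measured: ratio 1.69,
prediction matched to 6 %); else fast-global (measured ratio 1.27 at
gamma_g = 3e-4).  Thresholds are configurable; the defaults separate the
three generating variants with margins of at least 0.2 in the ratio.

## Problem sizes

Shipped scenarios and tests run on one CPU: moment propagations are
seconds; MI curves use the 12-dose protocols with a 501-point interpolated
input grid; the slow-variable identity check uses a 15-node G grid and a
51-point input grid; SSA cross-checks use n = 2000-5000 runs at low doses
and n = 2000 at the top dose (the figure-level validation).  The
synthetic-cytometry tables default to 3000 cells per well-time.
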