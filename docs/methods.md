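# Methods

This note records the modeling assumptions, numerical choices and known
limitations of `qrpop`. Units throughout: time in ms, rates in kHz
(reported as Hz at interfaces where noted), currents in pA.

## Single-neuron model

The neuron is a spike-response model (SRM) with escape noise and an
exponential link: the conditional intensity given the input and the
neuron's own spikes is `lambda(t|history) = lambda0 * exp(h(t) + sum_i
eta(t - t_i))`. The membrane filter `kappa` and the spike after-potential
(SAP) `eta` are causal sums of exponentials; `eta` is dimensionless and,
for the adapting regime studied here, non-positive. An optional absolute
refractory block forces the hazard to zero for a fixed interval after each
spike; it is modeled as a hard block rather than a large negative
amplitude so that classic renewal closed forms (`A = lambda/(1 +
lambda*Delta)`) hold exactly in tests. Restricting `kappa` and `eta` to
exponential sums lets every convolution advance by an O(1)-per-term
recursion; arbitrary kernels would require direct convolution and are out
of scope.

## Default parameters and calibration

The SAP shape is fixed at `eta = -5*exp(-t/30) - 1*exp(-t/400)`: a strong
fast component (refractoriness) plus a weak slow one (adaptation),
characteristic of layer-2/3 pyramidal cells. The two remaining scalars —
`lambda0` and the `kappa` amplitude `k0` (with `tau_m = 10` ms) — are not
hand-set numbers but the solution of a calibration: the quasi-renewal
stationary rate must equal 0.9 Hz at a constant 10 pA and 7 Hz at 70 pA.
The anchors place the model in the regime the theory was developed for:
quiescent near the 10-pA baseline (< 1 Hz), vigorously firing yet strongly
adapted at 70 pA (mean ISI ≈ 160 ms, consistent with strong-step
last-interval measurements), and — checked by direct simulation — peaking
near 90 Hz when driven by Ornstein-Uhlenbeck current of 80 pA standard
deviation, the reported response magnitude for such input. Because the
stationary rate depends on `lambda0` and `h` only through `lambda0*e^h`,
the calibration reduces to two independent scalar root solves (no nested
fixed point); `default_model()` computes and caches it per process,
yielding `lambda0 ≈ 5.8e-4` kHz and `k0 ≈ 7.9e-3 /(pA·ms)`.

## Direct simulation

Time is discretized in bins of `dt` (supported range 0.005–0.5 ms, default
0.5). Per neuron and bin a spike is drawn with probability `1 -
exp(-lambda*dt)` — the exact probability that an inhomogeneous Poisson
process with the bin's hazard emits at least one event. Each spike adds
one exponential state per SAP term; states decay by `exp(-dt/tau)` per
bin, and a spike's effect begins in the bin after emission so that a
neuron cannot interact with its own spike within a bin. One seeded
generator draws all neurons in a fixed order, making rasters bit-identical
under a fixed seed regardless of vectorization. The PSTH is the bin count
divided by `N*dt`, smoothed by a centered moving average (default 2 ms,
zero-padded ends, so the time integral of activity is conserved).

## Filtered input

`h = kappa * I` uses the zero-order-hold exponential integrator: for each
term, `s[n] = s[n-1]*exp(-dt/tau) + a*tau*(1-exp(-dt/tau))*I[n-1]`. This
is the exact continuous-time convolution of the piecewise-constant input,
sampled at bin starts, and is the same discretization the simulator and
all encoders consume, so theory and simulation see identical `h`. The
decoder-side inverse (`current_from_h`) solves the same recursion for
`I[n]` jointly over the kappa terms; it is exact on interior bins and
propagates masked gaps.

## Survival solvers (renewal and quasi-renewal)

The state is the density `S_j` of neurons whose last spike is `j*dt` old,
for ages up to the kernel cutoff `T_c` — the smallest time beyond which
`|e^eta - 1| < eps` (default `eps = 1e-4`, giving `T_c ≈ 3.7` s for the
default SAP) — plus the scalar `free` mass of older-last-spike neurons.
Hazards on the age grid are `K_j = lambda0*exp(h(t) + eta(j dt) + F_j)`;
the adaptation factor `F_j` integrates `(e^{eta} - 1)` against the past
activity from the age grid's suffix (a reversed cumulative sum, O(M) per
step), and the free population drops both the last-spike kernel and its
`F` (each below `eps` by the cutoff's definition). Renewal theory is the
same machinery with `F = 0`.

Emission uses per-bin probabilities: the activity of bin t is

```
A(t)*dt = sum_j S_j*dt * (1 - e^{-K_j dt}) + free * (1 - e^{-K_free dt})
```

with the surviving mass `S_j*(e^{-K_j dt})` aging by one bin and `A(t)*dt`
entering the first bin. This matches the simulator's per-bin semantics
exactly, conserves total probability identically (the tracked residual is
floating-point drift, ~1e-15), and remains stable when the population
fires as a near-synchronous burst (`A*dt -> 1`). The alternative
hazard-times-density emission (`A = sum K_j S_j dt + ...`) differs only at
O(K dt) per bin, but because the adapting steady state sits at the
`free ≈ 0` boundary the accumulated mismatch shifts the plateau by ~30% at
`dt = 0.5` ms; the emission-probability form removes that bias (plateau
within 0.04% of the stationary fixed point at `dt = 0.5`).

## Moment-expansion solvers

EME1 evaluates `A = lambda0*exp(h + integral)` with the adaptation
integral on a nonlinear age grid: bin widths `dt*ceil(a^j)` with `a`
chosen so ~200 bins cover `T_c` (fine near the spike where `e^eta - 1`
varies fast, coarse in the tail). Each bin's weight is the integral of
`e^{eta} - 1` over the bin, computed once on the fine `dt` grid, so the
coarse grid adds no stationary quadrature bias; past activity is sampled
at bin-end ages, making the scheme explicit. The stationary solution then
matches the closed-form Lambert-W gain to ~1e-4 relative.

EME2 adds the second cumulant of the spiking history:
`1/2 * sum_jk w_j w_k A(t-e_j) A(t-e_k) * (m_h(|e_j - e_k|)/A_h - 1)`,
where `m_h` is the renewal density (rate of an event at a given lag after
an event) of the stationary renewal process at filtered input `h`, and
`A_h` its rate. The pair-correlation matrices are precomputed on a lookup
table of 33 `h` values spanning the input trace (linear in `h`, i.e.
logarithmic in the exponentiated drive) and linearly interpolated; values
outside the table are clamped with a warning. Near the diagonal
`m_h/A_h - 1 ≈ -1` (refractoriness), so the correction lowers the
activity where recent firing was high — shortening the onset peak, as a
second-order term should. Forcing the correction to zero reproduces EME1
bit-for-bit.

## Decoders

Both decoders advance their internal state from the observed activity —
also through masked bins — so decoding resumes cleanly after gaps. The
EME1 decoder is the exact algebraic inverse (a log of the momentary
activity minus the past-activity accumulator). The QR decoder solves, per
bin, the emission equation for `x = e^h`; the emitted mass is concave and
increasing in `x`, so Newton iteration started from the direct ratio
(the small-dt limit) converges monotonically and quadratically, and the
encode→decode round trip is exact to machine precision. Bins with
activity below `a_min` are masked and reported with the upper bound on `h`
implied by `A < a_min`. The default `a_min` is one expected spike in the
estimation window, `1/(N*window)`; with a box window this coincides with
"the smoothed activity is nonzero".

A caveat established numerically: while the decoder itself is unbiased
(decoding a noise-free activity trace gives a sign-balanced error), the
error sign on finite-population PSTHs is not a fair coin — at low
per-window counts the validity mask selects upward activity fluctuations,
and at high counts percent-level theory-vs-simulation discrepancies are
amplified by the adaptation feedback in the decoder state.

## Steady state

The averaged hazard at age s is `lambda_bar(s) = lambda0*exp(h + eta(s) +
A*R(s))` with `R(s) = int_s^inf (e^{eta} - 1)`; note `R -> 0` as the last
spike ages (the adaptation factor covers only spikes before the last one),
so very-long-ISI neurons fire at the unadapted rate. The ISI density is
`P0 = lambda_bar * exp(-int lambda_bar)` on an adaptive uniform grid
(extended until the survival drops below 1e-9; the mean-ISI tail beyond
the grid uses the constant-hazard closed form, exact past the kernel
cutoff). The stationary rate solves `A = 1/mean-ISI(A)` by damped
iteration (factor 0.5, tolerance 1e-8) with a bracketing bisection
fallback; for an adapting SAP the map is monotone and the root unique in
`[0, lambda0*e^h]`. The autocorrelation is assembled from the renewal
density `m`, computed by the renewal integral equation `m = P0 + P0*m`
(a marching trapezoid recursion) rather than by FFT of
`P0_hat/(1 - P0_hat)`, whose DC singularity makes the periodized sum
ill-conditioned: `C(s) = A*m(|s|)` for `s != 0` plus a Dirac component of
weight `A` reported separately; `C -> A^2` at long lags and is flat for a
Poisson population.

## Synthetic stimuli

The fluctuating stimulus is a stationary OU process (default correlation
time 300 ms) generated with the exact update `x <- mu + (x-mu)e^{-dt/tau}
+ sigma*sqrt(1-e^{-2dt/tau})*xi`, which has no time-step bias; an `euler`
flag reproduces the literal first-order update for comparison. The
staircase variant rescales one continuous unit-variance path segment by
segment, so the trajectory is shared across variance steps. Steps use the
half-open convention (the bin containing the onset is already stepped).
These stimuli emulate in-vitro current injection: Gaussian, stationary
within segments, with a single correlation time. They do not emulate
synaptic bombardment with conductance effects, non-Gaussian natural
statistics, or slow nonstationarities, so agreement on them bounds, but
does not guarantee, performance on such inputs.

## Problem sizes and test design

Validation runs use 5,000–25,000 neurons for encoding comparisons (PSTH
sampling noise ~1/sqrt(N) per bin), 250 neurons for the small-population
decoding studies, and `dt = 0.5` ms throughout, with finer grids (0.25,
0.1 ms) in convergence checks. The error-sign balance between theory and
PSTH has a run-to-run scatter of ~0.04 even at 25,000 neurons (errors are
temporally correlated over the stimulus correlation time), so the suite
pools it over a grid of input means and replicate seeds. Statistical
assertions use 3–4 sigma tolerances derived from the relevant counting or
between-run noise.

## Known limitations

* All theories describe unconnected, homogeneous populations; coupled or
  heterogeneous populations are out of scope.
* The quasi-renewal truncation degrades during extreme synchronous bursts
  in which single neurons fire several spikes within a few tens of ms: the
  averaged pre-last-spike suppression (bounded by one `1/e` factor per
  expected past spike) underestimates the true multi-spike refractoriness,
  so burst peaks are overestimated at strong drive.
* At `dt = 0.5` ms the simulator and the solvers discretize synchronous
  bursts in opposite directions (the simulator caps one spike per neuron
  per bin); their agreement on burst peaks improves markedly at
  `dt = 0.1` ms.
* The EME2 correction assumes the pair correlation of a stationary renewal
  process at the momentary input — a quasi-static approximation validated
  here only by its EME1 degeneration and by improving the step-response
  error, not against an independent derivation.
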