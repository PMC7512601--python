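# Methods

## Problem and model

A stream X_1, X_2, … is i.i.d. f_{θ0} up to an unknown change time ν and
i.i.d. f_θ afterwards, with θ0 known and θ unknown.  All densities belong to
an exponential family f_θ(x) = exp{θᵀφ(x) − Φ(θ)} dH(x): the multivariate
normal N(θ, I_d), the exponential (Gamma with fixed shape α=1, natural
parameter θ = −β < 0), and the product of d independent Bernoulli coordinates
(θ_c = logit p_c).  The base measure H is never represented: every public
quantity is a likelihood ratio or a divergence, in which dH cancels.

The detectors replace the unknown post-change parameter with a
*non-anticipating* plug-in estimate: the term for X_t is computed with
θ̂_{t−1}, which depends only on X_1..X_{t−1}.  This preserves the martingale
property E_∞[Λ_t | F_{t−1}] = Λ_{t−1} under the null for the running product
Λ_t of plug-in density ratios, which in turn gives the distribution-free
false-alarm bound P_∞(τ(b) < ∞) ≤ e^{−b} for the one-sided SPRT
τ(b) = min{t : log Λ_t ≥ b}, and the run-length bound ARL ≥ γ at threshold
b = log γ for the change-point procedures.

For change detection, every hypothetical change point k in a sliding window
of w+1 candidates keeps its own branch: an estimator restarted at θ0 (its
step schedule begins again at η=1 with X_k as the first sample) and the
branch statistic log Λ_{k,t}.  The adaptive-CUSUM statistic (ACM) is the
maximum over branches, the adaptive Shiryaev–Roberts statistic (ASR) the
log-sum-exp; ASR ≥ ACM pathwise, so at equal threshold ASR stops no later.
ACM/ASR/CUSUM alarm on strict exceedance (statistic > b); the SPRT stops on
log Λ_t ≥ b.

## Estimators

Online mirror descent in the dual (mean) parametrization moves
μ̂ ← μ̂ − η_t(μ̂ − φ(X_t)), maps back through the inverse mean map ∇Φ*, and
Bregman-projects onto a feasible set Γ.  With the default harmonic steps
η_t = 1/t the dual state is exactly the running mean of the sufficient
statistics; for the Gaussian family the unconstrained estimator is therefore
the running sample mean, and on such paths the regret (cumulative plug-in
log-loss minus hindsight log-loss) equals the weighted Bregman sum
Σ_i i·B_{Φ*}(μ̂_i, μ̂_{i−1}) exactly.  Supported projections: full space
(identity), coordinate boxes (clipping — exact for these separable
log-partitions), and the Euclidean ℓ1 ball for the Gaussian family
(soft-thresholding).  Other (family, set) pairs raise an error rather than
silently falling back.

Boundary guards.  The mean-domain boundaries are open, so plug-in estimates
are clamped before inversion.  Gamma: μ ≥ 1e−8 and θ ≤ −1e−8.  Bernoulli:
a running mean over n samples is clamped to [1/(2(n+1)), 1 − 1/(2(n+1))]
(the Krichevsky–Trofimov boundary values, floored at 1e−8).  The width must
shrink with n: a fixed tiny clamp turns a one-sample estimate into
p̂ ≈ 0 or 1, whose next-step log-ratio is ≈ −18 per coordinate when
contradicted, destroying both the regret behaviour of the estimator and the
detection delay in high dimension.  Clamping keeps the estimate predictable,
so the null martingale property — and with it every false-alarm guarantee —
is unaffected.

Baselines.  Classical CUSUM uses a fixed nominal post-change parameter.  The
window-limited GLR recomputes the exact segment MLE from prefix means; the
hypothetical change k owns the segment X_{k+1}..X_t, the earliest candidate
is k=1, and the empty k=t segment contributes zero (so the statistic at t=1
is 0).  The "shrinkage" variant soft-thresholds the running segment mean at
λ = √(2 log d / n) (a convenience baseline, not a tuned estimator), and the
Gamma method-of-moments estimator θ̂ = −1/mean coincides with unconstrained
OMD for this family.

## Point-process extension

Events from a homogeneous Poisson process with known rate μ may start
self-exciting at the change: intensity μ + θ Σ_{t_j<s} βe^{−β(s−t_j)} with
unknown θ > 0.  The stream is scanned at event times; the events in
[T_i − L, T_i] form the window X_i, with per-window log-likelihood
ℓ(θ|X_i) = Σ_q log(μ + θA_q) − μL − θB (A_q the kernel excitation at event
q, B the compensator sum).  Because ℓ(0|X_i) is the Poisson window
log-likelihood rather than zero, branches accumulate the *centered* ratio
ℓ(θ̂) − ℓ(0), which vanishes at θ̂ = 0 and makes a newborn branch contribute
nothing — consistent with the exponential-family detectors.  Branch
estimates start at 0 and follow projected stochastic-gradient *ascent*
(a descent step on a log-likelihood objective would reduce the likelihood)
with clipping to [0, θ_max].  Defaults: μ = 1, β = 1, L = 5, w = 50,
step 0.01, θ_max = 0.99 (sub-critical branching).  Delay is counted in scan
steps.  The Poisson simulator uses exponential gaps; the Hawkes simulator is
Ogata thinning with the exponential-kernel recursion; θ ≥ 1 (explosive)
warns and is capped by the horizon.

## Calibration and Monte-Carlo harness

Thresholds are calibrated so the estimated ARL matches a target γ.  On a
fixed null path the first exceedance time of level b is nondecreasing in b,
so each path is simulated once while recording its first-hitting time for a
ladder of levels spanning [0.1 log γ, 3 log γ] (step 0.04; widened once to
6 log γ if the curve does not bracket γ): one pass yields the exact
common-random-numbers ARL(b) curve on the ladder, and the threshold is the
level whose ARL is closest to γ in log scale.  A small pilot (8 paths) finds
where ARL reaches ≈2.5γ so the remaining paths stop there.  Paths are
truncated at 3γ steps; truncated paths contribute the horizon, a downward
ARL bias of at most e^{−3} ≈ 5% at the solution that moves the calibrated
threshold by ≲0.05 nats.  Delay runs place the change at time 0 (where the
worst-case conditional delay is attained) and redraw the random change
support (shifted coordinates / changed edges) independently per trial.

Monte-Carlo scales: `full` (10,000 calibration + 10,000 delay trials,
matching the published protocol), `desk` (2,000 + 2,000) and `mini`
(~50–200 calibration paths + 300–500 delay trials), the default for the test
suite and the acceptance script.  Error budget at `mini`: the ARL estimate
from m paths has relative SE 1/√m (≈10% at m=100), which perturbs the
threshold by δb ≈ 0.1 and the delay by δb/I(θ, θ0) — well under 1% for the
reported cells; the delay SE at 400 trials is 3–4%.  The reference detectors
are plain Python/numpy; the harness drives numba kernels that the test suite
pins to the reference steppers step-by-step at 1e−9.

## Synthetic data: what it does and does not emulate

Streams are exactly i.i.d. before and after an abrupt, persistent parameter
change — the model under which the guarantees are derived.  Real surveillance
data (the motivating biosurveillance/social-network settings) add serial
dependence, drift, seasonality and model misspecification that the generator
deliberately omits; passing tests certify the procedures under the model,
not robustness beyond it.  The event-time generator produces exact Poisson
and Hawkes streams, so the point-process detector is likewise tested under
its own H0/H1.

## Numerical choices and known limitations

- Statistics are kept in log space; the ASR log-sum-exp is max-shifted.
- The ℓ1 projection solves the KKT threshold by sorting (O(d log d)).
- The martingale diagnostic (E_∞[Λ_t] = 1) is run with the estimator
  constrained to the box [−0.3, 0.3]: the property holds for any feasible
  set, but with an unconstrained estimator the mean of Λ_20 is carried by
  probability ≈ e^{−10} paths that no plain Monte Carlo can sample, whereas
  the constrained statistic has small finite variance.
- Gamma GLR: a single tiny observation x gives segment statistic
  ≈ −1 + x + log(1/x), so single-sample segments spike under the null and
  inflate the calibrated threshold; delays for the Gamma GLR baseline are
  therefore conservative relative to variants that exclude length-1
  segments.
- Bernoulli absolute delays at high dimension are sensitive to the boundary
  guard (see Estimators); the qualitative behaviour (delay decreasing in the
  number of changed edges, mismatched CUSUM failing for few changed edges,
  ACM ≈ ASR) is stable across guards.
- Pre-change parameters are assumed known exactly; only the one-node Hawkes
  model is implemented (no network influence matrix); mixture-type detection
  statistics are out of scope.
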