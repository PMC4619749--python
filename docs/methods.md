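# Methods

This note documents the models implemented in `wcst_attend`, the assumptions
behind them, the synthetic-data generator, and the numerical and design
choices that a user of the package should know about.

## The task

The probabilistic Wisconsin card sorting task presents, on every trial, a pair
of cards.  Each card carries one exemplar of each of three binary visual
features — color (red/green), motion (left/right), shape (circle/square) — so
there are 2³ = 8 distinct stimulus configurations.  A hidden rule H_t, one of
the six exemplars, determines the experimenter's choice: the card containing
the active exemplar is chosen with probability 1 − ε, the other card with
probability ε.  The design values are ε = 0.2 in the no-switch condition
(fixed rule) and ε = 0.3 in the switch condition, where the rule's *feature*
changes with probability p = 0.35 on any trial at least 8 trials after the
previous change (the refractory period; the block start counts as a change).
Blocks have T = 40 trials; a session has three blocks per condition.  Subjects
report beliefs by splitting $20 across the three features, a point r_t on the
2-simplex.

The simulator (`wcst_attend.task`) reproduces exactly this generative process.
On a switch the new rule is drawn uniformly among the four exemplars of the
other two features; a configuration flag (`allow_same_feature_switch`) permits
re-selecting the same feature's other exemplar instead, since the original
design is ambiguous on this point.

## Perceptual models

Beliefs live on a hidden state h_t = (h_e, h_f): six exemplar relevances and,
in the full hierarchy, three feature relevances.  The state propagates through
leaky winner-take-all (WTA) dynamics

    g_e(h) = τ_e h_e + κ_e + W_lat^e φ(h_e − κ_e) + W_dist^{fe} φ(h_f − κ_f)
    g_f(h) = τ_f h_f + κ_f + W_lat^f φ(h_f − κ_f) + W_dist^{ef} φ(h_e − κ_e)

with logistic φ, lateral inhibition of weight w_lat = 2κ (zero diagonal), and
symmetric excitation w_dist between an exemplar and its own feature.  Process
noise has variance q_e (q_f) per level.  Structural variants: `w1` (inhibition
on both levels), `w2` (κ_e = 0), `w3` (κ_f = 0), `d` (κ_e = κ_f = 0, purely
diffusive), and the reduced `rw`, `rd` (exemplar level only).  For `d` the
default wiring keeps only bottom-up excitation (exemplar → feature); the
bidirectional reading is available via `build_connectivity(...,
bidirectional_d=True)`.  We do not know which of the two the original analysis
used; the bottom-up default follows the structure diagrams rather than the
symmetric equations.

The Bayesian filter maintains a Gaussian belief {μ_t, Σ_t}.  Prediction
linearizes g, giving Σ̂ = J Σ J' + Q.  Observing the chosen card's exemplar
vector e_t yields a categorical hypothesis posterior

    ρ_k ∝ p(e_k | ε) exp(g_k),   p(e_k | ε) = 1 − ε if e_k = 1 else ε,

i.e. evidence gated by predicted relevance (the attention-like mechanism: a
hypothesis currently believed irrelevant contributes little even when the
evidence supports it).  The Gaussian update is one Newton step on the
quadratic expansion of the variational energy around the predicted mean:

    Σ_t = (Σ̂⁻¹ + Y)⁻¹,  Y = [diag(π) − π π'] ⊕ 0₃ₓ₃,  μ_t = g(μ_{t−1}) + Σ_t δ,

with π the softmax of the predicted exemplar relevances and δ = (ρ − π, 0₃).
The two algebraically equivalent covariance forms ((Σ̂⁻¹+Y)⁻¹ and
Σ̂(I+YΣ̂)⁻¹) are kept equivalent to 1e−10 by tests; the implementation
symmetrizes the result each trial and falls back to a 1e−8 diagonal jitter if
Σ̂ becomes numerically singular.

The non-Bayesian variants freeze the covariance at αI and update only means
with a fixed-gain prediction error (Rescorla–Wagner-like), with evidence
vector entries 1 − ϵ / ϵ left deliberately unnormalized (sum 3(1−ϵ)+3ϵ), as
the update rule defines them; a `normalize_rho` toggle exists for sensitivity
analysis.

Initial means are shared scalars per level (μ_e0, μ_f0) with isotropic
initial variances σ_e0, σ_f0.  The baseline model (BM) is the exception: its
response mean μ_f0 is a free 3-vector, since a scalar could not express a
subject's stationary response bias.

## Response models

The probability that feature i is relevant is p_i = softmax(μ_f)_i (full
hierarchy) or the summed exemplar-pair mass (reduced).  The modeled allocation
is the risk-adjusted power composition r = p^{θ1}/Σp^{θ1}; θ1 is an inverse
risk factor (θ1 → 0 gives uniform bets).  Stochastic responses perturb the log
of this composition with Gaussian noise ξ ~ N(0, P), P = θ2 I + θ3 Σ_f; θ3
(coupling response noise to belief uncertainty) is free only in the "full"
response model and only when Σ_f is dynamic, i.e. for Bayesian full-hierarchy
perceptual models.  The likelihood of an observed allocation is the
multivariate logistic-normal density evaluated at clr(r), with normalization
constant Z = (2π a'Pa)^{−1/2} exp(−(a'm)²/(2a'Pa)), a = (1,1,1)', correcting
for the projection of the unconstrained location m onto the zero-sum plane.
The location m = θ1 μ_f is used exactly as defined, without zero-sum
projection — Z carries the off-plane correction — and ln Z is computed in log
space so small covariances cannot underflow.

Observed responses are projected to the simplex interior (floor 1e−3,
renormalized) before the clr transform, because cursor responses can touch
the corners where clr is undefined.  The floor is configurable; whether the
original analysis clamped or excluded such trials is unknown.

## The 17-model space

BM; Bayesian {d, w1, w2, w3} × {full, reduced response} (8); Bayesian
{rw, rd} × reduced (2); non-Bayesian {all six structures} × reduced (6).
Family partitions used for family-wise comparison: {BM, NB, B},
{BM, RP, FP}, {BM, SFM, SM}, {RR, FR}; FR contains the four Bayesian
full-hierarchy models with full response, the only models that can carry θ3.

## Inversion

All free parameters are mapped to ℝ: ln for positive parameters, ln(2z/(1−2z))
for error rates (domain (0, ½)), ln((2z−1)/(2(1−z))) for time scales (domain
(½, 1); this is the sign-corrected reading — the alternative denominator is
negative on the whole domain), identity for initial means.  The prior is
N(χ; η0, s_o I) with η0 = 0 (i.e. ε = ¼, τ = ¾, positive parameters 1, means
0) and s_o = 2 by default; both are configurable, and nothing is known about
the original prior beyond its Gaussian form.

The log-joint (per-trial response log-likelihoods plus log-prior) is maximized
by a multi-restart derivative-free search from prior-dispersed starts.  The
default backend is an in-package implementation of CMA-ES (standard
(μ/μ_w, λ) strategy with rank-one and rank-μ covariance updates and cumulative
step-size adaptation), followed by a short Nelder–Mead polish; a pure
Nelder–Mead backend is available.  CMA-ES was adopted after Nelder–Mead alone
proved unable to reach the mode of the 14-parameter models reliably.  Each
restart's solution receives its own numerically differentiated Hessian
(central differences, per-coordinate steps 1e−3·max(1,|x|), optional
Richardson extrapolation) and Laplace evidence l(β) + ½ ln|2πS|, S = −H⁻¹;
the restart with the largest evidence wins.  Non-positive-definite −H is
shifted by the smallest diagonal amount achieving positive definiteness and
flagged.  The objective returns −∞ for numerically undefined parameter
regions, which simply ranks last inside the search.

A numba-compiled fast path evaluates the filter + likelihood loop (~0.3 ms
per 40-trial block, ~60× the pure-NumPy reference); it is verified against
the reference implementation to ~1e−10 in tests and falls back to the
reference automatically if numba is unavailable.

## Random-effects model selection

Per-condition, per-subject evidences (summed over blocks) enter a variational
Dirichlet random-effects scheme: subject posteriors g_nk ∝ exp(lme_nk +
ψ(α_k) − ψ(Σα)), α = α0 + Σ_n g_n, iterated to 1e−6.  EP = α/Σα; XP by 10⁶
seeded Dirichlet draws (analytic Beta tail for K = 2); the Bayes omnibus risk
compares the variational free energy of the alternative against the null in
which every subject's model is drawn uniformly, and the protected XP is
(1−BOR)·XP + BOR/K.  Family inference uses the family-balanced prior α0_k =
1/|family(k)| and aggregates Dirichlet mass within families.  Model-level
prior counts default to 1.  Note a known property of the variational update:
with *exactly* tied evidences and fractional prior counts the iteration
drifts toward the larger-α0 component; the BOR (which → 1 in that situation)
is the designed safeguard, which is why protected XP is the reported
quantity.

## Synthetic cohorts and what the tests show

`generate_cohort` emulates the study layout — n subjects × (3 switch + 3
no-switch) blocks × 40 trials — with per-subject parameters drawn uniformly
from stated ranges and responses generated by any chosen model.  The default
recovery-study regime uses structured Bayesian agents with ε ∈ [0.2, 0.3],
τ ∈ [0.7, 0.8], κ, w_dist ∈ [0.4, 0.6], q ∈ [0.8, 1.2], θ1 ∈ [0.8, 1.2],
θ2 = 0.05.  The high subjective process noise is deliberate: q is the noise
the *subject* assumes drives rule changes, so order-one values are the
realistic setting for agents trained on a switching environment, and they
keep belief amplitudes moderate so that responses stay off the simplex
corners.  What synthetic cohorts do not emulate: reaction times, learning
across sessions, cursor kinematics, response granularity, or any departure of
real humans from the model class — passing recovery tests shows internal
consistency of simulator + fitter, not validity for human data.

Problem sizes in the test suite (10 recovery subjects with 5 restarts,
16 + 8 subjects with 3 restarts and one block per subject for the family
study, 5,000 simulated blocks for design statistics) are chosen to keep the
full suite in the tens of minutes on one CPU while leaving the Monte-Carlo
error well below the asserted tolerances.

Known limitations: MAP parameter estimates of the 14-parameter full-hierarchy
models are only weakly identified from single-session data — the likelihood
has a flat ridge coupling trajectory amplitude (w_dist, κ, τ_f, q) with the
inverse risk factor θ1 and evidence weighting with ε — so individual
parameter values should be interpreted with the Laplace covariance in hand,
while model *evidence* (the quantity the pipeline is built around) remains
well behaved.  The alternative factorized hypothesis representation and
reaction-time analyses are out of scope.
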