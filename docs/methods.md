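# Methods

## The decision model

Each target-present trial is modeled as a one-dimensional Wiener process
for the decision *which color is the target*.  Evidence starts at
`z = B·a` between two absorbing boundaries — the distractor-color boundary
at 0 and the target-color boundary at `a` — and accumulates with drift `v`
and within-trial standard deviation `s`.  Absorption at `a` produces a
correct saccade, absorption at 0 an error; decision time plus a
non-decision component `Ter` (encoding and oculomotor delay) gives the
saccade latency.  Three trial-to-trial variabilities complete the model:
drift drawn from Normal(v, η) (the full, untruncated normal), starting
point from Uniform(z ± Sz/2), and non-decision time from
Uniform(Ter ± St/2).

### Parameters and units

| parameter | meaning | units | typical value |
|---|---|---|---|
| `v` | mean drift rate | evidence/s | 0.5–0.8 |
| `a` | boundary separation | evidence | 0.05–0.13 |
| `B` | relative bias z/a | — | 0.3–0.7 |
| `Ter` | non-decision time | s | 0.23–0.33 |
| `eta` | SD of drift across trials | evidence/s | 0–0.5 |
| `Sz` | range of starting point | evidence | 0–0.07 |
| `St` | range of non-decision time | s | 0.02–0.09 |
| `s` | within-trial noise (scale) | evidence/√s | fixed |

The scale constant deserves a note.  The pure-math layer
(`popddm.wiener`) defaults to `s = 1`, the natural mathematical
convention.  Everything at the study level (`RDMConditionParams`,
`FullModelParams`, the presets, fitting) defaults to the Ratcliff
convention `s = 0.1`, because that is the scale on which the reference
parameter values shipped in `popddm.presets` are expressed: at `s = 0.1`
those values predict ~92–100% accuracy and ~40 ms mean decision times,
matching the behavior they were estimated from, whereas at `s = 1` the
same numbers would predict chance accuracy and sub-millisecond decisions.
Since `s` only fixes the unit of the evidence axis, any analysis is
invariant as long as one convention is used throughout.

### Selection-history constraint scheme

A subject is described by 12 parameters (`popddm.conditions`): bias
deltas `dB_DPE`, `dB_POP`; baseline drift `v0` and drift deltas
`dv_DPE`, `dv_POP`; boundary separations and non-decision times per
trial family (`a_DPE`, `a_POP`, `T_DPE`, `T_POP`); shared `Sz`, `St`,
`eta`.  Deltas are signed: positive values favor the facilitated
condition of each effect (DP, SRe).  The preceding trial is identical
within each family (a target-present trial for SRe/SSw, a target-absent
preview for DP/TP), which is why `a` and `Ter` are tied within family
but free between families.  Eight sub-models constrain one or two of
these degrees of freedom (each delta pair or single delta to zero, or
`a`/`Ter` shared across families); constraints are implemented by
removing entries from the optimizer's parameter vector, so the search
dimension always equals the parameter count `M` used by AIC/BIC.

## Numerics

**First-passage quantities** (`popddm.wiener`).  Absorption
probabilities use the closed form `expm1(-2vz/s²)/expm1(-2va/s²)`,
evaluated after reflecting negative drift onto positive so no
exponential overflows; the `v → 0` limit `z/a` is substituted below
`2|v|a/s² < 1e-12`.  Densities use the two classical series — the
large-time trigonometric expansion and the small-time image-method
expansion — choosing per evaluation point whichever needs fewer terms
for an absolute unit-scale tolerance of 1e-10.  Defective CDFs use the
term-wise integral of the large-time series (`P_absorb − tail`), with an
early cutoff returning 0 when the start point is more than ~9.6
diffusion lengths from the boundary (mass < 1e-20).  A numba kernel
accelerates the CDF series when numba is importable; the pure-numpy
implementation is retained as the reference path and the two agree to
~1e-13.

**Variability integration** (`popddm.rdm`).  Gauss–Hermite quadrature
over η (default 20 nodes) and Gauss–Legendre over Sz and St (default 10
nodes each); a variability parameter equal to zero collapses its
quadrature to a single node, so the degenerate model reduces *exactly*
to the Wiener layer.  St enters by averaging time-shifted CDFs, which is
exact for CDFs.  Node counts are configurable; the fitting defaults in
the heavy recovery studies use (12, 6, 6), which changes a study-scale
chi-square by ≲0.2, and every reported `FitResult.chi_square` is
re-evaluated at the full (20, 10, 10) resolution.

**Trial sampling** (`popddm.simulate`).  Euler–Maruyama with a 0.1 ms
step and a Brownian-bridge crossing correction: after each interior
step, the probability that the within-step bridge touched either
boundary (`exp(-2(a-x₀)(a-x₁)/s²dt)` and `exp(-2x₀x₁/s²dt)`) is sampled.
Without the correction the discrete scheme under-detects crossings and
biases accuracy upward by several binomial standard errors at n = 10⁵;
with it, simulated accuracies sit within ~2 SE of the analytic values
and halving the step moves mean latency by well under 1 ms.

**Quantile chi-square** (`popddm.fitting`).  Per condition, observed
correct-latency quantiles at 10/30/50/70/90% (linear interpolation
between order statistics — the estimator is a documented choice) cut the
correct mass into bins with observed proportions (.1,.2,.2,.2,.2,.1) ×
accuracy; all errors form one bin.  Components are
`N(p_obs − p_exp)²/p_exp` with expected proportions floored at 1e-5; a
condition with zero observed errors contributes no error cell and
removes one degree of freedom.  Outliers (|latency − mean| > 5 SD, with
mean/SD over the subject's pooled target-present trials in a single
pass) are discarded before summarizing.  The total over the four
conditions is minimized by Nelder–Mead (adaptive, on a transformed
unconstrained space: tanh for bias deltas, log for scale parameters,
non-decision times as St/2 plus a positive gap) followed by a short
Powell polish, multistarted from a jittered method-of-moments
initialization (Ter from the fastest decile, the drift-boundary product
from overall accuracy through the logit link, `a` from mean decision
time).  The one remaining cross-parameter constraint — Sz small enough
to keep the start inside the boundaries in every condition — is enforced
by a large finite penalty.  Fits are deterministic given the options
seed.

**Likelihood for AIC/BIC** (`popddm.selection`).  The likelihood is the
multinomial likelihood of the binned counts over the same quantile bins
as the chi-square (the coefficient is omitted, so lnL ≤ 0), with
`n` = total trials entering the fit for BIC.  This is the only
construction self-consistent with the fitting statistic; nothing else
about the likelihood is assumed.

## The synthetic-data generator

`popddm.design` reproduces the study design: 32-trial sets built from
eight designed pairs (four inter-trial conditions × two distractor
colors) in random order with sixteen singletons — eight target-absent
(four per color) and eight target-present (four per distractor color) —
inserted uniformly at random into the gaps between pairs; five subjects
× 5 sessions × 5 blocks × 64 trials by default.  Labeling is by the
immediately preceding trial within a block (repeated/switched assignment
after a target-present trial; target- or distractor-color preview after
an absent trial); the first trial of a block is unlabeled and excluded
from fitting, and labeling never crosses block boundaries.  Under this
reading, essentially every predecessor-bearing target-present trial
receives a label, giving roughly 45–50 trials per condition per session.
Reported per-session condition counts for the original design are
somewhat lower and sum to fewer than the target-present trial count,
suggesting additional unstated exclusions; since the insertion and
labeling procedure is under-specified, the counts here are treated as a
plausibility anchor, not an exact contract.

Absent trials receive Bernoulli "false alarms" (default rate 0.02,
per-subject rates configurable; the presets carry the observed
0.6–10.6% rates) and no latency: the fixation-holding decision is not
modeled.  The generator's default parameters are the reference best-fit
sets in `popddm.presets`.

What the generator does *not* emulate: display geometry and timing
(ellipse positions, foreperiods), sequential dependencies beyond lag 1,
post-error effects, latency contaminants other than the diffusion
process itself, and any drift of parameters over sessions.  Passing
recovery tests on this synthetic data therefore demonstrates that the
estimation machinery is correct and well-calibrated for data generated
by the model — not that real saccade data satisfy the model's
assumptions.

## Problem sizes in the test suite and acceptance script

Simulation-versus-analytic checks use 10⁵ trials per parameter set.
Parameter-recovery and adequacy studies refit ten synthetic subjects of
1600 trials each (generation seeds 0–9); model recovery uses ten
two-subject studies with drift deltas zeroed, comparing the full and
drift-constrained models by summed AIC.  The acceptance script runs one
five-subject study end to end.  Optimizer budgets in these studies
(1–2 restarts, 1200–2500 simplex iterations plus polish, reduced
quadrature during search) were chosen as the package's standard
trade-off for studies of this size.

## Known limitations

* The recovered `dB_POP` estimator has a repeated-seed SD of ≈0.033 at
  the reference generating parameters (1600 trials/subject); its spread
  is dominated by a mild trade-off with η.  Recovery bands much tighter
  than ~2 SD of this spread will fail intermittently by construction.
* The quantile chi-square statistic is only asymptotically chi-square
  distributed; with ~200 trials per condition its minimized values run
  slightly heavy in the upper tail, so isolated adequacy rejections at
  the 5% level are expected even under the generating model.
* Only two-boundary (two-color) competition is modeled; location
  priming, three-accumulator dynamics, and fixation-holding on absent
  trials are out of scope.
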