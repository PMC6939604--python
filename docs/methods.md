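# Methods

This note documents the models, generator, numerical choices and known
limitations of `cptddm`. It complements the README (user-facing) and
the API docstrings (operation-level contracts).

## Task model

A CPT-AX session is 4 blocks × 100 trials: per block, 10 cue→target
("go") pairs, 10 cue-only trials, 10 uncued targets, remainder
distractors (11 identities). Stimuli show for 250 ms with a 1,400 ms
ISI; a go response must arrive within the 1,650 ms onset-to-onset
window. The pseudorandomisation enforces exactly three constraints:
fixed per-block counts; no undesignated cue→target adjacency (including
across block boundaries, guaranteed by never opening a block with a
target); and at least two intervening trials between go pairs. Go-pair
positions are drawn uniformly over the legal configurations via the
standard gap bijection, so sequences are unbiased within the constraint
set. Stronger constraints (e.g. spacing of cue-only trials) were left
out deliberately: they are not needed by any downstream computation and
would narrow the sequence space without observable consequence. One
template is shared by all children of a cohort (orders identical across
participants, different across blocks).

## Behavioural generator

Each synthetic child carries latent diffusion parameters (v, a, Ter)
and a commission rate. Go-trial behaviour is simulated from the Wiener
process: upper-boundary absorption → response at (Ter + decision time);
lower-boundary absorption → withheld response (miss). The two-boundary
mapping is required because EZ consumes hit/miss accuracy; responses
beyond the 1,650 ms deadline are additionally censored to misses.
No-go trials elicit a commission with the child's per-trial Bernoulli
rate, with RT uniform on 300–1,650 ms; the rate follows a
Beta(2, 81.3) distribution (mean 2.4%, matching the reported group-mean
commission percentage; the Beta shape is a modelling choice — no-go
behaviour is otherwise unmodelled and never enters the diffusion
analysis).

Group distributions (defaults): 33 VP / 32 term children; age
N(9.6, 1.0) vs N(9.1, 1.1) years; SWAN inattention N(−0.70, 9.89) vs
N(−6.58, 12.23); drift means 0.211 vs 0.191, boundary 0.112, Ter
0.253 vs 0.267 s. Between-child SDs are recovered from the reported
standard errors (SE·√n: 0.09 for v, 0.023 for a, 0.075 s for Ter).
Draws are truncated for physical validity (v, a > 0; Ter ≥ 0.05 s, a
floor covering minimal sensory-motor latency). Sex is Bernoulli at the
reported group percentages. One term-born child is marked missing their
SWAN rating by default, reproducing the study's listwise split
(multivariate comparison on the full N, correlations/regression on
N − 1). Each child consumes an independent `SeedSequence` substream, so
cohorts are reproducible and order-independent.

**Inattention–drift coupling.** Latent drift is
`v = v̄_group + β·z_swan + ε`, with z the within-group SWAN z-score and
the residual SD shrunk so the marginal drift SD stays at the group
value. β (default −0.050) was calibrated by replicate simulation so the
pooled age-partialed correlation between SWAN and *fitted* drift
averages ≈ −0.37 on 40-trial sessions, the magnitude the analysis is
designed around; the raw latent correlation is necessarily stronger
(≈ −0.55) because estimation noise at 40 go trials and the exclusion of
ceiling-accuracy children (range restriction in v) both attenuate it.
Inattention couples to drift only — not to boundary, Ter or commission
rate — so the generator embodies the "inefficient processing" account
in its purest form.

What the generator deliberately does **not** emulate: RT
autocorrelation and time-on-task drifts, post-error slowing, lapses or
fast guesses (contaminant RTs), distractor-identity effects, practice
effects, and any EEG-level structure. Passing tests therefore show the
*pipeline* behaves correctly under the model's own assumptions, not
that real children satisfy those assumptions.

## EZ estimation

`ez_fit` implements the three-equation closed form (see README) with
the s = 0.1 scaling convention; RTs are fitted in seconds, which is
what puts boundary separation near 0.11 and Ter near 0.25 s. Edge
policy: Pc = 1 or 0 raises `ParametersUndefined` (the study excluded
such children; the published edge correction is not implemented because
its recovery is unreliable at 40 trials); Pc = 0.5 raises
`DegenerateParameters` (L = 0 makes a indeterminate); below-chance Pc
yields negative drift with a warning; negative fitted Ter is reported
with a warning, never clamped — transparency over silent repair.
`ez_forward` is the exact algebraic inverse (`VRT` is the unique value
making the round trip an identity); the pair is verified to 1e−10 over
v ∈ [0.05, 0.5], a ∈ [0.05, 0.2], Ter ∈ [0.1, 0.4].

The accuracy entering EZ uses the same windowed hit definition as the
standard measures (200–1,650 ms; sub-200 ms responses are anticipatory
and count as misses, not merely as discarded RTs), keeping Pc and hit
rate consistent by construction.

## First-passage simulation

Trials are simulated by Euler–Maruyama from x₀ = a/2 with step
Δx = v·dt + s·√dt·ε. Naive discrete stepping has an O(√dt) absorption
bias (the path can cross a boundary inside a step and return), which at
dt = 0.5 ms inflates mean decision time by ~3% at group-mean
parameters. Each step therefore applies the Brownian-bridge correction:
given interior endpoints, the bridge crossed a boundary with probability
exp(−2·d₀·d₁/(s²·dt)) (d₀, d₁ the endpoint distances), resolved by one
uniform draw per step. The residual bias is O(dt): at dt = 0.5 ms and
10⁶ trials, simulated Pc, mean decision time and correct-RT variance
agree with the closed forms within Monte-Carlo error plus < 1%.
Decision times are recorded at step ends (a ≤ dt quantisation).
Default dt = 1 ms; the validation suite also runs 0.5 ms. A 120 s
safety horizon force-absorbs pathological trials (unreachable at
task-scale parameters). Antithetic variates are not used — plain
independent sampling keeps the per-child substream logic trivial.

## Goodness of fit

Per group, fitted parameters are arithmetically averaged across
children (not refitted to pooled data) and one supersubject of 1,000
trials (default) is simulated. Reported: simulated accuracy (%), mean
correct RT (ms) and correct-RT quantiles (10/30/50/70/90%), beside the
observed group means. Simulated accuracy is the raw upper-boundary
fraction; the observed hit rate additionally reflects window censoring,
so a small positive gap between them is expected and documented in the
README example.

## Inference

* **Partial correlation** — residual method: Pearson correlation of x
  and y residualised on [1, controls]; t on n − 2 − k df. With one
  control (age) this gives df = n − 3.
* **Fisher comparison** — z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)),
  using raw group n's; this convention reproduces the worked examples
  (z = 0.22 for hit rate, 0.32 for drift) to two decimals.
* **MANCOVA** — multivariate LM on [1, group, age]; per effect,
  H = (Lβ̂)'(L(X'X)⁻¹L')⁻¹(Lβ̂) with the other term retained in the
  model (unique/Type-III sums of squares), E from residuals; Pillai
  V = tr(H(H+E)⁻¹) with the standard F approximation — exact for
  single-df effects, df = (p, N − rank(X) − p + 1), hence (7, 56) at
  N = 65.
* **Stepwise regression** — {group, age} forced; candidates enter by
  smallest partial-F p ≤ .05, entered candidates leave at p ≥ .10
  (the conventional defaults of the likely original software; both
  exposed in config). Group is coded term = 0, VP = 1. Standardized β
  are b·sd(x)/sd(y) on the analysis sample (equivalently, the
  coefficients of the z-scored fit). ΔR² between nested steps equals
  the squared semipartial contribution of the added block and is tested
  by the block F.
* **Interaction regression** — three forced steps: {group, age};
  + measures (mean-centered); + group × centered-measure products.
  Centering makes the interaction ΔR² invariant to measure location.
* Listwise deletion is applied per operation over exactly the variables
  it uses; analysis Ns are recorded in the run manifest.

## Reproducibility and problem sizes

Every pipeline run derives all stage seeds from one master seed via
`SeedSequence` spawning; identical (config, seed) reproduce output
directories byte for byte (stage timings go to stderr only, keeping the
on-disk log deterministic). The validation suite uses 10⁶ trials for
simulator–analytic agreement, 100 × 10⁴ trials for parameter recovery,
and 100 replicate cohorts for the pipeline-level properties — sizes at
which Monte-Carlo error is well below the effects being checked while a
full run stays in the minutes range on one CPU.

## Known limitations

* EZ assumes unbiased starting point and zero cross-trial variability;
  starting-point bias or drift variability in real data bias its
  estimates, and no full-DDM refit is provided.
* At 40 go trials, fitted drift is a noisy estimate: across default
  replicate cohorts, the stepwise procedure identifies drift (rather
  than its own downstream proxies, hit rate and RT variability) as the
  best inattention predictor in roughly 70% of cohorts, rising to
  ~100% at several hundred children per group. Single-cohort stepwise
  selections at this design size should be read accordingly.
* The commission process is purely phenomenological; commission RTs
  carry no diffusion structure.
* Deadline censoring makes windowed hit rate sit slightly below the
  diffusion accuracy entering the supersubject comparison.
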