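# Methods

## Kinetic model

CFTR gating is modeled as a continuous-time Markov chain over seven
microstates ordered (C1a, C1b, C2, O1, O2, C3, C4).  The twelve directed
edges form a cycle with two reversible branches on each side and two
irreversible steps, O1 → O2 (ATP hydrolysis) and C4 → C1a (ADP release);
the reverse edges O2 → O1 and C1a → C4 do not exist.  Default rate
constants (wild-type, high open probability):

| edge | rate | edge | rate |
|---|---|---|---|
| C1a → C1b | 9.0·10³ (M·s)⁻¹ × [ATP] | O1 → O2 | 7.1 s⁻¹ |
| C1b → C1a | 5.0 s⁻¹ | O2 → C3 | 3.0 s⁻¹ |
| C1b → C2 | 7.7 s⁻¹ | C3 → O2 | 7.0 s⁻¹ |
| C2 → C1b | 5.8 s⁻¹ | C3 → C4 | 6.0 s⁻¹ |
| C2 → O1 | 4.9 s⁻¹ | C4 → C3 | 12.8 s⁻¹ |
| O1 → C2 | 10.0 s⁻¹ | C4 → C1a | 1.7 s⁻¹ |

C1a → C1b is the single second-order (ATP-binding) step; [ATP] is molar
and is an argument of `rate_matrix`, never baked into the scheme, so
concentration sweeps reuse one scheme object.  These rates give a
stationary open probability of ≈0.53 at 1 mM ATP and a total/nonpermissive
closing ratio of ≈12.4 in continuous time (stationary closing flux
π_O1·k(O1→C2) + π_O2·k(O2→C3) over the ADP-release flux π_C4·k(C4→C1a)),
nearly independent of concentration.

Discretization uses `Q = exp(R Δt)` via scipy's scaling-and-squaring
matrix exponential; tests cross-check it against a truncated Taylor
series rather than re-implementing it.  `Q` is dense: several transitions
can occur between consecutive samples, so off-topology entries are
positive but O(Δt²) (max ≈4·10⁻³ at 100 Hz and 1 mM; the entry grows with
[ATP] through the fast binding step).  The stationary distribution solves
πQ = π by direct linear solve with a strong-connectivity check first.

## Aliasing and the two closing definitions

A closing is a maximal run of closed-conductance samples flanked by open
samples; runs touching the sequence boundary are discarded because their
flanking open state is unobserved.  Classification uses only the flanking
open-state identities: permissive when they are equal, nonpermissive when
they differ.  On topology-respecting paths the flanking rule is equivalent
to "the closed segment contains the C4 → C1a step", and that equivalence
is exact on the embedded jump chain (`P_ij = R_ij / −R_ii`), which the
tests verify on 10⁶-step paths.  On Δt-sampled chains, however, ≈1% of
closings at 100 Hz are aliased — a brief open visit or a multi-step jump
falls between samples — producing flanking pairs such as (O1, O2) that no
valid path allows and (O2, O1) closings without a literal consecutive
(C4, C1a) sample pair.  Ground-truth labeling therefore follows the
flanking-state definition (different flanks ⇒ nonpermissive); a `strict`
flag that rejects impossible flanks is available for validated paths.

## Simulation

The simulator draws the hidden chain from `Q` starting at its stationary
distribution (a channel observed in steady state; a point-mass override
exists for tests) and adds iid Gaussian noise per `y_k = A·m(s_k) + n_k`.
Defaults mirror the benchmark conditions used throughout: Δt = 0.01 s
(100 Hz), n = 20,000 samples, A = 1, σ² = 0.02 (variance in squared
amplitude units, implying unit amplitude).  One integer seed feeds two
independent sub-streams (chain, noise), so the state path is reproducible
whether or not noise is drawn.  The generator emulates a single, stable
channel with white Gaussian noise; it does not model baseline drift,
correlated amplifier noise, 50/60 Hz pickup, multi-channel patches, or
flicker/subconductance behavior, so passing benchmarks here bound
performance on ideal recordings, not on every real patch.

## Inference

Posterior marginals p(s_k | y) and pairwise posteriors come from scaled
forward–backward message passing (sum-product on the chain factor graph),
exact for this model class.  States sharing a conductance class share a
Gaussian observation density, computed once per class per sample;
per-sample log-density rows are rescaled by their maximum before
exponentiation so that samples far from both current levels cannot
underflow, and the accumulated normalizers plus the rescaling constants
give the data log-likelihood.  Traces up to 10⁶ samples run without
underflow.  Exactness is pinned by an exhaustive-enumeration oracle on all
instances with |S|ⁿ ≤ 10⁵ (tolerance 10⁻¹⁰) and cross-checked against an
independent HMM library on a toy chain.

## Parameter estimation

`Q`, `σ²`, and optionally `A` are estimated by EM whose E-step is the
sum-product pass (factor-graph EM; for chain graphs the closed-form
M-step below is the standard Baum–Welch update, and that equivalence —
not message-level mimicry — is what the tests pin):

* `Q_ij ← Σ_k ξ_k(i,j)`, masked to the scheme edges plus self-loops and
  row-renormalized.  Estimating a *discrete-time* Q under the hard
  topology constraint is the module's central modeling decision: exp(RΔt)
  is technically dense, but its off-topology mass is O(Δt²), and the
  constraint is what makes the five electrically identical closed states
  identifiable.  Off-topology entries are exactly zero after every
  iteration.
* `σ² ← Σ_k Σ_i γ_k(i)(y_k − A·m(i))²/n`, floored at 10⁻⁸ to prevent
  likelihood blow-up on noise-free traces.
* `A ← Σ_k Σ_{i open} γ_k(i) y_k / Σ_k Σ_{i open} γ_k(i)` when enabled.
  Amplitude estimation is off in simulation benchmarks (A fixed at its
  true value) and on by default for real recordings; empirically the two
  modes give indistinguishable fits on benchmark traces (A is recovered
  to ≈0.1%).

Initialization is data-driven: the amplitude guess is the gap between the
means of samples above/below the midpoint of (min, max), the variance
guess the pooled within-cluster variance, and Q₀ puts 0.05·(1+u),
u ~ U(−0.5, 0.5), on each allowed off-diagonal entry with the remainder
on the self-loop.  A trace whose level separation is under three times
the within-level RMS raises "no openings detected".  The iteration count
is fixed (default 400) rather than tolerance-based; an optional early
stop exists but is off by default.  The inference initial distribution is
the stationary distribution of the current Q estimate, matching a channel
in steady state; strictly this ties the initial distribution to Q and is
not textbook EM, but the single-sample contribution is negligible and the
likelihood trajectory is non-decreasing to within 10⁻⁸ relative tolerance
on every benchmark run.  A state with zero expected occupancy keeps its
previous row (with a warning) rather than producing a 0/0 update.

## Detection and scoring

The decision rule keeps the per-sample MAP state when its posterior
probability exceeds C (0 ≤ C < 1) and returns null otherwise; C = 0 is
plain MAP.  Closings are segmented from the *ungated* MAP sequence, and C
enters through each event's confidence flag (both flanking open samples
above C), which the scorer uses as a filter.  Because marginal-MAP
sequences need not respect the topology, an estimated closing may carry
the impossible flank pair (O1, O2); it is labeled nonpermissive, following
the different-flanks definition.

Estimated events are matched one-to-one to ground-truth events by maximal
closed-interval overlap (≥1 shared sample), greedily in decreasing
overlap with ties broken by earlier start.  n_FA counts estimated
nonpermissive events whose match is not ground-truth-nonpermissive or that
match nothing; n_MD counts ground-truth nonpermissive events not matched
by an estimated nonpermissive event.  P_FA (resp. P_MD) is undefined when
no nonpermissive event is estimated (resp. present) and is reported as
NaN with an explicit flag; sweep averages exclude undefined runs.

## Preprocessing

Raw recordings (e.g. 2 kHz acquisition) are decimated by block averaging —
the mean over nonoverlapping blocks of `factor` samples (default 50,
giving 40 Hz from 2 kHz), trailing partial block discarded — chosen over
low-pass-plus-downsample for bit-reproducibility of the stated filter; it
cuts white-noise variance by the factor and pushes residual noise toward
Gaussian.  Polarity is flipped when openings deflect negative (the
cluster farther from zero is taken as open) and the baseline (median of
the closed-side samples) is subtracted, so closed ≈ 0 and open ≈ +A.

## Benchmark sizes and observed behavior

Prevalence statistics use 10⁶-sample ground-truth chains per
concentration on a five-point log grid from 0.05 to 5 mM (the
concentration axis of the original figures is not printed; the grid is
configurable).  Detection benchmarks use 20,000 samples, σ² = 0.02,
400 EM iterations, two runs per concentration (ten runs total), with the
ratio of nonpermissive to total closings ≈ 1/12 across the grid.  At
C = 0 the mean per-run false-alarm rate is ≈0.3 over this grid — it rises
steeply with [ATP] (≈0.1–0.3 at 0.05 mM, ≈0.4–0.7 at 1.6–5 mM, the upper
range matching the ≈50% figure reported for this detector) — and raising
C to 0.8 lowers P_FA at the cost of higher P_MD on every seed tested.
Running inference with the *true* parameters instead of EM estimates
gives P_FA ≈ 0.44–0.52 at 1 mM, so the error rates reflect the intrinsic
ambiguity of per-sample MAP under aggregated states, not estimation
quality.

## Known limitations

* The discrete-time Q estimate is not converted back to continuous-time
  rates (no matrix logarithm), and no standard errors are reported.
* Per-sample MAP can produce topology-violating sequences; a Viterbi-style
  joint decoder is not provided.
* Real-recording support expects text/CSV exports; native amplifier
  formats are out of scope.
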