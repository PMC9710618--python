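# Methods

## Probability model

A single photoswitchable fluorophore is assumed to emit a geometrically
("discrete-exponentially") distributed number of blinks before
photobleaching, with support B ≥ 1: every *detected* fluorophore blinked
at least once. Writing the characteristic blink number as λ, the success
probability of the geometric law is 1 − e^(−1/λ), so the mean number of
blinks per fluorophore is 1/(1 − e^(−1/λ)) ≈ λ + ½ for large λ. The
total blink count of a complex carrying N independent fluorophores is
the sum of N such draws — a negative-binomial distribution with support
B ≥ N:

    p(B|N) = C(B−1, N−1) (e^(1/λ) − 1)^N e^(−B/λ).

An ensemble of complexes with 1…h labeled subunits in fractions π₁…π_h
yields the mixture p(B) = Σ_k π_k p(B|k). All pmf arithmetic is done in
log space with log-gamma binomial coefficients: blink totals reach the
hundreds at large λ and N, where direct products underflow.

Assumptions worth validating on real data before trusting the output:
one fluorophore per subunit at most; independent, identically
distributed blinking across fluorophores; and a genuinely geometric
blink law. Organic dyes are environment-sensitive; a monomeric control
sample is the standard check.

## EM estimation

Latent per-complex oligomer orders make this a textbook
finite-mixture estimation problem. Each cycle:

1. **Responsibilities** r_k⁽ⁱ⁾ = π_k p(B⁽ⁱ⁾|k) / Σ_k′ π_k′ p(B⁽ⁱ⁾|k′)
   (Bayes); entries with k > B⁽ⁱ⁾ are exactly zero.
2. **Weight refresh**: π_k ← mean over complexes of r_k⁽ⁱ⁾.
3. **λ refresh** (closed form, the root of the score equation):
   λ ← 1 / log[ Σ r_k⁽ⁱ⁾B⁽ⁱ⁾ / Σ (r_k⁽ⁱ⁾B⁽ⁱ⁾ − k r_k⁽ⁱ⁾) ].

Steps 2 and 3 jointly maximize the expected complete-data
log-likelihood given the responsibilities from step 1 (the objective
separates in π and λ), so this is a standard EM cycle and the observed
log-likelihood is non-decreasing — an invariant the test suite checks on
every fit it runs. Internally the data are aggregated by unique blink
count, making an iteration O(U·h) rather than O(N_T·h).

Tunable settings (`EMConfig`) and their defaults:

| setting | default | rationale |
| --- | --- | --- |
| `tol` | 1e-8 | relative ΔL stopping rule; standard EM practice |
| `max_iter` | 1000 | ridge-shaped likelihoods (π₂/π₃ trade-off) converge slowly |
| `n_restarts` | 5 | mixture likelihoods are multimodal; best final L wins |
| `lam_bounds` | (1e-3, 1e3) | guards the log-of-ratio update on degenerate data |

Initialization: uniform weights and a method-of-moments λ₀ =
1/ln(B̄/(B̄−1)) from the sample mean (falling back to 1 when B̄ ≤ 1);
restarts draw weights uniformly on the simplex and jitter λ₀ by
U(0.5, 2). Weights are not floored — a component may converge to exactly
zero, which is the correct behaviour for over-parameterized fits.
Degenerate inputs (every count equal to its assigned component size,
e.g. all counts 1 under a monomer model) raise a dedicated error: λ is
not identifiable there.

## Labeling-efficiency correction

With labeling efficiency θ, each subunit of a k-mer independently
carries an active fluorophore, so the detected-label count is
Binomial(k, θ), and complexes with zero labels are invisible. The
apparent (detected-label-class) fractions are a renormalized binomial
thinning of the true fractions:

    π_k′ = Σ_{k ≥ k′} π′_k q(k′|k) / (1 − Σ_k π′_k q(0|k)).

EM is always run on the uncorrected mixture; the correction is applied
afterwards to the fitted weights, never folded into the EM objective. θ
is an input measured by control experiments, never estimated from blink
data. The forward map is projective-linear (upper-triangular matrix
followed by renormalization), so the generic inverse is a triangular
solve; closed forms for h = 2 and h = 3 are implemented and
cross-checked against the solve. Noisy EM estimates can invert to
slightly negative fractions; these are clipped to zero, renormalized,
and flagged (`clipped=True`) — clipping keeps the output interpretable
and the flag keeps it honest.

The h = 2 closed form fixes the orientation of the thinning sum: the
apparent class k′ aggregates *true species k ≥ k′*, the only orientation
under which the closed form exactly inverts the forward map (verified to
machine precision in the roundtrip tests).

## Model selection

Candidate maximum orders h = 1…h_max are each fitted by EM and scored
with AIC using k = h free parameters (h − 1 independent weights plus λ).
The default score is `2k − L`, the counting convention this method was
published with; the textbook `2k − 2L` is available via
`form="standard"`. The two weigh likelihood against parsimony
differently and can disagree near selection boundaries. Ties go to the
smaller order; candidates within ΔAIC < 2 of the winner are reported as
near-ties because AIC is guidance, not a verdict: at n = 1000 and
λ = 3.6 a 20% minority species contributes an expected log-likelihood
gain below the AIC penalty (≈0.7 nats for a 0.8/0.2 monomer/dimer
mixture), so small fractions are genuinely undetectable by AIC at this
sample size, and a true M/D/T mixture with a modest trimer fraction is
often scored as M/D.

## Simulator

`simulate_dataset` draws each complex's order from the true fractions,
thins labels with probability θ (discarding and counting zero-label
complexes), and generates blinks either **parametrically** (sums of
1-truncated geometric draws, realized as m + NegativeBinomial(m, p) for
m surviving labels) or by **pool resampling** — assembling protomers by
summing single-dye blink counts resampled with replacement from a
user-supplied pool, which mirrors how experimental benchmarks are built
from imaged single dyes. Replicates run on independent child streams
spawned from one root seed, so any replicate is reproducible in
isolation.

Default benchmark sizes are the study conditions the method was
characterized under: λ = 3.6, 1000 protomers per dataset, 50 replicates
at perfect labeling and 200 for θ sweeps. The acceptance script runs
exactly these sizes; the test suite trims some sweeps (100 replicates
for the θ = 0.8 correction check, restarts reduced to 1–2 in bulk
benchmarks) to keep a full run fast.

What the simulator does *not* emulate: frame-by-frame photophysics
(ON/OFF dwell times, photon budgets), localization error and drift,
spatial clustering or segmentation mistakes, and non-geometric blink
laws. Passing benchmarks therefore demonstrate correctness of the
estimator under the stated blinking model, not robustness to real-world
deviations from it — the monomeric-control check on real data remains
essential.

## Statistical limits worth knowing

The trimer fraction of an M/D/T mixture is intrinsically hard to pin
down from blink counts alone, because the N = 2 and N = 3
negative-binomial components overlap heavily. A Fisher-information
calculation at λ = 3.6, n = 1000 puts the Cramér–Rao bound on the
standard deviation of π̂₃ at ≈0.12 for a 0.4/0.4/0.2 mixture (replicate
CV ≥ 0.6) and ≈0.095 for 0.3/0.35/0.35 (CV ≥ 0.27) — and the converged
maximum-likelihood fit attains these bounds in our replicate
benchmarks. Mean estimates over replicates are accurate (biases of a
few percent for fractions ≥ 0.2 at θ = 1, worst-case ≈20% relative on
corrected fractions at θ = 0.8); single-measurement uncertainty is the
limiting factor, grows quickly as π₃ → 0 or θ drops, and grows with λ.
Smaller-λ fluorophores and larger fields of view help; more EM
iterations do not.

## Known limitations

* One fluorophore per subunit; heterogeneous or multi-dye labeling is
  out of scope.
* θ must be known; joint estimation of θ and λ from blink data is not
  identifiable in this model and is not attempted.
* The h = 3 closed-form correction is standard usage; for h > 3 the
  numeric inversion is used (with a warning at the CLI), and the
  apparent-weight inversion becomes increasingly ill-conditioned.
* AIC selection is unreliable for minority fractions at realistic
  sample sizes (see above) and degrades further when θ < 1.
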