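# Methods

## The sequential NTA chain

Nontemplated nucleotide addition is modeled as an irreversible first-order
chain S₀ → S₁ → … → Sₙ (n ≤ 3) with per-step observed rate constants
kᵢ (min⁻¹) and reactive fractions aᵢ ∈ (0, 1]. The reactive fraction
encodes the experimental observation that each addition step plateaus below
complete conversion: of the molecules arriving at species i−1, only aᵢ are
competent to undergo step i; the remainder is a dead-end pool that keeps
co-migrating with species i−1. Consequently the cumulative conversion of
step i saturates at a₁⋯aᵢ, and the reported "amplitude" of a step is its
reactive fraction.

Writing cᵢ = a₁⋯aᵢ and Pᵢ(t) for the occupancy of state i in the
all-competent chain (the Bateman solution with out-rates k₁,…,kₙ,0), the
measured species fractions are

    fᵢ(t) = cᵢ₊₁ Pᵢ(t) + (1 − aᵢ₊₁) cᵢ Qᵢ(t)   for i < n,
    fₙ(t) = cₙ Pₙ(t),

with Qᵢ = Σ_{j≥i} Pⱼ the cumulative arrivals at or beyond state i. The
fractions sum to one for all t, and the fraction with ≥ i additions,
cᵢ Qᵢ(t), is non-decreasing in time — both properties are enforced by
tests.

**Degenerate rates.** The generic Bateman denominators contain differences
of rates; when any two out-rates agree within 1e−8 of the largest rate the
implementation evaluates the exact matrix exponential of the chain
generator (`scipy.linalg.expm`) instead. The matrix exponential is the
analytic solution of the same linear system and is smooth through the
confluent point, so the model is continuous as k_{i+1} → k_i from either
side (tested from both directions). This choice replaces per-multiplicity
L'Hôpital expansions with one uniformly valid path.

**Independent oracle.** `ode_fractions` integrates the full compartment
system (reactive chain plus dead-end pools) with LSODA at rtol 1e−9 /
atol 1e−12. It shares no algebra with the closed form and serves as the
brute-force reference in tests; closed form and oracle agree within 1e−6
across 100 random models on 50-point grids.

## Fitting and uncertainty

`SequentialKineticsModel.fit` minimizes the unweighted sum of squared
residuals jointly over all species trajectories (all band fractions share
one densitometry measurement scale, so no per-species weighting is
warranted). Rates are parameterized as log₁₀ k for conditioning; bounds are
k ∈ (1e−6, 1e3) min⁻¹ and a ∈ (1e−3, 1]. Optimization uses
`scipy.optimize.least_squares` (trust-region reflective).

**Multistart.** Initialization never depends on the user: rate starts
{0.01, 0.1, 1} min⁻¹ are crossed per step (3ⁿ combinations), each combined
with a shared reactive-fraction start of 0.5 or 1.0 — 54 deterministic
starts for a three-step chain, scanned in a fixed order with early exit
once a start reaches machine-level rss. If every grid start fails, 20
seeded jitter starts are tried; if those fail too, the result is returned
flagged (`converged=False`), never as a silent success. On noiseless data
the generating parameters are recovered to optimizer tolerance (≪ 0.1 %
relative error; property-tested over random models).

**Order selection.** `select_n_steps` fits orders 1…3 and picks the
minimum small-sample-corrected AIC (AICc), breaking ties toward fewer
steps. Two numerical details make this robust: candidate predictions are
padded with zero columns so every order is scored against the same data
matrix, and rss is floored at n·1e−12 so that noiseless fits (rss at
machine epsilon) tie at the floor and the tie-break picks the smaller
model rather than comparing logs of round-off noise.

**Standard errors.** `bootstrap()` pools residuals over all cells,
resamples them with replacement onto the fitted surface, and refits each
pseudo-dataset warm-started at the point estimate. SEs are the standard
deviations of the bootstrap point estimates; non-convergent refits are
dropped and counted, with > 20 % drops flagging the result. On noiseless
data the SEs collapse below 1e−4 min⁻¹. Calibration: at noise 0.02 the
bootstrap SE of each rate falls within a factor of two of the standard
deviation observed across 200 independently simulated experiments.

**Time sampling.** Simulated experiments use `sampling_grid(t_max, 12)`:
zero plus a geometric progression from t_max/240 to t_max. Geometric
spacing is how chain kinetics are sampled at the bench — a uniform
12-point grid over 0–120 min puts its first nonzero sample ≈ 11 min in,
about seven half-lives past a 0.61 min⁻¹ second step, leaving that rate
essentially unidentifiable at realistic noise. With the geometric grid the
signed median relative bias of every rate constant stays below 2 % at
noise_sd = 0.02 (200 replicates).

**Noise model.** `simulate_timecourse` adds independent Gaussian noise per
band fraction, truncates at zero and renormalizes each row — a simple,
seedable stand-in for densitometry error. It is unbiased to O(noise_sd²);
the Monte-Carlo test budgets for that quadratic term explicitly.

## Gel quantification

Lane traces are integrated by the trapezoid rule over non-overlapping
per-band windows, with interpolated window endpoints so the integral covers
the window exactly; an optional rolling-minimum baseline subtraction is
available (default off — synthetic lanes are clean). Template-switching
efficiency is 100 × (sum of switched-product bands) / (total lane signal).
The denominator choice (total signal, including unswitched primer and
NTA-only bands) keeps the statistic in [0, 100] and comparable across
lanes; published per-lane efficiencies whose denominator convention is
unknown are treated as simulator parameters, not as recomputable targets.

## Library-prep simulator

Per molecule: transcript ∝ concentration; cDNA is full length by default
(the processive-enzyme assumption — an ultraprocessive RT copies through
structure; a `dropoff_rate` knob exists, default 0, for distributive
enzymes); overhang bases compete ∝ incorporation_rate × dNTP
concentration with chain extension governed by per-step continuation
probabilities (defaults equal to the measured step amplitudes 0.96, 0.96,
0.86); switching is Bernoulli with probability

    base_switch_eff × pairing_score × mod_penalty[template 5′ end],

and unblocked TSOs re-enter the cycle with probability `reswitch_prob`,
giving geometric concatemer counts (mean 1/(1−p)); a bulky 5′ block caps
the count at one.

Defaults are the measured study conditions: incorporation rates
A 0.19 / G 0.035 / C,T 0.002 min⁻¹ (first-step scale; C and T are only
marginally incorporated, so a small nonzero value is used), biased dNTP
mix 0.8 mM dATP + 0.4 mM others, pair weights AT/AU = GC = 1.0,
G:U wobble = 0.15 (weak but nonzero), mismatch = 0, modification penalties
hydroxyl 1.0 / triphosphate 20∕35 / m⁷G 10∕35 with base_switch_eff = 0.35
(the hydroxyl-template efficiency level). `reswitch_prob` defaults to 0.3 —
the cycling rate is not separately measured, and 0.3 yields visible
concatemer ladders (mean ≈ 1.4 copies) without dominating libraries. The
per-position overhang competition reuses first-step rates at every
position, since per-position rates in mixed-dNTP reactions are not
separately measurable; the qualitative acceptor ordering (U ≫ A, C, G) is
a validation check, not an input. A per-base 5′-nucleotide modulation hook
is deliberately absent: the mild 5′-G preference seen on capped templates
is not quantified, so neutral behavior is the default.

Pairing is scored antiparallel: overhang position j pairs with the j-th
base from the TSO 3′ end; the score is the product of per-position
weights, and an empty overhang scores zero (nothing to anneal). All
randomness in a `simulate_library` call flows from one counter-based
Philox stream with a fixed vectorized draw order, so identical seeds give
byte-identical libraries regardless of platform.

FASTA emission writes literal cDNA-strand sequences — primer +
reverse-complement(transcript) + (overhang + reverse-complement(TSO)) per
switching cycle — with `id|copies|mod` ground-truth headers that round-trip
through the reader.

## Spike-in quantification

TPM divides counts by transcript length in kb and normalizes to 10⁶; CPM
normalizes raw counts to 10⁶. Both accept expected (non-integer) counts so
that noiseless analyses are exact; sampled libraries always produce
integers. Linearity is ordinary least squares of log₂(TPM) on
log₂(concentration) restricted to detected transcripts (TPM > 0) — zeros
are excluded rather than pseudocounted, because at the bottom of a
six-decade ladder detection is depth-limited and a pseudocount would
manufacture signal where there are no reads. The detected dynamic range is
log₁₀(max/min concentration among detected transcripts). Downsampling is
without replacement (multivariate hypergeometric), mirroring read
subsampling semantics. Replicate agreement is Pearson r on log₂(metric+1).

## Synthetic generators

The default ladder has 92 transcripts with lengths uniform on
[250, 2000] nt and concentrations on a geometric grid spanning exactly six
decades (equally many transcripts per decade — the real control-mix
composition is proprietary, and a uniform log-grid is the right design for
linearity testing). The isoform set has 69 transcripts split as evenly as
possible over 7 loci, lengths uniform on [200, 2500] nt, with per-locus
concentrations cycling over {0.5, 1, 2, 4}. Gel fixtures render each band
as a Gaussian peak (σ = 0.8 migration units) of area equal to its
fraction at fixed per-label centers ≥ 6 units apart, so ±2.9-unit
integration windows capture > 99.9 % of each peak without overlap.

## What the synthetic data does and does not show

The generators emulate the *statistical structure* of the experiments:
band fractions with densitometry-scale noise, concentration-proportional
molecule sampling, pairing-gated switching, geometric concatemers, and a
six-decade abundance ladder. They do not emulate sequence-dependent RT
pausing, PCR preamplification bias, tagmentation, sequencing error, or the
true (proprietary) spike-in concentration table. Passing tests therefore
demonstrate that the estimators and statistics are correct and calibrated
under the stated generative assumptions — not that a particular wet-lab
protocol achieves any specific efficiency. Problem sizes in the test suite
(10⁵-draw distributional checks, 200-replicate calibration, 2 × 10⁵-molecule
libraries) are chosen so the binomial/chi-square tolerances stated in each
test are meaningful at desk scale.

## Known limitations

- Amplitudes are modeled as per-step dead-end partitioning; other
  topologies (e.g. a slowly exchanging inactive enzyme pool) could produce
  the same plateaus and are not distinguishable from band fractions alone.
- The fitter assumes homoscedastic Gaussian residuals; true densitometry
  error grows with band intensity.
- Pairing uses per-position multiplicative weights, not nearest-neighbor
  duplex thermodynamics; temperature and buffer composition enter only
  through the efficiency parameters.
- The re-switching probability is assumed equal across cycles and
  independent of concatemer length.
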