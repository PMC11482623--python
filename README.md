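# rtswitch

Kinetics, simulation and quantification toolkit for reverse-transcriptase
(RT) **template-switching** library preparation — the reaction chemistry
behind Smart-seq-style full-length RNA-seq.

Template switching works because an RT, after copying an RNA template
end-to-end, does three more things: it appends a few nontemplated
nucleotides to the cDNA 3′ end (NTA, a terminal-transferase side activity),
a template-switching oligo (TSO) anneals to that overhang by base pairing,
and the RT resumes synthesis on the TSO, stitching a known adapter onto the
cDNA. Each of those steps has its own kinetics, sequence specificity and
failure modes (weak wobble pairing, 5′-cap inhibition, runaway TSO
concatemers). `rtswitch` models each step quantitatively so that protocol
choices — dNTP mix, TSO 3′ end, TSO 5′ blocking, template 5′ chemistry —
can be explored and benchmarked *in silico* against spike-in style ground
truth.

The package is aimed at people developing or benchmarking RT-based
sequencing protocols and at method developers who need a seeded, fully
synthetic stand-in for gel densitometry and spike-in sequencing data.

## What it computes

**Sequential NTA kinetics.** Nucleotide additions form an irreversible
first-order chain, primer → +1 → +2 → +3. With per-step observed rate
constants *k₁…kₙ* (min⁻¹) and reactive fractions *a₁…aₙ* (the fraction of
molecules competent to make each step, so step *i* plateaus at
*a₁⋯aᵢ*), the species fractions follow the Bateman solution of

  S₀ →(k₁) S₁ →(k₂) S₂ →(k₃) S₃,

with a dead-end pool of size (1−aᵢ) retained at each upstream species.
`rtswitch.kinetics` evaluates the closed form (falling back to the exact
matrix exponential near confluent rates); `rtswitch.kinfit` estimates
(k, a) from band-fraction time courses by bounded multistart least squares,
selects the chain length by AICc, and attaches residual-bootstrap standard
errors.

**Gel quantification.** `rtswitch.gelquant` integrates lane traces into
band tables and computes the overall template-switching efficiency,
TS% = 100 × (all switched products) / (total lane signal).

**Library-prep simulation.** `rtswitch.switchsim` draws molecules from a
spike-in ladder, samples NTA overhangs (base competition ∝ incorporation
rate × dNTP concentration), gates switching on overhang:TSO base pairing
(Watson–Crick ≫ G:U wobble ≫ mismatch = 0) and on the template 5′-end
penalty (hydroxyl > triphosphate > m⁷G), and samples geometric concatemer
counts for unblocked TSOs.

**Spike-in quantification.** `rtswitch.quantify` counts reads, computes
TPM/CPM, assesses log–log linearity over the concentration ladder, detects
transcripts (TPM > 0), downsamples counts hypergeometrically and computes
log2(TPM+1) replicate correlations.

**Synthetic data.** `rtswitch.synthgen` generates every input: a 92-
transcript external-control-style ladder (250–2000 nt, six decades of
concentration), a 69-isoform set in 7 loci (200–2500 nt), kinetic time
courses and Gaussian-peak gel lanes. All generators are pure functions of
their seeded configuration.

## Worked example

Fit the three-step adenosine-addition chain from a simulated noisy time
course, then simulate and quantify a library:

```python
import numpy as np
from rtswitch import KineticModel, simulate_timecourse, fit_sequential
from rtswitch.kinetics import sampling_grid

model = KineticModel(k=[0.19, 0.61, 0.20], a=[0.96, 0.96, 0.86])
tc = simulate_timecourse(model, sampling_grid(120.0, 12), noise_sd=0.02, seed=7)
res = fit_sequential(tc, n_steps=3).bootstrap(n_boot=200, seed=7)
print(res.summary())
```

```
Sequential NTA kinetics fit
==============================================
n_steps:        3
observations:   48
rss:            0.00973351
converged:      True
starts used:    54
bootstrap:      200 resamples (0 dropped)
----------------------------------------------
step   k (min^-1)      se(k)        a      se(a)
   1        0.183     0.0039   0.9586    0.00628
   2       0.5725     0.0308   0.9656    0.00573
   3       0.2206    0.00975   0.8584    0.00667
```

At 2 % densitometry noise the fitted rate constants land within roughly one
standard error of the generating values (0.19, 0.61, 0.20 min⁻¹), and the
reactive fractions recover their plateaus (96 %, 96 %, 86 %).

```python
from rtswitch.switchsim import TSO, SwitchParams, simulate_library, library_efficiency
from rtswitch.quantify import count_reads, expression_table, linearity_assessment, detected_count
from rtswitch.synthgen import GeneratorConfig, make_ercc_like_ladder

ladder = make_ercc_like_ladder(GeneratorConfig(seed=7))
tso = TSO("CTCCTCTTCCTCCTCTTT", "DNA", blocked_5prime=True, block_name="abasic_x5")
reads = simulate_library(ladder, SwitchParams(), tso, n_molecules=200_000, seed=7)
print("efficiency:", round(library_efficiency(reads), 3))

table = expression_table(count_reads(reads, ladder).to_numpy(), ladder)
print("detected (TPM > 0):", detected_count(table, "tpm", 0.0), "of", len(ladder))
lin = linearity_assessment(table, ladder)
print(f"slope: {lin.slope:.3f}  r: {lin.pearson_r:.3f}  "
      f"dynamic range: {lin.dynamic_range_log10:.2f} decades")
```

```
efficiency: 0.265
detected (TPM > 0): 69 of 92
slope: 0.938  r: 0.974  dynamic range: 5.67 decades
```

The realized efficiency (~27 %) sits below the 35 % base level because some
overhangs pair imperfectly with the TSO; the bottom of the six-decade ladder
falls below one expected read at this depth, so detection — not chemistry —
limits the measured dynamic range, exactly as in real spike-in experiments.

The same stages are scriptable from the shell:

```bash
rtswitch make-data ladder --seed 1 --out ladder.tsv
rtswitch simulate-library --ladder ladder.tsv --n 100000 --seed 11 --out reads.csv
rtswitch quantify --reads reads.csv --ladder ladder.tsv --out expr.csv
rtswitch report --expr expr.csv --ladder ladder.tsv
rtswitch run --seed 3 --out pipeline_run     # full pipeline + manifest
```

CSV outputs are UTF-8 with a header row; the ladder is TSV; any positional
coordinates are 0-based half-open.

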