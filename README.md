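# looptasep

Stochastic simulation of mRNA translation on *closed-loop* transcripts: a
finite-lifetime totally asymmetric simple exclusion process (TASEP) with
extended ribosome particles and a reinitiation channel.

## The problem

Ribosome density, initiation rate and protein output all decline with coding
sequence (CDS) length in eukaryotes. One mechanistic explanation is the
closed-loop architecture of mRNAs: a ribosome terminating at the stop codon
can be handed straight back to the start codon of the same transcript
(reinitiation) instead of returning to the cytoplasmic pool. Because a
ribosome completes a cycle faster on a short transcript, efficient
reinitiation concentrates ribosomes — and protein output — on short CDSs.
The effect is intrinsically *non-steady-state*: under reinitiation the
effective initiation rate keeps rising over a transcript's life, so the
simulator integrates translation over the entire finite lifetime of each
transcript rather than assuming a steady state.

`looptasep` is for quantitative/systems biologists who want to simulate this
model, calibrate it against an observed ribosome load, and run the standard
in-silico experiments (length sweeps, parameter perturbations, single
slow-codon scans, steady-state diagnostics, whole-translatome runs).

## The model

A transcript of `L` codons is a 1-D lattice; site `L` is the termination
site. Each ribosome is tracked by its A-site position and occludes
`footprint` = 10 codons: adjacent A-sites must be ≥ 10 codons apart. Four
reactions, simulated exactly with the Gillespie algorithm:

| reaction          | rate | rule |
|-------------------|------|------|
| de novo initiation | α   | places an A-site at site 1; blocked while any A-site occupies sites 1..10 |
| elongation        | k_i  | A-site hops i → i+1; blocked unless the next A-site is > 10 codons ahead |
| release           | β    | ribosome at site `L` returns to the pool |
| reinitiation      | r    | ribosome at site `L` moves to site 1; blocked like initiation |

The **reinitiation level** `p = r / (r + β)` is the probability that a
terminating ribosome stays on the transcript. Scaling `r` by a factor `f`
shifts the level to `f·p / (f·p + 1 − p)`. Read-outs per lifetime `T`:
**density** (time-averaged ribosome count ÷ `L/10`), **effective initiation
rate** ((de novo + reinitiations)/`T`), and **protein yield** (ribosomes
reaching the stop codon). Elongation rates are uniform (10 s⁻¹ by default)
or codon-specific from a 61-codon decoding-rate table scaled to mean 10 s⁻¹.

## Worked example

Calibrated 400-codon transcript at 99.9 % reinitiation (α ≈ 0.00866 s⁻¹
from `calibrate_alpha`), lifetime 1553 s, uniform 10 s⁻¹ elongation:

```python
import looptasep as lt

spec = lt.TranscriptSpec.uniform(
    400, 10.0, alpha=0.00866, reinit_rate=9.99, release_rate=0.01,
    footprint=10, lifetime=1553.0, id="demo")
s = lt.summarize(spec, n_runs=1000, seed=1)
```

prints (via the fields of `s`):

```
mean ribosomes : 5.968 ± 0.055
density        : 0.1492 ± 0.0014
eff. initiation: 0.1490 /s ± 0.0013
protein yield  : 220.4 ± 2.0
```

The transcript carries ~6 ribosomes on average (density 6/40 = 0.15 of
maximum packing); almost every one of the ~220 completed protein chains per
lifetime came from a reinitiation cycle — the effective initiation rate
(0.149 s⁻¹) is ~17× the de novo rate. And the level algebra:

```python
lt.scale_reinitiation_level(0.90, 2.0)   # 0.947: doubling r at a 90% level
```

The same experiments are scriptable from the shell (`looptasep simulate`,
`sweep`, `calibrate`, `perturb`, `slowstep`, `steadystate`, `translatome`,
`fixtures`), each taking a flat `key = value` config file plus `-O`
overrides and writing TSV tables and a JSON manifest of the effective
configuration.

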