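# Methods

## Model and assumptions

`looptasep` simulates translation of a single mRNA as a continuous-time
Markov process: a totally asymmetric simple exclusion process (TASEP) with
extended particles on a lattice of `L` sites (one per codon, site `L` = stop
codon), augmented with a reinitiation channel that moves a terminating
ribosome directly back to site 1 (the closed-loop architecture). Only A-site
positions are tracked; the 10-codon ribosome footprint is enforced purely as
a minimum A-site spacing, so there are no leading/trailing offsets at the
lattice ends — under these reaction rules any other anchoring of the
footprint would be observationally equivalent.

Reaction rules:

* de novo initiation at rate α, enabled iff no A-site occupies sites
  1..footprint;
* elongation of the ribosome at site `i < L` at rate `k_i`, enabled iff the
  next A-site downstream is > footprint codons away;
* release at rate β and reinitiation at rate r from site `L`; reinitiation
  obeys the same initiation-region rule, and while it is blocked the
  terminal ribosome simply waits with the release channel still active.

Completions ("protein yield") are counted when an A-site *arrives* at site
`L`, so each reinitiation cycle contributes one completed chain and the
bookkeeping identity `completions = releases + reinitiations (+1 if the
terminal site is currently occupied by an arrived ribosome)` holds at every
instant, as does `de_novo = releases + ribosomes on board`.

The process is simulated exactly (Gillespie direct method; two uniforms per
event, waiting time then channel) from an empty lattice at t = 0 over the
transcript's finite lifetime `T`. No steady-state assumption is made: an
event sampled beyond `T` is discarded and the occupancy integral is closed
at exactly `T`. A frozen state (total rate zero, e.g. α = 0 on an empty
lattice) jumps straight to `T`. Transcripts are independent; there is no
shared ribosome pool, no UTR geometry, and no drop-off.

## Read-outs

Per replicate: time-averaged ribosome count (occupancy integral / `T`);
counts of de novo initiations, reinitiations, releases and completions.
Across replicates (default 1000, enough that standard errors are small
relative to the means): **density** = mean count / (`L`/footprint),
**effective initiation rate** = (de novo + reinits)/`T`, **protein yield** =
mean completions, each with its standard error.

## Parameters, units, defaults

| parameter | unit | default | rationale |
|---|---|---|---|
| footprint | codons | 10 | ribosome occludes ~10 codons; parameterised so small-lattice exact tests are possible |
| elongation rate | s⁻¹ | 10 (uniform) or codon-specific table | transcriptome-average decoding rate |
| reinitiation level p = r/(r+β) | — | experiment-specific | the biologically meaningful ratio |
| termination total r+β | s⁻¹ | 10 | only the ratio is constrained by the model; 10 s⁻¹ makes termination non-limiting relative to elongation |
| lifetime T | s | 1553 | typical budding-yeast transcript lifetime |
| α (de novo) | s⁻¹ | calibrated | see below |

Codon-specific elongation rates come from a 61-sense-codon table (DNA
alphabet; stop codons carry no decoding rate — the stop site has only the
termination channels). The packaged table
(`data/codon_rates_synthetic.tsv`) is **synthetic**: lognormal rates rescaled
to a mean of exactly 10 s⁻¹, shaped like a real decoding-rate table but
carrying no information about any organism. A real table in the same
two-column format can be supplied instead.

## Calibration

Changing transcriptome-wide parameters (level, elongation rate) changes
global ribosome usage, so comparisons across settings are normalised by
adjusting α until a 400-codon reference transcript carries a target mean
load of 6 ribosomes. The mean count is monotone non-decreasing in α, so the
search is bisection on log₁₀α over [10⁻⁶, 10²] s⁻¹ (expanded on demand),
with common random numbers across evaluations so Monte-Carlo noise cannot
stall the bracket. Default tolerance 0.05 ribosomes at 1000 replicates; an
unreachable target (e.g. a lifetime too short to accumulate the load at any
α) raises an explicit error with the achieved bound.

## Experiments

* **Length sweeps** simulate a set of CDS lengths (default 13 log-spaced
  points in 100–4000 codons) at a reinitiation policy (fixed level or the
  length-dependent rule p(L) = max(0, 1 − L/4000)) and fit log₁₀(read-out)
  on log₁₀(length) by OLS with 95 % t-intervals (n − 2 df; the CI method is
  a package choice). Fewer than three lengths flags the slope as undefined.
* **Perturbations** scale one parameter (r with β fixed, α, or all `k_i`) of
  a single transcript species and report each read-out relative to the
  unaltered transcript with paired replicate seeds — a factor of 1 returns
  exactly 1, and paired seeds cancel most Monte-Carlo variance from the
  ratio (delta-method standard errors).
* **Slow-step scans** replace one site's rate (start = site 1, middle =
  site ⌈(L−1)/2⌉, final = site L−1) with 1, 0.1 or 0.01 s⁻¹ and report the
  same paired ratios.
* **Steady-state diagnostics** run with lifetime = 3×10⁵ s, sample the
  instantaneous ribosome count on a fixed 10 s grid (event times differ
  across runs, so a common grid is needed for the across-run mean), define
  the steady-state density as the mean over the final 10⁴ s, and report the
  earliest grid time at which the across-run mean density reaches it. A
  directional drift over the final window (t-test, plus a 2 % relative-change
  floor) flags "steady state not attained", in which case no first-passage
  time is reported.
* **Translatome runs** build one transcript per CDS from a FASTA and a rate
  table, with a fixed or per-transcript lifetime table; when per-transcript
  lifetimes are supplied, transcripts with lifetime < 400 s are excluded
  (and reported) because at such short lifetimes even a reinitiation-free
  model is length-dependent — the first ribosome cannot finish a long CDS —
  which would bias length-dependence comparisons. Per-record failures are
  collected without aborting; seeds derive from the transcript id, so
  results are deterministic regardless of input order or chunking.

## Numerical choices

* RNG: one root seed; replicate `k` uses
  `SeedSequence(seed).generate_state(n_runs)[k]` masked to 31 bits. The
  production path is a numba-compiled kernel; a pure-Python reference engine
  implements the identical step rules for auditing and small-system tests.
  The two paths use different underlying generators, so they agree
  statistically (and both agree with the exact oracle), not trajectory by
  trajectory; each path is bit-reproducible given (spec, seed, n_runs).
* Channel order (initiation, elongations 5'→3', release, reinitiation) is
  fixed and identical in both paths; a floating-point fall-through in the
  channel draw selects the last enabled channel.
* The exact oracle enumerates all admissible A-site configurations of a
  small lattice (bound ~2000 states), builds the generator from the same
  reaction rules, and integrates the master equation with augmented ODEs for
  the expected occupancy integral, completions and initiations (LSODA,
  rtol 10⁻¹⁰). Augmented ODEs rather than matrix exponentials keep extreme
  rate ratios (0.01 vs 10 s⁻¹) well-conditioned. It is cross-checked against
  a hand-enumerated generator with matrix-exponential quadrature and against
  a hand-coded direct simulation of the minimal L = 11 lattice.

## What the synthetic data do and do not show

The synthetic transcriptome generator emulates the *shape* of real inputs
(CDS with start/stop structure, codon usage uniform over sense codons,
lognormal lifetimes) so that pipelines are exercised end to end. It does not
emulate real codon-usage bias, real decoding-rate covariance with
abundance, or empirical lifetime–length correlations, so passing tests
demonstrate correctness of the simulator and plumbing — not agreement with
any organism's measured densities or protein abundances, which would require
external datasets this package deliberately does not ship.

## Problem sizes

Default experiment sizes (1000 replicates; slow-codon and sweep grids as
above) follow the conventions stated earlier. The test suite runs reduced
sizes — e.g. calibration at 200 replicates with a correspondingly widened
tolerance, sweeps at 150–500 replicates — chosen so the statistical
assertions retain comfortable margins at their 3-SE criteria.

## Known limitations

* No 5'/3' UTRs, no ribosome drop-off, no finite shared ribosome pool, no
  transcript–transcript competition: transcripts are independent and the
  free-subunit supply is implicit in a constant α.
* The absolute termination timescale r+β is not identifiable from the
  model's constrained ratio; results at very high levels are insensitive to
  it as long as it is not limiting, but slow-termination regimes would need
  the configurable value changed.
* The "middle codon" of an even-length CDS is rounded to site ⌈(L−1)/2⌉.
* First-passage times are grid-resolved (default 10 s), not event-resolved.
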