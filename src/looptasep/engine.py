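"""Gillespie simulation of the closed-loop TASEP.

Two implementations share one model definition:

* a step-level pure-Python reference (:func:`enabled_reactions`,
  :func:`gillespie_step`, :func:`simulate_transcript`) used for unit testing,
  invariant checking and building the exact master-equation oracle;
* a compiled kernel (:mod:`looptasep._kernel`) used by :func:`summarize` and
  the experiment drivers, where millions of reaction events per replicate are
  routine.

Both consume two uniforms per event in the order (waiting time, channel) and
enumerate channels identically: de novo initiation, elongation in 5'→3'
order of the ribosomes, release, reinitiation.

Replicate ``k`` of a summary derives its seed from the root seed via
``numpy.random.SeedSequence(seed).generate_state(n_runs)`` masked to 31 bits,
so runs are independent and any single replicate can be replayed.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from . import _kernel
from .core import LatticeState, TrajectoryStats, TranscriptSpec, TranslationSummary

__all__ = [
    "FrozenStateError",
    "enabled_reactions",
    "apply_reaction",
    "gillespie_step",
    "simulate_transcript",
    "summarize",
    "run_replicates",
    "replicate_seeds",
    "pioneer_traversal_times",
]

# Reaction identifiers: ("init",), ("elong", site), ("release",), ("reinit",)
INIT = ("init",)
RELEASE = ("release",)
REINIT = ("reinit",)


class FrozenStateError(RuntimeError):
    """Total reaction rate is zero; no event can occur."""


def _enabled(a_sites: Sequence[int], spec: TranscriptSpec) -> list[tuple[tuple, float]]:
    """Enumerate enabled reaction channels for an A-site configuration."""
    fp = spec.footprint
    L = spec.L
    channels: list[tuple[tuple, float]] = []
    init_ok = not a_sites or a_sites[0] > fp
    if init_ok and spec.alpha > 0:
        channels.append((INIT, spec.alpha))
    for k, i in enumerate(a_sites):
        if i >= L:
            continue
        nxt = a_sites[k + 1] if k + 1 < len(a_sites) else L + fp + 1
        if nxt - i > fp:
            channels.append((("elong", i), spec.elong_rates[i - 1]))
    if a_sites and a_sites[-1] == L:
        if spec.release_rate > 0:
            channels.append((RELEASE, spec.release_rate))
        if init_ok and spec.reinit_rate > 0:
            channels.append((REINIT, spec.reinit_rate))
    return channels


def enabled_reactions(
    state: LatticeState, spec: TranscriptSpec
) -> list[tuple[tuple, float]]:
    """List the currently possible reactions and their rates.

    De novo initiation (and reinitiation) require the first ``footprint``
    sites to be free of A-sites; a ribosome may elongate only when the next
    A-site downstream is more than ``footprint`` codons away; a ribosome at
    the termination site always has the release channel and additionally the
    reinitiation channel when the initiation region is clear.
    """
    return _enabled(state.a_sites, spec)


def apply_reaction(a_sites: tuple[int, ...], rid: tuple) -> tuple[int, ...]:
    """Pure configuration update for reaction ``rid`` (no bookkeeping)."""
    if rid == INIT:
        return (1, *a_sites)
    if rid == RELEASE:
        return a_sites[:-1]
    if rid == REINIT:
        return (1, *a_sites[:-1])
    if rid[0] == "elong":
        i = rid[1]
        k = a_sites.index(i)
        return (*a_sites[:k], i + 1, *a_sites[k + 1 :])
    raise ValueError(f"unknown reaction id {rid!r}")


def gillespie_step(
    state: LatticeState,
    spec: TranscriptSpec,
    rng: np.random.Generator,
    t_max: float | None = None,
):
    """Advance the state by one stochastic event (in place).

    Draws the exponential waiting time from the total enabled rate, then the
    channel with probability proportional to its rate.  If ``t_max`` is given
    and the sampled event would occur after it, the event is discarded: the
    occupancy integral is closed at exactly ``t_max`` and the reaction id
    returned is ``None``.

    Returns ``(state, dt, reaction_id)``.

    Raises
    ------
    FrozenStateError
        If no reaction is enabled (the caller advances time to the lifetime).
    """
    channels = enabled_reactions(state, spec)
    total = sum(rate for _, rate in channels)
    if total <= 0.0:
        raise FrozenStateError("no enabled reaction (total rate 0)")
    u1 = rng.random()
    dt = -math.log(u1) / total
    if t_max is not None and state.t + dt > t_max:
        state.occupancy_integral += state.n_ribosomes * (t_max - state.t)
        state.t = t_max
        return state, dt, None
    u2 = rng.random() * total
    acc = 0.0
    rid = channels[-1][0]  # guard against floating-point fall-through
    for cid, rate in channels:
        acc += rate
        if u2 < acc:
            rid = cid
            break
    state.occupancy_integral += state.n_ribosomes * dt
    state.t += dt
    new_sites = apply_reaction(tuple(state.a_sites), rid)
    if rid == INIT:
        state.de_novo += 1
    elif rid == RELEASE:
        state.releases += 1
        state.terminal_arrived = False
    elif rid == REINIT:
        state.reinits += 1
        state.terminal_arrived = False
    else:  # elongation
        if rid[1] + 1 == spec.L:
            state.completions += 1
            state.terminal_arrived = True
    state.a_sites = list(new_sites)
    return state, dt, rid


def simulate_transcript(
    spec: TranscriptSpec,
    seed: int,
    *,
    check_invariants: bool = False,
) -> TrajectoryStats:
    """Reference simulation of one trajectory over the transcript lifetime.

    Starts from an empty lattice at t = 0 and applies Gillespie events until
    the next event would exceed the lifetime; the final partial interval
    contributes to the occupancy integral.  Deterministic given (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    state = LatticeState()
    T = spec.lifetime
    while state.t < T:
        try:
            _, _, rid = gillespie_step(state, spec, rng, t_max=T)
        except FrozenStateError:
            state.occupancy_integral += state.n_ribosomes * (T - state.t)
            state.t = T
            break
        if check_invariants:
            state.check_invariants(spec)
        if rid is None:
            break
    return TrajectoryStats.from_state(state, T)


def replicate_seeds(seed: int, n_runs: int) -> np.ndarray:
    """Derive the per-replicate seed array from a root seed (31-bit ints)."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n_runs, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_replicates(spec: TranscriptSpec, n_runs: int, seed: int) -> np.ndarray:
    """Compiled batch of independent trajectories.

    Returns an array of shape ``(n_runs, 5)`` with columns
    (mean_ribosomes, de_novo, reinits, releases, completions).
    """
    spec.validate()
    seeds = replicate_seeds(seed, n_runs)
    out = np.empty((n_runs, 5), dtype=np.float64)
    elong = np.zeros(spec.L, dtype=np.float64)
    elong[1:] = spec.elong_rates
    _kernel.run_batch(
        spec.L,
        elong,
        spec.alpha,
        spec.reinit_rate,
        spec.release_rate,
        spec.footprint,
        spec.lifetime,
        seeds,
        np.empty(0, dtype=np.float64),
        np.empty(0, dtype=np.float64),
        out,
    )
    return out


def summarize(
    spec: TranscriptSpec,
    n_runs: int = 1000,
    seed: int = 0,
    *,
    engine: str = "compiled",
) -> TranslationSummary:
    """Average the three translation read-outs over independent replicates.

    density
        mean ribosome count over the lifetime divided by ``L / footprint``.
    eff_init_rate
        (de novo initiations + reinitiations) / lifetime.
    protein_yield
        ribosomes reaching the termination site per lifetime.

    The default 1000 replicates keeps the standard errors small relative to
    the read-outs themselves.  ``engine="reference"`` runs the pure-Python
    path (slow; testing only).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec.validate()
    if engine == "compiled":
        res = run_replicates(spec, n_runs, seed)
        mean_ribs = res[:, 0]
        inits = res[:, 1] + res[:, 2]
        completions = res[:, 4]
    elif engine == "reference":
        seeds = replicate_seeds(seed, n_runs)
        stats = [simulate_transcript(spec, int(s)) for s in seeds]
        mean_ribs = np.array([s.mean_ribosomes for s in stats])
        inits = np.array([float(s.initiations) for s in stats])
        completions = np.array([float(s.completions) for s in stats])
    else:
        raise ValueError(f"unknown engine {engine!r}")
    T = spec.lifetime
    dens = mean_ribs / spec.max_packing
    eff = inits / T if T > 0 else np.zeros_like(inits)

    def _se(x: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(np.std(x, ddof=1) / math.sqrt(len(x)))

    return TranslationSummary(
        transcript_id=spec.id,
        n_runs=n_runs,
        mean_ribosomes=float(np.mean(mean_ribs)),
        density=float(np.mean(dens)),
        eff_init_rate=float(np.mean(eff)),
        protein_yield=float(np.mean(completions)),
        se_mean_ribosomes=_se(mean_ribs),
        se_density=_se(dens),
        se_eff_init_rate=_se(eff),
        se_protein_yield=_se(completions),
    )


def pioneer_traversal_times(
    L: int,
    elong_rates: Iterable[float] | float = 10.0,
    n_runs: int = 1000,
    seed: int = 0,
    *,
    footprint: int = 10,
) -> np.ndarray:
    """Traversal times of a lone ribosome from site 1 to the terminal site.

    Places a single ribosome at site 1 of an empty lattice with no further
    initiation and simulates until it arrives at site ``L`` (the pioneer
    round).  The expected time is ``sum(1 / k_i)`` over the ``L - 1``
    elongation steps.
    """
    if np.isscalar(elong_rates):
        rates = np.full(L - 1, float(elong_rates))
    else:
        rates = np.asarray(list(elong_rates), dtype=np.float64)
    spec = TranscriptSpec(
        id="pioneer",
        L=L,
        elong_rates=rates,
        alpha=0.0,
        reinit_rate=0.0,
        release_rate=1.0,
        footprint=footprint,
        lifetime=np.inf,
    )
    seeds = replicate_seeds(seed, n_runs)
    elong = np.zeros(L, dtype=np.float64)
    elong[1:] = rates
    times = np.empty(n_runs, dtype=np.float64)
    for k in range(n_runs):
        res = _kernel.run_transcript(
            L,
            elong,
            0.0,
            0.0,
            1.0,
            footprint,
            np.inf,
            seeds[k],
            1,  # initial ribosome at site 1
            True,  # stop at first arrival
            np.empty(0, dtype=np.float64),
            np.empty(0, dtype=np.float64),
        )
        times[k] = res[5]
    return times
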