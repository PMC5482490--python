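"""Domain types for the closed-loop translation TASEP.

A transcript is a one-dimensional lattice with one site per codon; site ``L``
is the termination (stop-codon) site.  Ribosomes are extended particles
tracked by the position of their A-site; the A-sites of adjacent ribosomes
must be spaced at least ``footprint`` codons apart.  Four reactions drive the
dynamics: de novo initiation (a ribosome from the free pool enters at site 1),
elongation (a ribosome hops one site 3'-ward), release (a ribosome at the
termination site returns to the pool) and reinitiation (a ribosome at the
termination site moves directly back to site 1 of the same transcript, the
closed-loop channel).  Simulation runs over the transcript's finite lifetime,
so both pre-steady-state and steady-state translation contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpecValidationError",
    "TranscriptSpec",
    "LatticeState",
    "TrajectoryStats",
    "TranslationSummary",
]


class SpecValidationError(ValueError):
    """A transcript specification violates one of its invariants."""


@dataclass(frozen=True)
class TranscriptSpec:
    """Parameters of one transcript species.

    Parameters
    ----------
    id : str
        Label for the transcript.
    L : int
        Lattice length in codons; site ``L`` is the termination site.
    elong_rates : array-like of float, shape (L - 1,)
        Elongation rate (s^-1) out of sites ``1 .. L-1``.
    alpha : float
        De novo initiation rate (s^-1).
    reinit_rate : float
        Reinitiation rate ``r`` (s^-1) out of the termination site.
    release_rate : float
        Release rate ``beta`` (s^-1) out of the termination site.
    footprint : int
        Minimum A-site spacing in codons (default 10, the ribosome footprint).
    lifetime : float
        Transcript lifetime ``T`` in seconds.
    """

    id: str
    L: int
    elong_rates: np.ndarray
    alpha: float
    reinit_rate: float
    release_rate: float
    footprint: int = 10
    lifetime: float = 1553.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "elong_rates", np.asarray(self.elong_rates, dtype=np.float64)
        )
        self.validate()

    def validate(self) -> None:
        if self.footprint < 1:
            raise SpecValidationError("footprint must be >= 1")
        if self.L <= self.footprint:
            raise SpecValidationError(
                f"L must exceed footprint (got L={self.L}, footprint={self.footprint})"
            )
        if self.elong_rates.shape != (self.L - 1,):
            raise SpecValidationError(
                f"elong_rates must have exactly L-1={self.L - 1} entries, "
                f"got {self.elong_rates.shape}"
            )
        if not np.all(self.elong_rates > 0):
            raise SpecValidationError("all elongation rates must be > 0")
        for name in ("alpha", "reinit_rate", "release_rate", "lifetime"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0")
        if self.reinit_rate + self.release_rate <= 0:
            raise SpecValidationError(
                "reinit_rate + release_rate must be > 0: a ribosome at the "
                "termination site needs an exit channel"
            )

    @property
    def max_packing(self) -> float:
        """Maximum ribosome load ``L / footprint`` (density denominator)."""
        return self.L / self.footprint

    def replace(self, **kwargs) -> "TranscriptSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    @classmethod
    def uniform(
        cls,
        L: int,
        rate: float = 10.0,
        *,
        alpha: float,
        reinit_rate: float,
        release_rate: float,
        footprint: int = 10,
        lifetime: float = 1553.0,
        id: str = "uniform",
    ) -> "TranscriptSpec":
        """Transcript with a single elongation rate at every site."""
        return cls(
            id=id,
            L=L,
            elong_rates=np.full(L - 1, float(rate)),
            alpha=alpha,
            reinit_rate=reinit_rate,
            release_rate=release_rate,
            footprint=footprint,
            lifetime=lifetime,
        )


@dataclass
class LatticeState:
    """Instantaneous configuration of one transcript.

    ``a_sites`` holds the strictly increasing A-site positions in ``1..L``;
    consecutive positions differ by at least the footprint.  Counters tally
    the four reaction types plus arrivals at the termination site
    (completions).  ``occupancy_integral`` accumulates ribosome-seconds.
    """

    a_sites: list[int] = field(default_factory=list)
    t: float = 0.0
    de_novo: int = 0
    reinits: int = 0
    releases: int = 0
    completions: int = 0
    occupancy_integral: float = 0.0
    # True while the ribosome currently at the termination site got there by
    # elongating (i.e. has been counted as a completion).
    terminal_arrived: bool = False

    @property
    def n_ribosomes(self) -> int:
        return len(self.a_sites)

    def check_invariants(self, spec: TranscriptSpec) -> None:
        pos = self.a_sites
        if any(p < 1 or p > spec.L for p in pos):
            raise AssertionError(f"A-site out of lattice: {pos}")
        if any(b - a < spec.footprint for a, b in zip(pos, pos[1:])):
            raise AssertionError(f"footprint spacing violated: {pos}")
        if self.de_novo != self.releases + len(pos):
            raise AssertionError("bookkeeping: de_novo != releases + on-board")
        expected = self.releases + self.reinits + (1 if self.terminal_arrived else 0)
        if self.completions != expected:
            raise AssertionError("bookkeeping: completions identity violated")


@dataclass(frozen=True)
class TrajectoryStats:
    """Per-run read-outs of a single stochastic trajectory."""

    mean_ribosomes: float
    de_novo: int
    reinits: int
    releases: int
    completions: int
    lifetime: float

    @property
    def initiations(self) -> int:
        """Total initiation events (de novo + reinitiation)."""
        return self.de_novo + self.reinits

    @classmethod
    def from_state(cls, state: LatticeState, lifetime: float) -> "TrajectoryStats":
        mean = state.occupancy_integral / lifetime if lifetime > 0 else 0.0
        return cls(
            mean_ribosomes=mean,
            de_novo=state.de_novo,
            reinits=state.reinits,
            releases=state.releases,
            completions=state.completions,
            lifetime=lifetime,
        )


@dataclass(frozen=True)
class TranslationSummary:
    """Across-replicate averages of the three translation read-outs.

    density
        Lifetime-averaged ribosome count divided by the maximum packing
        ``L / footprint`` (dimensionless).
    eff_init_rate
        Total initiations (de novo + reinitiation) per second of lifetime.
    protein_yield
        Mean number of ribosomes reaching the termination site per lifetime.
    """

    transcript_id: str
    n_runs: int
    mean_ribosomes: float
    density: float
    eff_init_rate: float
    protein_yield: float
    se_mean_ribosomes: float
    se_density: float
    se_eff_init_rate: float
    se_protein_yield: float

    def as_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "n_runs": self.n_runs,
            "mean_ribosomes": self.mean_ribosomes,
            "density": self.density,
            "eff_init_rate": self.eff_init_rate,
            "protein_yield": self.protein_yield,
            "se_mean_ribosomes": self.se_mean_ribosomes,
            "se_density": self.se_density,
            "se_eff_init_rate": self.se_eff_init_rate,
            "se_protein_yield": self.se_protein_yield,
        }
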