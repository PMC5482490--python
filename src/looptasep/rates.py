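"""Rate construction: reinitiation levels and per-site elongation rates.

The *reinitiation level* is the probability that a terminating ribosome
reinitiates rather than returns to the free pool:

    level = r / (r + beta)

where ``r`` is the reinitiation rate and ``beta`` the release rate.  Only the
ratio is biologically constrained; the absolute termination timescale
``r + beta`` defaults to 10 s^-1 (the transcriptome-average decoding rate) so
termination is not rate-limiting relative to elongation.

Per-site elongation rates come either from a uniform value or from a codon →
decoding-rate table (61 sense codons, DNA alphabet, scaled to a mean of
10 s^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "RateTable",
    "ReinitiationPolicy",
    "rates_from_level",
    "level_from_rates",
    "scale_reinitiation_level",
    "length_dependent_level",
    "build_elongation_rates",
    "with_slow_step",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)

DEFAULT_TERMINATION_TOTAL = 10.0


class RateTableError(ValueError):
    pass


class RateTable(Mapping):
    """Codon (3-letter uppercase DNA) → decoding rate in s^-1.

    Exactly the 61 sense codons must be present with positive rates; stop
    codons are rejected (the stop site has termination channels only).
    """

    def __init__(self, rates: Mapping[str, float]):
        clean = {}
        for codon, rate in rates.items():
            c = str(codon).strip().upper().replace("U", "T")
            if len(c) != 3 or any(b not in _BASES for b in c):
                raise RateTableError(f"invalid codon {codon!r}")
            if c in STOP_CODONS:
                raise RateTableError(f"stop codon {c} must not carry a decoding rate")
            r = float(rate)
            if not r > 0:
                raise RateTableError(f"non-positive rate {rate!r} for codon {c}")
            if c in clean:
                raise RateTableError(f"duplicate codon {c}")
            clean[c] = r
        missing = set(SENSE_CODONS) - set(clean)
        if missing:
            raise RateTableError(
                f"missing {len(missing)} sense codon(s): {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"missing sense codon(s): {sorted(missing)}"
            )
        self._rates = clean

    def __getitem__(self, codon: str) -> float:
        return self._rates[codon.upper().replace("U", "T")]

    def __iter__(self):
        return iter(self._rates)

    def __len__(self) -> int:
        return len(self._rates)

    @property
    def mean_rate(self) -> float:
        """Unweighted mean over the 61 sense codons."""
        return float(np.mean(list(self._rates.values())))


@dataclass(frozen=True)
class ReinitiationPolicy:
    """How to choose (reinit_rate, release_rate) for a transcript.

    Either a fixed ``level`` in [0, 1], or ``length_dependent=True`` for the
    linearly decreasing rule level(L) = max(0, 1 - L/4000).  The two terminal
    rates always sum to ``termination_total``.
    """

    level: float | None = None
    termination_total: float = DEFAULT_TERMINATION_TOTAL
    length_dependent: bool = False

    def __post_init__(self):
        if self.length_dependent == (self.level is not None):
            raise ValueError("give exactly one of level= or length_dependent=True")
        if self.level is not None and not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level must be in [0, 1], got {self.level}")
        if not self.termination_total > 0:
            raise ValueError("termination_total must be > 0")

    def resolve(self, L: int) -> tuple[float, float]:
        """(reinit_rate, release_rate) for a transcript of L codons."""
        level = length_dependent_level(L) if self.length_dependent else self.level
        return rates_from_level(level, self.termination_total)

    def level_for(self, L: int) -> float:
        return length_dependent_level(L) if self.length_dependent else float(self.level)


def rates_from_level(
    level: float, termination_total: float = DEFAULT_TERMINATION_TOTAL
) -> tuple[float, float]:
    """Split a termination timescale into (reinit_rate, release_rate).

    ``reinit = level * total``, ``release = (1 - level) * total``; at
    level 1 ribosomes never leave a transcript until it degrades.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be in [0, 1], got {level}")
    if not termination_total > 0:
        raise ValueError("termination_total must be > 0")
    return level * termination_total, (1.0 - level) * termination_total


def level_from_rates(reinit_rate: float, release_rate: float) -> float:
    """level = r / (r + beta)."""
    total = reinit_rate + release_rate
    if total <= 0:
        raise ValueError("reinit_rate + release_rate must be > 0")
    return reinit_rate / total


def scale_reinitiation_level(level: float, factor: float) -> float:
    """Reinitiation level after multiplying the reinitiation rate by ``factor``
    while keeping the release rate fixed.

        p' = f*p / (f*p + (1 - p))

    Fixed points at p = 0 and p = 1 for any factor: a transcript that never
    (or always) reinitiates keeps doing so however much r is scaled.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be in [0, 1], got {level}")
    if not factor > 0:
        raise ValueError("factor must be > 0")
    return factor * level / (factor * level + (1.0 - level))


def length_dependent_level(L: int) -> float:
    """Linearly decreasing reinitiation level, level(L) = max(0, 1 - L/4000).

    Short transcripts reinitiate almost perfectly; transcripts of 4000 codons
    or more do not reinitiate at all.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return max(0.0, 1.0 - L / 4000.0)


def build_elongation_rates(
    cds: str, table: RateTable, *, no_stop: bool = False
) -> np.ndarray:
    """Per-site elongation rates for a CDS from a codon decoding-rate table.

    The lattice has one site per codon (stop included): site ``i`` for
    ``1 <= i <= L-1`` elongates at the table rate of codon ``i``; the final
    codon is the termination site and carries no elongation rate, so the
    returned array has ``L - 1`` entries.

    The final codon must be a stop codon unless ``no_stop=True`` (then the
    final sense codon is taken as the termination site).  Internal stop
    codons are rejected with their position.
    """
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a positive multiple of 3")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"CDS contains non-ACGT characters: {sorted(bad)}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not no_stop and codons[-1] not in STOP_CODONS:
        raise ValueError(
            f"final codon {codons[-1]} is not a stop codon "
            "(pass no_stop=True if the CDS genuinely lacks one)"
        )
    for idx, codon in enumerate(codons[:-1], start=1):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon index {idx}")
    return np.array([table[c] for c in codons[:-1]], dtype=np.float64)


def with_slow_step(
    rates: Sequence[float], position: str | int, slow_rate: float
) -> np.ndarray:
    """Copy of per-site rates with a single slow decoding step.

    ``position`` is ``"start"`` (site 1), ``"middle"`` (site ceil((L-1)/2)),
    ``"final"`` (site L-1, immediately before the stop codon) or a 1-based
    site index in ``1..L-1``.
    """
    out = np.array(rates, dtype=np.float64)
    n = len(out)  # n = L - 1 elongation sites
    if not slow_rate > 0:
        raise ValueError("slow_rate must be > 0")
    if position == "start":
        site = 1
    elif position == "middle":
        site = (n + 1) // 2
    elif position == "final":
        site = n
    else:
        site = int(position)
    if not 1 <= site <= n:
        raise ValueError(f"site index {site} out of range 1..{n}")
    out[site - 1] = float(slow_rate)
    return out
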