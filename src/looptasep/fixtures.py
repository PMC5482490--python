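"""Synthetic inputs and exact small-system oracles.

Everything other modules need for testing is generated here, without any
download: random coding sequences with valid start/stop structure, a packaged
synthetic codon decoding-rate table (mean exactly 10 s^-1), per-transcript
lifetime tables, and an exact master-equation (CTMC) integrator for lattices
small enough to enumerate.

The packaged rate table is a synthetic stand-in with the same shape as a real
codon-specific decoding-rate table (61 sense codons, lognormal spread,
rescaled to a mean of 10 s^-1); it carries no information about any real
organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csr_matrix

from .core import TranscriptSpec
from .engine import INIT, REINIT, _enabled, apply_reaction
from .rates import RateTable, SENSE_CODONS, STOP_CODONS

__all__ = [
    "synthetic_rate_table_path",
    "synthetic_rate_table",
    "make_transcriptome",
    "make_lifetime_table",
    "write_fixture_files",
    "enumerate_states",
    "CtmcSummary",
    "exact_ctmc_summary",
]

_START = "ATG"


def synthetic_rate_table_path() -> Path:
    """Path of the packaged synthetic codon rate table (TSV)."""
    return Path(resources.files("looptasep") / "data" / "codon_rates_synthetic.tsv")


def synthetic_rate_table() -> RateTable:
    """The packaged synthetic codon → decoding-rate table (mean 10 s^-1)."""
    from .io import read_rate_table

    return read_rate_table(synthetic_rate_table_path())


def make_transcriptome(
    n: int,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random coding sequences: ATG start, random sense codons, one stop.

    Lengths (in codons, stop included) are drawn uniformly from
    ``length_range``.  Reproducible given the seed; every sequence passes
    :func:`looptasep.rates.build_elongation_rates` validation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 3:
        raise ValueError("transcripts need at least 3 codons (start, body, stop)")
    if hi < lo:
        raise ValueError("empty length range")
    rng = np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    stops = sorted(STOP_CODONS)
    records = []
    for k in range(n):
        n_codons = int(rng.integers(lo, hi + 1))
        body = sense[rng.integers(0, len(sense), size=n_codons - 2)]
        stop = stops[rng.integers(0, len(stops))]
        seq = _START + "".join(body) + stop
        records.append((f"synth_{k:04d}", seq))
    return records


def make_lifetime_table(
    ids: list[str],
    mean_lifetime: float = 1553.0,
    cv: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Lognormal per-transcript lifetimes around a typical mean (seconds)."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean_lifetime) - sigma**2 / 2
    return {i: float(t) for i, t in zip(ids, rng.lognormal(mu, sigma, len(ids)))}


def write_fixture_files(
    directory: str | Path,
    n: int = 10,
    length_range: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> dict[str, Path]:
    """Emit a synthetic CDS FASTA, rate table and lifetime TSV into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = make_transcriptome(n, length_range, seed)
    fasta = directory / "synthetic_cds.fasta"
    with open(fasta, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    lifetimes = make_lifetime_table([r[0] for r in records], seed=seed + 1)
    lt_path = directory / "synthetic_lifetimes.tsv"
    with open(lt_path, "w") as fh:
        fh.write("id\tlifetime_s\n")
        for rid, t in lifetimes.items():
            fh.write(f"{rid}\t{t:.6g}\n")
    table_path = directory / "codon_rates_synthetic.tsv"
    table_path.write_text(synthetic_rate_table_path().read_text())
    return {"fasta": fasta, "lifetimes": lt_path, "rate_table": table_path}


# --------------------------------------------------------------------------
# Exact master-equation oracle
# --------------------------------------------------------------------------


def enumerate_states(
    L: int, footprint: int, limit: int | None = None
) -> list[tuple[int, ...]]:
    """All A-site configurations with spacing >= footprint, empty included.

    The count grows exponentially in ``L / footprint``; pass ``limit`` to
    abort the enumeration as soon as it is exceeded instead of building the
    full list.
    """
    states: list[tuple[int, ...]] = [()]

    def extend(prefix: tuple[int, ...], min_pos: int) -> None:
        for p in range(min_pos, L + 1):
            cfg = prefix + (p,)
            states.append(cfg)
            if limit is not None and len(states) > limit:
                raise ValueError(
                    f"state space too large: more than {limit} configurations "
                    f"for L={L}, footprint={footprint}"
                )
            extend(cfg, p + footprint)

    extend((), 1)
    return states


@dataclass(frozen=True)
class CtmcSummary:
    """Exact expectations of the translation read-outs at time T."""

    mean_ribosomes: float
    density: float
    eff_init_rate: float
    expected_completions: float
    expected_initiations: float


def exact_ctmc_summary(
    spec: TranscriptSpec,
    T: float | None = None,
    *,
    max_states: int = 2000,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> CtmcSummary:
    """Integrate the exact master equation from the empty lattice to time T.

    Enumerates every admissible A-site configuration, builds the
    transition-rate matrix from the same reaction rules as the simulator, and
    integrates the probability vector together with three accumulated
    expectations (augmented-ODE formulation, which stays well-behaved at
    extreme rate ratios where matrix exponentials get stiff):

    * ribosome-seconds  (d/dt = sum_s |s| P_s),
    * completions       (d/dt = sum_s k_{L-1} 1[elong into L enabled] P_s),
    * initiations       (d/dt = sum_s (alpha 1[init] + r 1[reinit]) P_s).

    Only feasible for small lattices; raises if the state space exceeds
    ``max_states``.
    """
    spec.validate()
    if T is None:
        T = spec.lifetime
    states = enumerate_states(spec.L, spec.footprint, limit=max_states)
    ns = len(states)
    index = {s: i for i, s in enumerate(states)}

    rows, cols, vals = [], [], []
    occ_w = np.array([len(s) for s in states], dtype=np.float64)
    comp_w = np.zeros(ns)
    init_w = np.zeros(ns)
    diag = np.zeros(ns)
    for i, s in enumerate(states):
        for rid, rate in _enabled(s, spec):
            j = index[apply_reaction(s, rid)]
            rows.append(j)
            cols.append(i)
            vals.append(rate)
            diag[i] += rate
            if rid == INIT or rid == REINIT:
                init_w[i] += rate
            if rid[0] == "elong" and rid[1] == spec.L - 1:
                comp_w[i] += rate
    rows.extend(range(ns))
    cols.extend(range(ns))
    vals.extend(-diag)
    QT = csr_matrix((vals, (rows, cols)), shape=(ns, ns))

    def rhs(_t, y):
        p = y[:ns]
        dp = QT @ p
        return np.concatenate(
            [dp, [occ_w @ p, comp_w @ p, init_w @ p]]
        )

    y0 = np.zeros(ns + 3)
    y0[index[()]] = 1.0
    if T == 0:
        occ_int = comps = inits = 0.0
    else:
        sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"master-equation integration failed: {sol.message}")
        occ_int, comps, inits = sol.y[ns:, -1]
    mean_count = occ_int / T if T > 0 else 0.0
    return CtmcSummary(
        mean_ribosomes=mean_count,
        density=mean_count / spec.max_packing,
        eff_init_rate=inits / T if T > 0 else 0.0,
        expected_completions=float(comps),
        expected_initiations=float(inits),
    )
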