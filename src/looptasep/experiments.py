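"""In-silico experiment drivers.

Each driver wraps :func:`looptasep.engine.summarize` to reproduce one family
of simulation experiments:

* :func:`length_sweep` — the three translation read-outs across CDS lengths
  at a given reinitiation policy, with log-log slope estimates;
* :func:`perturb` — ratio of read-outs after changing one parameter of a
  single transcript species (reinitiation rate, de novo initiation rate, or
  all elongation rates), with paired replicate seeds;
* :func:`slow_step_scan` — effect of a single slow decoding step at the
  start, middle or final codon across lengths and slow rates;
* :func:`steady_state_diagnostics` — steady-state density over the tail of a
  long run and the first-passage time to that density;
* :func:`translatome_run` — one summary per CDS for a whole transcriptome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import _kernel
from .core import TranscriptSpec, TranslationSummary
from .engine import replicate_seeds, run_replicates, summarize
from .rates import ReinitiationPolicy, RateTable, build_elongation_rates

__all__ = [
    "SlopeFit",
    "loglog_slope",
    "SweepResult",
    "length_sweep",
    "PerturbResult",
    "perturb",
    "slow_step_scan",
    "SteadyStateResult",
    "steady_state_diagnostics",
    "TranslatomeResult",
    "translatome_run",
]

MEASURES = ("density", "eff_init_rate", "protein_yield")


# --------------------------------------------------------------------------
# slopes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    ci_low: float
    ci_high: float
    stderr: float
    intercept: float

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def loglog_slope(x: Sequence[float], y: Sequence[float]) -> SlopeFit:
    """OLS slope of log10(y) on log10(x) with a 95% t-interval (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a slope with a CI")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log slope requires strictly positive x and y")
    res = sstats.linregress(np.log10(x), np.log10(y))
    tcrit = sstats.t.ppf(0.975, len(x) - 2)
    half = tcrit * res.stderr
    return SlopeFit(
        slope=float(res.slope),
        ci_low=float(res.slope - half),
        ci_high=float(res.slope + half),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
    )


# --------------------------------------------------------------------------
# length sweeps
# --------------------------------------------------------------------------

DEFAULT_LENGTHS: tuple[int, ...] = tuple(
    int(round(v)) for v in np.logspace(np.log10(100), np.log10(4000), 13)
)


@dataclass
class SweepResult:
    """Rows of read-outs per (length, level) plus log-log slope records."""

    table: pd.DataFrame
    slopes: dict[str, SlopeFit | None]


def length_sweep(
    lengths: Sequence[int],
    policy: ReinitiationPolicy,
    alpha: float,
    lifetime: float,
    *,
    elong_rate: float = 10.0,
    rate_builder: Callable[[int], np.ndarray] | None = None,
    footprint: int = 10,
    n_runs: int = 1000,
    seed: int = 0,
) -> SweepResult:
    """Simulate the three read-outs across CDS lengths at one policy.

    ``rate_builder(L)`` may supply per-site elongation rates; by default a
    uniform ``elong_rate`` is used.  Slopes are fitted when at least three
    lengths are given and every measure is positive; otherwise the slope
    record is ``None`` (flagged, not an error).
    """
    lengths = sorted(int(L) for L in lengths)
    rows = []
    for i, L in enumerate(lengths):
        r, beta = policy.resolve(L)
        rates = rate_builder(L) if rate_builder else np.full(L - 1, elong_rate)
        spec = TranscriptSpec(
            id=f"L{L}",
            L=L,
            elong_rates=rates,
            alpha=alpha,
            reinit_rate=r,
            release_rate=beta,
            footprint=footprint,
            lifetime=lifetime,
        )
        s = summarize(spec, n_runs=n_runs, seed=seed + i)
        rows.append(
            {
                "length": L,
                "level": policy.level_for(L),
                "density": s.density,
                "eff_init_rate": s.eff_init_rate,
                "protein_yield": s.protein_yield,
                "se_density": s.se_density,
                "se_eff_init_rate": s.se_eff_init_rate,
                "se_protein_yield": s.se_protein_yield,
            }
        )
    table = pd.DataFrame(rows)
    slopes: dict[str, SlopeFit | None] = {}
    for m in MEASURES:
        y = table[m].to_numpy()
        if len(lengths) >= 3 and np.all(y > 0):
            slopes[m] = loglog_slope(table["length"].to_numpy(), y)
        else:
            slopes[m] = None
    return SweepResult(table=table, slopes=slopes)


# --------------------------------------------------------------------------
# perturbations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbResult:
    """Read-outs of an altered transcript relative to the unaltered one.

    Ratios are ratios of across-replicate means with paired seeds; standard
    errors come from the paired delta method.
    """

    which: str
    factor: float
    density_ratio: float
    eff_init_ratio: float
    yield_ratio: float
    se_density_ratio: float
    se_eff_init_ratio: float
    se_yield_ratio: float

    def ratios(self) -> dict[str, float]:
        return {
            "density": self.density_ratio,
            "eff_init_rate": self.eff_init_ratio,
            "protein_yield": self.yield_ratio,
        }


def _paired_ratio(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ratio mean(x)/mean(y) with a delta-method SE for paired replicates."""
    mx, my = x.mean(), y.mean()
    if my == 0:
        return (1.0 if mx == 0 else np.inf), np.nan
    ratio = mx / my
    n = len(x)
    if n < 2:
        return float(ratio), np.nan
    cov = np.cov(x, y, ddof=1)
    var = (cov[0, 0] - 2 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]) / (n * my**2)
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def _altered_spec(spec: TranscriptSpec, which: str, factor: float) -> TranscriptSpec:
    if which == "reinit_rate":
        return spec.replace(reinit_rate=spec.reinit_rate * factor)
    if which == "alpha":
        return spec.replace(alpha=spec.alpha * factor)
    if which == "elong_all":
        return spec.replace(elong_rates=spec.elong_rates * factor)
    raise ValueError(f"unknown perturbation target {which!r}")


def perturb(
    spec: TranscriptSpec,
    which: str,
    factor: float,
    n_runs: int = 1000,
    seed: int = 0,
) -> PerturbResult:
    """Ratio of read-outs for a single transcript species after scaling one
    parameter by ``factor``, relative to the unaltered transcript.

    ``which`` is one of ``reinit_rate`` (release rate held fixed, so the
    reinitiation level shifts as f*p / (f*p + 1 - p)), ``alpha``, or
    ``elong_all`` (every elongation site scaled).  Baseline and altered
    transcripts use identical replicate seeds, so ``factor=1`` returns
    ratios of exactly 1.
    """
    if not factor > 0:
        raise ValueError("factor must be > 0")
    base = run_replicates(spec, n_runs, seed)
    alt = run_replicates(_altered_spec(spec, which, factor), n_runs, seed)
    T = spec.lifetime
    pack = spec.max_packing
    dens_r, dens_se = _paired_ratio(alt[:, 0] / pack, base[:, 0] / pack)
    init_r, init_se = _paired_ratio(
        (alt[:, 1] + alt[:, 2]) / T, (base[:, 1] + base[:, 2]) / T
    )
    yld_r, yld_se = _paired_ratio(alt[:, 4], base[:, 4])
    return PerturbResult(
        which=which,
        factor=factor,
        density_ratio=dens_r,
        eff_init_ratio=init_r,
        yield_ratio=yld_r,
        se_density_ratio=dens_se,
        se_eff_init_ratio=init_se,
        se_yield_ratio=yld_se,
    )


def slow_step_scan(
    lengths: Sequence[int],
    positions: Sequence[str] = ("start", "middle", "final"),
    slow_rates: Sequence[float] = (1.0, 0.1, 0.01),
    *,
    level: float = 0.999,
    alpha: float,
    base_rate: float = 10.0,
    termination_total: float = 10.0,
    footprint: int = 10,
    lifetime: float = 1553.0,
    n_runs: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect of one slow decoding step on the three read-outs.

    For every (length, position, slow rate) combination, simulates a
    transcript with a single site slowed to ``slow_rate`` and reports each
    read-out relative to the unaltered uniform transcript (paired seeds).
    """
    from .rates import rates_from_level, with_slow_step

    r, beta = rates_from_level(level, termination_total)
    rows = []
    for i, L in enumerate(sorted(int(x) for x in lengths)):
        base_spec = TranscriptSpec(
            id=f"L{L}",
            L=L,
            elong_rates=np.full(L - 1, base_rate),
            alpha=alpha,
            reinit_rate=r,
            release_rate=beta,
            footprint=footprint,
            lifetime=lifetime,
        )
        base = run_replicates(base_spec, n_runs, seed + i)
        base_dens = base[:, 0]
        base_init = base[:, 1] + base[:, 2]
        base_yield = base[:, 4]
        for pos in positions:
            for srate in slow_rates:
                slowed = with_slow_step(base_spec.elong_rates, pos, srate)
                alt = run_replicates(
                    base_spec.replace(elong_rates=slowed), n_runs, seed + i
                )
                dens_r, _ = _paired_ratio(alt[:, 0], base_dens)
                init_r, _ = _paired_ratio(alt[:, 1] + alt[:, 2], base_init)
                yld_r, _ = _paired_ratio(alt[:, 4], base_yield)
                rows.append(
                    {
                        "length": L,
                        "position": pos,
                        "slow_rate": srate,
                        "density_ratio": dens_r,
                        "eff_init_ratio": init_r,
                        "yield_ratio": yld_r,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# steady-state diagnostics
# --------------------------------------------------------------------------


@dataclass
class SteadyStateResult:
    """Steady-state density and the first-passage time to it.

    ``attained`` is a self-consistency flag: False when the across-run mean
    density still drifts directionally over the final window, in which case
    ``first_passage`` is None ("not reached").
    """

    ss_density: float
    first_passage: float | None
    attained: bool
    drift_slope: float
    drift_pvalue: float
    times: np.ndarray
    mean_density: np.ndarray


def steady_state_diagnostics(
    spec: TranscriptSpec,
    run_time: float = 3e5,
    window: float = 1e4,
    n_runs: int = 1000,
    *,
    grid_dt: float = 10.0,
    seed: int = 0,
    drift_alpha: float = 0.01,
    drift_rel_tol: float = 0.02,
) -> SteadyStateResult:
    """Run long trajectories and locate the steady state.

    The transcript is simulated with lifetime ``run_time``; the instantaneous
    ribosome count is sampled on a fixed grid (``grid_dt`` spacing) and
    averaged across runs (event times differ between runs, so a common grid
    is needed for the across-run mean).  The steady-state density is the mean
    over the final ``window`` seconds; the first-passage time is the earliest
    grid time at which the mean density equals or exceeds it.  A directional
    drift over the final window (t-test at ``drift_alpha`` and a relative
    change above ``drift_rel_tol``) flags the steady state as not attained.
    """
    if window >= run_time:
        raise ValueError("window must be smaller than run_time")
    spec = spec.replace(lifetime=float(run_time))
    grid = np.arange(grid_dt, run_time + grid_dt / 2, grid_dt)
    seeds = replicate_seeds(seed, n_runs)
    out = np.empty((n_runs, 5), dtype=np.float64)
    grid_acc = np.zeros(grid.shape[0])
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
        grid,
        grid_acc,
        out,
    )
    mean_density = grid_acc / n_runs / spec.max_packing
    tail = grid >= run_time - window
    ss_density = float(mean_density[tail].mean())
    if ss_density == 0.0:
        return SteadyStateResult(0.0, 0.0, True, 0.0, 1.0, grid, mean_density)
    res = sstats.linregress(grid[tail], mean_density[tail])
    rel_change = abs(res.slope) * window / ss_density
    attained = (res.pvalue >= drift_alpha) or (rel_change < drift_rel_tol)
    first_passage: float | None = None
    if attained:
        hit = np.nonzero(mean_density >= ss_density)[0]
        if hit.size:
            first_passage = float(grid[hit[0]])
    return SteadyStateResult(
        ss_density=ss_density,
        first_passage=first_passage,
        attained=attained,
        drift_slope=float(res.slope),
        drift_pvalue=float(res.pvalue),
        times=grid,
        mean_density=mean_density,
    )


# --------------------------------------------------------------------------
# whole-translatome simulation
# --------------------------------------------------------------------------


@dataclass
class TranslatomeResult:
    table: pd.DataFrame
    excluded: list[str]
    failures: list[tuple[str, str]]


def _transcript_seed(seed: int, transcript_id: str) -> int:
    """Stable per-transcript seed: runs are deterministic per id regardless
    of ordering or chunking."""
    h = zlib.crc32(transcript_id.encode())
    return int(
        np.random.SeedSequence([int(seed), h]).generate_state(1, dtype=np.uint32)[0]
        & 0x7FFFFFFF
    )


def translatome_run(
    records: Sequence[tuple[str, str]] | str | Path,
    rate_table: RateTable,
    lifetime: float | Mapping[str, float] = 1553.0,
    policy: ReinitiationPolicy | None = None,
    alpha: float = 0.004,
    n_runs: int = 1000,
    seed: int = 0,
    *,
    footprint: int = 10,
    min_lifetime: float = 400.0,
    out_path: str | Path | None = None,
    chunk_size: int = 200,
) -> TranslatomeResult:
    """Simulate every CDS of a transcriptome, one summary row per transcript.

    ``records`` is a list of (id, sequence) pairs or a FASTA path;
    ``lifetime`` is a fixed value or a per-transcript mapping.  When a
    per-transcript mapping is supplied, transcripts with lifetimes below
    ``min_lifetime`` (default 400 s) are excluded and reported — shorter
    lifetimes make even a reinitiation-free model length-dependent (a
    pioneer-round artefact), which would bias comparisons.

    Per-record validation failures are collected and the run continues.  If
    ``out_path`` is given, results are checkpointed to TSV after every
    ``chunk_size`` transcripts.
    """
    if isinstance(records, (str, Path)):
        from .io import read_cds_fasta

        records = read_cds_fasta(records)
    if policy is None:
        policy = ReinitiationPolicy(level=0.999)
    per_transcript = isinstance(lifetime, Mapping)
    rows: list[dict] = []
    excluded: list[str] = []
    failures: list[tuple[str, str]] = []

    def _checkpoint() -> None:
        if out_path is not None and rows:
            from .io import write_summary_table

            write_summary_table(pd.DataFrame(rows), out_path)

    for i, (rid, seq) in enumerate(records):
        try:
            if per_transcript:
                if rid not in lifetime:
                    raise ValueError(f"no lifetime for transcript {rid!r}")
                T = float(lifetime[rid])
                if T < min_lifetime:
                    excluded.append(rid)
                    continue
            else:
                T = float(lifetime)
            elong = build_elongation_rates(seq, rate_table)
            L = len(elong) + 1
            r, beta = policy.resolve(L)
            spec = TranscriptSpec(
                id=rid,
                L=L,
                elong_rates=elong,
                alpha=alpha,
                reinit_rate=r,
                release_rate=beta,
                footprint=footprint,
                lifetime=T,
            )
            s: TranslationSummary = summarize(
                spec, n_runs=n_runs, seed=_transcript_seed(seed, rid)
            )
            row = s.as_dict()
            row["length"] = L
            row["lifetime"] = T
            rows.append(row)
        except Exception as exc:  # collect and continue
            failures.append((rid, str(exc)))
        if (i + 1) % chunk_size == 0:
            _checkpoint()
    _checkpoint()
    return TranslatomeResult(
        table=pd.DataFrame(rows), excluded=excluded, failures=failures
    )
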