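"""Calibration of the de novo initiation rate.

Raising either the reinitiation level or the elongation rate changes how
many ribosomes a transcript carries, so simulations at different parameter
settings are made comparable by adjusting the de novo initiation rate
``alpha`` until a reference transcript (400 codons by convention) carries a
target lifetime-averaged ribosome count (6 by convention).

The mean count is monotone non-decreasing in ``alpha``, so the search is a
bisection on log10(alpha).  Every evaluation reuses the same replicate seeds
(common random numbers), which makes the count-vs-alpha curve smooth in the
search and prevents Monte-Carlo noise from stalling the bracket.
"""

from __future__ import annotations

import numpy as np

from .core import TranscriptSpec
from .engine import run_replicates

__all__ = ["CalibrationError", "calibrate_alpha", "mean_ribosome_count"]


class CalibrationError(RuntimeError):
    """The target ribosome count cannot be reached within the bracket."""


def mean_ribosome_count(
    spec: TranscriptSpec, n_runs: int = 1000, seed: int = 0
) -> float:
    """Mean over replicates of the lifetime-averaged ribosome count."""
    return float(run_replicates(spec, n_runs, seed)[:, 0].mean())


def calibrate_alpha(
    reference: TranscriptSpec,
    target_count: float = 6.0,
    n_runs: int = 1000,
    seed: int = 0,
    tolerance: float = 0.05,
    bracket: tuple[float, float] = (1e-6, 1e2),
    max_expand: int = 4,
    max_iter: int = 60,
) -> float:
    """Find alpha so the reference transcript carries ``target_count`` ribosomes.

    Parameters
    ----------
    reference : TranscriptSpec
        Reference transcript; its ``alpha`` field is ignored and replaced
        during the search.
    target_count : float
        Target lifetime-averaged ribosome count (must be below the maximum
        packing ``L / footprint``).
    tolerance : float
        Acceptable deviation of the achieved mean count, in ribosomes.  The
        default 0.05 is comfortably above the standard error of the mean at
        1000 replicates for typical parameters.

    Returns the calibrated alpha; raises :class:`CalibrationError` with the
    achieved bound if the target is unreachable (e.g. the lifetime is too
    short to ever accumulate the target load).
    """
    if target_count < 0:
        raise ValueError("target_count must be >= 0")
    if target_count >= reference.max_packing:
        raise ValueError(
            f"target_count {target_count} >= maximum packing {reference.max_packing}"
        )
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if target_count == 0:
        return 0.0

    def count_at(alpha: float) -> float:
        return mean_ribosome_count(reference.replace(alpha=alpha), n_runs, seed)

    lo, hi = bracket
    f_lo = count_at(lo) - target_count
    for _ in range(max_expand):
        if f_lo <= 0:
            break
        lo /= 100.0
        f_lo = count_at(lo) - target_count
    if f_lo > 0:
        raise CalibrationError(
            f"target {target_count} already exceeded at alpha={lo:g} "
            f"(achieved {f_lo + target_count:.3f})"
        )
    f_hi = count_at(hi) - target_count
    for _ in range(max_expand):
        if f_hi >= 0:
            break
        hi *= 100.0
        f_hi = count_at(hi) - target_count
    if f_hi < 0:
        raise CalibrationError(
            f"target {target_count} unreachable: alpha={hi:g} achieves only "
            f"{f_hi + target_count:.3f} ribosomes"
        )

    log_lo, log_hi = np.log10(lo), np.log10(hi)
    alpha = lo
    for _ in range(max_iter):
        log_mid = 0.5 * (log_lo + log_hi)
        alpha = 10.0**log_mid
        f_mid = count_at(alpha) - target_count
        if abs(f_mid) <= tolerance:
            return float(alpha)
        if f_mid < 0:
            log_lo = log_mid
        else:
            log_hi = log_mid
        if log_hi - log_lo < 1e-12:
            break
    achieved = count_at(alpha)
    raise CalibrationError(
        f"bisection exhausted: best alpha={alpha:g} gives {achieved:.3f} "
        f"ribosomes (target {target_count} ± {tolerance})"
    )
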