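"""Growth-physiology annotation: replication time, R-factor, doubling time.

The R-factor ``R_f = T_R / T_D`` compares the time needed for one full round
of chromosome replication (``T_R``, half the genome length divided by an
average in vivo fork speed of 600 nt/s) with the organism's minimum doubling
time ``T_D``.  ``R_f > 1`` marks fast growers that must run overlapping
replication cycles, and hence experience a steep oriC-to-ter gene dosage
gradient.  The fixed fork speed is an acknowledged simplification; it is a
parameter here, overridable per organism.

Where no measured doubling time exists, ``T_D`` is estimated from the 16S
rRNA gene copy number, a well-established growth-rate proxy (fast growers
carry more rRNA operons), using a reference table of measured doubling times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_FORK_SPEED = 600.0  # nt per second


@dataclass(frozen=True)
class GrowthProfile:
    """Replication time, doubling time and their ratio for one organism."""

    t_r: float  # seconds
    t_d: float  # seconds
    r_f: float
    fast: bool


def replication_time(genome_length: float, fork_speed: float = DEFAULT_FORK_SPEED) -> float:
    """Seconds to replicate the chromosome: (length / 2) / fork speed.

    Two forks proceed in opposite directions from oriC, so each covers half
    the circle.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if fork_speed <= 0:
        raise ValueError("fork speed must be positive")
    return (genome_length / 2.0) / fork_speed


def r_factor(t_r: float, t_d: float) -> GrowthProfile:
    """R-factor from replication time and minimum doubling time (seconds).

    ``fast`` is set by the strict inequality ``R_f > 1``.
    """
    if t_r <= 0 or t_d <= 0:
        raise ValueError("times must be positive")
    rf = t_r / t_d
    return GrowthProfile(t_r=t_r, t_d=t_d, r_f=rf, fast=rf > 1.0)


def doubling_time_from_rrna(copy_number: int,
                            reference: list[tuple[int, float]]) -> float:
    """Estimate minimum doubling time (hours) from 16S rRNA copy number.

    The estimate is the median reference doubling time among organisms with
    that copy number.  Copy numbers absent from the reference are filled by
    log-linear interpolation between the nearest observed copy-number class
    medians (doubling times are strictly positive and span orders of
    magnitude, so interpolation is linear in log T_D); copy numbers outside
    the observed range clamp to the nearest class median.
    """
    if copy_number < 1:
        raise ValueError("copy number must be >= 1")
    if not reference:
        raise ValueError("reference table is empty")
    classes: dict[int, list[float]] = {}
    for copies, hours in reference:
        if copies < 1 or hours <= 0:
            raise ValueError(f"invalid reference entry ({copies}, {hours})")
        classes.setdefault(int(copies), []).append(float(hours))
    medians = {c: float(np.median(v)) for c, v in classes.items()}
    if copy_number in medians:
        return medians[copy_number]
    observed = sorted(medians)
    lower = [c for c in observed if c < copy_number]
    upper = [c for c in observed if c > copy_number]
    if not lower:
        return medians[observed[0]]
    if not upper:
        return medians[observed[-1]]
    lo, hi = lower[-1], upper[0]
    frac = (copy_number - lo) / (hi - lo)
    log_td = (1 - frac) * math.log(medians[lo]) + frac * math.log(medians[hi])
    return math.exp(log_td)


def profile_for_genome(genome_length: float, doubling_time_h: float,
                       fork_speed: float = DEFAULT_FORK_SPEED) -> GrowthProfile:
    """Convenience: GrowthProfile from genome length and doubling time in hours."""
    return r_factor(replication_time(genome_length, fork_speed),
                    doubling_time_h * 3600.0)
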