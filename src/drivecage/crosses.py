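"""Single-generation cross estimators and allele-competition expectations.

Transmission is the fraction of scored progeny inheriting the drive
marker; the gene-conversion (HDR) rate follows from it as
``2(X - 0.5 n)/n``, i.e. the excess over Mendelian transmission rescaled
to the convertible allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CrossTally",
    "transmission_rate",
    "hdr_rate",
    "replicate_summary",
    "competition_expectation",
]


@dataclass(frozen=True)
class CrossTally:
    """Scored progeny of one replicate cross.

    ``gfp_pos`` individuals inherited the drive marker; the GFP-negative
    progeny split into black, white and mosaic eye classes.  Eye-class
    counts must sum to ``n`` when provided (pass ``validate_eyes=False``
    for marker-only tallies).
    """

    n: int
    gfp_pos: int
    nogfp_black: int = 0
    nogfp_white: int = 0
    nogfp_mosaic: int = 0
    replicate: str = ""
    lineage: str = ""  # parent of origin of the drive allele: "female" | "male"
    validate_eyes: bool = True

    def __post_init__(self) -> None:
        counts = (self.n, self.gfp_pos, self.nogfp_black, self.nogfp_white, self.nogfp_mosaic)
        if any(c < 0 or c != int(c) for c in counts):
            raise ValueError("all counts must be non-negative integers")
        if self.gfp_pos > self.n:
            raise ValueError("gfp_pos cannot exceed n")
        if self.validate_eyes:
            total = self.gfp_pos + self.nogfp_black + self.nogfp_white + self.nogfp_mosaic
            if total != self.n:
                raise ValueError(
                    f"category counts sum to {total}, expected n={self.n}"
                )


def transmission_rate(t: CrossTally) -> float:
    """Fraction of progeny inheriting the drive marker."""
    if t.n == 0:
        raise ValueError("cannot compute a rate from an empty tally")
    return t.gfp_pos / t.n


def hdr_rate(t: CrossTally) -> float:
    """Gene-conversion rate 2(X - 0.5 n)/n.

    Equals ``2 * transmission - 1`` exactly.  Transmission below the
    Mendelian 50% yields a negative value, which is returned as computed
    with a warning rather than clamped.
    """
    if t.n == 0:
        raise ValueError("cannot compute a rate from an empty tally")
    rate = 2.0 * (t.gfp_pos - 0.5 * t.n) / t.n
    if rate < 0.0:
        warnings.warn(
            f"transmission below Mendelian expectation (HDR rate {rate:.4f} < 0)",
            stacklevel=2,
        )
    return rate


def replicate_summary(
    tallies: Sequence[CrossTally],
    statistic: Callable[[CrossTally], float] = transmission_rate,
) -> Tuple[float, float, int]:
    """Mean, standard error and count of a per-replicate rate.

    The SEM is computed across replicates (the reporting unit of the
    crosses), not from a pooled binomial.
    """
    if len(tallies) < 2:
        raise ValueError("need at least two replicates for a summary")
    rates = np.array([statistic(t) for t in tallies], dtype=float)
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / math.sqrt(len(rates)))
    return mean, sem, len(rates)


def competition_expectation(generations: int) -> np.ndarray:
    """Expected GFP+ fraction, generations 1..G, for an H/R founding cage.

    A population founded entirely by drive/functional-resistant (H/R)
    heterozygotes with equal allele fitness, no loads and no cleavable
    target reaches the Mendelian 1:2:1 equilibrium in one generation:
    3/4 of individuals carry at least one drive allele at every
    generation thereafter.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return np.full(generations, 0.75)
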