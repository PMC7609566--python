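"""Deterministic (infinite-population) genotype-frequency recursion.

Generations are discrete and nonoverlapping with random mixing.  Each
step (i) weights mothers by frequency times one minus their reproductive
load, (ii) sums the cross-specific offspring distributions over all
mother x father genotype pairs, and (iii) splits offspring 1:1 into the
two sexes with identical genotype distributions.  Phenotype frequencies
are reported on offspring before loads act, matching larval scoring in
the cage protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    GENOTYPES,
    GENOTYPE_INDEX,
    GFP_MASK,
    N_GENOTYPES,
    WHITE_INDEX,
    Allele,
    DriveParams,
    Genotype,
    load_vector,
    offspring_tensor,
)

__all__ = [
    "SeedingConfig",
    "PopulationState",
    "Trajectory",
    "seeding_state",
    "next_generation",
    "run_deterministic",
    "phenotype_trajectory",
    "first_generation_at_threshold",
    "write_trajectory_csv",
    "write_phenotype_csv",
    "ReproductiveFailure",
]

_WW = GENOTYPE_INDEX[Genotype(Allele.W, Allele.W)]
_HW = GENOTYPE_INDEX[Genotype(Allele.W, Allele.H)]

#: heterozygous-drive males released per ratio label at census 200
RELEASE_COUNTS = {"1:1": 50, "1:3": 25, "1:9": 10}

_NORM_TOL = 1e-10
_DRIFT_TOL = 1e-8


class ReproductiveFailure(RuntimeError):
    """Raised when every female genotype has zero reproductive weight."""


@dataclass(frozen=True)
class SeedingConfig:
    """Release composition at generation 0.

    ``counts`` is a (2, 10) integer array of (sex, genotype) adults,
    row 0 females, row 1 males, in canonical genotype order.
    """

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, N_GENOTYPES) or (counts < 0).any():
            raise ValueError("counts must be a non-negative (2, 10) integer array")
        object.__setattr__(self, "counts", counts)

    @property
    def census(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        """(2, 10) per-sex genotype frequencies."""
        out = self.counts.astype(float)
        return out / out.sum(axis=1, keepdims=True)


def seeding_state(ratio: str, census: int = 200) -> SeedingConfig:
    """Cage seeding for a drive:wild-type male release ratio.

    Half the census is wild-type females.  Of the males, ``1/(1+m)`` are
    heterozygous drive carriers for ratio label ``"1:m"`` (50, 25 and 10
    drive males at census 200 for 1:1, 1:3 and 1:9).
    """
    try:
        one, m = ratio.split(":")
        m = int(m)
        if one != "1" or m < 1:
            raise ValueError
    except ValueError:
        raise ValueError(f"unknown release ratio {ratio!r}; expected '1:m'") from None
    males = census // 2
    drive_males = round(males / (1 + m))
    counts = np.zeros((2, N_GENOTYPES), dtype=int)
    counts[0, _WW] = census - males
    counts[1, _HW] = drive_males
    counts[1, _WW] = males - drive_males
    return SeedingConfig(counts=counts, label=ratio)


@dataclass(frozen=True)
class PopulationState:
    """Per-sex genotype frequencies at one generation."""

    generation: int
    freq: np.ndarray  # (2, 10), row 0 females, row 1 males

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (2, N_GENOTYPES):
            raise ValueError("freq must have shape (2, 10)")
        if (freq < -_NORM_TOL).any() or np.abs(freq.sum(axis=1) - 1.0).max() > _NORM_TOL:
            raise ValueError("each sex's frequencies must be >=0 and sum to 1")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        object.__setattr__(self, "freq", freq)

    def pooled(self) -> np.ndarray:
        """Genotype frequencies pooled over sexes (1:1 sex ratio)."""
        return 0.5 * (self.freq[0] + self.freq[1])

    def gfp_fraction(self) -> float:
        return float(self.pooled()[GFP_MASK].sum())


@dataclass
class Trajectory:
    """Ordered deterministic states with the parameters that produced them."""

    states: List[PopulationState]
    params: DriveParams
    seeding: Optional[SeedingConfig] = None

    def __post_init__(self) -> None:
        gens = [s.generation for s in self.states]
        if gens != list(range(len(gens))):
            raise ValueError("generations must be consecutive from 0")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> PopulationState:
        return self.states[i]

    def freq_array(self) -> np.ndarray:
        """(G+1, 2, 10) stacked frequencies."""
        return np.stack([s.freq for s in self.states])

    def gfp_fractions(self) -> np.ndarray:
        return np.array([s.gfp_fraction() for s in self.states])


def next_generation(
    state: PopulationState,
    p: DriveParams,
    tensor: Optional[np.ndarray] = None,
    deposition_mode: str = "per_allele",
) -> PopulationState:
    """One step of the expected genotype-frequency recursion.

    Mothers contribute in proportion to frequency x (1 - load); fathers
    in proportion to frequency.  A precomputed ``offspring_tensor`` may
    be passed to avoid rebuilding it (the likelihood hot path).
    """
    if tensor is None:
        tensor = offspring_tensor(p, deposition_mode)
    weights = state.freq[0] * (1.0 - load_vector(p))
    total = weights.sum()
    if total <= 0.0:
        raise ReproductiveFailure(
            f"all female reproductive weights are zero at generation {state.generation}"
        )
    weights = weights / total
    offspring = np.einsum("m,f,mfg->g", weights, state.freq[1], tensor)
    drift = abs(offspring.sum() - 1.0)
    if drift > _DRIFT_TOL:
        raise FloatingPointError(f"frequency normalization drifted by {drift:g}")
    offspring = offspring / offspring.sum()
    return PopulationState(
        generation=state.generation + 1,
        freq=np.stack([offspring, offspring]),
    )


def run_deterministic(
    seed_cfg: SeedingConfig,
    p: DriveParams,
    generations: int,
    deposition_mode: str = "per_allele",
) -> Trajectory:
    """Expected trajectory over ``generations`` steps from a seeding state."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    tensor = offspring_tensor(p, deposition_mode)
    state = PopulationState(generation=0, freq=seed_cfg.frequencies())
    states = [state]
    for _ in range(generations):
        state = next_generation(state, p, tensor=tensor)
        states.append(state)
    return Trajectory(states=states, params=p, seeding=seed_cfg)


def phenotype_trajectory(traj: Trajectory) -> pd.DataFrame:
    """Per-generation observable phenotype frequencies, pooled over sexes.

    Columns: generation, gfp_pos (drive carriers), gfp_neg_black
    (non-drive with at least one functional allele), gfp_neg_white (B/B).
    """
    rows = []
    for s in traj.states:
        pooled = s.pooled()
        gfp = pooled[GFP_MASK].sum()
        white = pooled[WHITE_INDEX]
        rows.append(
            {
                "generation": s.generation,
                "gfp_pos": gfp,
                "gfp_neg_black": 1.0 - gfp - white,
                "gfp_neg_white": white,
            }
        )
    return pd.DataFrame(rows)


def first_generation_at_threshold(traj: Trajectory, threshold: float) -> Optional[int]:
    """Smallest generation with GFP+ frequency >= threshold, else None."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    for s in traj.states:
        if s.gfp_fraction() >= threshold:
            return s.generation
    return None


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per (generation, sex, genotype, frequency)."""
    rows = []
    for s in traj.states:
        for sex_i, sex in enumerate("FM"):
            for k, g in enumerate(GENOTYPES):
                rows.append(
                    {
                        "generation": s.generation,
                        "sex": sex,
                        "genotype": str(g),
                        "frequency": s.freq[sex_i, k],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_phenotype_csv(traj: Trajectory, path) -> None:
    phenotype_trajectory(traj).to_csv(path, index=False)
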