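"""Finite-population cage simulator.

One generation applies four sampling layers, mirroring the cage
protocol: multinomial mate choice (each female mates once, by male
genotype frequency), Poisson egg production with fecundity reduced by
the female's load, multinomial offspring genotypes from the cross
distribution (with Bernoulli(1/2) sex), and multivariate-hypergeometric
sampling of the fixed adult census from the larval pool.  A scored
subsample (default 500 larvae) is drawn from the pool independently of
the next-generation adults, as in the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .deterministic import SeedingConfig
from .genetics import (
    GENOTYPES,
    N_GENOTYPES,
    DriveParams,
    load_vector,
    offspring_tensor,
)

__all__ = [
    "StochasticConfig",
    "CageRealization",
    "PopulationCrash",
    "simulate_generation",
    "run_stochastic",
    "write_realization_csv",
]


class PopulationCrash(RuntimeError):
    """Population cannot continue (empty larval pool or a missing sex)."""

    def __init__(self, generation: int, reason: str):
        super().__init__(f"population crash at generation {generation}: {reason}")
        self.generation = generation
        self.reason = reason


@dataclass(frozen=True)
class StochasticConfig:
    """Cage simulation settings.

    ``mean_eggs`` is the mean egg batch per unloaded female; cage
    dynamics at census 200 are insensitive to it beyond ~20 because the
    hypergeometric census draw discards the surplus.
    """

    census: int = 200
    mean_eggs: float = 50.0
    scored: int = 500
    generations: int = 18

    def __post_init__(self) -> None:
        if self.census <= 0 or self.mean_eggs <= 0 or self.scored <= 0:
            raise ValueError("census, mean_eggs and scored must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class CageRealization:
    """One stochastic cage run.

    ``adults``: (G+1, 2, 10) integer counts (row 0 females);
    ``scored``: (G, 2, 10) scored-larvae counts for generations 1..G.
    ``crashed_at`` is the generation at which the run stopped early.
    """

    adults: np.ndarray
    scored: np.ndarray
    params: DriveParams
    config: StochasticConfig
    seed: Optional[int] = None
    crashed_at: Optional[int] = None

    @property
    def generations(self) -> int:
        return self.adults.shape[0] - 1

    def scored_gfp_fractions(self) -> np.ndarray:
        from .genetics import GFP_MASK

        pooled = self.scored.sum(axis=1)
        return pooled[:, GFP_MASK].sum(axis=1) / pooled.sum(axis=1)


def _sample_pool(
    adults: np.ndarray,
    p: DriveParams,
    cfg: StochasticConfig,
    rng: np.random.Generator,
    tensor: np.ndarray,
    generation: int,
) -> np.ndarray:
    """Larval pool (2, 10) produced by the current adults."""
    n_f = adults[0]
    n_m = adults[1]
    if n_f.sum() == 0 or n_m.sum() == 0:
        raise PopulationCrash(generation, "no adults of one sex")
    male_freq = n_m / n_m.sum()
    fecundity = cfg.mean_eggs * (1.0 - load_vector(p))
    pool = np.zeros(N_GENOTYPES, dtype=np.int64)
    for g in np.nonzero(n_f)[0]:
        # monandry: each female draws one mate by male genotype frequency
        mates = rng.multinomial(n_f[g], male_freq)
        eggs_expected = fecundity[g] * mates
        for f in np.nonzero(mates)[0]:
            eggs = rng.poisson(eggs_expected[f])
            if eggs:
                pool += rng.multinomial(eggs, tensor[g, f])
    if pool.sum() == 0:
        raise PopulationCrash(generation, "empty larval pool")
    # sex assigned Bernoulli(1/2) at the egg stage
    females = rng.binomial(pool, 0.5)
    return np.stack([females, pool - females])


def simulate_generation(
    adults: np.ndarray,
    p: DriveParams,
    cfg: StochasticConfig,
    rng: np.random.Generator,
    tensor: Optional[np.ndarray] = None,
    generation: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one generation; returns (next adults, larval pool).

    Both arrays are (2, 10) integer (sex, genotype) counts; the next
    adults are a multivariate-hypergeometric draw of ``cfg.census``
    individuals from the pool, jointly over (sex, genotype) cells.
    """
    adults = np.asarray(adults, dtype=np.int64)
    if tensor is None:
        tensor = offspring_tensor(p)
    pool = _sample_pool(adults, p, cfg, rng, tensor, generation)
    if pool.sum() < cfg.census:
        raise PopulationCrash(generation, f"larval pool {pool.sum()} < census {cfg.census}")
    nxt = rng.multivariate_hypergeometric(pool.ravel(), cfg.census).reshape(2, N_GENOTYPES)
    return nxt, pool


def run_stochastic(
    seed_cfg: SeedingConfig,
    p: DriveParams,
    cfg: StochasticConfig,
    rng: np.random.Generator | int | None = None,
    allow_crash: bool = False,
) -> CageRealization:
    """Full cage realization, including the per-generation scored subsample.

    The scored sample (``cfg.scored`` larvae) is drawn from the larval
    pool independently of the census draw.  With ``allow_crash`` a crash
    truncates the realization (recorded in ``crashed_at``) instead of
    raising.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    tensor = offspring_tensor(p)
    adults = [np.asarray(seed_cfg.counts, dtype=np.int64)]
    scored: List[np.ndarray] = []
    crashed_at = None
    for gen in range(cfg.generations):
        try:
            nxt, pool = simulate_generation(
                adults[-1], p, cfg, rng, tensor=tensor, generation=gen
            )
            if pool.sum() < cfg.scored:
                raise PopulationCrash(
                    gen, f"larval pool {pool.sum()} < scored sample {cfg.scored}"
                )
        except PopulationCrash:
            if not allow_crash:
                raise
            crashed_at = gen
            break
        sample = rng.multivariate_hypergeometric(pool.ravel(), cfg.scored)
        scored.append(sample.reshape(2, N_GENOTYPES))
        adults.append(nxt)
    return CageRealization(
        adults=np.stack(adults),
        scored=(
            np.stack(scored)
            if scored
            else np.zeros((0, 2, N_GENOTYPES), dtype=np.int64)
        ),
        params=p,
        config=cfg,
        seed=seed,
        crashed_at=crashed_at,
    )


def write_realization_csv(real: CageRealization, path) -> None:
    """One row per (generation, sex, genotype) with adult and scored counts."""
    rows = []
    for gen in range(real.adults.shape[0]):
        for sex_i, sex in enumerate("FM"):
            for k, g in enumerate(GENOTYPES):
                rows.append(
                    {
                        "generation": gen,
                        "sex": sex,
                        "genotype": str(g),
                        "adult_count": int(real.adults[gen, sex_i, k]),
                        "scored_count": (
                            int(real.scored[gen - 1, sex_i, k])
                            if 1 <= gen <= real.scored.shape[0]
                            else 0
                        ),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
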