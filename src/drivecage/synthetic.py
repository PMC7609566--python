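"""Synthetic cage-trial and cross datasets with the experiments' observation structure.

The generator reproduces the design of the published cage trials:
triplicate cages at 1:1, 1:3 and 1:9 heterozygous-drive:wild-type male
release ratios, adult census 200, 18 nonoverlapping generations, and a
random sample of 500 scored larvae per generation tallied into
GFP +/- x black/white/mosaic eye categories.  Because deposition is
modelled as complete allele conversion, the model itself produces no
partial-eye mosaics; the generator emits GFP-/mosaic = 0 by default and
offers an observation-noise mode that reassigns a fraction of model
GFP-/white individuals to the mosaic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .crosses import CrossTally
from .deterministic import seeding_state
from .genetics import (
    GENOTYPE_INDEX,
    GFP_MASK,
    WHITE_INDEX,
    Allele,
    DriveParams,
    Genotype,
    Sex,
    offspring_tensor,
)
from .inference import CageDataset, PhenotypeCounts
from .stochastic import StochasticConfig, run_stochastic

__all__ = [
    "ExperimentDesign",
    "generate_cage_dataset",
    "generate_cross_dataset",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic multi-cage trial (defaults: the published design)."""

    ratios: Tuple[str, ...] = ("1:1", "1:3", "1:9")
    replicates: int = 3
    generations: int = 18
    scored: int = 500
    census: int = 200
    mean_eggs: float = 50.0
    truth: DriveParams = field(default_factory=DriveParams.cage_fit)
    seed: int = 0
    mosaic_fraction: float = 0.0  # observation noise: white scored as mosaic

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.generations < 1:
            raise ValueError("replicates and generations must be positive")
        if self.scored < 1:
            raise ValueError("scored sample size must be positive")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")

    def to_manifest(self) -> Dict:
        d = asdict(self)
        d["truth"] = self.truth.to_dict()
        d["ratios"] = list(self.ratios)
        return d

    @classmethod
    def from_manifest(cls, manifest: Dict) -> "ExperimentDesign":
        d = dict(manifest)
        d["truth"] = DriveParams(**d["truth"])
        d["ratios"] = tuple(d["ratios"])
        return cls(**d)


def _tally(scored: np.ndarray, generation: int, rng, mosaic_fraction: float) -> PhenotypeCounts:
    pooled = scored.sum(axis=0)
    gfp = int(pooled[GFP_MASK].sum())
    white = int(pooled[WHITE_INDEX])
    black = int(pooled.sum()) - gfp - white
    mosaic = int(rng.binomial(white, mosaic_fraction)) if mosaic_fraction > 0 else 0
    return PhenotypeCounts(
        generation=generation,
        gfp_black=gfp,
        gfp_white=0,
        nogfp_black=black,
        nogfp_white=white - mosaic,
        nogfp_mosaic=mosaic,
        total=int(pooled.sum()),
    )


def generate_cage_dataset(design: ExperimentDesign) -> List[CageDataset]:
    """Simulate every cage of the design and tally the scored samples.

    Cage seeds are spawned deterministically from the design's master
    seed, so regeneration from a manifest is bit-identical.  A crashed
    realization yields a truncated, flagged series.
    """
    cfg = StochasticConfig(
        census=design.census,
        mean_eggs=design.mean_eggs,
        scored=design.scored,
        generations=design.generations,
    )
    root = np.random.SeedSequence(design.seed)
    datasets = []
    for ratio in design.ratios:
        for rep in range(design.replicates):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            real = run_stochastic(
                seeding_state(ratio, design.census),
                design.truth,
                cfg,
                rng=rng,
                allow_crash=True,
            )
            counts = [
                _tally(real.scored[g], g + 1, rng, design.mosaic_fraction)
                for g in range(real.scored.shape[0])
            ]
            datasets.append(
                CageDataset(
                    cage_id=f"{ratio}_{chr(ord('A') + rep)}",
                    ratio=ratio,
                    counts=tuple(counts),
                    census=design.census,
                    crashed=real.crashed_at is not None,
                )
            )
    return datasets


_HW = GENOTYPE_INDEX[Genotype(Allele.W, Allele.H)]
_WW = GENOTYPE_INDEX[Genotype(Allele.W, Allele.W)]


def generate_cross_dataset(
    parent: Sex,
    n_per_replicate: int,
    replicates: int,
    p: DriveParams,
    seed: int = 0,
) -> List[CrossTally]:
    """Replicate heterozygous-drive x wild-type cross tallies.

    The drive parent has the given sex; deposition shapes the offspring
    phenotypes only when the drive parent is the mother.  ``n_per_replicate
    = 0`` yields empty (marker-only) tallies.
    """
    if n_per_replicate < 0 or replicates < 1:
        raise ValueError("n_per_replicate must be >= 0 and replicates >= 1")
    tensor = offspring_tensor(p)
    dist = tensor[_HW, _WW] if parent is Sex.F else tensor[_WW, _HW]
    rng = np.random.default_rng(seed)
    lineage = "female" if parent is Sex.F else "male"
    tallies = []
    for rep in range(replicates):
        counts = rng.multinomial(n_per_replicate, dist)
        gfp = int(counts[GFP_MASK].sum())
        white = int(counts[WHITE_INDEX])
        black = int(counts.sum()) - gfp - white
        tallies.append(
            CrossTally(
                n=n_per_replicate,
                gfp_pos=gfp,
                nogfp_black=black,
                nogfp_white=white,
                nogfp_mosaic=0,
                replicate=chr(ord("A") + rep),
                lineage=lineage,
            )
        )
    return tallies
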