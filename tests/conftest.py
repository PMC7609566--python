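"""Shared fixtures and independent brute-force oracles.

The oracles deliberately enumerate event trees (cleavage/repair outcomes,
gamete pairs, per-allele deposition) instead of reusing the package's
vectorised kernels, so that implementation and test stay independent.
"""

from __future__ import annotations

import itertools
from typing import Dict

import numpy as np
import pytest

from drivecage import Allele, DriveParams, Genotype, Sex
from drivecage.genetics import GENOTYPES


@pytest.fixture
def fitted_params() -> DriveParams:
    return DriveParams.cage_fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_params(rng: np.random.Generator) -> DriveParams:
    """A random full parameter draw (p_mr drawn independently of p_res)."""
    v = rng.uniform(0, 1, size=9)
    return DriveParams(
        c=v[0], p_hdr_f=v[1], p_hdr_m=v[2], p_res=v[3], p_mc=v[4],
        p_mr=v[5], s_h1=v[6], s_h2=v[7], s_bb=v[8],
    )


def oracle_gametes(g: Genotype, sex: Sex, p: DriveParams) -> Dict[Allele, float]:
    """Enumerate the per-allele cleavage/repair outcome tree of gametogenesis."""
    out = {a: 0.0 for a in Allele}
    alleles = list(g.alleles)
    homing = set(alleles) == {Allele.H, Allele.W}
    for allele in alleles:
        if homing and allele is Allele.W:
            hdr = p.p_hdr_f if sex is Sex.F else p.p_hdr_m
            out[Allele.W] += 0.5 * (1 - p.c)
            out[Allele.H] += 0.5 * p.c * hdr
            out[Allele.R] += 0.5 * p.c * (1 - hdr) * p.p_res
            out[Allele.B] += 0.5 * p.c * (1 - hdr) * (1 - p.p_res)
        else:
            out[allele] += 0.5
    return out


def oracle_offspring(
    mother: Genotype, father: Genotype, p: DriveParams
) -> Dict[Genotype, float]:
    """Enumerate (maternal gamete, paternal gamete, per-allele deposition)."""
    gm = oracle_gametes(mother, Sex.F, p)
    gf = oracle_gametes(father, Sex.M, p)
    deposits = Allele.H in mother

    def deposition_outcomes(a: Allele):
        if not deposits or a is not Allele.W:
            return [(a, 1.0)]
        return [
            (Allele.W, 1.0 - p.p_mc),
            (Allele.R, p.p_mc * p.p_mr),
            (Allele.B, p.p_mc * (1.0 - p.p_mr)),
        ]

    out: Dict[Genotype, float] = {}
    for (ma, pma), (fa, pfa) in itertools.product(gm.items(), gf.items()):
        if pma == 0.0 or pfa == 0.0:
            continue
        for (xa, qa), (xb, qb) in itertools.product(
            deposition_outcomes(ma), deposition_outcomes(fa)
        ):
            prob = pma * pfa * qa * qb
            if prob > 0.0:
                g = Genotype(xa, xb)
                out[g] = out.get(g, 0.0) + prob
    return out


def dist_as_array(dist: Dict[Genotype, float]) -> np.ndarray:
    out = np.zeros(len(GENOTYPES))
    for g, v in dist.items():
        out[g.index] = v
    return out
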