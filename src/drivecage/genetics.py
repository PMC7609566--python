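"""Allele/genotype state space and inheritance rules for a homing rescue drive.

The model tracks four alleles at the target locus of an autosomal
CRISPR/Cas9 homing gene drive that carries a recoded rescue copy of an
essential gene (eye-pigmentation / female-fitness gene in an anopheline
mosquito):

* ``W`` -- wild-type, cleavable allele;
* ``H`` -- the drive (rescue) allele, marked with a dominant fluorescent
  marker and providing a functional copy of the target gene;
* ``R`` -- a cleavage-resistant, in-frame allele that preserves gene
  function (functional resistance);
* ``B`` -- a cleavage-resistant, loss-of-function allele (nonfunctional
  resistance).  ``B/B`` females carry a severe reproductive load.

Inheritance follows Mendelian segregation with two drive-specific
modifications:

1. **Germline homing.**  In ``H/W`` heterozygous adults a fraction *c* of
   W alleles is cleaved during gametogenesis.  Cleaved alleles are
   converted to ``H`` by homology-directed repair with sex-specific
   probability *p_HDR*; the remainder end-join into ``R`` (with
   probability *p_RES*) or ``B``.
2. **Maternal deposition.**  Mothers carrying ``H`` load Cas9/gRNA
   complexes into all their eggs.  Each W allele of the zygote is cleaved
   with probability *p_MC* and end-joins into ``R`` (probability *p_MR*)
   or ``B``.  Deposition is modelled as complete allele conversion, so
   partial somatic mosaics are not a genotype-level outcome here.

All probability rules are exposed both as readable per-genotype functions
and as vectorised kernels (gamete matrix, offspring tensor) used by the
simulators and the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum, IntEnum
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "Allele",
    "Sex",
    "Genotype",
    "GENOTYPES",
    "GENOTYPE_INDEX",
    "N_GENOTYPES",
    "GFP_MASK",
    "WHITE_INDEX",
    "H_CARRIER_MASK",
    "DriveParams",
    "GameteDistribution",
    "Phenotype",
    "gamete_distribution",
    "gamete_matrix",
    "deposition_matrix",
    "offspring_tensor",
    "offspring_distribution",
    "phenotype_of",
    "female_load",
    "load_vector",
    "allele_frequencies",
]


class Allele(IntEnum):
    """The four alleles at the drive locus."""

    W = 0  # wild type, the only cleavable allele
    H = 1  # drive (rescue) allele, GFP-marked
    R = 2  # functional (in-frame) resistant allele
    B = 3  # nonfunctional resistant allele


class Sex(Enum):
    F = "F"
    M = "M"


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered diploid genotype; ``Genotype(H, W) == Genotype(W, H)``."""

    a: Allele
    b: Allele

    def __post_init__(self) -> None:
        lo, hi = sorted((Allele(self.a), Allele(self.b)))
        object.__setattr__(self, "a", lo)
        object.__setattr__(self, "b", hi)

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        if len(s) != 2:
            raise ValueError(f"genotype string must have two letters, got {s!r}")
        return cls(Allele[s[0]], Allele[s[1]])

    @property
    def alleles(self) -> Tuple[Allele, Allele]:
        return (self.a, self.b)

    @property
    def index(self) -> int:
        return GENOTYPE_INDEX[self]

    def count(self, allele: Allele) -> int:
        return int(self.a == allele) + int(self.b == allele)

    def __contains__(self, allele: Allele) -> bool:
        return allele in (self.a, self.b)

    def __str__(self) -> str:
        return self.a.name + self.b.name

    def __iter__(self) -> Iterator[Allele]:
        return iter((self.a, self.b))


#: Canonical ordering of the 10 unordered diploid genotypes:
#: WW, WH, WR, WB, HH, HR, HB, RR, RB, BB
GENOTYPES: Tuple[Genotype, ...] = tuple(
    Genotype(Allele(i), Allele(j)) for i in range(4) for j in range(i, 4)
)
GENOTYPE_INDEX: Dict[Genotype, int] = {g: k for k, g in enumerate(GENOTYPES)}
N_GENOTYPES = len(GENOTYPES)

# fold an ordered allele pair (4x4) onto the unordered genotype index
_FOLD = np.empty((4, 4), dtype=np.intp)
for _i in range(4):
    for _j in range(4):
        _FOLD[_i, _j] = GENOTYPE_INDEX[Genotype(Allele(_i), Allele(_j))]

#: genotype carries >=1 H allele (GFP-positive marker)
GFP_MASK = np.array([Allele.H in g for g in GENOTYPES])
H_CARRIER_MASK = GFP_MASK  # alias used by the deposition rule (mothers)
#: index of the unique white-eyed genotype (B/B)
WHITE_INDEX = GENOTYPE_INDEX[Genotype(Allele.B, Allele.B)]

_PROB_FIELDS = (
    "c",
    "p_hdr_f",
    "p_hdr_m",
    "p_res",
    "p_mc",
    "p_mr",
    "s_h1",
    "s_h2",
    "s_bb",
)


@dataclass(frozen=True)
class DriveParams:
    """All probabilities and loads of the drive model (each in [0, 1]).

    Parameters
    ----------
    c : germline cleavage probability of a W allele in H/W adults.
    p_hdr_f, p_hdr_m : probability that a cleaved germline W is converted
        to H by accurate HDR, in females / males.
    p_res : probability that a non-HDR (end-joined) germline allele is
        functional (R); otherwise it is nonfunctional (B).
    p_mc : probability that a W allele in an embryo of an H-carrying
        mother is cleaved by deposited Cas9/gRNA complexes.
    p_mr : probability that a deposition-cleaved allele becomes R (else
        B).  ``None`` ties it to ``p_res``, the identifiability choice
        used in the cage fit.
    s_h1, s_h2 : female reproductive load with one / two H copies.
    s_bb : female reproductive load of the B/B genotype.
    """

    c: float = 1.0
    p_hdr_f: float = 1.0
    p_hdr_m: float = 1.0
    p_res: float = 0.0
    p_mc: float = 0.0
    p_mr: float | None = None
    s_h1: float = 0.0
    s_h2: float = 0.0
    s_bb: float = 0.0

    def __post_init__(self) -> None:
        if self.p_mr is None:
            object.__setattr__(self, "p_mr", self.p_res)
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"DriveParams.{name} must be in [0, 1], got {v!r}")

    def p_hdr(self, sex: Sex) -> float:
        return self.p_hdr_f if sex is Sex.F else self.p_hdr_m

    def replace(self, **kwargs) -> "DriveParams":
        # retying p_mr to p_res must be explicit, not implicit
        return replace(self, **kwargs)

    def to_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def cage_fit(cls) -> "DriveParams":
        """Point estimates from the nine-cage trial fit.

        Germline cleavage is complete with 99.5% HDR in both sexes;
        deposition cleaves 93.7% of embryonic W alleles; 17% of
        end-joined alleles are functional (p_mr tied); B/B females carry
        a 99.8% reproductive load; the drive itself is load-free.
        """
        return cls(
            c=1.0,
            p_hdr_f=0.995,
            p_hdr_m=0.995,
            p_res=0.17,
            p_mc=0.937,
            p_mr=0.17,
            s_h1=0.0,
            s_h2=0.0,
            s_bb=0.998,
        )


@dataclass(frozen=True)
class GameteDistribution(Mapping):
    """Probability distribution over the four gamete alleles."""

    probs: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"gamete probabilities must be >=0 and sum to 1, got {p}")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    def __getitem__(self, allele: Allele) -> float:
        return self.probs[Allele(allele)]

    def __iter__(self) -> Iterator[Allele]:
        return iter(Allele)

    def __len__(self) -> int:
        return 4

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass(frozen=True)
class Phenotype:
    """Observable phenotype: drive marker (GFP) and eye colour."""

    gfp: bool
    eye: str  # "black" | "white"


_HW_INDEX = GENOTYPE_INDEX[Genotype(Allele.W, Allele.H)]


def _gamete_row(g: Genotype, sex: Sex, p: DriveParams) -> np.ndarray:
    out = np.zeros(4)
    if g.index == _HW_INDEX:
        hdr = p.p_hdr(sex)
        out[Allele.H] = 0.5 + 0.5 * p.c * hdr
        out[Allele.W] = 0.5 * (1.0 - p.c)
        out[Allele.R] = 0.5 * p.c * (1.0 - hdr) * p.p_res
        out[Allele.B] = 0.5 * p.c * (1.0 - hdr) * (1.0 - p.p_res)
    else:
        # homing requires both an H allele and a cleavable W target;
        # HH, HR, HB and all non-drive genotypes segregate Mendelianly
        out[g.a] += 0.5
        out[g.b] += 0.5
    return out


def gamete_distribution(g: Genotype, sex: Sex, p: DriveParams) -> GameteDistribution:
    """Gamete allele distribution of an adult, including germline homing."""
    return GameteDistribution(tuple(_gamete_row(g, sex, p)))


def gamete_matrix(p: DriveParams, sex: Sex) -> np.ndarray:
    """(10, 4) array of gamete distributions for every genotype."""
    return np.stack([_gamete_row(g, sex, p) for g in GENOTYPES])


def deposition_matrix(p: DriveParams, mode: str = "per_allele") -> np.ndarray:
    """(10, 10) zygote-genotype transition matrix for maternal deposition.

    Applied only to offspring of H-carrying mothers.  ``per_allele``
    cleaves each W allele of the zygote independently with probability
    ``p_mc``; ``per_embryo`` cleaves either every W allele of the embryo
    (probability ``p_mc``) or none.  The two coincide except for W/W
    zygotes, which the paper's rules leave ambiguous.
    """
    if mode not in ("per_allele", "per_embryo"):
        raise ValueError(f"unknown deposition mode {mode!r}")
    pmc, pmr = p.p_mc, p.p_mr
    cleaved = [(Allele.R, pmr), (Allele.B, 1.0 - pmr)]
    dep = np.zeros((N_GENOTYPES, N_GENOTYPES))
    for z, g in enumerate(GENOTYPES):
        if Allele.W not in g:
            dep[z, z] = 1.0
            continue
        if mode == "per_allele":
            def outcomes(x: Allele):
                if x is not Allele.W:
                    return [(x, 1.0)]
                return [(Allele.W, 1.0 - pmc)] + [(a, pmc * q) for a, q in cleaved]

            for xa, pa in outcomes(g.a):
                for xb, pb in outcomes(g.b):
                    dep[z, _FOLD[xa, xb]] += pa * pb
        else:  # per_embryo: all-or-none cleavage of the embryo's W alleles
            dep[z, z] += 1.0 - pmc

            def repaired(x: Allele):
                return [(x, 1.0)] if x is not Allele.W else cleaved

            for xa, pa in repaired(g.a):
                for xb, pb in repaired(g.b):
                    dep[z, _FOLD[xa, xb]] += pmc * pa * pb
    return dep


def offspring_tensor(p: DriveParams, deposition_mode: str = "per_allele") -> np.ndarray:
    """(10, 10, 10) tensor ``O[m, f, g]``: probability that a (mother
    genotype m) x (father genotype f) cross produces offspring genotype g,
    including germline homing and maternal deposition."""
    g_f = gamete_matrix(p, Sex.F)
    g_m = gamete_matrix(p, Sex.M)
    # ordered zygote allele pairs, folded onto unordered genotypes
    zygote = np.einsum("ma,fb->mfab", g_f, g_m).reshape(N_GENOTYPES, N_GENOTYPES, 16)
    fold = np.zeros((16, N_GENOTYPES))
    fold[np.arange(16), _FOLD.ravel()] = 1.0
    off = zygote @ fold
    dep = deposition_matrix(p, deposition_mode)
    off[H_CARRIER_MASK] = off[H_CARRIER_MASK] @ dep
    return off


def offspring_distribution(
    mother: Genotype,
    father: Genotype,
    p: DriveParams,
    deposition_mode: str = "per_allele",
) -> Dict[Genotype, float]:
    """Offspring genotype distribution of a single cross.

    Deposition applies iff the mother carries H; probabilities sum to 1.
    """
    row = offspring_tensor(p, deposition_mode)[mother.index, father.index]
    return {g: float(row[k]) for k, g in enumerate(GENOTYPES) if row[k] > 0.0}


def phenotype_of(g: Genotype) -> Phenotype:
    """GFP iff the genotype carries the drive; white eyes iff B/B."""
    return Phenotype(gfp=Allele.H in g, eye="white" if g.index == WHITE_INDEX else "black")


def female_load(g: Genotype, p: DriveParams) -> float:
    """Fractional reduction of a female's reproductive contribution."""
    n_h = g.count(Allele.H)
    if n_h == 2:
        return p.s_h2
    if n_h == 1:
        return p.s_h1
    if g.index == WHITE_INDEX:
        return p.s_bb
    return 0.0


def load_vector(p: DriveParams) -> np.ndarray:
    """(10,) female loads in canonical genotype order."""
    return np.array([female_load(g, p) for g in GENOTYPES])


def allele_frequencies(genotype_freq: np.ndarray) -> np.ndarray:
    """(…, 10) genotype frequencies -> (…, 4) allele frequencies."""
    freq = np.asarray(genotype_freq, dtype=float)
    out = np.zeros(freq.shape[:-1] + (4,))
    for k, g in enumerate(GENOTYPES):
        out[..., g.a] += 0.5 * freq[..., k]
        out[..., g.b] += 0.5 * freq[..., k]
    return out
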