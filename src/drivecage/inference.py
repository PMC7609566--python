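"""Multinomial-likelihood MCMC estimation of drive parameters from cage counts.

The likelihood compares per-generation scored phenotype counts, merged
into three observable categories (GFP+, GFP-/black, GFP-/white), with
the category probabilities predicted by the deterministic recursion for
each cage's seeding.  Posterior sampling uses an affine-invariant
ensemble (emcee) on the logit scale with uniform(0, 1) priors on every
estimated probability or load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .deterministic import SeedingConfig, seeding_state
from .genetics import GFP_MASK, WHITE_INDEX, DriveParams, load_vector, offspring_tensor

__all__ = [
    "PhenotypeCounts",
    "CageDataset",
    "FitSpec",
    "MCMCResult",
    "PosteriorSummary",
    "map_to_observable",
    "observable_counts",
    "log_likelihood",
    "run_mcmc",
    "summarize_posterior",
]

#: probability floor applied before renormalising predicted categories
_EPS = 1e-9

#: parameters that may be estimated (uniform(0, 1) priors)
ESTIMABLE = ("c", "p_hdr_f", "p_hdr_m", "p_res", "p_mc", "p_mr", "s_h1", "s_h2", "s_bb")


@dataclass(frozen=True)
class PhenotypeCounts:
    """Scored phenotype counts of one generation of one cage."""

    generation: int
    gfp_black: int
    gfp_white: int
    nogfp_black: int
    nogfp_white: int
    nogfp_mosaic: int
    total: int

    def __post_init__(self) -> None:
        cats = (
            self.gfp_black,
            self.gfp_white,
            self.nogfp_black,
            self.nogfp_white,
            self.nogfp_mosaic,
        )
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if any(c < 0 for c in cats):
            raise ValueError("counts must be non-negative")
        if sum(cats) != self.total:
            raise ValueError(
                f"generation {self.generation}: categories sum to {sum(cats)},"
                f" expected total {self.total}"
            )


@dataclass(frozen=True)
class CageDataset:
    """Phenotype time series of one cage with its seeding metadata."""

    cage_id: str
    ratio: str
    counts: Tuple[PhenotypeCounts, ...]
    census: int = 200
    crashed: bool = False

    def __post_init__(self) -> None:
        counts = tuple(self.counts)
        gens = [c.generation for c in counts]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")
        object.__setattr__(self, "counts", counts)

    def seeding(self) -> SeedingConfig:
        return seeding_state(self.ratio, self.census)

    @property
    def generations(self) -> List[int]:
        return [c.generation for c in self.counts]


@dataclass(frozen=True)
class FitSpec:
    """What to estimate, what to hold fixed, and how to sample.

    ``base`` supplies the fixed parameter values (germline cleavage and
    the sex-specific HDR probabilities are fixed by default, as they are
    pinned by single-generation crosses).  ``estimate`` names the
    parameters given uniform(0, 1) priors.  With ``tie_p_mr`` the
    deposition repair split follows ``p_res`` (the identifiability choice
    of the cage fit).  ``overdispersion`` > 1 scales the multinomial
    log-likelihood down by that factor (quasi-likelihood); the default 1
    is the plain multinomial.
    """

    estimate: Tuple[str, ...] = ("s_h1", "s_h2", "s_bb", "p_res", "p_mc")
    base: DriveParams = field(
        default_factory=lambda: DriveParams(c=1.0, p_hdr_f=0.995, p_hdr_m=0.995)
    )
    tie_p_mr: bool = True
    nwalkers: int = 32
    nsteps: int = 3000
    burn: Optional[int] = None
    thin: int = 1
    seed: int = 0
    deposition_mode: str = "per_allele"
    overdispersion: float = 1.0

    def __post_init__(self) -> None:
        bad = [n for n in self.estimate if n not in ESTIMABLE]
        if bad:
            raise ValueError(f"cannot estimate unknown parameters {bad}")
        if len(set(self.estimate)) != len(self.estimate):
            raise ValueError("estimated parameter names must be unique")
        if self.tie_p_mr and "p_mr" in self.estimate:
            raise ValueError("p_mr cannot be both tied to p_res and estimated")
        if self.nwalkers < 2 * max(1, len(self.estimate)) or self.nwalkers % 2:
            raise ValueError("nwalkers must be even and at least twice the dimension")
        if self.nsteps < 1 or self.thin < 1:
            raise ValueError("nsteps and thin must be positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")

    @property
    def burn_in(self) -> int:
        return self.nsteps // 2 if self.burn is None else self.burn

    def params_from(self, values: Sequence[float]) -> DriveParams:
        """DriveParams with estimated entries replaced by ``values``."""
        d = self.base.to_dict()
        for name, v in zip(self.estimate, values):
            d[name] = float(v)
        if self.tie_p_mr:
            d["p_mr"] = d["p_res"]
        return DriveParams(**d)


def map_to_observable(freq: np.ndarray) -> np.ndarray:
    """Model genotype frequencies -> (GFP+, GFP-/black, GFP-/white) probabilities.

    Probabilities are floored at 1e-9 and renormalised so that a finite
    log-likelihood exists for categories the deterministic model puts at
    exactly zero.
    """
    freq = np.asarray(freq, dtype=float)
    gfp = freq[..., GFP_MASK].sum(axis=-1)
    white = freq[..., WHITE_INDEX]
    probs = np.stack([gfp, 1.0 - gfp - white, white], axis=-1)
    probs = np.clip(probs, _EPS, None)
    return probs / probs.sum(axis=-1, keepdims=True)


def observable_counts(c: PhenotypeCounts) -> np.ndarray:
    """Observed 5-category counts -> the model's 3 observable categories.

    GFP-/mosaic individuals carry deposition-cleaved tissue and are
    merged into GFP-/white; the rare GFP+/white class is merged into
    GFP+ (the drive marker dominates the call).
    """
    return np.array(
        [
            c.gfp_black + c.gfp_white,
            c.nogfp_black,
            c.nogfp_white + c.nogfp_mosaic,
        ],
        dtype=float,
    )


def _predicted_category_probs(
    seed_freq: np.ndarray, p: DriveParams, generations: int, tensor: np.ndarray
) -> np.ndarray:
    """(G+1, 3) observable probabilities along the deterministic recursion.

    Lean float-only twin of the public recursion in
    :mod:`drivecage.deterministic` (equality is enforced by tests).
    """
    loads = 1.0 - load_vector(p)
    f_f = seed_freq[0].astype(float)
    f_m = seed_freq[1].astype(float)
    out = np.empty((generations + 1, 3))
    out[0] = map_to_observable(0.5 * (f_f + f_m))
    for gen in range(1, generations + 1):
        w = f_f * loads
        total = w.sum()
        if total <= 0.0:
            out[gen:] = np.nan
            return out
        off = np.einsum("m,f,mfg->g", w / total, f_m, tensor)
        off /= off.sum()
        f_f = off
        f_m = off
        out[gen] = map_to_observable(off)
    return out


class _LikelihoodData:
    """Preprocessed observation arrays shared across likelihood calls."""

    def __init__(self, datasets: Sequence[CageDataset], overdispersion: float = 1.0):
        self.groups: Dict[Tuple[str, int], Dict] = {}
        self.constant = 0.0
        for ds in datasets:
            if not ds.counts:
                continue
            key = (ds.ratio, ds.census)
            grp = self.groups.setdefault(
                key,
                {
                    "seed_freq": seeding_state(ds.ratio, ds.census).frequencies(),
                    "gens": [],
                    "counts": [],
                },
            )
            for c in ds.counts:
                obs = observable_counts(c)
                grp["gens"].append(c.generation)
                grp["counts"].append(obs)
                # multinomial coefficient, constant in the parameters
                self.constant += float(
                    gammaln(obs.sum() + 1.0) - gammaln(obs + 1.0).sum()
                )
        for grp in self.groups.values():
            grp["gens"] = np.asarray(grp["gens"], dtype=int)
            grp["counts"] = np.asarray(grp["counts"], dtype=float)
            grp["max_gen"] = int(grp["gens"].max())
        self.constant /= overdispersion
        self.overdispersion = overdispersion

    def log_likelihood(self, p: DriveParams, deposition_mode: str = "per_allele") -> float:
        if not self.groups:
            return 0.0
        tensor = offspring_tensor(p, deposition_mode)
        ll = 0.0
        for grp in self.groups.values():
            probs = _predicted_category_probs(grp["seed_freq"], p, grp["max_gen"], tensor)
            picked = probs[grp["gens"]]
            if not np.isfinite(picked).all():
                return -np.inf
            ll += float((grp["counts"] * np.log(picked)).sum())
        return ll / self.overdispersion + self.constant


def log_likelihood(
    p: DriveParams,
    data: Sequence[CageDataset],
    spec: Optional[FitSpec] = None,
) -> float:
    """Multinomial log-likelihood of cage datasets under the deterministic model.

    Sums over cages and generations; an empty dataset scores 0, and a
    reproductive collapse of the model trajectory scores ``-inf``.
    """
    mode = spec.deposition_mode if spec is not None else "per_allele"
    od = spec.overdispersion if spec is not None else 1.0
    return _LikelihoodData(data, od).log_likelihood(p, mode)


@dataclass
class MCMCResult:
    """Posterior samples (probability scale) and sampling diagnostics.

    ``chain`` has shape (nsteps, nwalkers, n_params) and includes
    burn-in; ``posterior()`` returns the flattened post-burn-in draws.
    """

    chain: np.ndarray
    param_names: Tuple[str, ...]
    spec: FitSpec
    acceptance_fraction: float
    log_prob: Optional[np.ndarray] = None

    def posterior(self, burn: Optional[int] = None, thin: Optional[int] = None) -> np.ndarray:
        burn = self.spec.burn_in if burn is None else burn
        thin = self.spec.thin if thin is None else thin
        return self.chain[burn::thin].reshape(-1, self.chain.shape[-1])

    def post_burn_chain(self, burn: Optional[int] = None) -> np.ndarray:
        burn = self.spec.burn_in if burn is None else burn
        return self.chain[burn :: self.spec.thin]


@dataclass
class PosteriorSummary:
    """Medians, means, central 95% credible intervals and diagnostics."""

    table: pd.DataFrame  # index: parameter; columns: median, mean, q2.5, q97.5, rhat, ess

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["q2.5"] > self.table["median"])
            | (self.table["median"] > self.table["q97.5"])
        ]
        if len(bad):
            raise ValueError(f"inconsistent quantiles for {list(bad.index)}")

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])

    def credible_interval(self, name: str) -> Tuple[float, float]:
        return (
            float(self.table.loc[name, "q2.5"]),
            float(self.table.loc[name, "q97.5"]),
        )

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.credible_interval(name)
        return lo <= value <= hi


def run_mcmc(data: Sequence[CageDataset], spec: FitSpec) -> MCMCResult:
    """Sample the posterior of the estimated parameters.

    Uniform(0, 1) priors; sampling on the logit scale (with the Jacobian
    correction) using emcee's stretch move.  Fully seeded: two runs with
    the same spec and data give identical chains.
    """
    import emcee

    if not data:
        raise ValueError("cannot fit an empty collection of cage datasets")
    ndim = len(spec.estimate)
    like = _LikelihoodData(data, spec.overdispersion)
    mode = spec.deposition_mode

    if ndim == 0:
        # degenerate fit: every parameter fixed, nothing to sample
        ll = like.log_likelihood(spec.base, mode)
        return MCMCResult(
            chain=np.zeros((1, 1, 0)),
            param_names=(),
            spec=spec,
            acceptance_fraction=1.0,
            log_prob=np.array([[ll]]),
        )

    def log_post(theta: np.ndarray) -> float:
        p_vec = expit(theta)
        try:
            params = spec.params_from(p_vec)
        except ValueError:
            return -np.inf
        ll = like.log_likelihood(params, mode)
        if not np.isfinite(ll):
            return -np.inf
        # Jacobian of the logit transform => uniform(0, 1) prior on p;
        # -inf at the boundary (p of exactly 0 or 1) rejects the proposal
        with np.errstate(divide="ignore"):
            return ll + float(np.sum(np.log(p_vec) + np.log1p(-p_vec)))

    rng = np.random.default_rng(spec.seed)
    p0 = logit(rng.uniform(0.05, 0.95, size=(spec.nwalkers, ndim)))
    sampler = emcee.EnsembleSampler(spec.nwalkers, ndim, log_post)
    sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
    sampler.run_mcmc(p0, spec.nsteps, progress=False)
    chain = expit(sampler.get_chain())  # (nsteps, nwalkers, ndim)
    return MCMCResult(
        chain=chain,
        param_names=tuple(spec.estimate),
        spec=spec,
        acceptance_fraction=float(sampler.acceptance_fraction.mean()),
        log_prob=sampler.get_log_prob(),
    )


def summarize_posterior(
    chains: "MCMCResult | np.ndarray",
    param_names: Optional[Sequence[str]] = None,
    burn: int = 0,
) -> PosteriorSummary:
    """Posterior medians and central 95% credible intervals per parameter.

    Accepts an :class:`MCMCResult` (burn-in taken from its spec) or a raw
    (draws, nwalkers, n_params) / (draws, n_params) array already past
    burn-in.  Requires at least 100 post-burn-in draws.
    """
    import arviz as az

    if isinstance(chains, MCMCResult):
        if param_names is None:
            param_names = chains.param_names
        arr = chains.post_burn_chain()
    else:
        arr = np.asarray(chains, dtype=float)[burn:]
    if arr.ndim == 2:
        arr = arr[:, None, :]
    if arr.ndim != 3:
        raise ValueError("chains must have shape (draws, nwalkers, n_params)")
    ndraws = arr.shape[0] * arr.shape[1]
    if ndraws < 100:
        raise ValueError(f"need >= 100 post-burn-in draws, got {ndraws}")
    if param_names is None:
        param_names = [f"p{i}" for i in range(arr.shape[-1])]
    rows = {}
    for i, name in enumerate(param_names):
        flat = arr[:, :, i].ravel()
        by_walker = arr[:, :, i].T  # (chains, draws) for split diagnostics
        spread = float(flat.max() - flat.min())
        if arr.shape[1] > 1 and spread > 0.0:
            rhat = float(az.rhat(by_walker))
            ess = float(az.ess(by_walker))
        else:  # single walker or degenerate chain: diagnostics undefined
            rhat = np.nan
            ess = float(flat.size) if spread == 0.0 else float(az.ess(flat[None, :]))
        rows[name] = {
            "median": float(np.median(flat)),
            "mean": float(flat.mean()),
            "q2.5": float(np.percentile(flat, 2.5)),
            "q97.5": float(np.percentile(flat, 97.5)),
            "rhat": rhat,
            "ess": ess,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return PosteriorSummary(table=table)
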