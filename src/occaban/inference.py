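"""Posterior sampling, convergence diagnostics and significance calls.

``fit`` runs the NUTS sampler on the selected model variant, returns a
labelled :class:`PosteriorDraws` container (chain x draw arrays per
parameter) with rank-normalized split R-hat attached for every sampled
quantity, and flags non-convergence (any R-hat >= 1.1) with a warning
rather than an exception.

Species-level significance follows the reporting rule of the analysis: a
species responds negatively if the upper bound of the equal-tailed 95%
credible interval of its coefficient is below zero, positively if the lower
bound is above zero, otherwise it is not significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .data_model import DesignInputs, HabitatMatrix, SurveyTable
from .model_core import OccurrenceModel, PriorConfig
from .nuts import sample_nuts

#: slope column order in the design matrix
SLOPE_NAMES = ["aban", "temp", "month", "dry", "built"]

RHAT_THRESHOLD = 1.1


@dataclass
class McmcSettings:
    """Sampler settings; defaults are the analysis' stated MCMC protocol
    (three chains, 1000 warmup + 1000 sampling iterations, no thinning)."""

    n_chains: int = 3
    n_warmup: int = 1000
    n_samples: int = 1000
    thinning: int = 1
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples, self.thinning) < 1:
            raise ValueError("chain/iteration counts must be >= 1")


@dataclass
class PosteriorDraws:
    """Labelled posterior samples with chain structure and diagnostics.

    ``draws[name]`` has shape (chain, iteration, *param_shape); ``rhat`` has
    one entry per scalar component of every sampled parameter.
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, np.ndarray]
    divergences: int
    settings: McmcSettings
    variant: str
    species: list[str] = field(default_factory=list)
    converged: bool = True
    loglik: np.ndarray | None = None  # (chain, iteration) untempered loglik
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        name = next(iter(self.draws))
        return self.draws[name].shape[0] * self.draws[name].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chain*iteration, *param_shape)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def max_rhat(self) -> float:
        vals = np.concatenate([np.ravel(v) for v in self.rhat.values()])
        finite = vals[np.isfinite(vals)]
        return float(finite.max()) if finite.size else float("nan")

    def to_arviz(self):
        """Posterior as an :class:`arviz.InferenceData` (lazy import)."""
        import arviz as az

        return az.from_dict(posterior=self.draws)


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    n_chain, n_draw = x.shape
    half = n_draw // 2
    return np.concatenate([x[:, :half], x[:, n_draw - half:]], axis=0)


def _rhat_base(x: np.ndarray) -> float:
    """Classic potential scale reduction on an already-split array."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average").reshape(x.shape)
    return ndtri((r - 3.0 / 8.0) / (x.size + 0.25))


def rhat(x: np.ndarray, method: str = "rank") -> float:
    """Split R-hat of one parameter's (chain, iteration) draws.

    ``method="split"`` is the classic split potential scale reduction;
    ``method="rank"`` (default) is the rank-normalized variant: the larger
    of the split R-hat of the rank-normal-transformed draws (bulk) and of
    the rank-normal-transformed folded draws (tail-sensitive).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs a (chain, iteration) array with >= 2 chains")
    if x.shape[1] < 4:
        raise ValueError("rhat needs at least 4 iterations per chain")
    if method == "split":
        return _rhat_base(_split_chains(x))
    if method != "rank":
        raise ValueError(f"unknown rhat method {method!r}")
    split = _split_chains(x)
    bulk = _rhat_base(_rank_normalize(split))
    folded = _rhat_base(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


def _all_rhats(draws: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, arr in draws.items():
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if arr.shape[0] < 2 or arr.shape[1] < 4:
            vals = np.full(flat.shape[2], np.nan)  # undiagnosable run shape
        else:
            vals = np.array(
                [rhat(flat[:, :, k]) for k in range(flat.shape[2])]
            )
        out[name] = vals.reshape(arr.shape[2:]) if arr.ndim > 2 else vals[0]
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit(
    variant: str,
    data: SurveyTable,
    design: DesignInputs,
    settings: McmcSettings | None = None,
    prior: PriorConfig | None = None,
    habitat: HabitatMatrix | None = None,
    habitat_type: str | None = None,
    temper: float = 1.0,
) -> PosteriorDraws:
    """Sample the posterior of one model variant with NUTS.

    Chains run sequentially with independent streams spawned from
    ``settings.seed``; reruns with the same seed and data are bit-identical.
    """
    settings = settings or McmcSettings()
    model = OccurrenceModel(
        variant,
        data.occupancy_matrix(),
        design,
        prior=prior,
        habitat=habitat,
        habitat_type=habitat_type,
        temper=temper,
    )
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    kept = settings.n_samples // settings.thinning
    z_chains = np.empty((settings.n_chains, kept, model.dim))
    divergences = 0
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        z0 = model.init_z(rng)
        draws, stats = sample_nuts(
            model.logp_and_grad,
            z0,
            settings.n_warmup,
            settings.n_samples,
            rng,
            target_accept=settings.target_accept,
            max_treedepth=settings.max_treedepth,
        )
        z_chains[c] = draws[settings.thinning - 1:: settings.thinning][:kept]
        divergences += stats.divergences

    out: dict[str, np.ndarray] = {}
    loglik = np.empty((settings.n_chains, kept))
    store = None
    for c in range(settings.n_chains):
        for d in range(kept):
            params = model.unpack(z_chains[c, d])
            params.pop("slope_means")
            if store is None:
                store = {
                    k: np.empty((settings.n_chains, kept) + np.shape(v))
                    for k, v in params.items()
                }
            for k, v in params.items():
                store[k][c, d] = v
            loglik[c, d] = model.loglik(z_chains[c, d])
    out = store or {}
    # drop structural mu entries (replaced by habitat-model alphas) so every
    # stored series is an actual sampled quantity
    if variant == "M2" or (
        variant == "M3" and model.prior.ridge_temperature
    ):
        out["mu"] = out["mu"][:, :, 2:]
    elif variant == "M3":
        out["mu"] = out["mu"][:, :, 1:]

    rhats = _all_rhats(out)
    result = PosteriorDraws(
        draws=out,
        rhat=rhats,
        divergences=divergences,
        settings=settings,
        variant=variant,
        species=data.species,
        loglik=loglik,
        meta={"temper": temper, "habitat_type": habitat_type},
    )
    mr = result.max_rhat()
    result.converged = not (np.isfinite(mr) and mr >= RHAT_THRESHOLD)
    if not result.converged:
        warnings.warn(
            f"MCMC may not have converged: max R-hat = {result.max_rhat():.3f}"
            f" >= {RHAT_THRESHOLD}",
            stacklevel=2,
        )
    return result


# ---------------------------------------------------------------------------
# Significance calls
# ---------------------------------------------------------------------------

def significant_species(
    draws: PosteriorDraws,
    parameter_family: str = "aban",
    level: float = 0.95,
) -> dict[str, str]:
    """Classify each species by its credible interval for one slope family.

    Returns ``{"species_id": "negative" | "positive" | "ns"}`` using
    equal-tailed quantile intervals at the given level.
    """
    if parameter_family not in SLOPE_NAMES:
        raise ValueError(
            f"unknown parameter family {parameter_family!r}; "
            f"expected one of {SLOPE_NAMES}"
        )
    col = SLOPE_NAMES.index(parameter_family)
    sl = draws.stacked("slopes")[:, :, col]  # (n_draws, n_species)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(sl, alpha, axis=0)
    hi = np.quantile(sl, 1.0 - alpha, axis=0)
    out = {}
    for i, sp in enumerate(draws.species):
        if hi[i] < 0:
            out[sp] = "negative"
        elif lo[i] > 0:
            out[sp] = "positive"
        else:
            out[sp] = "ns"
    return out
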