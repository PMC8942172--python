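"""Synthetic survey, habitat and range-stack generators with known truth.

The generators emulate the study design the models were built for: 18
climatic regions spanning mean annual temperatures of 4.5-15.7 degC, each
containing 2-5 settlements split between abandoned and inhabited, each
settlement holding 4-16 survey plots across three land-use types (paddy,
dry crop field, built-up), surveyed in a single month between May and
August, with ~49 butterfly species carrying binary habitat-preference
vectors over 11 habitat types.

Occupancy is drawn from the random-slope logistic model itself: species
slopes from a bivariate normal for (abandonment, temperature) plus
independent normals for the confounders, and nested normal random effects
at region, settlement and settlement x land-use level.  Covariates are
generated on the standardized scale on which the model is fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    HABITAT_TYPES,
    LAND_USES,
    HabitatMatrix,
    RangeStack,
    SurveyTable,
    build_design,
)


@dataclass
class DesignConfig:
    """Survey-design dimensions; defaults mirror the field design."""

    n_regions: int = 18
    settlements_per_region: tuple[int, int] = (2, 5)
    plots_per_settlement: tuple[int, int] = (4, 16)
    mat_range: tuple[float, float] = (4.5, 15.7)
    mat_jitter: float = 0.0
    month_range: tuple[int, int] = (5, 8)
    n_species: int = 49
    abandoned_fraction: float = 34 / 64
    years_range: tuple[int, int] = (8, 53)

    def __post_init__(self) -> None:
        if self.mat_range[0] >= self.mat_range[1]:
            raise ValueError("mat_range must be non-degenerate")
        if not 0.0 <= self.abandoned_fraction <= 1.0:
            raise ValueError("abandoned_fraction must be in [0, 1]")
        if self.n_regions < 1 or self.n_species < 1:
            raise ValueError("n_regions and n_species must be >= 1")


@dataclass
class GenerativeHyper:
    """Population-level truth for the generator (free defaults, documented).

    ``mu_beta`` are the slope means on the standardized covariate scale in
    (aban, temp, month, dry, built) order; ``rho`` is the correlation of the
    abandonment and temperature slopes across species.
    """

    mu_beta: tuple = (-0.5, 0.5, 0.0, 0.0, 0.0)
    sigma_beta: tuple = (1.0, 1.0, 0.3, 0.3, 0.3)
    rho: float = 0.4
    sigma_groups: tuple = (0.5, 0.5, 0.5)
    beta0_mean: float = -2.0
    beta0_sd: float = 1.0
    # optional habitat-structured slope means (used to generate M2/M3 data):
    # mu_b1i = alpha0 + H_i @ alpha_vec, mu_b2i = alphaT0 + H_i @ alphaT_vec
    alpha0: float | None = None
    alpha_vec: tuple | None = None
    alphaT0: float | None = None
    alphaT_vec: tuple | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")
        if any(s < 0 for s in self.sigma_beta) or any(
            s < 0 for s in self.sigma_groups
        ):
            raise ValueError("SDs must be non-negative")


@dataclass
class SyntheticTruth:
    """Everything the generator drew, for parameter-recovery checks."""

    hyper: GenerativeHyper
    beta0: np.ndarray
    slopes: np.ndarray  # n_species x 5
    habitat: HabitatMatrix | None = None
    species: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = asdict(self.hyper)
        out["beta0"] = self.beta0.tolist()
        out["slopes"] = self.slopes.tolist()
        out["species"] = list(self.species)
        return out


def _species_names(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(n)]


def generate_habitats(
    n_species: int,
    seed: int,
    mean_types: float = 2.5,
    red_list_fraction: float = 0.2,
) -> HabitatMatrix:
    """Random binary habitat-preference matrix; every species uses >= 1 type.

    Each species draws a number of habitat types around ``mean_types``
    (species often use several types) and then a random subset of the 11.
    """
    rng = np.random.default_rng(seed)
    names = _species_names(n_species)
    H = np.zeros((n_species, 11), dtype=int)
    for i in range(n_species):
        k = 1 + rng.poisson(max(mean_types - 1.0, 0.0))
        k = min(k, 11)
        cols = rng.choice(11, size=k, replace=False)
        H[i, cols] = 1
    red = (rng.uniform(size=n_species) < red_list_fraction).astype(int)
    return HabitatMatrix(
        H=pd.DataFrame(H, index=names, columns=HABITAT_TYPES),
        red_list=pd.Series(red, index=names),
    )


def generate_truth(
    config: DesignConfig,
    hyper: GenerativeHyper | None = None,
    seed: int = 0,
    habitat: HabitatMatrix | None = None,
) -> SyntheticTruth:
    """Draw species-level intercepts and slopes from the generative model.

    The abandonment and temperature slopes are drawn jointly from the
    bivariate normal with correlation ``rho``; confounder slopes are
    independent normals.  If ``hyper`` carries habitat-model alphas and a
    habitat matrix is supplied, the slope means are habitat-structured
    instead of shared.
    """
    hyper = hyper or GenerativeHyper()
    rng = np.random.default_rng(seed)
    n = config.n_species
    mu = np.asarray(hyper.mu_beta, dtype=float)
    sd = np.asarray(hyper.sigma_beta, dtype=float)
    rho = hyper.rho

    if hyper.alpha0 is not None:
        if habitat is None:
            raise ValueError("habitat-structured truth requires a habitat matrix")
        Hm = habitat.matrix()[:n]
        m1 = hyper.alpha0 + Hm @ np.asarray(hyper.alpha_vec, dtype=float)
        if hyper.alphaT0 is not None:
            m2 = hyper.alphaT0 + Hm @ np.asarray(hyper.alphaT_vec, dtype=float)
        else:
            m2 = np.full(n, mu[1])
    else:
        m1 = np.full(n, mu[0])
        m2 = np.full(n, mu[1])

    z = rng.standard_normal((n, 2))
    rt = np.sqrt(1.0 - rho**2)
    slopes = np.empty((n, 5))
    slopes[:, 0] = m1 + sd[0] * z[:, 0]
    slopes[:, 1] = m2 + sd[1] * (rho * z[:, 0] + rt * z[:, 1])
    for k in range(2, 5):
        slopes[:, k] = mu[k] + sd[k] * rng.standard_normal(n)
    beta0 = hyper.beta0_mean + hyper.beta0_sd * rng.standard_normal(n)
    return SyntheticTruth(
        hyper=hyper,
        beta0=beta0,
        slopes=slopes,
        habitat=habitat,
        species=_species_names(n),
    )


def generate_survey(
    config: DesignConfig,
    truth: SyntheticTruth,
    seed: int = 0,
    effect_scale: str = "binary",
) -> SurveyTable:
    """Simulate a nested survey and Bernoulli occupancy from the truth.

    ``effect_scale`` chooses which abandonment covariate multiplies the
    abandonment slope in the generating linear predictor: ``"binary"`` (a
    step effect of abandonment) or ``"years"`` (effect linear in
    standardized years since abandonment).
    """
    if truth.slopes.shape[0] != config.n_species:
        raise ValueError("truth species count does not match config")
    if effect_scale not in ("binary", "years"):
        raise ValueError(f"unknown effect_scale {effect_scale!r}")
    rng = np.random.default_rng(seed)
    lo, hi = config.mat_range
    region_mat = np.linspace(lo, hi, config.n_regions)

    rows = []
    for r in range(config.n_regions):
        region = f"R{r:02d}"
        n_set = int(
            rng.integers(
                config.settlements_per_region[0],
                config.settlements_per_region[1] + 1,
            )
        )
        # both settlement types in every region when possible
        n_aban = int(round(config.abandoned_fraction * n_set))
        if n_set >= 2:
            n_aban = min(max(n_aban, 1), n_set - 1)
        aban_flags = np.zeros(n_set, dtype=int)
        aban_flags[:n_aban] = 1
        rng.shuffle(aban_flags)
        for s in range(n_set):
            settlement = f"{region}S{s:02d}"
            abandoned = int(aban_flags[s])
            years = (
                int(rng.integers(config.years_range[0], config.years_range[1] + 1))
                if abandoned
                else 0
            )
            month = int(
                rng.integers(config.month_range[0], config.month_range[1] + 1)
            )
            mat = region_mat[r] + (
                config.mat_jitter * rng.standard_normal()
                if config.mat_jitter > 0
                else 0.0
            )
            n_plot = int(
                rng.integers(
                    config.plots_per_settlement[0],
                    config.plots_per_settlement[1] + 1,
                )
            )
            for q in range(n_plot):
                rows.append(
                    {
                        "plot_id": f"{settlement}P{q:02d}",
                        "region_id": region,
                        "settlement_id": settlement,
                        "land_use": LAND_USES[int(rng.integers(0, 3))],
                        "abandoned": abandoned,
                        "years_since_abandonment": years,
                        "mat": float(mat),
                        "month": month,
                    }
                )
    plots = pd.DataFrame(rows)

    # linear predictor on the standardized covariate scale
    placeholder = pd.DataFrame(
        0, index=truth.species, columns=plots["plot_id"]
    )
    table = SurveyTable(plots=plots, occupancy=placeholder)
    design = build_design(table, aban_coding=effect_scale, standardize=True)

    sg = np.asarray(truth.hyper.sigma_groups, dtype=float)
    eps_reg = sg[0] * rng.standard_normal(design.n_regions)
    eps_set = sg[1] * rng.standard_normal(design.n_settlements)
    eps_lu = sg[2] * rng.standard_normal(design.n_lu_groups)
    eps = (
        eps_reg[design.region_idx]
        + eps_set[design.settlement_idx]
        + eps_lu[design.lu_group_idx]
    )
    eta = truth.beta0[:, None] + truth.slopes @ design.x.T + eps[None, :]
    p = expit(eta)
    y = (rng.uniform(size=p.shape) < p).astype(int)
    occupancy = pd.DataFrame(y, index=truth.species, columns=plots["plot_id"])
    return SurveyTable(plots=plots, occupancy=occupancy)


def generate_range_stack(
    n_cells: int,
    habitat: HabitatMatrix,
    seed: int = 0,
    prevalence: float | np.ndarray = 0.5,
) -> RangeStack:
    """Independent Bernoulli presence per (cell, species) at given prevalence.

    A stand-in for model-projected range maps; stores optional per-cell
    coordinates on a unit grid.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    species = habitat.species
    prev = np.broadcast_to(
        np.asarray(prevalence, dtype=float), (len(species),)
    )
    if ((prev < 0) | (prev > 1)).any():
        raise ValueError("prevalence must be in [0, 1]")
    pres = (rng.uniform(size=(n_cells, len(species))) < prev[None, :]).astype(int)
    cells = [f"c{i:05d}" for i in range(n_cells)]
    side = int(np.ceil(np.sqrt(n_cells)))
    coords = pd.DataFrame(
        {
            "lon": [i % side for i in range(n_cells)],
            "lat": [i // side for i in range(n_cells)],
            "elevation": rng.uniform(0, 1500, size=n_cells),
        },
        index=cells,
    )
    return RangeStack(
        presence=pd.DataFrame(pres, index=cells, columns=species),
        coords=coords,
    )
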