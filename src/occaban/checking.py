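"""Posterior predictive checking with five community-level summary statistics.

The statistics are (1) the proportion of presence records over the whole
dataset, (2) the same proportion restricted to abandoned settlements,
(3) restricted to inhabited settlements, (4) the Gini coefficient of
per-settlement presence proportions and (5) the Gini coefficient of
per-species presence proportions.  For each posterior draw a replicate
occupancy matrix is simulated from the fitted model and the statistics are
recomputed; the posterior predictive p-value of a statistic T is the
upper-tail frequency P(T_rep > T_obs) with half weight on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import DesignInputs, SurveyTable
from .inference import PosteriorDraws

STATISTIC_NAMES = [
    "prop_presence",
    "prop_presence_abandoned",
    "prop_presence_inhabited",
    "gini_settlements",
    "gini_species",
]


@dataclass
class PpcReport:
    statistic_name: str
    observed: float
    replicate_values: np.ndarray
    p_value: float
    significant: bool  # p outside (0.025, 0.975), two-sided convention


def gini(values) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 xbar) of a
    non-negative vector; 0 for a constant (or all-zero) vector.

    Computed via the sorted O(n log n) identity
    G = (2 * sum_i i*x_(i) / (n * sum x)) - (n + 1) / n.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("gini needs a non-empty 1-d vector")
    if (x < 0).any():
        raise ValueError("gini is defined for non-negative values")
    total = x.sum()
    if total == 0.0:
        return 0.0
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * (i @ xs) / (n * total) - (n + 1.0) / n)


def _stats_from_matrix(
    y: np.ndarray, plots, settlement_codes: np.ndarray, n_set: int,
    weight_by_plots: bool = False,
) -> dict[str, float]:
    n_s, n_p = y.shape
    aban = plots["abandoned"].to_numpy() == 1
    out: dict[str, float] = {}
    out["prop_presence"] = float(y.mean())
    out["prop_presence_abandoned"] = (
        float(y[:, aban].mean()) if aban.any() else np.nan
    )
    out["prop_presence_inhabited"] = (
        float(y[:, ~aban].mean()) if (~aban).any() else np.nan
    )
    pres_per_plot = y.sum(axis=0)
    counts = np.bincount(settlement_codes, minlength=n_set)
    pres_set = np.bincount(
        settlement_codes, weights=pres_per_plot, minlength=n_set
    )
    props = pres_set / (counts * n_s)
    if weight_by_plots:
        props = np.repeat(props, counts)
    out["gini_settlements"] = gini(props)
    out["gini_species"] = gini(y.mean(axis=1))
    return out


def summary_statistics(
    table: SurveyTable, weight_by_plots: bool = False
) -> dict[str, float]:
    """The five observed community summary statistics of a survey table.

    Settlement proportions are unweighted by plot count by default (each
    settlement's proportion is presences / (species x its plots));
    ``weight_by_plots=True`` weights each settlement's proportion by its
    plot count in the settlement Gini.  If the table has no abandoned (or no
    inhabited) plots the corresponding statistic is NaN.
    """
    codes, n_set = _settlement_codes(table)
    return _stats_from_matrix(
        table.occupancy_matrix(), table.plots, codes, n_set,
        weight_by_plots=weight_by_plots,
    )


def _settlement_codes(table: SurveyTable):
    import pandas as pd

    vals = table.plots["settlement_id"]
    cats = pd.Categorical(vals, categories=sorted(vals.unique()))
    return cats.codes.astype(int), len(cats.categories)


def posterior_predictive_pvalues(
    fit: PosteriorDraws,
    data: SurveyTable,
    design: DesignInputs,
    seed: int = 0,
    max_draws: int | None = None,
    redraw_group_effects: bool = False,
) -> dict[str, PpcReport]:
    """Posterior predictive p-values of the five summary statistics.

    By default replicates condition on the fitted group effects (each draw's
    eps values are kept, not re-drawn), so the check targets the
    observation model given the estimated spatial structure;
    ``redraw_group_effects=True`` re-draws them from N(0, sigma^2) per draw,
    giving a mixed predictive check.  ``max_draws`` subsamples posterior
    draws evenly for speed.
    """
    rng = np.random.default_rng(seed)
    beta0 = fit.stacked("beta0")
    slopes = fit.stacked("slopes")
    eps_reg = fit.stacked("eps_reg")
    eps_set = fit.stacked("eps_set")
    eps_lu = fit.stacked("eps_lu")
    n_total = beta0.shape[0]
    idx = np.arange(n_total)
    if max_draws is not None and max_draws < n_total:
        idx = np.linspace(0, n_total - 1, max_draws).round().astype(int)

    codes, n_set = _settlement_codes(data)
    observed = _stats_from_matrix(
        data.occupancy_matrix(), data.plots, codes, n_set
    )
    x = design.x
    sigma_groups = (
        fit.stacked("sigma_groups") if redraw_group_effects else None
    )
    reps = {name: [] for name in STATISTIC_NAMES}
    for d in idx:
        if redraw_group_effects:
            sg = sigma_groups[d]
            eps = (
                (sg[0] * rng.standard_normal(design.n_regions))[
                    design.region_idx]
                + (sg[1] * rng.standard_normal(design.n_settlements))[
                    design.settlement_idx]
                + (sg[2] * rng.standard_normal(design.n_lu_groups))[
                    design.lu_group_idx]
            )
        else:
            eps = (
                eps_reg[d][design.region_idx]
                + eps_set[d][design.settlement_idx]
                + eps_lu[d][design.lu_group_idx]
            )
        eta = beta0[d][:, None] + slopes[d] @ x.T + eps[None, :]
        p = expit(eta)
        y_rep = (rng.uniform(size=p.shape) < p).astype(int)
        rep_stats = _stats_from_matrix(y_rep, data.plots, codes, n_set)
        for name in STATISTIC_NAMES:
            reps[name].append(rep_stats[name])

    out: dict[str, PpcReport] = {}
    for name in STATISTIC_NAMES:
        t_obs = observed[name]
        t_rep = np.asarray(reps[name])
        if np.isnan(t_obs):
            p_val = np.nan
        else:
            p_val = float(
                (np.sum(t_rep > t_obs) + 0.5 * np.sum(t_rep == t_obs))
                / len(t_rep)
            )
        out[name] = PpcReport(
            statistic_name=name,
            observed=t_obs,
            replicate_values=t_rep,
            p_value=p_val,
            significant=bool(p_val <= 0.025 or p_val >= 0.975)
            if not np.isnan(p_val)
            else False,
        )
    return out
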