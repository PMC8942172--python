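"""Projection of predicted abandonment effects onto range maps (CL/CG).

For each grid cell, cumulative loss CL is the sum over species present in
the cell of the absolute value of their negative predicted abandonment
effects, and cumulative gain CG is the sum of the positive effects.  The
per-species effect is the ridge-model predicted slope mean mu_b1i computed
from the species' habitat-preference vector, per posterior draw; CL/CG are
accumulated per draw and then summarized (posterior mean and SD), so the
reported SD maps reflect the full posterior of the sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import HabitatMatrix, RangeStack
from .inference import PosteriorDraws
from .model_core import predict_mu_beta1


@dataclass
class ProjectionMaps:
    """Per-cell posterior summaries of loss/gain under land abandonment."""

    table: pd.DataFrame  # indexed by cell_id
    subset_label: str = "all"

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def species_effects(
    habitat: HabitatMatrix,
    m3_draws: PosteriorDraws,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Per-draw predicted abandonment effect mu_b1i for each species.

    Works for species absent from the survey, as long as they have a
    habitat-preference row.  Returns a (draw x species) DataFrame.
    """
    species = species if species is not None else habitat.species
    missing = [s for s in species if s not in habitat.H.index]
    if missing:
        raise KeyError(f"species without habitat rows: {missing}")
    alpha_draws = {
        "alpha0": m3_draws.stacked("alpha0"),
        "alpha_vec": m3_draws.stacked("alpha_vec"),
    }
    cols = {}
    for sp in species:
        h = habitat.H.loc[sp].to_numpy(dtype=float)
        cols[sp] = predict_mu_beta1(h, alpha_draws)
    return pd.DataFrame(cols)


def compute_cl_cg(
    stack: RangeStack,
    effects: pd.DataFrame,
    subset_label: str = "all",
    per_draw: bool = True,
) -> ProjectionMaps:
    """Cumulative species loss (CL) and gain (CG) per grid cell.

    ``effects`` is (draw x species).  With ``per_draw=True`` (default) the
    negative/positive split and the sums are formed within each posterior
    draw and then summarized; with ``per_draw=False`` the split uses the
    posterior-mean effects (a point-estimate variant, no SD maps).
    """
    common = [s for s in stack.species if s in effects.columns]
    missing = [s for s in stack.species if s not in effects.columns]
    if missing:
        raise KeyError(f"range-stack species without effects: {missing}")
    pres = stack.presence[common].to_numpy(dtype=float)  # cell x species
    eff = effects[common].to_numpy(dtype=float)          # draw x species

    if per_draw:
        loss = np.where(eff < 0, -eff, 0.0)              # draw x species
        gain = np.where(eff > 0, eff, 0.0)
        cl = pres @ loss.T                               # cell x draw
        cg = pres @ gain.T
        with np.errstate(invalid="ignore", divide="ignore"):
            prop_cl = np.where(cl + cg > 0, cl / (cl + cg), np.nan)
            prop_cg = np.where(cl + cg > 0, cg / (cl + cg), np.nan)
        diff = cg - cl
        import warnings

        with warnings.catch_warnings():
            # empty cells yield all-NaN proportion rows by design
            warnings.simplefilter("ignore", RuntimeWarning)
            prop_summ = {
                "prop_cl_mean": np.nanmean(prop_cl, axis=1),
                "prop_cl_sd": np.nanstd(prop_cl, axis=1),
                "prop_cg_mean": np.nanmean(prop_cg, axis=1),
                "prop_cg_sd": np.nanstd(prop_cg, axis=1),
            }
        table = pd.DataFrame(
            {
                "cl_mean": cl.mean(axis=1),
                "cl_sd": cl.std(axis=1),
                "cg_mean": cg.mean(axis=1),
                "cg_sd": cg.std(axis=1),
                **prop_summ,
                "cg_minus_cl_mean": diff.mean(axis=1),
                "cg_minus_cl_sd": diff.std(axis=1),
            },
            index=stack.presence.index,
        )
    else:
        e_mean = eff.mean(axis=0)
        cl = pres @ np.where(e_mean < 0, -e_mean, 0.0)
        cg = pres @ np.where(e_mean > 0, e_mean, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop_cl = np.where(cl + cg > 0, cl / (cl + cg), np.nan)
        table = pd.DataFrame(
            {
                "cl_mean": cl,
                "cg_mean": cg,
                "prop_cl_mean": prop_cl,
                "prop_cg_mean": 1.0 - prop_cl,
                "cg_minus_cl_mean": cg - cl,
            },
            index=stack.presence.index,
        )
    table["richness"] = stack.presence[common].sum(axis=1).to_numpy()
    table["prop_defined"] = ~table["prop_cl_mean"].isna()
    if stack.coords is not None:
        for c in stack.coords.columns:
            table[c] = stack.coords[c].to_numpy()
    return ProjectionMaps(table=table, subset_label=subset_label)


def red_list_subset(habitat: HabitatMatrix, stack: RangeStack) -> RangeStack:
    """Range stack restricted to red-list species."""
    keep = [
        s
        for s in stack.species
        if s in habitat.red_list.index and habitat.red_list[s] == 1
    ]
    return RangeStack(
        presence=stack.presence[keep].copy(), coords=stack.coords
    )


def map_summary(maps: ProjectionMaps) -> dict:
    """Headline map summaries: CL>CG cell fraction and CL/CG correlations."""
    t = maps.table
    out: dict = {"subset": maps.subset_label, "n_cells": len(t)}
    out["frac_cl_gt_cg"] = float((t["cl_mean"] > t["cg_mean"]).mean())
    if len(t) >= 2 and t["cl_mean"].std() > 0 and t["cg_mean"].std() > 0:
        out["corr_cl_cg"] = float(
            np.corrcoef(t["cl_mean"], t["cg_mean"])[0, 1]
        )
    else:
        out["corr_cl_cg"] = np.nan
    for name in ("cl", "cg"):
        sd_col = f"{name}_sd"
        if sd_col in t.columns and t[sd_col].std() > 0 and t[
            f"{name}_mean"
        ].std() > 0:
            out[f"corr_{name}_mean_sd"] = float(
                np.corrcoef(t[f"{name}_mean"], t[sd_col])[0, 1]
            )
    return out
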