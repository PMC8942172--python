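"""End-to-end orchestration: simulate -> validate -> fit -> compare -> check
-> project, with deterministic seed management and per-stage manifests.

A single global seed is split into independent per-stage streams with
``numpy.random.SeedSequence(global_seed).spawn``; stage k always receives
the k-th child, so re-running any stage from persisted artifacts reproduces
it bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .checking import posterior_predictive_pvalues
from .data_model import (
    SurveyTable,
    build_design,
    load_habitats,
    load_range_stack,
    load_survey,
    write_habitats,
    write_range_stack,
    write_survey,
)
from .inference import McmcSettings, PosteriorDraws, fit, significant_species
from .model_core import PriorConfig
from .model_selection import compare_aban_codings
from .projection import (
    compute_cl_cg,
    map_summary,
    red_list_subset,
    species_effects,
)
from .synthetic import (
    DesignConfig,
    GenerativeHyper,
    generate_habitats,
    generate_range_stack,
    generate_survey,
    generate_truth,
)

log = logging.getLogger("occaban")

STAGES = ["simulate", "fit", "compare", "check", "project"]


@dataclass
class RunConfig:
    out_dir: str = "occaban_run"
    seed: int = 0
    variant: str = "M1"
    aban_coding: str = "binary"
    design: DesignConfig = field(default_factory=DesignConfig)
    hyper: GenerativeHyper = field(default_factory=GenerativeHyper)
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    n_cells: int = 500
    range_prevalence: float = 0.5
    ppc_max_draws: int | None = 500

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage 31-bit seed derived from the global seed."""
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))

    def config_hash(self) -> str:
        body = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(body.encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: RunConfig, extra: dict,
                    status: str = "ok") -> None:
    manifest = {
        "stage": stage,
        "status": status,
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seed": config.stage_seed(stage) if stage in STAGES else None,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )


# ---------------------------------------------------------------------------
# Draw persistence (self-describing CSV + JSON diagnostics sidecar)
# ---------------------------------------------------------------------------

def save_draws(draws: PosteriorDraws, prefix: Path) -> None:
    cols: dict[str, np.ndarray] = {}
    n_c, n_d = next(iter(draws.draws.values())).shape[:2]
    cols["chain"] = np.repeat(np.arange(n_c), n_d)
    cols["draw"] = np.tile(np.arange(n_d), n_c)
    for name, arr in draws.draws.items():
        flat = arr.reshape(n_c * n_d, -1)
        shape = arr.shape[2:]
        if flat.shape[1] == 1:
            cols[name] = flat[:, 0]
        else:
            for k in range(flat.shape[1]):
                idx = np.unravel_index(k, shape)
                cols[f"{name}[{','.join(map(str, idx))}]"] = flat[:, k]
    pd.DataFrame(cols).to_csv(f"{prefix}.csv", index=False)
    diag = {
        "variant": draws.variant,
        "divergences": draws.divergences,
        "converged": draws.converged,
        "max_rhat": draws.max_rhat(),
        "rhat": {k: np.asarray(v).tolist() for k, v in draws.rhat.items()},
        "settings": asdict(draws.settings),
        "species": draws.species,
        "meta": draws.meta,
    }
    Path(f"{prefix}_diagnostics.json").write_text(
        json.dumps(diag, indent=2, default=str)
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path):
    seed = config.stage_seed("simulate")
    habitat = generate_habitats(config.design.n_species, seed=seed)
    truth = generate_truth(
        config.design, config.hyper, seed=seed + 1, habitat=habitat
    )
    table = generate_survey(config.design, truth, seed=seed + 2)
    stack = generate_range_stack(
        config.n_cells, habitat, seed=seed + 3,
        prevalence=config.range_prevalence,
    )
    write_survey(table, out / "survey.csv")
    write_habitats(habitat, out / "habitats.csv")
    write_range_stack(stack, out / "range_stack.csv")
    (out / "truth.yaml").write_text(yaml.safe_dump(truth.as_dict()))
    _write_manifest(out, "simulate", config, {
        "n_plots": table.n_plots, "n_species": table.n_species,
    })
    return table, habitat, stack, truth


def stage_validate(out: Path) -> list[str]:
    table = load_survey(out / "survey.csv")
    problems = table.violations()
    load_habitats(out / "habitats.csv")
    load_range_stack(out / "range_stack.csv")
    (out / "validation.json").write_text(
        json.dumps({"violations": problems}, indent=2)
    )
    return problems


def stage_fit(config: RunConfig, out: Path, table, habitat):
    design = build_design(table, aban_coding=config.aban_coding)
    settings = McmcSettings(
        **{**asdict(config.mcmc), "seed": config.stage_seed("fit")}
    )
    habitat_type = "grassland" if config.variant == "M2" else None
    draws = fit(
        config.variant, table, design, settings=settings, prior=config.prior,
        habitat=habitat if config.variant in ("M2", "M3") else None,
        habitat_type=habitat_type,
    )
    save_draws(draws, out / f"draws_{config.variant.lower()}")
    calls = significant_species(draws)
    (out / "significance.json").write_text(json.dumps(calls, indent=2))
    _write_manifest(out, "fit", config, {
        "variant": config.variant,
        "max_rhat": draws.max_rhat(),
        "divergences": draws.divergences,
    })
    return draws, design


def stage_compare(config: RunConfig, out: Path, table):
    settings = McmcSettings(
        **{**asdict(config.mcmc), "seed": config.stage_seed("compare")}
    )
    report = compare_aban_codings(table, settings=settings, prior=config.prior)
    (out / "coding_comparison.json").write_text(
        json.dumps(report.as_dict(), indent=2)
    )
    _write_manifest(out, "compare", config, report.as_dict())
    return report


def stage_check(config: RunConfig, out: Path, draws, table, design):
    reports = posterior_predictive_pvalues(
        draws, table, design, seed=config.stage_seed("check"),
        max_draws=config.ppc_max_draws,
    )
    body = {
        name: {
            "observed": r.observed,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for name, r in reports.items()
    }
    (out / "ppc.json").write_text(json.dumps(body, indent=2, default=str))
    _write_manifest(out, "check", config, {"ppc": body})
    return reports


def stage_project(config: RunConfig, out: Path, table, habitat, stack):
    design = build_design(table, aban_coding=config.aban_coding)
    settings = McmcSettings(
        **{**asdict(config.mcmc), "seed": config.stage_seed("project")}
    )
    m3 = fit(
        "M3", table, design, settings=settings, prior=config.prior,
        habitat=habitat,
    )
    save_draws(m3, out / "draws_m3")
    eff = species_effects(habitat, m3, species=stack.species)
    summaries = {}
    for label, st in (
        ("all", stack), ("red_list", red_list_subset(habitat, stack)),
    ):
        if not st.species:
            continue
        maps = compute_cl_cg(st, eff[st.species], subset_label=label)
        maps.table.to_csv(out / f"maps_{label}.csv", index_label="cell_id")
        summaries[label] = map_summary(maps)
    (out / "map_summary.json").write_text(
        json.dumps(summaries, indent=2, default=str)
    )
    _write_manifest(out, "project", config, {"summaries": summaries})
    return summaries


def run_pipeline(config: RunConfig) -> int:
    """Run every stage in order; returns 0 on success, 1 on failure.

    Partial artifacts are kept on failure and the failing stage is recorded
    in its manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        t0 = time.time()
        table, habitat, stack, truth = stage_simulate(config, out)
        log.info("simulate done in %.1fs", time.time() - t0)
        stage = "validate"
        problems = stage_validate(out)
        if problems:
            raise ValueError(f"validation failed: {problems}")
        stage = "fit"
        draws, design = stage_fit(config, out, table, habitat)
        stage = "compare"
        stage_compare(config, out, table)
        stage = "check"
        stage_check(config, out, draws, table, design)
        stage = "project"
        stage_project(config, out, table, habitat, stack)
    except Exception as exc:  # noqa: BLE001 - stage failure is reported
        log.error("stage %s failed: %s", stage, exc)
        _write_manifest(out, stage, config, {"error": str(exc)},
                        status="failed")
        return 1
    _write_manifest(out, "run_all", config, {})
    return 0
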