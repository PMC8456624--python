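"""End-to-end orchestration: simulate -> sample -> perturb -> rescue -> enrich.

A single seed in the config governs every stochastic stage through
documented sub-streams (the flux sampler consumes the seed directly;
the synthetic generators derive per-stage child streams from it).
Outputs are plain TSV/JSON with fixed float formatting and no
timestamps, so re-running with an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .growth import compute_growth_metrics, percent_change
from .lp import FlexSpec, fba
from .model import EcModel, load_model, set_carbon_source
from .rescue import (
    enrichment_to_frame,
    hypergeometric_enrichment,
    read_gmt,
    rescue_to_frame,
    single_enzyme_rescue,
)
from .sampling import SamplingConfig, sample_flux_distributions, samples_to_frame
from .synthetic import (
    SyntheticScenario,
    default_gene_sets,
    enzyme_gene_map,
    make_core_ecmodel,
    simulate_de_tables,
    simulate_enzyme_de,
    simulate_growth_curve,
)
from .transcriptome import (
    DeTable,
    build_perturbation_set,
    perturbed_growth_screen,
    screen_to_frame,
    select_de_enzymes,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All pipeline knobs, defaulting to the study's values."""

    outdir: str = "ecflux_out"
    seed: int = 0
    n_samples: int = 1000
    pool_bound: float = 0.1
    growth_value: float = 0.22  # h^-1, reference growth on ethanol
    growth_delta: float = 0.05
    enzyme_delta: float = 0.20
    mu_target: float = 0.22
    rescue_delta: float = 0.05
    carbon_source: str = "ethanol"
    enzyme_fdr_threshold: float = 0.05
    perturb_direction: str = "all"  # or "down_only"
    enrichment_min_genes: int = 6
    enrichment_filter_on: str = "overlap"
    # optional external inputs; simulated from the scenario when absent
    model_path: str | None = None
    enzyme_de_path: str | None = None
    gene_sets_path: str | None = None
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)

    def __post_init__(self):
        # one seed governs everything, including the synthetic scenario
        self.scenario = dataclasses.replace(self.scenario, seed=self.seed)


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scenario_kwargs = raw.pop("scenario", {})
    cfg = PipelineConfig(**raw)
    if scenario_kwargs:
        cfg.scenario = dataclasses.replace(
            cfg.scenario, **scenario_kwargs, seed=cfg.seed
        )
    return cfg


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # output location is not part of the analysis
    d["scenario"]["read_fractions"] = dict(config.scenario.read_fractions)
    d["scenario"]["deleted_genes"] = list(config.scenario.deleted_genes)
    return d


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _require_file(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"input file not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: model (load or calibrate) -> reference flux sampling ->
    perturbed-growth screen -> single-enzyme rescue -> enrichment of
    rescuer genes -> growth-curve metrics.  Any stage error aborts with
    the stage name; a FAILED marker is left next to partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        manifest = _run(config, outdir)
    except Exception as exc:
        failed_marker.write_text(f"{exc}\n")
        raise
    return manifest


def _run(config: PipelineConfig, outdir: Path) -> dict:
    scenario = config.scenario

    # -- model ---------------------------------------------------------
    log.info("stage model: building enzyme-constrained model")
    if config.model_path:
        model = load_model(_require_file(config.model_path, "model"))
    else:
        model = make_core_ecmodel(scenario)
    model.save(outdir / "model.json")
    mu_eth = fba(set_carbon_source(model, config.carbon_source),
                 {model.biomass_id: 1.0}, "max").objective_value

    # -- enzyme DE and perturbations ------------------------------------
    log.info("stage perturbations: enzyme DE -> usage multipliers")
    if config.enzyme_de_path:
        enzyme_de = DeTable.read_tsv(_require_file(config.enzyme_de_path, "perturbations"))
    else:
        enzyme_de, _ = simulate_enzyme_de(scenario, model)
    gmap = select_de_enzymes(
        enzyme_de, enzyme_gene_map(model), scenario.deleted_genes,
        config.enzyme_fdr_threshold,
    )
    pset = build_perturbation_set(
        enzyme_de, gmap, scenario.deleted_genes,
        delta=config.enzyme_delta, direction=config.perturb_direction,
    )
    pset.records.to_csv(outdir / "perturbations.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)

    # -- sampling --------------------------------------------------------
    log.info("stage sample: %d randomly weighted objective pairs", config.n_samples)
    sampling = SamplingConfig(
        n_samples=config.n_samples, seed=config.seed,
        growth_value=config.growth_value, growth_delta=config.growth_delta,
        carbon_source=config.carbon_source,
    )
    try:
        samples = sample_flux_distributions(model, sampling)
    except Exception as exc:
        raise PipelineError("sample", str(exc)) from exc
    samples_to_frame(model, samples).to_csv(
        outdir / "samples.tsv", sep="\t", float_format=FLOAT_FMT
    )
    with open(outdir / "samples_provenance.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": config.seed,
                "n_samples": config.n_samples,
                "draws": [
                    {
                        "sample_index": fd.info["sample_index"],
                        "objective_reactions": list(fd.info["objective_reactions"]),
                        "weights": [round(w, 12) for w in fd.info["weights"]],
                    }
                    for fd in samples
                ],
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    # -- perturbed-growth screen ----------------------------------------
    log.info("stage perturb: screening %d samples", len(samples))
    screen = perturbed_growth_screen(
        model, samples, pset, config.growth_delta, config.carbon_source
    )
    screen_frame = screen_to_frame(screen)
    screen_frame.to_csv(outdir / "screen.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)
    feasible = screen_frame[screen_frame["status"] == "optimal"]

    # -- rescue ----------------------------------------------------------
    log.info("stage rescue: releasing %d enzymes one at a time", len(pset.multipliers))
    rescue = single_enzyme_rescue(
        model, samples, pset, config.mu_target, config.rescue_delta,
        screen=screen, carbon_source=config.carbon_source,
    )
    rescue_frame = rescue_to_frame(rescue)
    rescue_frame.to_csv(outdir / "rescue.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)
    rescuers = [r.enzyme for r in rescue if r.rescuer]

    # -- enrichment ------------------------------------------------------
    log.info("stage enrich: %d rescuer enzymes", len(rescuers))
    if config.gene_sets_path:
        gene_sets = read_gmt(_require_file(config.gene_sets_path, "enrich"))
    else:
        _, _, de_truth = simulate_de_tables(scenario)
        gene_sets = default_gene_sets(scenario, model, de_truth)
    universe = sorted({g for e in model.enzymes for g in e.genes})
    query = sorted({g for e in rescuers for g in model.enzyme(e).genes})
    enrichment = hypergeometric_enrichment(
        query, gene_sets, universe,
        min_genes=config.enrichment_min_genes,
        filter_on=config.enrichment_filter_on,
    )
    enrichment_to_frame(enrichment).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # -- growth metrics --------------------------------------------------
    log.info("stage growth: doubling time / lag / final OD per strain")
    growth_rows = []
    tds = {}
    for strain in ("reference", "mutant"):
        curve = simulate_growth_curve(scenario, strain)
        metrics = compute_growth_metrics(curve)
        tds[strain] = metrics.doubling_time_min
        growth_rows.append(
            {
                "label": strain,
                "doubling_time_min": metrics.doubling_time_min,
                "lag_min": metrics.lag_min,
                "final_od": metrics.final_od,
                "r2": metrics.r2,
            }
        )
    import pandas as pd

    pd.DataFrame(growth_rows).to_csv(outdir / "growth_metrics.tsv", sep="\t",
                                     index=False, float_format=FLOAT_FMT)
    td_change_pct = percent_change(tds["reference"], tds["mutant"], round_to_int=True)

    # -- manifest and summary -------------------------------------------
    n_feasible = int(len(feasible))
    mean_mu = float(feasible["mu_max"].mean()) if n_feasible else float("nan")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": _config_dict(config),
        "counts": {
            "n_samples": len(samples),
            "n_feasible": n_feasible,
            "n_infeasible": len(samples) - n_feasible,
            "n_perturbed_enzymes": len(pset.multipliers),
            "n_unmapped_enzymes": len(pset.unmapped),
            "n_rescuers": len(rescuers),
            "n_enriched_terms": len(enrichment),
        },
        "results": {
            "mu_max_ethanol_reference": round(mu_eth, 10),
            "mean_mu_max_perturbed": round(mean_mu, 10),
            "rescuers": rescuers,
            "doubling_time_min": {k: round(v, 6) for k, v in tds.items()},
            "doubling_time_change_pct": td_change_pct,
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    summary = (
        f"ecflux pipeline (seed {config.seed})\n"
        f"  reference mu_max on {config.carbon_source}: {mu_eth:.4f} h^-1\n"
        f"  samples: {len(samples)} ({n_feasible} feasible under perturbation)\n"
        f"  mean perturbed mu_max: {mean_mu:.4f} h^-1\n"
        f"  perturbed enzymes: {len(pset.multipliers)}; rescuers: "
        f"{', '.join(rescuers) or 'none'}\n"
        f"  doubling time: reference {tds['reference']:.1f} min, "
        f"mutant {tds['mutant']:.1f} min ({td_change_pct:+.0f}%)\n"
        f"  enriched terms reported: {len(enrichment)}\n"
    )
    (outdir / "summary.txt").write_text(summary)
    return manifest
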