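"""Synthetic study data: toy ec-model, DE tables, counts, growth curves.

Everything the pipeline consumes can be generated here with no
downloads, with the planted truth recorded alongside: a small
enzyme-constrained model of yeast central carbon metabolism calibrated
so that the maximum growth rate on ethanol falls in the reference
window 0.22 h^-1 +/- 5%; differential-expression tables with planted
poorly-induced genes; an enzyme-level DE table with a planted
bottleneck; negative-binomial count matrices whose designated gene set
occupies prescribed read fractions per condition group; and
lag/exponential/saturation growth curves.

Gene and enzyme names are analogs of the yeast genes they emulate
(ACS1x, ADH2x, CIT2x, ...) — readable without claiming real
S. cerevisiae stoichiometry or kinetics.  Every generator is a pure
function of the scenario and its seed; independent sub-streams are
derived per generator so outputs are reproducible individually and in
any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import fba
from .model import (
    EcModel,
    Enzyme,
    EnzymeLink,
    Metabolite,
    Reaction,
    set_carbon_source,
    split_reversible,
    to_enzyme_constrained,
)
from .transcriptome import CountMatrix, DeTable
from .growth import GrowthCurve

# sub-stream indices (rng = default_rng([seed, STREAM_*]))
STREAM_DE = 1
STREAM_ENZYME_DE = 2
STREAM_COUNTS = 3
STREAM_CURVE = 4


class CalibrationError(RuntimeError):
    """kcat calibration failed to land in the target growth window."""


@dataclass
class SyntheticScenario:
    """All knobs of the synthetic study, with the study's values as defaults."""

    seed: int = 0

    # -- ec-model ------------------------------------------------------
    pool_bound: float = 0.1  # g enzyme / gDW
    target_mu_ethanol: float = 0.22  # h^-1
    growth_delta: float = 0.05
    ngam_min: float = 0.0  # mmol ATP gDW^-1 h^-1 maintenance floor

    # -- gene-level DE (glucose -> ethanol contrast per strain) --------
    n_genes: int = 2000
    n_poorly_induced: int = 111
    n_induced_both: int = 300
    wt_fc_mean: float = 2.5
    wt_fc_sd: float = 0.5
    wt_fc_floor: float = 1.2
    attenuation_mean: float = 1.8
    attenuation_sd: float = 0.3
    attenuation_floor: float = 1.05
    background_fc_sd: float = 0.3
    significant_fdr: tuple[float, float] = (1e-6, 0.005)
    background_fdr: tuple[float, float] = (0.1, 1.0)

    # -- enzyme-level DE (mutant vs reference on ethanol) --------------
    #: planted log2 fold-changes of enzyme-encoding genes; the ACS analog
    #: is the bottleneck (multiplier 0.1)
    enzyme_log2fc: dict[str, float] = field(
        default_factory=lambda: {
            "ACS1x": math.log2(0.1),
            "ALD3x": 0.26,
            "CIT2x": 0.40,
            "PDC6x": -1.0,
            "HXK1x": -0.5,
        }
    )
    deleted_genes: tuple[str, ...] = ("AAD4x",)
    enzyme_delta: float = 0.20

    # -- counts --------------------------------------------------------
    n_replicates: int = 3
    library_size: int = 100_000
    dispersion: float = 0.05  # NB shape = 1/dispersion
    #: percent of reads carried by the designated (poorly induced) set
    read_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "ref_glu": 1.8,
            "ref_eth": 7.1,
            "mut_glu": 1.8,
            "mut_eth": 3.56,
        }
    )

    # -- growth curves -------------------------------------------------
    doubling_time_ref: float = 111.0  # min, glucose phase
    doubling_time_mut: float = 120.0  # min
    start_od: float = 0.1
    capacity: float = 10.0  # carrying capacity (OD600)
    dead_time_min: float = 0.0
    curve_noise_sd: float = 0.0  # multiplicative
    curve_duration_min: float = 720.0
    curve_step_min: float = 10.0

    @property
    def bottleneck_enzyme(self) -> str:
        return min(self.enzyme_log2fc, key=self.enzyme_log2fc.get)

    @property
    def growth_window(self) -> tuple[float, float]:
        mu, d = self.target_mu_ethanol, self.growth_delta
        return mu * (1 - d), mu * (1 + d)


# ---------------------------------------------------------------------
# toy central-carbon ec-model
# ---------------------------------------------------------------------

#: molecular weights, g/mmol (numerically kDa)
_MW = {
    "HXK1x": 55.0, "PDC6x": 61.0, "PDH1x": 100.0, "ADH2x": 37.0,
    "AAD4x": 35.0, "ALD3x": 54.0, "ACS1x": 75.0, "RSP1x": 250.0, "CIT2x": 53.0,
}

#: pre-calibration turnover numbers, h^-1
_KCAT = {
    "HXK1x": 600_000.0, "PDC6x": 300_000.0, "PDH1x": 200_000.0, "ADH2x": 480_000.0,
    "AAD4x": 60_000.0, "ALD3x": 150_000.0, "ACS1x": 70_000.0, "RSP1x": 100_000.0,
    "CIT2x": 120_000.0,
}

#: ATP stoichiometry: lumped glycolysis yield, respiration yield per
#: acetyl-CoA, gluconeogenic cost per precursor, growth cost per unit mu
_ATP_GLYC = 2.0
_ATP_RESP = 9.0
_ATP_GLX = 2.0
_ATP_BIOMASS = 20.0


def _base_network(ngam_min: float) -> tuple[EcModel, list[Enzyme]]:
    mets = [
        Metabolite("GLC", "glucose"), Metabolite("ETH", "ethanol"),
        Metabolite("ACALD", "acetaldehyde"), Metabolite("ACE", "acetate"),
        Metabolite("ACCOA", "acetyl-CoA"), Metabolite("PYR", "pyruvate"),
        Metabolite("ATP", "ATP"), Metabolite("PREC", "biomass precursor"),
        Metabolite("CO2", "carbon dioxide"),
    ]

    def link(enzyme: str) -> list[EnzymeLink]:
        return [EnzymeLink(enzyme, _KCAT[enzyme])]

    reactions = [
        Reaction("EX_glc", {"GLC": 1.0}, 0.0, 1000.0, "exchange"),
        # ethanol exchange is reversible (uptake positive); split below
        Reaction("EX_eth", {"ETH": 1.0}, -1000.0, 1000.0, "exchange"),
        Reaction("EX_co2", {"CO2": -1.0}, 0.0, 1000.0, "exchange"),
        Reaction("GLYC", {"GLC": -1.0, "PYR": 2.0, "ATP": _ATP_GLYC},
                 0.0, 1000.0, "metabolic", link("HXK1x")),
        Reaction("PDC", {"PYR": -1.0, "ACALD": 1.0, "CO2": 1.0},
                 0.0, 1000.0, "metabolic", link("PDC6x")),
        Reaction("PDH", {"PYR": -1.0, "ACCOA": 1.0, "CO2": 1.0},
                 0.0, 1000.0, "metabolic", link("PDH1x")),
        # alcohol dehydrogenase, reversible: fermentation forward,
        # ethanol assimilation reverse
        Reaction("ADH", {"ACALD": -1.0, "ETH": 1.0}, -1000.0, 1000.0,
                 "metabolic", link("ADH2x")),
        # aryl-alcohol dehydrogenase analog: isozyme of the fermentative
        # direction, expressed as a parallel reaction copy
        Reaction("AAR", {"ACALD": -1.0, "ETH": 1.0}, 0.0, 1000.0,
                 "metabolic", link("AAD4x")),
        Reaction("ALD", {"ACALD": -1.0, "ACE": 1.0}, 0.0, 1000.0,
                 "metabolic", link("ALD3x")),
        Reaction("ACS", {"ACE": -1.0, "ATP": -1.0, "ACCOA": 1.0}, 0.0, 1000.0,
                 "metabolic", link("ACS1x")),
        # lumped TCA + oxidative phosphorylation
        Reaction("RESP", {"ACCOA": -1.0, "CO2": 2.0, "ATP": _ATP_RESP},
                 0.0, 1000.0, "metabolic", link("RSP1x")),
        # glyoxylate shunt + gluconeogenesis, lumped
        Reaction("GLX", {"ACCOA": -2.0, "ATP": -_ATP_GLX, "PREC": 1.0},
                 0.0, 1000.0, "metabolic", link("CIT2x")),
        Reaction("BIOMASS", {"PREC": -1.0, "ATP": -_ATP_BIOMASS},
                 0.0, 1000.0, "biomass"),
        Reaction("NGAM", {"ATP": -1.0}, ngam_min, 1000.0, "ngam"),
    ]
    enzymes = [Enzyme(eid, mw, [eid]) for eid, mw in _MW.items()]
    model = EcModel(
        metabolites=mets,
        reactions=reactions,
        biomass_id="BIOMASS",
        ngam_id="NGAM",
        carbon_exchange_ids={"glucose": "EX_glc", "ethanol": "EX_eth_fwd"},
    )
    return model, enzymes


def _max_mu(model: EcModel, source: str) -> float:
    fd = fba(set_carbon_source(model, source), {model.biomass_id: 1.0}, "max")
    if not fd.optimal:
        raise CalibrationError(f"growth FBA on {source} ended {fd.status}")
    return fd.objective_value


def make_core_ecmodel(scenario: SyntheticScenario | None = None,
                      max_iterations: int = 25) -> EcModel:
    """Build and calibrate the toy central-carbon ec-model.

    A deterministic calibration scales all kcats uniformly until the
    maximum growth rate with ethanol as sole carbon source equals the
    target (0.22 h^-1); with the default zero maintenance floor the
    scaling is exact after one step, otherwise it iterates.  Glucose
    growth must exceed the ethanol window, as it does in vivo.
    """
    scenario = scenario or SyntheticScenario()
    target = scenario.target_mu_ethanol
    scale = 1.0
    model, mu = None, float("nan")
    for _ in range(max_iterations):
        base, enzymes = _base_network(scenario.ngam_min)
        for r in base.reactions:
            for l in r.enzymes:
                l.kcat = _KCAT[l.enzyme_id] * scale
        model = to_enzyme_constrained(
            split_reversible(base), enzymes, scenario.pool_bound
        )
        mu = _max_mu(model, "ethanol")
        if mu <= 0:
            raise CalibrationError("no growth on ethanol before calibration")
        if abs(mu - target) <= 1e-9 * target:
            break
        scale *= target / mu
    else:
        raise CalibrationError(
            f"calibration did not converge within {max_iterations} iterations "
            f"(last mu={mu:.6g}, scale={scale:.6g})"
        )
    lo, hi = scenario.growth_window
    mu_eth = _max_mu(model, "ethanol")
    mu_glc = _max_mu(model, "glucose")
    if not (lo <= mu_eth <= hi):
        raise CalibrationError(f"ethanol mu_max {mu_eth:.4g} outside [{lo}, {hi}]")
    if mu_glc <= hi:
        raise CalibrationError(
            f"glucose mu_max {mu_glc:.4g} does not exceed the ethanol window"
        )
    return model


def enzyme_gene_map(model: EcModel) -> dict[str, list[str]]:
    return {e.id: list(e.genes) for e in model.enzymes}


# ---------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, floor, size):
    out = rng.normal(mean, sd, size)
    while True:
        low = out <= floor
        if not low.any():
            return out
        out[low] = rng.normal(mean, sd, int(low.sum()))


def simulate_de_tables(
    scenario: SyntheticScenario,
) -> tuple[DeTable, DeTable, dict]:
    """Glucose-to-ethanol DE tables for reference and mutant strains.

    Plants ``n_poorly_induced`` genes that are strongly induced in the
    reference (log2FC ~ N(2.5, 0.5) truncated above 1.2, FDR well below
    0.01) but attenuated by ~1.8 log2 units in the mutant, plus a set
    induced equally in both strains; all remaining genes are null.
    Returns the two tables and the planted truth.
    """
    rng = np.random.default_rng([scenario.seed, STREAM_DE])
    genes = np.array([f"G{i:04d}" for i in range(scenario.n_genes)])
    n_pi, n_both = scenario.n_poorly_induced, scenario.n_induced_both
    if n_pi + n_both > scenario.n_genes:
        raise ValueError("more planted genes than genes")
    picked = rng.choice(scenario.n_genes, size=n_pi + n_both, replace=False)
    pi_idx, both_idx = picked[:n_pi], picked[n_pi:]

    wt_lfc = rng.normal(0.0, scenario.background_fc_sd, scenario.n_genes)
    mut_lfc = rng.normal(0.0, scenario.background_fc_sd, scenario.n_genes)
    wt_fdr = rng.uniform(*scenario.background_fdr, scenario.n_genes)
    mut_fdr = rng.uniform(*scenario.background_fdr, scenario.n_genes)

    induced = np.concatenate([pi_idx, both_idx])
    wt_lfc[induced] = _truncated_normal(
        rng, scenario.wt_fc_mean, scenario.wt_fc_sd, scenario.wt_fc_floor, len(induced)
    )
    wt_fdr[induced] = rng.uniform(*scenario.significant_fdr, len(induced))
    mut_fdr[induced] = rng.uniform(*scenario.significant_fdr, len(induced))

    mut_lfc[pi_idx] = wt_lfc[pi_idx] - _truncated_normal(
        rng, scenario.attenuation_mean, scenario.attenuation_sd,
        scenario.attenuation_floor, n_pi,
    )
    # induced to a similar degree in both strains: |gap| kept below 0.8
    mut_lfc[both_idx] = wt_lfc[both_idx] - np.clip(
        rng.normal(0.0, 0.2, n_both), -0.8, 0.8
    )

    de_wt = DeTable("ref_eth_vs_glu", pd.DataFrame(
        {"gene": genes, "log2FC": wt_lfc, "FDR": wt_fdr}))
    de_mut = DeTable("mut_eth_vs_glu", pd.DataFrame(
        {"gene": genes, "log2FC": mut_lfc, "FDR": mut_fdr}))
    truth = {
        "poorly_induced": sorted(genes[pi_idx]),
        "induced_both": sorted(genes[both_idx]),
    }
    return de_wt, de_mut, truth


def simulate_enzyme_de(
    scenario: SyntheticScenario, model: EcModel
) -> tuple[DeTable, dict]:
    """Mutant-vs-reference ethanol-phase DE of enzyme-encoding genes.

    Planted fold-changes come straight from ``scenario.enzyme_log2fc``
    (significant FDR); all other model enzymes are null; deleted genes
    are absent from the table, as they are from the mutant genome.
    """
    rng = np.random.default_rng([scenario.seed, STREAM_ENZYME_DE])
    deleted = set(scenario.deleted_genes)
    rows = []
    for enz in model.enzymes:
        for gene in enz.genes:
            if gene in deleted:
                continue
            if gene in scenario.enzyme_log2fc:
                lfc = scenario.enzyme_log2fc[gene]
                fdr = rng.uniform(1e-5, 0.01)
            else:
                lfc = rng.normal(0.0, 0.1)
                fdr = rng.uniform(0.2, 1.0)
            rows.append({"gene": gene, "log2FC": lfc, "FDR": fdr})
    table = DeTable("mut_vs_ref_ethanol", pd.DataFrame(rows))
    truth = {
        "bottleneck_enzyme": scenario.bottleneck_enzyme,
        "planted_log2fc": dict(scenario.enzyme_log2fc),
        "multipliers": {g: 2.0 ** f for g, f in scenario.enzyme_log2fc.items()},
        "deleted_genes": sorted(deleted),
    }
    return table, truth


# ---------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------

def simulate_counts(
    scenario: SyntheticScenario, designated_genes
) -> CountMatrix:
    """Negative-binomial counts with planted per-group read fractions.

    Per condition group the expected read share of the designated gene
    set equals ``scenario.read_fractions[group]`` percent; within each
    set genes carry fixed lognormal relative weights.  Library sizes
    are ~1e5 per sample — far below real sequencing depth, which is
    irrelevant here since the assertions concern fractions, not depth.
    """
    rng = np.random.default_rng([scenario.seed, STREAM_COUNTS])
    genes = [f"G{i:04d}" for i in range(scenario.n_genes)]
    designated = [g for g in genes if g in set(designated_genes)]
    others = [g for g in genes if g not in set(designated)]
    w_des = rng.lognormal(0.0, 0.5, len(designated))
    w_des = w_des / w_des.sum() if len(designated) else w_des
    w_oth = rng.lognormal(0.0, 0.5, len(others))
    w_oth /= w_oth.sum()
    shape = 1.0 / scenario.dispersion  # NB size parameter

    columns, groups = {}, {}
    for group, pct in scenario.read_fractions.items():
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"read fraction for {group!r} must be in [0, 100], got {pct}")
        p = pct / 100.0
        mean_map = {}
        for g, w in zip(designated, w_des):
            mean_map[g] = scenario.library_size * p * w
        for g, w in zip(others, w_oth):
            mean_map[g] = scenario.library_size * (1.0 - p) * w
        mu = np.array([mean_map[g] for g in genes])
        for rep in range(scenario.n_replicates):
            sample = f"{group}_r{rep + 1}"
            nb_p = shape / (shape + np.maximum(mu, 1e-12))
            counts = np.where(mu > 0, rng.negative_binomial(shape, nb_p), 0)
            columns[sample] = counts
            groups[sample] = group
    frame = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    return CountMatrix(frame, groups)


# ---------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------

def simulate_growth_curve(
    scenario: SyntheticScenario,
    strain: str = "reference",
    doubling_time_min: float | None = None,
) -> GrowthCurve:
    """Lag + exponential + saturation OD600 curve, sampled every 10 min.

    Logistic growth from the inoculation density with the specified
    exponential-phase doubling time and carrying capacity; an infinite
    capacity yields a pure exponential.  Optional dead time holds the
    curve flat before growth; multiplicative Gaussian noise as
    configured.  Note that a finite capacity bends the curve away from
    exponential growth well below the carrying capacity, so fitted
    doubling times on saturating curves are slightly longer than the
    generative parameter.
    """
    if doubling_time_min is None:
        doubling_time_min = (
            scenario.doubling_time_ref if strain == "reference"
            else scenario.doubling_time_mut
        )
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be > 0")
    od0, K = scenario.start_od, scenario.capacity
    if K <= od0:
        # no headroom: flat culture
        K = od0
    rng = np.random.default_rng([scenario.seed, STREAM_CURVE,
                                 0 if strain == "reference" else 1])
    t = np.arange(0.0, scenario.curve_duration_min + scenario.curve_step_min / 2,
                  scenario.curve_step_min)
    te = np.maximum(t - scenario.dead_time_min, 0.0)
    mu = math.log(2.0) / doubling_time_min
    if math.isinf(K):
        od = od0 * np.exp(mu * te)
    else:
        growth = np.exp(mu * te)
        od = K * od0 * growth / (K + od0 * (growth - 1.0))
    if scenario.curve_noise_sd > 0:
        od = od * np.maximum(1.0 + rng.normal(0.0, scenario.curve_noise_sd, od.shape), 0.0)
    return GrowthCurve(t, od, label=strain)


# ---------------------------------------------------------------------
# scenario directory
# ---------------------------------------------------------------------

def default_gene_sets(scenario: SyntheticScenario, model: EcModel,
                      de_truth: dict) -> dict[str, tuple[str, list[str]]]:
    """Synthetic GO-slim-like gene sets over the scenario's namespace."""
    rng = np.random.default_rng([scenario.seed, 5])
    ethanol_enzymes = ["ADH2x", "ALD3x", "ACS1x", "CIT2x", "AAD4x", "RSP1x"]
    glucose_enzymes = ["HXK1x", "PDC6x", "PDH1x"]
    pi = list(de_truth["poorly_induced"])
    filler = [f"G{i:04d}" for i in rng.choice(scenario.n_genes, 60, replace=False)]
    return {
        "ethanol_utilization": (
            "non-fermentable carbon source utilization",
            ethanol_enzymes + pi[: len(pi) // 2],
        ),
        "energy_generation": ("ATP generation", ethanol_enzymes + glucose_enzymes),
        "glycolysis": ("glucose fermentation", glucose_enzymes),
        "random_set_a": ("background set", filler[:30]),
        "random_set_b": ("background set", filler[30:]),
    }


def write_scenario(scenario: SyntheticScenario, outdir) -> dict:
    """Generate every pipeline input into a directory; returns the truth."""
    import json
    from pathlib import Path

    from .model import save_model
    from .rescue import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = make_core_ecmodel(scenario)
    save_model(model, outdir / "model.json")
    de_wt, de_mut, de_truth = simulate_de_tables(scenario)
    de_wt.to_tsv(outdir / "de_reference.tsv")
    de_mut.to_tsv(outdir / "de_mutant.tsv")
    enz_de, enz_truth = simulate_enzyme_de(scenario, model)
    enz_de.to_tsv(outdir / "de_enzymes.tsv")
    counts = simulate_counts(scenario, de_truth["poorly_induced"])
    counts.to_tsv(outdir / "counts.tsv", outdir / "groups.tsv")
    for strain in ("reference", "mutant"):
        simulate_growth_curve(scenario, strain).to_csv(outdir / f"curve_{strain}.csv")
    write_gmt(default_gene_sets(scenario, model, de_truth), outdir / "gene_sets.gmt")
    truth = {
        "seed": scenario.seed,
        "de": de_truth,
        "enzymes": enz_truth,
        "read_fractions": dict(scenario.read_fractions),
        "doubling_times_min": {
            "reference": scenario.doubling_time_ref,
            "mutant": scenario.doubling_time_mut,
        },
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
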