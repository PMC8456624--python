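"""Transcriptome integration: DE tables, count matrices, enzyme bounds.

This module consumes differential-expression results (gene, log2FC,
FDR) and raw count matrices as produced by a standard RNA-seq pipeline;
no DE model is fitted here.  It provides

* the *poorly induced* classifier — genes significantly upregulated on
  the glucose-to-ethanol transition in the reference strain
  (log2FC > 1, FDR < 0.01) but at least two-fold less induced in the
  mutant;
* the CPM prefilter and gene-set read-fraction accounting;
* translation of enzyme-gene fold-changes into per-sample enzyme-usage
  upper bounds (multiplier ``2^log2FC``, zero for deleted genes, with a
  +/-20% flexibilization), and the perturbed-growth screen that applies
  them to every sampled reference flux distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import FlexSpec, FluxDistribution, apply_flexible_constraint, fba, lexicographic_optimize
from .model import EcModel, usage_reaction_id

DE_COLUMNS = ["gene", "log2FC", "FDR"]


@dataclass
class DeTable:
    """Per-gene log2 fold-change and FDR records for one contrast."""

    label: str
    frame: pd.DataFrame  # columns gene, log2FC, FDR

    def __post_init__(self):
        missing = [c for c in DE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"DE table {self.label!r} lacks columns {missing}")
        if self.frame["gene"].duplicated().any():
            dup = self.frame.loc[self.frame["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"DE table {self.label!r} has duplicate genes {dup[:5]}")
        bad = ~self.frame["FDR"].between(0.0, 1.0)
        if bad.any():
            raise ValueError(
                f"DE table {self.label!r}: FDR outside [0, 1] for "
                f"{self.frame.loc[bad, 'gene'].tolist()[:5]}"
            )
        self._by_gene = self.frame.set_index("gene")

    def __len__(self):
        return len(self.frame)

    def __contains__(self, gene):
        return gene in self._by_gene.index

    def log2fc(self, gene: str) -> float:
        return float(self._by_gene.at[gene, "log2FC"])

    def fdr(self, gene: str) -> float:
        return float(self._by_gene.at[gene, "FDR"])

    @classmethod
    def from_records(cls, label: str, records) -> "DeTable":
        return cls(label, pd.DataFrame(records, columns=DE_COLUMNS))

    @classmethod
    def read_tsv(cls, path, label: str | None = None) -> "DeTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(label or str(path), frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class CountMatrix:
    """Genes x samples integer read counts plus a sample -> group map."""

    counts: pd.DataFrame  # index gene, columns samples
    groups: dict[str, str]

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = [s for s in self.counts.columns if s not in self.groups]
        if unknown:
            raise ValueError(f"samples without a condition group: {unknown}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        lib = self.library_sizes()
        if (lib <= 0).any():
            raise ValueError(f"zero library size in samples {list(lib[lib <= 0].index)}")
        return self.counts * 1e6 / lib

    def samples_in(self, group: str) -> list[str]:
        hits = [s for s, g in self.groups.items() if g == group and s in self.counts.columns]
        if not hits:
            raise KeyError(f"no samples in group {group!r}")
        return hits

    @classmethod
    def read_tsv(cls, counts_path, groups_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        gm = pd.read_csv(groups_path, sep="\t")
        if not {"sample", "group"} <= set(gm.columns):
            raise ValueError("group map must have columns 'sample' and 'group'")
        return cls(counts, dict(zip(gm["sample"], gm["group"])))

    def to_tsv(self, counts_path, groups_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        pd.DataFrame(
            {"sample": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------
# expression classification and accounting
# ---------------------------------------------------------------------

def classify_poorly_induced(
    de_wt: DeTable,
    de_mut: DeTable,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
    gap: float = 1.0,
) -> set[str]:
    """Genes induced in the reference but under-induced in the mutant.

    A gene qualifies when ``log2FC_wt > fc_threshold`` with
    ``FDR_wt < fdr_threshold`` (strict, following the published rule)
    and the induction deficit ``log2FC_wt - log2FC_mut >= gap`` (gap 1
    = at least two-fold less induced).  Genes absent from the mutant
    table are treated as not induced there (log2FC 0), with a warning.
    """
    if len(de_wt) == 0:
        warnings.warn("empty reference DE table; returning empty set", stacklevel=2)
        return set()
    wt = de_wt.frame
    sig = wt[(wt["log2FC"] > fc_threshold) & (wt["FDR"] < fdr_threshold)]
    out: set[str] = set()
    missing = []
    for gene, lfc in zip(sig["gene"], sig["log2FC"]):
        if gene in de_mut:
            mut_lfc = de_mut.log2fc(gene)
        else:
            missing.append(gene)
            mut_lfc = 0.0
        if lfc - mut_lfc >= gap:
            out.add(gene)
    if missing:
        warnings.warn(
            f"{len(missing)} induced genes absent from {de_mut.label!r}; "
            "treated as log2FC 0 there",
            stacklevel=2,
        )
    return out


def cpm_filter(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    group_threshold: int = 3,
    dubious_orfs=(),
    mode: str = "groups",
) -> list[str]:
    """Expression prefilter; returns the kept genes in matrix order.

    ``mode="groups"`` (default) removes a gene whose CPM is below the
    threshold in *every sample* of at least ``group_threshold``
    condition groups; ``mode="samples"`` removes a gene below threshold
    in at least ``group_threshold`` individual samples.  Dubious-ORF
    ids are always removed.
    """
    cpm = counts.cpm()
    below = cpm < cpm_threshold
    if mode == "groups":
        group_all_below = pd.DataFrame(
            {
                g: below[counts.samples_in(g)].all(axis=1)
                for g in sorted(set(counts.groups.values()))
            }
        )
        removed = group_all_below.sum(axis=1) >= group_threshold
    elif mode == "samples":
        removed = below.sum(axis=1) >= group_threshold
    else:
        raise ValueError(f"mode must be 'groups' or 'samples', got {mode!r}")
    dubious = set(dubious_orfs)
    return [g for g in counts.genes if not removed[g] and g not in dubious]


def read_fraction(counts: CountMatrix, gene_set, sample_group: str) -> float:
    """Percentage of a group's reads assigned to ``gene_set``."""
    gene_set = set(gene_set)
    missing = gene_set - set(counts.genes)
    if missing:
        warnings.warn(
            f"{len(missing)} genes absent from the count matrix; counted as 0",
            stacklevel=2,
        )
    samples = counts.samples_in(sample_group)
    total = float(counts.counts[samples].values.sum())
    if total <= 0:
        raise ValueError(f"group {sample_group!r} has zero total counts")
    in_set = counts.counts.index.isin(gene_set)
    part = float(counts.counts.loc[in_set, samples].values.sum())
    return 100.0 * part / total


# ---------------------------------------------------------------------
# expression -> enzyme bound perturbations
# ---------------------------------------------------------------------

@dataclass
class PerturbationSet:
    """Per-enzyme usage-bound multipliers derived from fold-changes."""

    multipliers: dict[str, float]
    delta: float = 0.20
    contrast: str = ""
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = {e: m for e, m in self.multipliers.items() if m < 0}
        if bad:
            raise ValueError(f"negative multipliers: {bad}")


def build_perturbation_set(
    de_table: DeTable,
    enzyme_gene_map: dict[str, list[str]],
    deleted_genes=(),
    delta: float = 0.20,
    direction: str = "all",
) -> PerturbationSet:
    """Fold-changes of enzyme-encoding genes to usage-bound multipliers.

    Multiplier is ``2^log2FC`` for genes in the table and 0 for deleted
    genes; an enzyme mapping to several genes takes the minimum
    (conservative bottleneck assumption).  ``direction="down_only"``
    keeps only enzymes with multiplier < 1.  Enzymes whose genes appear
    neither in the table nor in the deletion list are reported in
    ``unmapped`` rather than silently dropped.
    """
    deleted = set(deleted_genes)
    multipliers: dict[str, float] = {}
    unmapped: list[str] = []
    rows = []
    for enzyme, genes in enzyme_gene_map.items():
        per_gene = {}
        for gene in genes:
            if gene in deleted:
                per_gene[gene] = (0.0, float("nan"), True)
            elif gene in de_table:
                per_gene[gene] = (2.0 ** de_table.log2fc(gene), de_table.log2fc(gene), False)
        if not per_gene:
            unmapped.append(enzyme)
            continue
        gene, (mult, lfc, was_deleted) = min(per_gene.items(), key=lambda kv: kv[1][0])
        rows.append(
            {"enzyme": enzyme, "gene": gene, "log2FC": lfc,
             "multiplier": mult, "deleted": was_deleted}
        )
        multipliers[enzyme] = mult
    if direction == "down_only":
        multipliers = {e: m for e, m in multipliers.items() if m < 1.0}
        rows = [r for r in rows if r["enzyme"] in multipliers]
    elif direction != "all":
        raise ValueError(f"direction must be 'all' or 'down_only', got {direction!r}")
    return PerturbationSet(
        multipliers=multipliers,
        delta=delta,
        contrast=de_table.label,
        records=pd.DataFrame(rows, columns=["enzyme", "gene", "log2FC", "multiplier", "deleted"]),
        unmapped=unmapped,
    )


def select_de_enzymes(
    de_table: DeTable,
    enzyme_gene_map: dict[str, list[str]],
    deleted_genes=(),
    fdr_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Restrict an enzyme-gene map to differentially expressed or deleted genes."""
    deleted = set(deleted_genes)
    out = {}
    for enzyme, genes in enzyme_gene_map.items():
        hit = [
            g for g in genes
            if g in deleted or (g in de_table and de_table.fdr(g) < fdr_threshold)
        ]
        if hit:
            out[enzyme] = hit
    return out


# ---------------------------------------------------------------------
# perturbed-growth screen
# ---------------------------------------------------------------------

@dataclass
class ScreenRecord:
    sample_index: int
    status: str  # optimal | infeasible
    mu_max: float = float("nan")
    ethanol_uptake: float = float("nan")
    ngam: float = float("nan")


def apply_perturbation(
    model: EcModel, sample: FluxDistribution, pset: PerturbationSet
) -> EcModel:
    """Cap each perturbed enzyme's usage at its sampled usage x multiplier x (1+delta)."""
    out = model.copy()
    for enzyme, mult in pset.multipliers.items():
        uid = usage_reaction_id(enzyme)
        if uid not in sample.values:
            raise KeyError(f"sample lacks enzyme usage flux {uid!r}")
        r = out.reaction(uid)
        r.upper_bound = sample.values[uid] * mult * (1.0 + pset.delta)
        r.lower_bound = min(r.lower_bound, r.upper_bound)
    return out


def perturbed_growth_screen(
    model: EcModel,
    samples: list[FluxDistribution],
    pset: PerturbationSet,
    growth_delta: float = 0.05,
    carbon_source: str = "ethanol",
) -> list[ScreenRecord]:
    """Maximum growth of the perturbed strain against each sampled background.

    For every sampled reference distribution the enzyme-usage upper
    bounds are capped by the expression multipliers, growth is
    maximized, infeasible samples are flagged (and excluded from
    downstream means), and for feasible samples growth is fixed to the
    computed maximum (+/- ``growth_delta``) before lexicographically
    maximizing carbon-source uptake and then NGAM.

    ``model`` must be the unsampled ec-model; the sole-carbon-source
    environment is applied here (growth is left free, as the screen's
    first objective is to maximize it).
    """
    from .model import reverse_sibling, set_carbon_source

    if model.biomass_id is None or model.ngam_id is None:
        raise ValueError("screen needs biomass and NGAM reactions")
    env = set_carbon_source(model, carbon_source)
    uptake_id = model.carbon_exchange_ids[carbon_source]
    # maximize *net* consumption: an uptake/secretion split pair would
    # otherwise admit an unbounded futile exchange cycle
    uptake_objective = {uptake_id: 1.0}
    sibling = reverse_sibling(model, uptake_id)
    if sibling is not None:
        uptake_objective[sibling] = -1.0
    out: list[ScreenRecord] = []
    for k, sample in enumerate(samples):
        m = apply_perturbation(env, sample, pset)
        fd = fba(m, {model.biomass_id: 1.0}, "max")
        if not fd.optimal:
            out.append(ScreenRecord(k, "infeasible"))
            continue
        mu = fd.objective_value
        fixed = apply_flexible_constraint(m, FlexSpec(model.biomass_id, mu, growth_delta))
        lex = lexicographic_optimize(
            fixed, [(uptake_objective, "max"), ({model.ngam_id: 1.0}, "max")]
        )
        if not lex.optimal:  # pragma: no cover - growth window contains mu
            out.append(ScreenRecord(k, "infeasible"))
            continue
        eth, ngam = lex.info["stage_optima"]
        out.append(ScreenRecord(k, "optimal", mu, eth, ngam))
    return out


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_index": r.sample_index,
                "status": r.status,
                "mu_max": r.mu_max,
                "ethanol_uptake": r.ethanol_uptake,
                "ngam": r.ngam,
            }
            for r in records
        ]
    )
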