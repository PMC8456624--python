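"""In-silico single-enzyme rescue screen and gene-set enrichment.

The rescue experiment asks which expression-constrained enzymes, when
individually released, restore the mutant's mean maximum growth rate to
the reference window (0.22 h^-1 +/- 5% by default).  "Released" means
the enzyme's usage upper bound is restored to the pool-only limit
``P/mw`` — the most the shared enzyme pool could ever allocate to it —
rather than to infinity, staying inside the enzyme-constrained
formulation.  Means are taken over the samples that were feasible in
the perturbed-growth screen.

Rescuer gene sets are then tested for over-representation with an
upper-tail hypergeometric test and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .lp import fba
from .model import EcModel, set_carbon_source, usage_reaction_id
from .transcriptome import (
    PerturbationSet,
    ScreenRecord,
    apply_perturbation,
    perturbed_growth_screen,
)


@dataclass
class RescueRecord:
    enzyme: str
    mean_mu_max: float
    n_samples: int
    rescuer: bool


def single_enzyme_rescue(
    model: EcModel,
    samples,
    pset: PerturbationSet,
    mu_target: float = 0.22,
    delta: float = 0.05,
    screen: list[ScreenRecord] | None = None,
    carbon_source: str = "ethanol",
) -> list[RescueRecord]:
    """Release perturbed enzymes one at a time and recompute max growth.

    For each perturbed enzyme and each feasible sampled background, the
    perturbed model is rebuilt with only that enzyme's usage bound
    restored to the pool-only limit, growth is maximized by FBA, and
    the per-enzyme mean is compared against ``mu_target * (1 - delta)``
    to set the rescuer flag.
    """
    if not pset.multipliers:
        return []
    if screen is None:
        screen = perturbed_growth_screen(model, samples, pset, delta, carbon_source)
    feasible_idx = [r.sample_index for r in screen if r.status == "optimal"]
    env = set_carbon_source(model, carbon_source)
    out: list[RescueRecord] = []
    for enzyme in pset.multipliers:
        mus = []
        for k in feasible_idx:
            m = apply_perturbation(env, samples[k], pset)
            r = m.reaction(usage_reaction_id(enzyme))
            r.upper_bound = m.pool_limit(enzyme)
            fd = fba(m, {model.biomass_id: 1.0}, "max")
            if fd.optimal:
                mus.append(fd.objective_value)
        mean_mu = float(np.mean(mus)) if mus else float("nan")
        out.append(
            RescueRecord(
                enzyme=enzyme,
                mean_mu_max=mean_mu,
                n_samples=len(mus),
                rescuer=bool(mus) and mean_mu >= mu_target * (1.0 - delta),
            )
        )
    return out


def rescue_to_frame(records: list[RescueRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": r.enzyme,
                "mean_mu_max": r.mean_mu_max,
                "n_samples": r.n_samples,
                "rescuer": r.rescuer,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term: str
    description: str
    term_size: int  # |term ∩ universe|
    overlap: int  # |term ∩ query|
    p_value: float
    q_value: float


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT gene sets: term <tab> description <tab> gene ..."""
    sets = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], parts[2:])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, genes) in sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def hypergeometric_enrichment(
    query,
    gene_sets: dict[str, tuple[str, list[str]]],
    universe,
    min_genes: int = 6,
    filter_on: str = "overlap",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test.

    ``p = P(X >= overlap)`` with population ``|universe|``, successes
    ``|term ∩ universe|`` and draws ``|query|``; BH adjustment is
    applied across all tested terms.  Only terms passing the "> 5
    genes" rule are reported — by default terms whose *overlap* with
    the query reaches ``min_genes``; ``filter_on="term"`` applies the
    cut to the term size instead.
    """
    query, universe = set(query), set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders}")
    if filter_on not in ("overlap", "term"):
        raise ValueError(f"filter_on must be 'overlap' or 'term', got {filter_on!r}")
    N, n = len(universe), len(query)
    tested = []
    for term, (desc, genes) in gene_sets.items():
        members = set(genes) & universe
        if not members:
            continue
        K, k = len(members), len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((term, desc, K, k, p))
    if not tested:
        return []
    qvals = multipletests([t[4] for t in tested], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, desc, K, k, p, float(q))
        for (term, desc, K, k, p), q in zip(tested, qvals)
    ]
    keep = (lambda r: r.overlap >= min_genes) if filter_on == "overlap" else (
        lambda r: r.term_size >= min_genes
    )
    return sorted((r for r in results if keep(r)), key=lambda r: (r.p_value, r.term))


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "description": r.description,
                "term_size": r.term_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
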