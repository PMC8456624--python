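"""Random sampling of reference-strain flux distributions.

The reference condition fixes growth on a single carbon source
(ethanol, 0.22 h^-1 +/- 5% by default) and then repeatedly maximizes a
pair of randomly weighted fluxes: two distinct candidate reactions are
drawn uniformly, given independent U(0,1) weights, and the weighted sum
is maximized by FBA.  Each retained sample is therefore a vertex of the
constrained polytope.  Draws consume a single seeded generator in a
fixed order — reaction pair first, then the two weights — so sample
lists are bitwise reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lp import FlexSpec, FluxDistribution, apply_flexible_constraint, fba, feasible
from .model import EcModel, set_carbon_source

log = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    """Raised when the base (unsampled) constraints are already infeasible."""


@dataclass
class SamplingConfig:
    n_samples: int = 1000
    seed: int = 0
    #: reactions eligible as random objectives; default: all but pool_exchange
    candidate_reactions: list[str] | None = None
    growth_value: float = 0.22  # h^-1
    growth_delta: float = 0.05
    carbon_source: str = "ethanol"
    max_redraws: int = 1000

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.growth_delta < 0:
            raise ValueError("growth_delta must be >= 0")


def prepare_reference_model(model: EcModel, config: SamplingConfig) -> EcModel:
    """Sole carbon source + flexibilized growth, the sampling base model."""
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction")
    m = set_carbon_source(model, config.carbon_source)
    return apply_flexible_constraint(
        m, FlexSpec(model.biomass_id, config.growth_value, config.growth_delta)
    )


def sample_flux_distributions(
    model: EcModel, config: SamplingConfig
) -> list[FluxDistribution]:
    """Draw ``config.n_samples`` optimal flux distributions.

    Each distribution's ``info`` records the drawn objective pair and
    weights.  Unbounded draws are rejected and redrawn (with a logged
    count) so that every retained sample is a genuine optimum.
    """
    base = prepare_reference_model(model, config)
    if not feasible(base):
        raise SamplingError(
            f"base constraints infeasible: growth {config.growth_value} "
            f"(+/-{config.growth_delta:.0%}) on {config.carbon_source}"
        )
    candidates = config.candidate_reactions
    if candidates is None:
        candidates = [r.id for r in base.reactions if r.kind != "pool_exchange"]
    if len(candidates) < 2:
        raise SamplingError("need at least two candidate objective reactions")
    rng = np.random.default_rng(config.seed)
    samples: list[FluxDistribution] = []
    n_redrawn = 0
    for k in range(config.n_samples):
        for _attempt in range(config.max_redraws):
            i, j = rng.choice(len(candidates), size=2, replace=False)
            w1, w2 = rng.random(2)
            rid_i, rid_j = candidates[int(i)], candidates[int(j)]
            fd = fba(base, {rid_i: float(w1), rid_j: float(w2)}, "max")
            if fd.status == "unbounded":
                n_redrawn += 1
                continue
            if fd.status != "optimal":
                raise SamplingError(
                    f"draw {k} ({rid_i}, {rid_j}) ended with status {fd.status}"
                )
            fd.info.update(
                sample_index=k,
                objective_reactions=(rid_i, rid_j),
                weights=(float(w1), float(w2)),
            )
            samples.append(fd)
            break
        else:
            raise SamplingError(f"exceeded {config.max_redraws} redraws at sample {k}")
    if n_redrawn:
        log.info("rejected and redrew %d unbounded objective draws", n_redrawn)
    return samples


def samples_to_frame(model: EcModel, samples: list[FluxDistribution]):
    """Reactions x samples matrix (pandas DataFrame) of sampled fluxes."""
    import pandas as pd

    rxn_ids = [r.id for r in model.reactions]
    cols = {f"sample_{fd.info.get('sample_index', k):04d}": [fd.values[r] for r in rxn_ids]
            for k, fd in enumerate(samples)}
    return pd.DataFrame(cols, index=pd.Index(rxn_ids, name="reaction"))
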