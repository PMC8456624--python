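"""Metabolic network data model with GECKO-style enzyme constraints.

An enzyme-constrained model (ecModel) augments an irreversible
stoichiometric network with one pseudo-metabolite per enzyme.  Every
catalysed reaction consumes the pseudo-metabolite of each required
enzyme at ``1/kcat`` per unit flux, and a dedicated *enzyme usage*
reaction produces it while drawing enzyme mass (``mw`` grams per mmol
of enzyme) from a shared pool.  The pool itself is replenished by a
single *pool exchange* reaction whose upper bound is the enzyme pool
parameter ``P`` (g enzyme per gDW); the steady-state condition then
encodes ``sum_i mw_i * e_i <= P``.

Units follow the GECKO convention: fluxes in mmol gDW^-1 h^-1, kcat in
h^-1 (input files may declare per-second values, converted on load),
molecular weights in g mmol^-1 (numerically kDa) and the pool bound in
g gDW^-1.

Serialization is canonical and lossless: keys sorted, floats rendered
with 12 significant digits, so ``save(load(f))`` is byte-identical to
the canonical re-serialization of ``f``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = "ecmodel-v1"

#: Default flux bound used where a file or builder gives none.
DEFAULT_BOUND = 1000.0

VALID_KINDS = frozenset(
    {"metabolic", "exchange", "biomass", "ngam", "enzyme_usage", "pool_exchange"}
)


class ModelParseError(ValueError):
    """Raised when a model file is malformed (names the offending key)."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates an invariant (lists all violations)."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("model validation failed:\n  - " + "\n  - ".join(self.violations))


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class EnzymeLink:
    """Association of a reaction with one enzyme (complex subunit)."""

    enzyme_id: str
    kcat: float  # h^-1


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    kind: str = "metabolic"
    enzymes: list[EnzymeLink] = field(default_factory=list)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class Enzyme:
    id: str
    mw: float  # g mmol^-1 (numerically kDa)
    genes: list[str] = field(default_factory=list)


def usage_reaction_id(enzyme_id: str) -> str:
    """Id of the enzyme-usage reaction created for ``enzyme_id``."""
    return f"usage__{enzyme_id}"


def enzyme_metabolite_id(enzyme_id: str) -> str:
    return f"enz__{enzyme_id}"


POOL_METABOLITE_ID = "enzyme_pool"
POOL_EXCHANGE_ID = "pool_exchange"


@dataclass
class EcModel:
    """A (possibly enzyme-constrained) irreversible metabolic model.

    A plain stoichiometric model is represented with an empty enzyme
    list and ``pool_bound=None``; :func:`to_enzyme_constrained` turns it
    into a full ecModel.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    enzymes: list[Enzyme] = field(default_factory=list)
    pool_bound: float | None = None
    biomass_id: str | None = None
    ngam_id: str | None = None
    carbon_exchange_ids: dict[str, str] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"no metabolite with id {mid!r}")

    def enzyme(self, eid: str) -> Enzyme:
        for e in self.enzymes:
            if e.id == eid:
                return e
        raise KeyError(f"no enzyme with id {eid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    @property
    def is_enzyme_constrained(self) -> bool:
        return bool(self.enzymes)

    def copy(self) -> "EcModel":
        return copy.deepcopy(self)

    # -- numerics ------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus row/column id orders."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        midx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[midx[mid], j] = coef
        return S, met_ids, rxn_ids

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def pool_limit(self, enzyme_id: str) -> float:
        """Usage bound if the whole pool were devoted to one enzyme (P/mw)."""
        if self.pool_bound is None:
            raise ValueError("model has no enzyme pool")
        return self.pool_bound / self.enzyme(enzyme_id).mw

    # -- validation ----------------------------------------------------
    def validate(self, require_irreversible: bool | None = None,
                 require_growth: bool = False) -> None:
        """Check all structural invariants, raising with every violation.

        ``require_irreversible`` defaults to True for enzyme-constrained
        models (the GECKO coupling needs non-negative flux) and False
        for plain models.  ``require_growth`` additionally demands one
        biomass and one NGAM reaction, as growth simulation needs.
        """
        if require_irreversible is None:
            require_irreversible = self.is_enzyme_constrained
        v: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        if any(not m for m in met_ids):
            v.append("empty metabolite id")
        if len(set(met_ids)) != len(met_ids):
            v.append("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            v.append("duplicate reaction ids")
        enz_ids = [e.id for e in self.enzymes]
        if len(set(enz_ids)) != len(enz_ids):
            v.append("duplicate enzyme ids")
        met_set, enz_set = set(met_ids), set(enz_ids)
        for e in self.enzymes:
            if e.mw <= 0:
                v.append(f"enzyme {e.id}: mw must be > 0 (got {e.mw})")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                v.append(
                    f"reaction {r.id}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if require_irreversible and r.lower_bound < 0:
                v.append(f"reaction {r.id}: reversible (lower_bound < 0) in ec model")
            if r.kind not in VALID_KINDS:
                v.append(f"reaction {r.id}: unknown kind {r.kind!r}")
            for mid in r.stoichiometry:
                if mid not in met_set:
                    v.append(f"reaction {r.id}: unknown metabolite {mid!r}")
            for link in r.enzymes:
                if link.enzyme_id not in enz_set:
                    v.append(f"reaction {r.id}: unknown enzyme {link.enzyme_id!r}")
                if link.kcat <= 0:
                    v.append(f"reaction {r.id}: kcat must be > 0 for {link.enzyme_id}")
        for kind, rid in (("biomass", self.biomass_id), ("ngam", self.ngam_id)):
            tagged = [r.id for r in self.reactions if r.kind == kind]
            if len(tagged) > 1:
                v.append(f"more than one reaction of kind={kind}: {tagged}")
            if rid is not None and rid not in rxn_ids:
                v.append(f"{kind}_id {rid!r} not among reactions")
            if rid is not None and tagged and tagged != [rid]:
                v.append(f"{kind}_id {rid!r} does not match kind={kind} reaction {tagged}")
            if require_growth and rid is None:
                v.append(f"model lacks a {kind} reaction but growth simulation needs one")
        if self.is_enzyme_constrained:
            usage_of = {}
            for r in self.reactions:
                if r.kind == "enzyme_usage":
                    for mid, coef in r.stoichiometry.items():
                        if coef > 0 and mid.startswith("enz__"):
                            usage_of.setdefault(mid[len("enz__"):], []).append(r.id)
            for e in self.enzymes:
                n = len(usage_of.get(e.id, []))
                if n != 1:
                    v.append(f"enzyme {e.id}: expected exactly 1 usage reaction, found {n}")
            if not self.has_reaction(POOL_EXCHANGE_ID):
                v.append("enzyme-constrained model lacks a pool_exchange reaction")
            elif self.pool_bound is None:
                v.append("enzyme-constrained model has no pool_bound")
            else:
                pe = self.reaction(POOL_EXCHANGE_ID)
                if abs(pe.upper_bound - self.pool_bound) > 1e-9:
                    v.append(
                        f"pool_exchange upper bound {pe.upper_bound} != "
                        f"pool_bound {self.pool_bound}"
                    )
        if v:
            raise ModelValidationError(v)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema": SCHEMA_VERSION,
            "pool_bound": self.pool_bound,
            "biomass_id": self.biomass_id,
            "ngam_id": self.ngam_id,
            "carbon_exchange_ids": dict(self.carbon_exchange_ids),
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites
            ],
            "enzymes": [
                {"id": e.id, "mw": e.mw, "genes": list(e.genes)} for e in self.enzymes
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "kind": r.kind,
                    "enzymes": [
                        {"id": l.enzyme_id, "kcat": l.kcat, "kcat_unit": "per_hour"}
                        for l in r.enzymes
                    ],
                }
                for r in self.reactions
            ],
        }
        return d

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(canonical_json(self.to_dict()))


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(x) for k, x in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(x) for x in obj]
    return obj


def canonical_json(obj) -> str:
    """Canonical text form: sorted keys, 12-significant-digit floats."""
    return json.dumps(_round_floats(obj), sort_keys=True, indent=2) + "\n"


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ModelParseError(f"missing required key {key!r} in {where}")
    return d[key]


def model_from_dict(data: dict) -> EcModel:
    if not isinstance(data, dict):
        raise ModelParseError("top level of a model file must be a JSON object")
    schema = _require(data, "schema", "top level")
    if schema != SCHEMA_VERSION:
        raise ModelParseError(f"unsupported value for key 'schema': {schema!r}")
    mets = [
        Metabolite(
            id=_require(m, "id", "metabolite"),
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
        )
        for m in _require(data, "metabolites", "top level")
    ]
    enzymes = [
        Enzyme(
            id=_require(e, "id", "enzyme"),
            mw=float(_require(e, "mw", "enzyme")),
            genes=list(e.get("genes", [])),
        )
        for e in data.get("enzymes", [])
    ]
    reactions = []
    for rd in _require(data, "reactions", "top level"):
        rid = _require(rd, "id", "reaction")
        links = []
        for ld in rd.get("enzymes", []):
            kcat = float(_require(ld, "kcat", f"reaction {rid} enzyme link"))
            unit = ld.get("kcat_unit", "per_hour")
            if unit == "per_second":
                kcat *= 3600.0
            elif unit != "per_hour":
                raise ModelParseError(
                    f"unsupported value for key 'kcat_unit' in reaction {rid}: {unit!r}"
                )
            links.append(EnzymeLink(_require(ld, "id", f"reaction {rid} enzyme link"), kcat))
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    k: float(x)
                    for k, x in _require(rd, "stoichiometry", f"reaction {rid}").items()
                },
                lower_bound=float(rd.get("lower_bound", 0.0)),
                upper_bound=float(rd.get("upper_bound", DEFAULT_BOUND)),
                kind=rd.get("kind", "metabolic"),
                enzymes=links,
            )
        )
    pool = data.get("pool_bound")
    model = EcModel(
        metabolites=mets,
        reactions=reactions,
        enzymes=enzymes,
        pool_bound=None if pool is None else float(pool),
        biomass_id=data.get("biomass_id"),
        ngam_id=data.get("ngam_id"),
        carbon_exchange_ids=dict(data.get("carbon_exchange_ids", {})),
    )
    model.validate(require_irreversible=None)
    return model


def load_model(path) -> EcModel:
    """Load and validate a model from the canonical JSON schema."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"malformed JSON in {path}: {exc}") from exc
    return model_from_dict(data)


def save_model(model: EcModel, path) -> None:
    model.save(path)


# ---------------------------------------------------------------------
# structural transformations
# ---------------------------------------------------------------------

def split_reversible(model: EcModel) -> EcModel:
    """Replace every reversible reaction by an irreversible forward/reverse pair.

    ``v in [-a, b]`` becomes ``v_fwd in [0, b]`` and ``v_rev in [0, a]``
    with reversed stoichiometry; the net flux space is unchanged.  Enzyme
    associations are copied to both directions (the same enzyme catalyses
    both).  Already-irreversible reactions are returned as-is.
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    for r in out.reactions:
        if r.lower_bound >= 0:
            new_reactions.append(r)
            continue
        rev_stoich = {m: -c for m, c in r.stoichiometry.items()}
        rev = Reaction(
            id=f"{r.id}_rev",
            stoichiometry=rev_stoich,
            lower_bound=0.0,
            upper_bound=-r.lower_bound,
            kind=r.kind,
            enzymes=copy.deepcopy(r.enzymes),
        )
        if r.upper_bound <= 0:
            new_reactions.append(rev)
            continue
        fwd = Reaction(
            id=f"{r.id}_fwd",
            stoichiometry=dict(r.stoichiometry),
            lower_bound=0.0,
            upper_bound=r.upper_bound,
            kind=r.kind,
            enzymes=copy.deepcopy(r.enzymes),
        )
        new_reactions.extend([fwd, rev])
    out.reactions = new_reactions
    return out


def to_enzyme_constrained(
    model: EcModel, enzymes: list[Enzyme], pool_bound: float = 0.1
) -> EcModel:
    """Augment an irreversible model with GECKO enzyme constraints.

    Each reaction carrying enzyme associations consumes one
    pseudo-metabolite per associated enzyme (complex subunits are listed
    together on one reaction; isozymes are expressed as parallel
    reaction copies, one per enzyme).  Usage reactions are bounded above
    by the pool-only limit ``pool_bound / mw``.
    """
    for r in model.reactions:
        if r.lower_bound < 0:
            raise ValueError(
                f"reaction {r.id} is reversible; run split_reversible() first"
            )
        for link in r.enzymes:
            if link.kcat <= 0:
                raise ValueError(
                    f"reaction {r.id}: kcat must be > 0 for enzyme {link.enzyme_id}"
                )
    out = model.copy()
    out.enzymes = copy.deepcopy(enzymes)
    out.pool_bound = float(pool_bound)
    enz_by_id = {e.id: e for e in out.enzymes}
    used = set()
    for r in out.reactions:
        for link in r.enzymes:
            if link.enzyme_id not in enz_by_id:
                raise ModelValidationError(
                    [f"reaction {r.id} references unknown enzyme {link.enzyme_id!r}"]
                )
            r.stoichiometry[enzyme_metabolite_id(link.enzyme_id)] = (
                r.stoichiometry.get(enzyme_metabolite_id(link.enzyme_id), 0.0)
                - 1.0 / link.kcat
            )
            used.add(link.enzyme_id)
    out.metabolites.extend(
        Metabolite(enzyme_metabolite_id(e.id), name=f"enzyme {e.id}", compartment="enzyme")
        for e in out.enzymes
    )
    out.metabolites.append(
        Metabolite(POOL_METABOLITE_ID, name="shared enzyme pool", compartment="enzyme")
    )
    for e in out.enzymes:
        cap = pool_bound / e.mw if pool_bound > 0 else 0.0
        out.reactions.append(
            Reaction(
                id=usage_reaction_id(e.id),
                stoichiometry={
                    enzyme_metabolite_id(e.id): 1.0,
                    POOL_METABOLITE_ID: -e.mw,
                },
                lower_bound=0.0,
                upper_bound=cap,
                kind="enzyme_usage",
            )
        )
    out.reactions.append(
        Reaction(
            id=POOL_EXCHANGE_ID,
            stoichiometry={POOL_METABOLITE_ID: 1.0},
            lower_bound=0.0,
            upper_bound=float(pool_bound),
            kind="pool_exchange",
        )
    )
    out.validate()
    return out


def reverse_sibling(model: EcModel, reaction_id: str) -> str | None:
    """Id of the reverse copy of a split reversible reaction, if any."""
    if reaction_id.endswith("_fwd"):
        rev = reaction_id[: -len("_fwd")] + "_rev"
        if model.has_reaction(rev):
            return rev
    return None


def set_carbon_source(model: EcModel, source: str) -> EcModel:
    """Close the uptake of every registered carbon source except ``source``."""
    if source not in model.carbon_exchange_ids:
        raise KeyError(
            f"unknown carbon source {source!r}; known: {sorted(model.carbon_exchange_ids)}"
        )
    out = model.copy()
    for name, rid in out.carbon_exchange_ids.items():
        if name != source:
            r = out.reaction(rid)
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out
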