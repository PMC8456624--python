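"""Model data structures, GECKO augmentation, and canonical serialization."""

import json

import numpy as np
import pytest

from ecflux.lp import fba
from ecflux.model import (
    EcModel,
    Enzyme,
    EnzymeLink,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    canonical_json,
    load_model,
    split_reversible,
    to_enzyme_constrained,
    usage_reaction_id,
)
from oracles import lp_vertex_optimum, model_arrays


def test_save_load_roundtrip_is_byte_identical(chain_model, tmp_path):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    chain_model.save(p1)
    reloaded = load_model(p1)
    reloaded.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert reloaded.to_dict() == chain_model.to_dict()


def test_load_is_canonical_form_of_arbitrary_key_order(tmp_path):
    raw = {
        "reactions": [{"stoichiometry": {"A": 1.0}, "id": "EX_A",
                       "upper_bound": 5, "lower_bound": 0, "kind": "exchange"}],
        "metabolites": [{"compartment": "c", "id": "A", "name": "A"}],
        "schema": "ecmodel-v1",
    }
    p = tmp_path / "m.json"
    p.write_text(json.dumps(raw))
    model = load_model(p)
    out = tmp_path / "canon.json"
    model.save(out)
    assert out.read_text() == canonical_json(model.to_dict())


def test_bound_inversion_is_a_validation_error_naming_the_reaction():
    model = EcModel(
        metabolites=[Metabolite("A")],
        reactions=[Reaction("BAD", {"A": 1.0}, 3.0, 1.0)],
    )
    with pytest.raises(ModelValidationError, match="BAD"):
        model.validate()


def test_validation_collects_all_violations():
    model = EcModel(
        metabolites=[Metabolite("A"), Metabolite("A")],
        reactions=[Reaction("BAD", {"A": 1.0, "MISSING": 1.0}, 3.0, 1.0)],
    )
    with pytest.raises(ModelValidationError) as err:
        model.validate()
    assert len(err.value.violations) >= 3


def test_malformed_json_and_missing_keys_name_the_problem(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text("{not json")
    with pytest.raises(ModelParseError, match="malformed JSON"):
        load_model(p)
    p.write_text(json.dumps({"schema": "ecmodel-v1", "metabolites": []}))
    with pytest.raises(ModelParseError, match="'reactions'"):
        load_model(p)


def test_per_second_kcats_are_converted_on_load(single_enzyme_ec, tmp_path):
    p = tmp_path / "m.json"
    single_enzyme_ec.save(p)
    raw = json.loads(p.read_text())
    for r in raw["reactions"]:
        for link in r["enzymes"]:
            link["kcat"] /= 3600.0
            link["kcat_unit"] = "per_second"
    p.write_text(json.dumps(raw))
    model = load_model(p)
    assert model.reaction("CAT").enzymes[0].kcat == pytest.approx(360000.0)


class TestSplitReversible:
    def test_reversible_reaction_becomes_forward_reverse_pair(self):
        model = EcModel(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R", {"A": -1.0, "B": 1.0}, -5.0, 10.0)],
        )
        out = split_reversible(model)
        fwd, rev = out.reaction("R_fwd"), out.reaction("R_rev")
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
        assert (rev.lower_bound, rev.upper_bound) == (0.0, 5.0)
        assert rev.stoichiometry == {"A": 1.0, "B": -1.0}

    def test_irreversible_model_is_unchanged(self, chain_model):
        out = split_reversible(chain_model)
        assert [r.id for r in out.reactions] == [r.id for r in chain_model.reactions]

    def test_fba_optimum_is_invariant_under_splitting(self):
        # 4-reaction toy with one reversible internal reaction
        model = EcModel(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[
                Reaction("EX_A", {"A": 1.0}, 0.0, 6.0, "exchange"),
                Reaction("R", {"A": -1.0, "B": 1.0}, -4.0, 9.0),
                Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, "exchange"),
                Reaction("EX_B_in", {"B": 1.0}, 0.0, 3.0, "exchange"),
            ],
        )
        split = split_reversible(model)
        S, lb, ub, rxn_ids = model_arrays(model)
        c = np.array([0.0 if r != "EX_B" else 1.0 for r in rxn_ids])
        oracle = lp_vertex_optimum(S, lb, ub, c, "max")
        got = fba(split, {"EX_B": 1.0}, "max")
        assert got.objective_value == pytest.approx(oracle, abs=1e-9)


class TestEnzymeConstraints:
    def test_pool_limited_flux_matches_closed_form(self, single_enzyme_ec):
        # v <= kcat * e and mw * e <= P give v_max = kcat * P / mw = 720
        fd = fba(single_enzyme_ec, {"CAT": 1.0}, "max")
        assert fd.objective_value == pytest.approx(720.0, rel=1e-6)

    def test_pool_is_tight_at_the_pool_limited_optimum(self, single_enzyme_ec):
        fd = fba(single_enzyme_ec, {"CAT": 1.0}, "max")
        usage = fd.values[usage_reaction_id("E1")]
        assert 50.0 * usage == pytest.approx(0.1, abs=1e-6)

    def test_zero_pool_kills_catalysed_flux_but_not_spontaneous(self):
        plain = EcModel(
            metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
            reactions=[
                Reaction("EX_in", {"A": 1.0}, 0.0, 10.0, "exchange"),
                Reaction("CAT", {"A": -1.0, "B": 1.0}, 0.0, 100.0, "metabolic",
                         [EnzymeLink("E1", 1000.0)]),
                Reaction("SPONT", {"A": -1.0, "C": 1.0}, 0.0, 100.0),
                Reaction("EX_B", {"B": -1.0}, 0.0, 100.0, "exchange"),
                Reaction("EX_C", {"C": -1.0}, 0.0, 100.0, "exchange"),
            ],
        )
        ec = to_enzyme_constrained(plain, [Enzyme("E1", 10.0)], pool_bound=0.0)
        assert fba(ec, {"EX_B": 1.0}, "max").objective_value == pytest.approx(0.0, abs=1e-9)
        assert fba(ec, {"EX_C": 1.0}, "max").objective_value == pytest.approx(10.0)

    def test_doubling_kcats_doubles_a_pool_limited_optimum(self):
        def build(kcat):
            plain = EcModel(
                metabolites=[Metabolite("A"), Metabolite("B")],
                reactions=[
                    Reaction("EX_in", {"A": 1.0}, 0.0, 1e6, "exchange"),
                    Reaction("CAT", {"A": -1.0, "B": 1.0}, 0.0, 1e6, "metabolic",
                             [EnzymeLink("E1", kcat)]),
                    Reaction("EX_out", {"B": -1.0}, 0.0, 1e6, "exchange"),
                ],
            )
            return to_enzyme_constrained(plain, [Enzyme("E1", 50.0)], 0.1)

        v1 = fba(build(360000.0), {"EX_out": 1.0}, "max").objective_value
        v2 = fba(build(720000.0), {"EX_out": 1.0}, "max").objective_value
        assert v2 == pytest.approx(2.0 * v1, rel=1e-9)

    def test_nonpositive_kcat_is_rejected(self):
        plain = EcModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("R", {"A": -1.0}, 0.0, 1.0, "metabolic",
                                [EnzymeLink("E1", 0.0)])],
        )
        with pytest.raises(ValueError, match="kcat"):
            to_enzyme_constrained(plain, [Enzyme("E1", 10.0)], 0.1)

    def test_reversible_input_is_rejected(self):
        plain = EcModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("R", {"A": -1.0}, -1.0, 1.0)],
        )
        with pytest.raises(ValueError, match="split_reversible"):
            to_enzyme_constrained(plain, [], 0.1)

    def test_huge_pool_recovers_the_unconstrained_polytope(self, tradeoff_model):
        # 10 random objectives: ec-model with an effectively unlimited
        # pool must reproduce every plain-model FBA optimum
        plain = tradeoff_model.copy()
        plain.reaction("R1").enzymes = [EnzymeLink("E1", 100.0)]
        plain.reaction("R2").enzymes = [EnzymeLink("E2", 100.0)]
        ec = to_enzyme_constrained(
            plain, [Enzyme("E1", 1.0), Enzyme("E2", 1.0)], pool_bound=1e9
        )
        rng = np.random.default_rng(0)
        rxns = [r.id for r in tradeoff_model.reactions]
        for _ in range(10):
            w = {rid: float(x) for rid, x in zip(rxns, rng.random(len(rxns)))}
            expect = fba(tradeoff_model, w, "max").objective_value
            got = fba(ec, w, "max").objective_value
            assert got == pytest.approx(expect, rel=1e-7, abs=1e-7)
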