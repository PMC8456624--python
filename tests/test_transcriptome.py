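"""DE parsing, the poorly-induced classifier, CPM filtering, read
fractions, and the perturbed-growth screen."""

import numpy as np
import pandas as pd
import pytest

from ecflux.model import set_carbon_source, usage_reaction_id
from ecflux.lp import fba
from ecflux.synthetic import simulate_de_tables
from ecflux.transcriptome import (
    CountMatrix,
    DeTable,
    PerturbationSet,
    apply_perturbation,
    build_perturbation_set,
    classify_poorly_induced,
    cpm_filter,
    perturbed_growth_screen,
    read_fraction,
)


def de(label, rows):
    return DeTable(label, pd.DataFrame(rows, columns=["gene", "log2FC", "FDR"]))


class TestClassifier:
    def test_definition_and_strict_boundaries(self):
        wt = de("wt", [("g1", 2.0, 0.001), ("g2", 1.0, 0.001), ("g3", 2.0, 0.01),
                       ("g4", 2.0, 0.001)])
        mut = de("mut", [("g1", 0.5, 0.5), ("g2", -1.0, 0.5), ("g3", 0.0, 0.5),
                         ("g4", 1.5, 0.5)])
        got = classify_poorly_induced(wt, mut)
        # g1: induced and attenuated by 1.5 -> in.  g2: log2FC exactly 1
        # (strict >) -> out.  g3: FDR exactly 0.01 (strict <) -> out.
        # g4: gap 0.5 < 1 -> out.
        assert got == {"g1"}

    def test_gene_missing_from_mutant_counts_as_not_induced(self):
        wt = de("wt", [("g1", 2.0, 0.001)])
        mut = de("mut", [("other", 0.0, 0.9)])
        with pytest.warns(UserWarning, match="absent"):
            assert classify_poorly_induced(wt, mut) == {"g1"}

    def test_empty_tables_warn_and_return_empty(self):
        empty = de("wt", [])
        with pytest.warns(UserWarning, match="empty"):
            assert classify_poorly_induced(empty, empty) == set()

    def test_raising_the_gap_only_shrinks_the_set(self, scenario):
        wt, mut, _ = simulate_de_tables(scenario)
        sets = [classify_poorly_induced(wt, mut, gap=g) for g in (0.5, 1.0, 1.5, 2.5)]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_recovers_exactly_the_planted_set(self, scenario):
        wt, mut, truth = simulate_de_tables(scenario)
        assert classify_poorly_induced(wt, mut) == set(truth["poorly_induced"])

    def test_fdr_outside_unit_interval_is_rejected(self):
        with pytest.raises(ValueError, match="FDR"):
            de("wt", [("g1", 1.0, 1.5)])


def toy_counts():
    # 6 genes x 4 groups x 2 samples; library sizes 100 -> CPM = count * 1e4
    counts = pd.DataFrame(
        {
            "s1": [50, 30, 10, 5, 5, 0], "s2": [45, 35, 10, 5, 5, 0],
            "s3": [90, 0, 5, 0, 5, 0], "s4": [85, 0, 10, 0, 5, 0],
            "s5": [60, 20, 10, 5, 5, 0], "s6": [60, 20, 10, 5, 5, 0],
            "s7": [70, 10, 10, 5, 5, 0], "s8": [70, 10, 10, 5, 5, 0],
        },
        index=pd.Index([f"g{i}" for i in range(1, 7)], name="gene"),
    )
    groups = {s: f"grp{(i // 2) + 1}" for i, s in enumerate(counts.columns)}
    return CountMatrix(counts, groups)


class TestCpmFilter:
    def test_hand_computed_toy_matrix(self):
        cm = toy_counts()
        # g6: zero everywhere -> below 1 CPM in all 4 groups -> removed;
        # g2: zero in only one group -> kept; others well expressed
        kept = cpm_filter(cm, cpm_threshold=1.0, group_threshold=3)
        assert kept == ["g1", "g2", "g3", "g4", "g5"]

    def test_threshold_counts_groups_not_samples(self):
        cm = toy_counts()
        # with the per-sample interpretation, g4's two zero samples and
        # g2's two zero samples matter at group_threshold=2
        kept_groups = cpm_filter(cm, group_threshold=2, mode="groups")
        kept_samples = cpm_filter(cm, group_threshold=2, mode="samples")
        assert "g2" in kept_groups and "g4" in kept_groups
        assert "g2" not in kept_samples and "g4" not in kept_samples

    def test_high_expression_always_kept_and_dubious_always_removed(self):
        cm = toy_counts()
        kept = cpm_filter(cm, dubious_orfs=["g1"])
        assert "g1" not in kept and "g3" in kept

    def test_unknown_sample_group_is_an_error(self):
        counts = toy_counts().counts
        with pytest.raises(ValueError, match="without a condition group"):
            CountMatrix(counts, {"s1": "grp1"})


class TestReadFraction:
    def test_simple_fraction_and_conservation(self):
        cm = toy_counts()
        # grp2 = s3 + s4: g1 carries 90 + 85 of the 200 reads
        assert read_fraction(cm, ["g1"], "grp2") == pytest.approx(87.5)
        assert read_fraction(cm, cm.genes, "grp1") == pytest.approx(100.0)

    def test_partition_sums_to_one_hundred(self):
        cm = toy_counts()
        parts = [["g1", "g2"], ["g3", "g4"], ["g5", "g6"]]
        total = sum(read_fraction(cm, p, "grp3") for p in parts)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_missing_genes_warn_and_zero_group_errors(self):
        cm = toy_counts()
        with pytest.warns(UserWarning, match="absent"):
            assert read_fraction(cm, ["nope"], "grp1") == 0.0
        zero = CountMatrix(cm.counts * 0, cm.groups)
        with pytest.raises(ValueError, match="zero total"):
            read_fraction(zero, ["g1"], "grp1")


class TestPerturbationSet:
    def test_fold_change_to_multiplier(self):
        table = de("c", [("gA", -1.0, 0.001), ("gB", 2.0, 0.001), ("gC", 0.0, 0.001)])
        pset = build_perturbation_set(
            table,
            {"EA": ["gA"], "EB": ["gB"], "EC": ["gC", "gDel"], "ED": ["gDel"]},
            deleted_genes=["gDel"],
        )
        assert pset.multipliers["EA"] == pytest.approx(0.5)
        assert pset.multipliers["EB"] == pytest.approx(4.0)
        # multi-gene enzyme takes the minimum (deletion wins)
        assert pset.multipliers["EC"] == 0.0
        assert pset.multipliers["ED"] == 0.0
        assert bool(pset.records.set_index("enzyme").at["ED", "deleted"]) is True

    def test_unmapped_enzymes_are_reported_not_dropped(self):
        table = de("c", [("gA", -1.0, 0.001)])
        pset = build_perturbation_set(table, {"EA": ["gA"], "EX": ["unknown"]})
        assert pset.unmapped == ["EX"]
        assert "EX" not in pset.multipliers

    def test_down_only_drops_upregulated_enzymes(self):
        table = de("c", [("gA", -1.0, 0.001), ("gB", 2.0, 0.001)])
        pset = build_perturbation_set(table, {"EA": ["gA"], "EB": ["gB"]},
                                      direction="down_only")
        assert set(pset.multipliers) == {"EA"}


class TestPerturbedGrowthScreen:
    def test_neutral_multipliers_never_infeasible(self, core_model, reference_samples):
        pset = PerturbationSet({e.id: 1.0 for e in core_model.enzymes}, delta=0.2)
        records = perturbed_growth_screen(core_model, reference_samples[:25], pset)
        assert all(r.status == "optimal" for r in records)
        for r, fd in zip(records, reference_samples):
            # the sample's own flux pattern stays feasible
            assert r.mu_max >= fd.values["BIOMASS"] - 1e-6

    def test_deleting_the_ethanol_gateway_abolishes_growth(
        self, core_model, reference_samples
    ):
        pset = PerturbationSet({"ACS1x": 0.0}, delta=0.2)
        records = perturbed_growth_screen(core_model, reference_samples[:5], pset)
        assert all(r.mu_max == pytest.approx(0.0, abs=1e-8) for r in records)

    def test_planted_bottleneck_lowers_growth_and_ethanol_uptake(
        self, core_model, reference_samples, perturbation_set, screen_records
    ):
        neutral = PerturbationSet({e: 1.0 for e in perturbation_set.multipliers},
                                  delta=perturbation_set.delta)
        base = perturbed_growth_screen(core_model, reference_samples[:40], neutral)
        pert = screen_records[:40]
        assert np.mean([r.mu_max for r in pert]) < np.mean([r.mu_max for r in base])
        assert np.mean([r.ethanol_uptake for r in pert]) < np.mean(
            [r.ethanol_uptake for r in base]
        )

    def test_growth_is_monotone_in_the_bottleneck_multiplier(
        self, core_model, reference_samples
    ):
        mus = []
        for mult in (0.1, 0.5, 1.0):
            pset = PerturbationSet({"ACS1x": mult}, delta=0.2)
            records = perturbed_growth_screen(core_model, reference_samples[:5], pset)
            mus.append(np.mean([r.mu_max for r in records]))
        assert mus[0] <= mus[1] + 1e-9 <= mus[2] + 2e-9

    def test_sample_without_usage_fluxes_is_an_error(self, core_model):
        from ecflux.lp import FluxDistribution

        bogus = FluxDistribution({"BIOMASS": 0.2}, 0.2, "optimal")
        with pytest.raises(KeyError, match="usage"):
            apply_perturbation(core_model, bogus, PerturbationSet({"ACS1x": 1.0}))
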