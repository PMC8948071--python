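"""Association rules R1-R3, ambiguity clades, and the two-tier workflow."""

import numpy as np
import pytest

from barcode_associate.associate import (
    AssociationConfig,
    associate_all,
    monophyly,
    reference_specimens,
    results_table,
    rule_R1,
    rule_R2,
    rule_R3,
    two_tier_workflow,
)
from barcode_associate.distmat import DistanceMatrix, build_matrix
from barcode_associate.njtree import nj
from barcode_associate.records import Dataset
from barcode_associate.synthgen import SimulationConfig, evaluate_recovery, simulate_dataset
from barcode_associate.tree import PhyloTree

from conftest import make_record


def tree_of(newick: str) -> PhyloTree:
    return PhyloTree.from_newick(newick)


def dm_of(ids, D):
    D = np.asarray(D, dtype=float)
    return DistanceMatrix(list(ids), D, np.full_like(D, 100, dtype=int), "k2p")


def refs_of(*pairs):
    return [make_record(sid, "A" * 10, species=sp) for sid, sp in pairs]


class TestMonophyly:
    def test_clade_and_non_clade(self):
        t = tree_of("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        assert monophyly(t, {"A1", "A2"})[0]
        t2 = tree_of("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        assert not monophyly(t2, {"A1", "A2"})[0]

    def test_singleton_and_near_full_subsets_trivially_true(self):
        t = tree_of("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        assert monophyly(t, {"A1"}) == (True, None)
        assert monophyly(t, {"A1", "A2", "B1"})[0]  # complement is one leaf
        assert monophyly(t, {"A1", "A2", "B1", "B2"}) == (True, None)

    def test_support_returned_when_annotated(self):
        t = tree_of("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        t.support[t.canonical_split({"B1", "B2"})] = 91.0
        assert monophyly(t, {"B1", "B2"}) == (True, 91.0)

    def test_missing_leaves_rejected(self):
        t = tree_of("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        with pytest.raises(KeyError):
            monophyly(t, {"A1", "zz"})


class TestRuleR1:
    def test_identical_to_one_species(self):
        dm = dm_of(["u", "m1", "m2"], [[0, 0, 0.05], [0, 0, 0.05], [0.05, 0.05, 0]])
        res = rule_R1("u", dm, refs_of(("m1", "X"), ("m2", "Y")))
        assert res.status == "associated"
        assert res.assigned_species == "X" and res.rule == "R1_identical"

    def test_no_zero_distance_no_fire(self):
        dm = dm_of(["u", "m1"], [[0, 0.003], [0.003, 0]])
        assert rule_R1("u", dm, refs_of(("m1", "X"))) is None

    def test_identical_to_two_species_is_ambiguous(self):
        dm = dm_of(["u", "m1", "m2"], [[0, 0, 0], [0, 0, 0], [0, 0, 0]])
        res = rule_R1("u", dm, refs_of(("m1", "X"), ("m2", "Y")))
        assert res.status == "ambiguous" and res.assigned_species is None


class TestRuleR2:
    def test_near_identical_single_species(self):
        ids = ["u", "m1", "m2", "m3"]
        D = np.array([
            [0, 0.004, 0.009, 0.06],
            [0.004, 0, 0.006, 0.06],
            [0.009, 0.006, 0, 0.06],
            [0.06, 0.06, 0.06, 0],
        ])
        res = rule_R2("u", dm_of(ids, D), refs_of(("m1", "X"), ("m2", "X"), ("m3", "Y")), 0.02)
        assert res.status == "associated" and res.assigned_species == "X"
        assert res.evidence["min_distance"] == pytest.approx(0.004)

    def test_empty_neighborhood_no_fire(self):
        dm = dm_of(["u", "m1"], [[0, 0.05], [0.05, 0]])
        assert rule_R2("u", dm, refs_of(("m1", "X")), 0.02) is None

    def test_mixed_neighborhood_is_ambiguous(self):
        dm = dm_of(
            ["u", "m1", "m2"],
            [[0, 0.01, 0.015], [0.01, 0, 0.02], [0.015, 0.02, 0]],
        )
        res = rule_R2("u", dm, refs_of(("m1", "X"), ("m2", "Y")), 0.02)
        assert res.status == "ambiguous"

    def test_r1_implies_r2_with_same_species(self):
        dm = dm_of(["u", "m1"], [[0, 0.0], [0.0, 0]])
        refs = refs_of(("m1", "X"))
        r1 = rule_R1("u", dm, refs)
        r2 = rule_R2("u", dm, refs, 0.02)
        assert r1.assigned_species == r2.assigned_species == "X"


class TestRuleR3:
    NJ = "((u:1,(X1:1,X2:1)90:1)80:1,((Y1:1,Y2:1)95:1,Z1:2):1);"
    ML = "((u:1,(X1:1,X2:1)88:1)70:1,((Y1:1,Y2:1)93:1,Z1:2):1);"
    LABELS = {"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y", "Z1": "Z", "u": "UNKNOWN"}
    REFS = refs_of(("X1", "X"), ("X2", "X"), ("Y1", "Y"), ("Y2", "Y"), ("Z1", "Z"))

    def test_nested_in_supported_clade_on_both_trees(self):
        res = rule_R3("u", tree_of(self.NJ), tree_of(self.ML), self.LABELS, self.REFS, 50)
        assert res.status == "associated" and res.assigned_species == "X"
        assert res.evidence["support_nj"] == 80.0

    def test_discordant_trees_block_assignment(self):
        ml = tree_of("((u:1,(Y1:1,Y2:1)90:1)80:1,((X1:1,X2:1)95:1,Z1:2):1);")
        res = rule_R3("u", tree_of(self.NJ), ml, self.LABELS, self.REFS, 50)
        assert res is None or res.status != "associated"

    def test_support_gate_blocks_weak_clades(self):
        nj_weak = "((u:1,(X1:1,X2:1)90:1)30:1,((Y1:1,Y2:1)95:1,Z1:2):1);"
        ml_weak = "((u:1,(X1:1,X2:1)88:1)20:1,((Y1:1,Y2:1)93:1,Z1:2):1);"
        res = rule_R3("u", tree_of(nj_weak), tree_of(ml_weak), self.LABELS, self.REFS, 50)
        assert res.status == "ambiguous"
        # a lower gate admits the same clade
        res2 = rule_R3("u", tree_of(nj_weak), tree_of(ml_weak), self.LABELS, self.REFS, 20)
        assert res2.status == "associated"

    def test_unknown_absent_from_tree_is_fatal(self):
        with pytest.raises(KeyError):
            rule_R3("ghost", tree_of(self.NJ), tree_of(self.ML), self.LABELS, self.REFS, 50)


class TestAssociateAll:
    def _pipeline(self, seed=0, scenario="clean_gap", **kw):
        cfg = SimulationConfig(
            n_species=6, specimens_per_species=(3, 5), fraction_unknown=0.25,
            scenario=scenario, seed=seed, **kw,
        )
        ds, truth = simulate_dataset(cfg)
        acfg = AssociationConfig(nj_replicates=40, ml_replicates=0, seed=seed)
        from barcode_associate.associate import analyze_tier

        return ds, truth, analyze_tier(ds, acfg)

    def test_no_unknowns_gives_empty_results(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(2, 3),
                               fraction_unknown=0.0, seed=1)
        ds, _ = simulate_dataset(cfg)
        dm = build_matrix(ds, "k2p")
        assert associate_all(ds, dm, None, None) == []

    def test_clean_gap_all_recovered(self):
        ds, truth, tier = self._pipeline(seed=2)
        rec = evaluate_recovery(tier.results, truth)
        assert rec.sensitivity == 1.0
        assert rec.false_assignment_rate == 0.0

    def test_no_unknown_assigned_to_two_species(self):
        ds, truth, tier = self._pipeline(seed=3)
        for r in tier.results:
            assert (r.status == "associated") == (
                r.assigned_species is not None and r.rule is not None
            )

    def test_record_order_invariance(self):
        cfg = SimulationConfig(n_species=5, specimens_per_species=(3, 4),
                               fraction_unknown=0.3, seed=4)
        ds, _ = simulate_dataset(cfg)
        acfg = AssociationConfig(nj_replicates=20, ml_replicates=0, seed=4)
        from barcode_associate.associate import analyze_tier

        t1 = analyze_tier(ds, acfg)
        shuffled = Dataset(list(reversed(ds.records)), tier_tag=ds.tier_tag)
        t2 = analyze_tier(shuffled, acfg)
        v1 = {r.specimen_id: (r.status, r.assigned_species, r.ambiguity_clade) for r in t1.results}
        v2 = {r.specimen_id: (r.status, r.assigned_species, r.ambiguity_clade) for r in t2.results}
        assert v1 == v2

    def test_co_located_unknowns_form_one_lettered_clade(self):
        # two unknowns of an unsampled species: no references anywhere near
        cfg = SimulationConfig(n_species=6, specimens_per_species=(3, 4),
                               fraction_unknown=0.0, seed=6)
        ds, truth = simulate_dataset(cfg)
        # unlabel every specimen of one species, including its male
        victim = "sp06"
        recs = [
            r.with_species("UNKNOWN") if r.species_label == victim else r
            for r in ds.records
        ]
        ds2 = Dataset(recs)
        from barcode_associate.associate import analyze_tier

        tier = analyze_tier(ds2, AssociationConfig(nj_replicates=20, ml_replicates=0, seed=6))
        orphan = [r for r in tier.results if r.specimen_id.startswith(victim)]
        assert len(orphan) >= 2
        letters = {r.ambiguity_clade for r in orphan}
        assert len(letters) == 1 and letters != {None}
        assert all(r.status in ("ambiguous", "unassociated") for r in orphan)

    def test_results_table_shape(self):
        ds, truth, tier = self._pipeline(seed=7)
        table = results_table(tier.results)
        assert list(table.columns)[:4] == ["specimen_id", "status", "species", "rule"]
        assert len(table) == len(truth.unknown_ids)


class TestReferenceSet:
    def test_males_only_by_default(self):
        ds = Dataset(
            [
                make_record("m", "A" * 10, species="X", stage="male"),
                make_record("f", "A" * 10, species="X", stage="female"),
                make_record("l", "A" * 10, species="X", stage="larva"),
                make_record("u", "A" * 10, species="UNKNOWN", stage="larva"),
            ]
        )
        assert [r.specimen_id for r in reference_specimens(ds)] == ["m"]
        assert [r.specimen_id for r in reference_specimens(ds, include_females=True)] == ["m", "f"]


class TestTwoTier:
    def test_agreeing_tiers_confirm_association(self):
        cfg = SimulationConfig(n_species=8, specimens_per_species=(4, 5),
                               fraction_unknown=0.2, seed=8)
        ds, truth = simulate_dataset(cfg)
        acfg = AssociationConfig(nj_replicates=40, ml_replicates=0, seed=8)
        report = two_tier_workflow(ds, acfg)
        rec = evaluate_recovery(report.final, truth)
        assert rec.sensitivity == 1.0
        assert rec.false_assignment_rate == 0.0
        # confirmed unknowns carry the filtered tier tag
        for r in report.final:
            if r.status == "associated":
                assert r.tier in ("east", "west")

    def test_filtered_tiers_partition_by_region(self):
        cfg = SimulationConfig(n_species=8, specimens_per_species=(4, 5),
                               fraction_unknown=0.2, seed=9)
        ds, _ = simulate_dataset(cfg)
        acfg = AssociationConfig(nj_replicates=30, ml_replicates=0, seed=9)
        report = two_tier_workflow(ds, acfg)
        for region, tier in report.filtered.items():
            assert all(r.region == region for r in tier.dataset.records)

    def test_rejects_non_pooled_input(self):
        cfg = SimulationConfig(n_species=4, specimens_per_species=(3, 3),
                               fraction_unknown=0.0, seed=10)
        ds, _ = simulate_dataset(cfg)
        east = Dataset([r for r in ds.records if r.region == "east"], tier_tag="east")
        with pytest.raises(ValueError):
            two_tier_workflow(east, AssociationConfig())
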