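"""Dollo/Fitch loss mapping, event tabulation, and the packaged fixture."""

import numpy as np
import pytest

from obpscaffold.loss_parsimony import (
    LOSS_FIXTURE_SHA256,
    infer_losses,
    load_event_fixture,
    tabulate_events,
)
from obpscaffold.msa_profile import CysteineProfile

from conftest import (
    dollo_minimum_bruteforce,
    make_tree,
    random_tree,
    single_character_profiles,
)


def quartet():
    return make_tree("((A,B),(C,D));")


class TestInferLosses:
    def test_single_clade_single_event(self):
        profiles = single_character_profiles({"A": False, "B": False, "C": True, "D": True})
        events = infer_losses(quartet(), profiles)
        assert len(events) == 1
        assert events[0].lost == {"C1"}
        assert events[0].affected_genes == ("A", "B")

    def test_scattered_absences_need_two_events(self):
        states = {"A": False, "B": True, "C": False, "D": True}
        profiles = single_character_profiles(states)
        events = infer_losses(quartet(), profiles)
        assert len(events) == 2
        assert dollo_minimum_bruteforce(quartet(), states) == 2

    def test_joint_losses_merge_into_one_event(self):
        profiles = []
        for sid in "ABCD":
            absent = sid in "AB"
            present = (True, not absent, True, True, not absent, True)
            profiles.append(CysteineProfile(sid, present, (False,) * 6, 0))
        events = infer_losses(quartet(), profiles)
        assert len(events) == 1
        assert events[0].lost == {"C2", "C5"}
        assert events[0].affected_genes == ("A", "B")

    def test_rootmost_placement_groups_all_descendants(self):
        # all four leaves absent: one loss at the root, not four at the tips
        profiles = single_character_profiles({s: False for s in "ABCD"})
        events = infer_losses(quartet(), profiles)
        assert len(events) == 1
        assert events[0].affected_genes == ("A", "B", "C", "D")

    def test_unknown_leaves_excluded_per_character(self):
        # C is unknown at C1: a single event above (A,B) still explains all
        profiles = single_character_profiles({"A": False, "B": False, "C": None, "D": True})
        events = infer_losses(quartet(), profiles)
        assert len(events) == 1
        assert events[0].affected_genes == ("A", "B")

    def test_leaf_profile_mismatch_lists_difference(self):
        profiles = single_character_profiles({"A": False, "B": True, "C": True})
        with pytest.raises(ValueError, match=r"\['D'\]"):
            infer_losses(quartet(), profiles)

    def test_multifurcation_one_event_per_child_branch(self):
        tree = make_tree("(A,B,C,D);")
        profiles = single_character_profiles({"A": False, "B": False, "C": True, "D": True})
        events = infer_losses(tree, profiles)
        assert len(events) == 2  # hard polytomy: one loss per child branch

    @pytest.mark.parametrize("mode", ["dollo", "fitch"])
    def test_modes_agree_on_clean_clade(self, mode):
        profiles = single_character_profiles({"A": False, "B": False, "C": True, "D": True})
        events = infer_losses(quartet(), profiles, mode=mode)
        assert len(events) == 1

    def test_dollo_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            n = int(rng.integers(3, 9))
            tree = random_tree(rng, n)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            states = {l: bool(rng.integers(0, 2)) for l in leaves}
            if all(states.values()):
                states[leaves[0]] = False
            events = infer_losses(tree, single_character_profiles(states))
            assert len(events) == dollo_minimum_bruteforce(tree, states)

    def test_grafting_an_absent_leaf_never_decreases_events(self):
        import dendropy

        rng = np.random.default_rng(7)
        for _ in range(50):
            tree = random_tree(rng, 6)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            states = {l: bool(rng.integers(0, 2)) for l in leaves}
            if all(states.values()):
                states[leaves[0]] = False
            before = len(infer_losses(tree, single_character_profiles(states)))
            # graft a new absent leaf onto a random branch
            targets = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
            target = targets[int(rng.integers(len(targets)))]
            parent = target.parent_node
            joint = dendropy.Node()
            parent.remove_child(target)
            parent.add_child(joint)
            joint.add_child(target)
            new_leaf = dendropy.Node(taxon=tree.taxon_namespace.new_taxon(label="extra"))
            joint.add_child(new_leaf)
            states["extra"] = False
            after = len(infer_losses(tree, single_character_profiles(states)))
            assert after >= before

    def test_dollo_covers_all_absences_fitch_a_subset(self):
        # Dollo must explain every absence by a loss event; Fitch may
        # instead reconstruct an absent root (ancestral absence), so its
        # events cover a subset of the absent leaves
        rng = np.random.default_rng(99)
        for _ in range(30):
            tree = random_tree(rng, 7)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            states = {l: bool(rng.integers(0, 2)) for l in leaves}
            dollo = infer_losses(tree, single_character_profiles(states))
            fitch = infer_losses(tree, single_character_profiles(states), mode="fitch")
            absent = {l for l, s in states.items() if not s}
            d_cov = set().union(*(e.affected_genes for e in dollo)) if dollo else set()
            f_cov = set().union(*(e.affected_genes for e in fitch)) if fitch else set()
            assert d_cov == absent
            assert f_cov <= absent
            assert len(fitch) <= len(dollo)


class TestTabulateEvents:
    def test_empty(self):
        table = tabulate_events([])
        assert table.total_events == 0
        assert table.rows == {}

    def test_grouping_and_order(self):
        from obpscaffold.loss_parsimony import LossEvent

        events = [
            LossEvent("b1", frozenset({"C2", "C5"}), ("g1", "g2")),
            LossEvent("b2", frozenset({"C1"}), ("g3",)),
            LossEvent("b3", frozenset({"C5", "C2"}), ("g4",)),
        ]
        table = tabulate_events(events)
        assert list(table.rows) == ["C1", "C2/C5"]
        assert table.rows["C2/C5"] == (2, 3, [("g1", "g2"), ("g4",)])
        # merging groups assignments without changing their number
        n_assignments = sum(len(e.lost) * 1 for e in events)
        assert n_assignments == sum(
            len(k.split("/")) * n for k, (n, _, _) in table.rows.items()
        )


class TestEventFixture:
    def test_totals_match_reported_accounting(self):
        table = tabulate_events(load_event_fixture())
        assert table.total_events == 22
        assert table.events_of_size(2) == 13
        assert table.genes_of_size(2) == 58
        assert table.events_of_size(1) == 8
        assert table.genes_of_size(1) == 15

    def test_specific_rows(self):
        table = tabulate_events(load_event_fixture())
        assert table.rows["C4/C5/C6"][:2] == (1, 1)
        assert table.rows["C4/C5/C6"][2] == [("AgamOBP16",)]
        assert table.rows["C2/C6"][2] == [("NvitOBP69",)]
        assert table.rows["C2/C5"][:2] == (8, 50)

    def test_checksum_guard(self, tmp_path):
        bad = tmp_path / "events.tsv"
        bad.write_text("C1\t1\tgeneA\n")
        with pytest.raises(ValueError, match="checksum"):
            load_event_fixture(bad, expected_sha256=LOSS_FIXTURE_SHA256)

    def test_gene_lists_disjoint_across_events_per_cysteine(self):
        events = load_event_fixture()
        for cys in ("C1", "C2", "C3", "C4", "C5", "C6"):
            seen = set()
            for ev in events:
                if cys in ev.lost:
                    assert not (seen & set(ev.affected_genes))
                    seen |= set(ev.affected_genes)
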