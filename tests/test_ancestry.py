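import itertools
import random

import pytest

from dolloscan import (
    brute_force_min_losses,
    dollo_reconstruct,
    gene_content_report,
    label_bottlenecks,
)
from dolloscan.ancestry import render_ascii_content
from dolloscan.simulate import simulate_tree
from dolloscan.statuses import GeneStatusMatrix
from dolloscan.tree import SpeciesTree


def make_presence(leaves, absent):
    return {l: ("absent" if l in absent else "present") for l in leaves}


class TestDolloReconstruct:
    def test_all_present_zero_losses(self, amniote_toy_tree):
        tree = amniote_toy_tree
        states = dollo_reconstruct(tree, make_presence(tree.leaf_labels(), set()))
        assert states.n_losses == 0

    def test_clade_wide_absence_is_one_stem_loss(self, amniote_toy_tree):
        # a gene absent in every sauropsid but present in mammals was lost
        # once, on the sauropsid stem
        tree = amniote_toy_tree
        absent = {"squamates", "turtles", "birds", "crocs"}
        states = dollo_reconstruct(
            tree, make_presence(tree.leaf_labels(), absent), gene="gcF"
        )
        assert states.n_losses == 1
        (ev,) = states.loss_events
        assert ev.affected_leaves == frozenset(absent)

    def test_single_leaf_absence_is_terminal_loss(self, amniote_toy_tree):
        tree = amniote_toy_tree
        states = dollo_reconstruct(
            tree, make_presence(tree.leaf_labels(), {"turtles"}), gene="gcD"
        )
        assert states.n_losses == 1
        (ev,) = states.loss_events
        assert ev.affected_leaves == frozenset({"turtles"})

    def test_all_absent_raises_without_root_assertion(self, amniote_toy_tree):
        tree = amniote_toy_tree
        pres = make_presence(tree.leaf_labels(), set(tree.leaf_labels()))
        with pytest.raises(ValueError, match="ancestral presence"):
            dollo_reconstruct(tree, pres)
        states = dollo_reconstruct(tree, pres, assert_root_presence=True)
        assert states.n_losses == 1
        assert states.loss_events[0].affected_leaves == frozenset(tree.leaf_labels())

    def test_missing_leaf_value_is_error(self, amniote_toy_tree):
        with pytest.raises(ValueError, match="presence value"):
            dollo_reconstruct(amniote_toy_tree, {"mammals": "present"})

    def test_irreversibility_on_random_instances(self):
        rng = random.Random(17)
        for _ in range(30):
            tree = simulate_tree(rng.randrange(4, 10), rng.randrange(10**6))
            leaves = tree.leaf_labels()
            absent = {l for l in leaves if rng.random() < 0.4}
            if absent == set(leaves):
                absent.pop()
            states = dollo_reconstruct(tree, make_presence(leaves, absent))
            for node in tree.preorder():
                if node.parent is not None:
                    assert not (
                        states.states[id(node.parent)] == "absent"
                        and states.states[id(node)] == "present"
                    )

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(23)
        for _ in range(100):
            tree = simulate_tree(rng.randrange(4, 9), rng.randrange(10**6))
            leaves = tree.leaf_labels()
            absent = {l for l in leaves if rng.random() < 0.5}
            if absent == set(leaves):
                absent.pop()
            pres = make_presence(leaves, absent)
            assert dollo_reconstruct(tree, pres).n_losses == brute_force_min_losses(
                tree, pres
            )

    def test_pruning_absent_leaf_inside_lost_clade_keeps_loss_branch(
        self, amniote_toy_tree
    ):
        tree = amniote_toy_tree
        absent = {"squamates", "turtles", "birds", "crocs"}
        full = dollo_reconstruct(tree, make_presence(tree.leaf_labels(), absent))
        pruned = tree.pruned({"turtles"})
        states = dollo_reconstruct(
            pruned, make_presence(pruned.leaf_labels(), absent - {"turtles"})
        )
        assert states.n_losses == full.n_losses == 1
        # still the branch separating mammals from the rest
        assert states.loss_events[0].affected_leaves == frozenset(
            absent - {"turtles"}
        )


class TestBruteForce:
    def test_trivial_cases(self, amniote_toy_tree):
        tree = amniote_toy_tree
        assert brute_force_min_losses(tree, make_presence(tree.leaf_labels(), set())) == 0
        assert (
            brute_force_min_losses(tree, make_presence(tree.leaf_labels(), {"mammals"}))
            == 1
        )

    def test_leaf_limit(self):
        tree = simulate_tree(13, 0)
        with pytest.raises(ValueError, match="12"):
            brute_force_min_losses(tree, make_presence(tree.leaf_labels(), set()))


class TestLabelBottlenecks:
    def test_stem_and_terminal_kinds(self, amniote_toy_tree):
        tree = amniote_toy_tree
        absent = {"squamates", "turtles", "birds", "crocs"}
        states = dollo_reconstruct(tree, make_presence(tree.leaf_labels(), absent))
        (ev,) = label_bottlenecks(states, tree)
        assert ev.kind == "stem" and len(ev.affected_leaves) == 4

        states = dollo_reconstruct(
            tree, make_presence(tree.leaf_labels(), {"turtles"})
        )
        (ev,) = label_bottlenecks(states, tree)
        assert ev.kind == "terminal"

    def test_independent_terminal_losses_never_merged(self):
        tree = SpeciesTree.from_nested((("a", "b"), ("c", "d")))
        pres = make_presence(tree.leaf_labels(), {"a", "c"})
        states = dollo_reconstruct(tree, pres)
        events = label_bottlenecks(states, tree)
        assert len(events) == 2
        assert all(ev.kind == "terminal" for ev in events)
        assert brute_force_min_losses(tree, pres) == 2

    def test_age_interval_from_branch_lengths(self):
        from dolloscan.formats import read_newick

        tree = read_newick("((a:1,b:1):1,c:2);")
        states = dollo_reconstruct(
            tree, {"a": "absent", "b": "absent", "c": "present"}
        )
        (ev,) = label_bottlenecks(states, tree)
        assert ev.kind == "stem"
        assert ev.age_interval == (0.0, 1.0)


class TestGeneContentReport:
    def _matrix(self):
        # amniote toy content: gcF lost on the sauropsid stem, gcD lost on
        # the turtle branch (stem of all turtles), gcE everywhere
        statuses = {}
        leaves = ["mammals", "squamates", "turtles", "birds", "crocs"]
        for sp in leaves:
            statuses[(sp, "gcE")] = "INTACT"
            statuses[(sp, "gcF")] = (
                "INTACT" if sp == "mammals" else "PSEUDOGENE"
            )
            statuses[(sp, "gcD")] = "PSEUDOGENE" if sp == "turtles" else "INTACT"
        return GeneStatusMatrix(statuses)

    def test_toy_ancestral_contents(self, amniote_toy_tree):
        content = gene_content_report(self._matrix(), amniote_toy_tree)
        node_names = list(content.index)
        # amniote ancestor (root): all three genes
        root = [n for n in node_names if n.startswith("node")][-1]
        assert set(
            g for g in content.columns if content.loc[root, g] == "present"
        ) == {"gcD", "gcE", "gcF"}
        # sauropsid ancestor: parent of squamates subtree -> {gcD, gcE}
        sauropsid = [
            n
            for n in node_names
            if n.startswith("node")
            and content.loc[n, "gcF"] == "absent"
            and content.loc[n, "gcD"] == "present"
        ]
        assert sauropsid, content
        # turtles leaf: only gcE
        assert content.loc["turtles", "gcE"] == "present"
        assert content.loc["turtles", "gcD"] == "absent"
        assert content.loc["turtles", "gcF"] == "absent"

    def test_single_gene_all_present(self, amniote_toy_tree):
        statuses = {
            (sp, "g"): "INTACT" for sp in amniote_toy_tree.leaf_labels()
        }
        content = gene_content_report(GeneStatusMatrix(statuses), amniote_toy_tree)
        assert (content["g"] == "present").all()

    def test_ascii_rendering_mentions_every_leaf(self, amniote_toy_tree):
        content = gene_content_report(self._matrix(), amniote_toy_tree)
        art = render_ascii_content(amniote_toy_tree, content)
        for leaf in amniote_toy_tree.leaf_labels():
            assert leaf in art
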