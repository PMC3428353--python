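"""Shared fixtures: toy alignments, trees, and independent oracles."""

from __future__ import annotations

from itertools import combinations

import dendropy
import numpy as np
import pytest

from obpscaffold.msa_profile import Alignment, CysteineProfile


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def random_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    from obpscaffold.synthetic_data import _random_topology

    return _random_topology(rng, n_leaves)


def single_character_profiles(states: dict[str, object]) -> list[CysteineProfile]:
    """Profiles varying only in C1: True present, False absent, None unknown."""
    out = []
    for sid, s in states.items():
        present = [True] * 6
        unknown = [False] * 6
        if s is None:
            present[0] = False
            unknown[0] = True
        else:
            present[0] = bool(s)
        out.append(CysteineProfile(sid, tuple(present), tuple(unknown), 0))
    return out


def dollo_minimum_bruteforce(tree: dendropy.Tree, states: dict[str, object]) -> int:
    """Exhaustive minimal number of loss branches for one binary character.

    A loss on a branch makes every known descendant leaf absent and can
    never be regained, so a solution is a set of nodes whose known-leaf
    sets are all-absent and whose union covers every absent leaf.  The
    search enumerates node subsets by increasing size; independent of the
    recursive reconstruction it checks.
    """
    absent = frozenset(l for l, s in states.items() if s is False)
    if not absent:
        return 0
    candidates = []
    for node in tree.preorder_node_iter():
        leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
        if any(states[l] is True for l in leaves):
            continue
        covered = frozenset(l for l in leaves if states[l] is False)
        if covered:
            candidates.append(covered)
    for k in range(1, len(candidates) + 1):
        for combo in combinations(candidates, k):
            if frozenset().union(*combo) == absent:
                return k
    raise AssertionError("no valid reconstruction found")


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four 110-column sequences with unanimous cysteines at columns
    10, 40, 44, 80, 92, 101 (C2-C3 spacing of exactly 3 residues)."""
    rng = np.random.default_rng(42)
    non_cys = list("ADEFGHIKLMNPQRSTVWY")
    cols = (10, 40, 44, 80, 92, 101)
    records = []
    for i in range(4):
        seq = list(rng.choice(non_cys, 110))
        for c in cols:
            seq[c - 1] = "C"
        records.append((f"seq{i + 1}", "".join(seq)))
    return Alignment.from_records(records)


TOY_COLUMNS = (10, 40, 44, 80, 92, 101)
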