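"""Parsimony mapping of canonical-cysteine losses onto a gene tree.

Given per-leaf cysteine profiles and a rooted gene tree, infer the minimal
set of branches on which each canonical cysteine was lost.  The default
model is Dollo-style: the cysteine is ancestrally present and can be lost
any number of times but never regained — the natural model for a residue
embedded in a disulphide scaffold.  Fitch parsimony (regain allowed) is
available for sensitivity analysis.  Losses of different cysteines mapped
to the same branch are merged into one multi-cysteine event, and events are
tabulated by lost-set with per-event affected-gene lists.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import dendropy

from .msa_profile import CYSTEINES, CysteineProfile

__all__ = [
    "LossEvent",
    "EventTable",
    "read_gene_tree",
    "infer_losses",
    "tabulate_events",
    "load_event_fixture",
    "LOSS_FIXTURE_SHA256",
]

# sha256 of the packaged loss-event fixture (data/loss_events.tsv);
# guards against accidental edits to the transcription
LOSS_FIXTURE_SHA256 = "3a8ebf72d39868f3ba945d1cf1315e2276cc48f2619bc87d9b95d7c9875f971a"


def _cys_key(lost: Iterable[str]) -> str:
    """Canonical 'C2/C5'-style key for a lost-set."""
    order = {c: i for i, c in enumerate(CYSTEINES)}
    return "/".join(sorted(lost, key=order.__getitem__))


@dataclass(frozen=True)
class LossEvent:
    """One loss event: a tree branch (named by its child node), the set of
    canonical cysteines lost there, and the descendant genes affected."""

    branch: str
    lost: frozenset[str]
    affected_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lost:
            raise ValueError("lost set must be non-empty")
        bad = self.lost - set(CYSTEINES)
        if bad:
            raise ValueError(f"unknown cysteines in lost set: {sorted(bad)}")
        if not self.affected_genes:
            raise ValueError("affected_genes must be non-empty")

    @property
    def lost_key(self) -> str:
        return _cys_key(self.lost)


@dataclass
class EventTable:
    """Loss events grouped by lost-set.

    ``rows`` maps a lost-set key ('C1', 'C2/C5', ...) to
    (event_count, gene_count, per-event gene lists).  Row order is
    deterministic: by lost-set size, then by cysteine index.
    """

    rows: dict[str, tuple[int, int, list[tuple[str, ...]]]] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return sum(n for n, _, _ in self.rows.values())

    @property
    def total_genes(self) -> int:
        return sum(g for _, g, _ in self.rows.values())

    def events_of_size(self, k: int) -> int:
        return sum(n for key, (n, _, _) in self.rows.items() if key.count("/") == k - 1)

    def genes_of_size(self, k: int) -> int:
        return sum(g for key, (_, g, _) in self.rows.items() if key.count("/") == k - 1)

    def lost_sets(self) -> list[frozenset[str]]:
        """One lost-set per event, in row order (input to the bond-bias count)."""
        out = []
        for key, (n, _, _) in self.rows.items():
            out.extend([frozenset(key.split("/"))] * n)
        return out

    def to_dataframe(self):
        import pandas as pd

        recs = [
            {
                "lost_set": key,
                "n_events": n,
                "n_genes": g,
                "genes": "; ".join(", ".join(ev) for ev in evs),
            }
            for key, (n, g, evs) in self.rows.items()
        ]
        return pd.DataFrame(recs, columns=["lost_set", "n_events", "n_genes", "genes"])


def read_gene_tree(path) -> dendropy.Tree:
    """Read a rooted Newick gene tree; branch lengths, if any, are ignored."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    _label_nodes(tree)
    return tree


def _label_nodes(tree: dendropy.Tree) -> None:
    """Give every node a stable identifier: taxon label for leaves, a
    preorder 'node_<k>' label for unlabelled internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("gene tree has an unlabelled leaf")
        elif not node.label:
            node.label = f"node_{k}"
        k += 1


def _node_id(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _leaf_states(
    tree: dendropy.Tree, profiles: Sequence[CysteineProfile]
) -> dict[str, CysteineProfile]:
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    prof = {p.sequence_id: p for p in profiles}
    if leaves != set(prof):
        missing = sorted(leaves - set(prof))
        extra = sorted(set(prof) - leaves)
        raise ValueError(
            f"leaf/profile mismatch: leaves without profile {missing}, "
            f"profiles without leaf {extra}"
        )
    return prof


def _dollo_losses_one_cysteine(
    tree: dendropy.Tree, state: dict[str, Optional[bool]]
) -> list[tuple[str, list[str]]]:
    """Minimal loss branches for one cysteine under Dollo parsimony.

    ``state[leaf]`` is True (present), False (absent) or None (unknown;
    uninformative for this character).  A loss on a branch makes every known
    descendant absent, so a valid loss branch subtends no known-present
    leaf; the minimal, root-most reconstruction takes the maximal such
    branches that cover all absent leaves.
    """
    # postorder: does the subtree contain any known-present / known-absent leaf?
    has_present: dict[int, bool] = {}
    has_absent: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = state[node.taxon.label]
            has_present[id(node)] = s is True
            has_absent[id(node)] = s is False
        else:
            has_present[id(node)] = any(has_present[id(c)] for c in node.child_nodes())
            has_absent[id(node)] = any(has_absent[id(c)] for c in node.child_nodes())

    losses: list[tuple[str, list[str]]] = []

    def descend(node: dendropy.Node) -> None:
        # node's parent clade contains a present leaf (or node is root);
        # place a loss here if the clade is all-absent, else recurse.
        if not has_absent[id(node)]:
            return
        if not has_present[id(node)]:
            affected = sorted(
                leaf.taxon.label
                for leaf in node.leaf_iter()
                if state[leaf.taxon.label] is False
            )
            losses.append((_node_id(node), affected))
            return
        for child in node.child_nodes():
            descend(child)

    descend(tree.seed_node)
    return losses


def _fitch_losses_one_cysteine(
    tree: dendropy.Tree, state: dict[str, Optional[bool]]
) -> list[tuple[str, list[str]]]:
    """Loss branches for one cysteine under Fitch/Hartigan parsimony
    (regain allowed; works on multifurcating trees).

    Returns the branches with a present->absent transition in one
    minimum-change assignment (ties resolved toward presence, which pushes
    losses root-ward)."""
    BOTH = frozenset({True, False})
    downpass: dict[int, frozenset[bool]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = state[node.taxon.label]
            downpass[id(node)] = BOTH if s is None else frozenset({s})
        else:
            votes = {True: 0, False: 0}
            for c in node.child_nodes():
                for s in downpass[id(c)]:
                    votes[s] += 1
            top = max(votes.values())
            downpass[id(node)] = frozenset(s for s, v in votes.items() if v == top)

    assigned: dict[int, bool] = {}
    losses: list[tuple[str, list[str]]] = []
    for node in tree.preorder_node_iter():
        opts = downpass[id(node)]
        if node.parent_node is None:
            assigned[id(node)] = True if True in opts else False
        else:
            parent = assigned[id(node.parent_node)]
            if parent in opts:
                assigned[id(node)] = parent
            else:
                # deterministic tie-break toward presence
                assigned[id(node)] = True if True in opts else False
            if assigned[id(node.parent_node)] and not assigned[id(node)]:
                affected = sorted(
                    leaf.taxon.label
                    for leaf in node.leaf_iter()
                    if state[leaf.taxon.label] is False
                )
                if affected:
                    losses.append((_node_id(node), affected))
    return losses


def infer_losses(
    tree: dendropy.Tree,
    profiles: Sequence[CysteineProfile],
    mode: str = "dollo",
) -> list[LossEvent]:
    """Infer the minimal cysteine-loss events on a gene tree.

    Each canonical cysteine is reconstructed independently; leaves whose
    state at a cysteine is unknown (incomplete sequences) are excluded for
    that character only.  Losses of different cysteines assigned to the
    same branch are merged into one multi-cysteine event.  Among equally
    parsimonious reconstructions the root-most placement is chosen, which
    groups as many affected genes as possible under each event.
    """
    if mode not in ("dollo", "fitch"):
        raise ValueError(f"unknown parsimony mode {mode!r}")
    _label_nodes(tree)
    prof = _leaf_states(tree, profiles)
    infer = _dollo_losses_one_cysteine if mode == "dollo" else _fitch_losses_one_cysteine

    per_branch: dict[str, tuple[set[str], set[str]]] = {}
    for i, cys in enumerate(CYSTEINES):
        state = {
            sid: (None if p.unknown[i] else bool(p.present[i])) for sid, p in prof.items()
        }
        if all(s is not False for s in state.values()):
            continue  # no observed absence of this cysteine
        for branch, affected in infer(tree, state):
            lost, genes = per_branch.setdefault(branch, (set(), set()))
            lost.add(cys)
            genes.update(affected)

    # deterministic event order: preorder position of the branch's child node
    order = {_node_id(n): k for k, n in enumerate(tree.preorder_node_iter())}
    events = [
        LossEvent(branch, frozenset(lost), tuple(sorted(genes)))
        for branch, (lost, genes) in per_branch.items()
    ]
    events.sort(key=lambda e: order.get(e.branch, len(order)))
    return events


def tabulate_events(events: Sequence[LossEvent]) -> EventTable:
    """Group loss events by lost-set, in deterministic row order
    (lost-set size, then cysteine index)."""
    order = {c: i for i, c in enumerate(CYSTEINES)}

    def row_key(key: str):
        parts = key.split("/")
        return (len(parts), tuple(order[p] for p in parts))

    grouped: dict[str, list[LossEvent]] = {}
    for ev in events:
        grouped.setdefault(ev.lost_key, []).append(ev)

    table = EventTable()
    for key in sorted(grouped, key=row_key):
        evs = grouped[key]
        gene_lists = [tuple(ev.affected_genes) for ev in evs]
        n_genes = sum(len(g) for g in gene_lists)
        table.rows[key] = (len(evs), n_genes, gene_lists)
    return table


def _default_fixture_path():
    return resources.files("obpscaffold").joinpath("data/loss_events.tsv")


def load_event_fixture(path=None, expected_sha256: Optional[str] = None) -> list[LossEvent]:
    """Load the packaged cysteine-loss event list (one event per line).

    The fixture transcribes the published loss-event table for the insect
    OBP family analysis: 22 events across several species' OBPs, each with
    its lost cysteine set and affected genes.  The packaged file is
    integrity-checked against a recorded sha256; pass ``expected_sha256``
    to check an external copy, or ``expected_sha256=""`` to skip.
    """
    if path is None:
        data = _default_fixture_path().read_bytes()
        expected = LOSS_FIXTURE_SHA256 if expected_sha256 is None else expected_sha256
    else:
        with open(path, "rb") as fh:
            data = fh.read()
        expected = expected_sha256 or ""
    if expected:
        digest = hashlib.sha256(data).hexdigest()
        if digest != expected:
            raise ValueError(
                f"loss-event fixture checksum mismatch: {digest} != {expected}"
            )
    events: list[LossEvent] = []
    for line in data.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lost_key, event_id, genes = line.split("\t")
        events.append(
            LossEvent(
                branch=f"fixture_{event_id}",
                lost=frozenset(lost_key.split("/")),
                affected_genes=tuple(g.strip() for g in genes.split(",")),
            )
        )
    return events
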