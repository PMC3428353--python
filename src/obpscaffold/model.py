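"""Model/Results interface over the loss-parsimony and bond-bias core.

`CysteineLossModel` bundles the inputs of the central analysis — a rooted
gene tree and per-leaf cysteine profiles — and `fit()` runs the parsimony
reconstruction and the bond-bias test, returning a `CysteineLossResults`
with the event list, the grouped event table, the binomial test and a
`summary()` in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from .bond_bias import BondBiasResult, BondTopology, bond_bias_pvalue, count_bond_events
from .loss_parsimony import (
    EventTable,
    LossEvent,
    infer_losses,
    read_gene_tree,
    tabulate_events,
)
from .msa_profile import (
    Alignment,
    CysteineProfile,
    locate_canonical_columns,
    profile_sequence,
    read_alignment,
)

__all__ = ["CysteineLossModel", "CysteineLossResults"]


class CysteineLossModel:
    """Parsimony model of canonical-cysteine loss on a gene tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted gene tree whose leaves match the profiled sequences.
    profiles : sequence of CysteineProfile
        Per-leaf canonical-cysteine states.
    mode : {'dollo', 'fitch'}
        Parsimony variant; Dollo (no regain) is the default.
    topology : BondTopology, optional
        Disulphide connectivity for the bond-bias test.
    q : float
        Null probability that a second same-event loss hits the bond
        partner (1/5 for the six-cysteine, three-bond fold).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        profiles: Sequence[CysteineProfile],
        mode: str = "dollo",
        topology: Optional[BondTopology] = None,
        q: float = 0.2,
    ) -> None:
        self.tree = tree
        self.profiles = list(profiles)
        self.mode = mode
        self.topology = topology or BondTopology()
        self.q = q

    @classmethod
    def from_files(
        cls,
        tree_path,
        alignment_path,
        alignment_format: str = "fasta",
        mode: str = "dollo",
        **profile_kwargs,
    ) -> "CysteineLossModel":
        """Build the model from a Newick tree and a protein alignment,
        locating canonical columns by majority rule."""
        tree = read_gene_tree(tree_path)
        aln = read_alignment(alignment_path, format=alignment_format)
        cols = locate_canonical_columns(aln)
        profiles = [profile_sequence(aln, cols, sid, **profile_kwargs) for sid in aln.ids]
        return cls(tree, profiles, mode=mode)

    def fit(self) -> "CysteineLossResults":
        events = infer_losses(self.tree, self.profiles, mode=self.mode)
        table = tabulate_events(events)
        x, y = count_bond_events(table, self.topology)
        bias = bond_bias_pvalue(x, y, self.q)
        return CysteineLossResults(model=self, events=events, event_table=table, bond_bias=bias)


@dataclass
class CysteineLossResults:
    """Fitted cysteine-loss reconstruction with the bond-bias test."""

    model: CysteineLossModel
    events: list[LossEvent]
    event_table: EventTable
    bond_bias: BondBiasResult

    @property
    def n_events(self) -> int:
        return self.event_table.total_events

    def summary(self) -> str:
        t = self.event_table
        b = self.bond_bias
        lines = [
            "Cysteine-loss parsimony results",
            "=" * 46,
            f"mode:                    {self.model.mode}",
            f"leaves:                  {len(self.model.profiles)}",
            f"loss events (total):     {t.total_events}",
            f"  single-cysteine:       {t.events_of_size(1)}",
            f"  two-cysteine:          {t.events_of_size(2)}",
            f"  three-cysteine:        {t.events_of_size(3)}",
            f"genes affected (total):  {t.total_genes}",
            "-" * 46,
            "Bond-bias test (two-cysteine events)",
            f"  x (events):            {b.x}",
            f"  y (bond-pair events):  {b.y}",
            f"  q (null):              {b.q:g}",
            f"  P(Y >= y):             {b.p_value:.6e}",
            "-" * 46,
            f"{'lost set':<12}{'events':>8}{'genes':>8}",
        ]
        for key, (n, g, _) in t.rows.items():
            lines.append(f"{key:<12}{n:>8}{g:>8}")
        return "\n".join(lines)
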