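"""Simulation of OBP gene families with known ground truth.

Generates a rooted gene tree, a root protein carrying the six-cysteine
scaffold (with the hallmark three-residue C2-C3 spacing), and evolves it
along the tree with per-site substitutions, branch-placed cysteine-loss
events, and optional tandem-fusion events that duplicate the gene into a
double-domain architecture.  The partner-loss hypothesis — losing one
cysteine of a disulphide bond relaxes selection on its partner — is a
single dial: ``partner_multiplier`` scales the loss rate of a cysteine
whose bond partner is already gone.  At ``partner_multiplier = 1`` the
process reduces to independent losses, matching the binomial null of the
bond-bias test (a second same-event loss hits the partner with
probability 1/5); values above 1 enrich bond-pair double losses.

Every simulated family carries its truth: the event log (branch, lost
cysteines, affected genes), fusion junctions, the true residue-homology
alignment, and per-gene exon structures — so column finding, profiling,
parsimony mapping, and domain detection can all be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .bond_bias import BondTopology
from .domain_arch import GeneStructure
from .loss_parsimony import LossEvent, _label_nodes, _node_id
from .msa_profile import CYSTEINES, Alignment, CanonicalColumns

__all__ = ["SimulationConfig", "SyntheticFamily", "simulate_family", "write_family"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NON_CYS = AMINO_ACIDS.replace("C", "")

#: residue gaps (min, max) before C1 and between consecutive cysteines;
#: the exact C2-C3 gap of 3 is the scaffold hallmark
DEFAULT_SPACINGS = ((15, 25), (25, 35), (3, 3), (25, 40), (8, 15), (15, 25))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated family.

    Rates are per branch (each branch is one unit of process time):
    ``loss_rate`` is the expected number of loss events per cysteine per
    branch, ``substitution_rate`` the per-site replacement probability per
    branch, ``fusion_probability`` the per-branch chance of a tandem
    duplication (at most one per lineage).
    """

    n_leaves: int = 20
    seed: int = 0
    loss_rate: float = 0.05
    partner_multiplier: float = 1.0
    fusion_probability: float = 0.0
    substitution_rate: float = 0.02
    scaffold_spacings: tuple[tuple[int, int], ...] = DEFAULT_SPACINGS
    domain_length: int = 160

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least two leaves")
        if self.loss_rate < 0 or self.substitution_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.fusion_probability <= 1.0:
            raise ValueError("fusion_probability must lie in [0, 1]")
        if self.partner_multiplier < 1.0:
            raise ValueError("partner_multiplier must be >= 1")
        if len(self.scaffold_spacings) != 6:
            raise ValueError("scaffold_spacings needs six (min, max) gap ranges")
        if any(lo > hi or lo < 0 for lo, hi in self.scaffold_spacings):
            raise ValueError("invalid scaffold gap range")
        max_span = sum(hi for _, hi in self.scaffold_spacings) + 6
        if self.domain_length < max_span:
            raise ValueError(
                f"domain_length {self.domain_length} cannot hold the scaffold "
                f"(needs up to {max_span})"
            )


@dataclass
class SyntheticFamily:
    """A simulated family with its complete ground truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    sequences: dict[str, str]
    alignment: Alignment
    structures: dict[str, GeneStructure]
    truth_events: list[LossEvent]
    truth_fusions: list[tuple[str, int]]
    #: true 1-based alignment columns of the domain-1 canonical cysteines
    canonical_columns: CanonicalColumns

    def profiles(self):
        """True per-leaf cysteine profiles of domain 1 (no unknowns)."""
        from .msa_profile import CysteineProfile

        out = []
        cols = self.canonical_columns
        for sid in self.alignment.ids:
            residues = self.alignment[sid]
            present = tuple(residues[c - 1] == "C" for c in cols)
            out.append(CysteineProfile(sid, present, (False,) * 6, 0))
        return out


def _random_topology(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random rooted binary topology by sequential random joins."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        taxon = taxa.new_taxon(label=f"g{i + 1:03d}")
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.exponential(0.3))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(0.3))
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    _label_nodes(tree)
    return tree


def _root_scaffold(rng: np.random.Generator, config: SimulationConfig) -> tuple[list[str], list[int]]:
    """Root mature sequence and its six cysteine positions (1-based)."""
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in config.scaffold_spacings]
    positions = []
    pos = 0
    for g in gaps:
        pos += g + 1
        positions.append(pos)
    seq = [NON_CYS[rng.integers(len(NON_CYS))] for _ in range(config.domain_length)]
    for p in positions:
        seq[p - 1] = "C"
    return seq, positions


_PARTNER = {}
for _pair in BondTopology().pairs:
    _a, _b = sorted(_pair)
    _PARTNER[_a] = _b
    _PARTNER[_b] = _a


def _branch_losses(
    rng: np.random.Generator,
    present: dict[str, bool],
    loss_rate: float,
    partner_multiplier: float,
) -> list[str]:
    """Cysteines lost on one branch (unit process time), by a Gillespie
    walk in which losing a cysteine immediately raises its partner's rate."""
    if loss_rate <= 0:
        return []
    status = dict(present)
    lost: list[str] = []
    t = 0.0
    while True:
        rates = {}
        for c, p in status.items():
            if not p:
                continue
            mult = partner_multiplier if not status[_PARTNER[c]] else 1.0
            rates[c] = loss_rate * mult
        total = sum(rates.values())
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > 1.0:
            break
        names = sorted(rates)
        probs = np.array([rates[c] for c in names]) / total
        c = names[int(rng.choice(len(names), p=probs))]
        status[c] = False
        lost.append(c)
    return lost


def _make_structure(gene_id: str, domain_length: int, fused: bool) -> GeneStructure:
    """Two exons with an internal phase-1 intron per domain; fused genes
    add a phase-0 intron at the domain junction."""
    L = domain_length
    k = L // 2
    cut = 3 * k + 1  # phase-1 position inside the domain
    if not fused:
        return GeneStructure(gene_id, ((1, cut), (cut + 1, 3 * L)), (1,))
    return GeneStructure(
        gene_id,
        ((1, cut), (cut + 1, 3 * L), (3 * L + 1, 3 * L + cut), (3 * L + cut + 1, 6 * L)),
        (1, 0, 1),
    )


def simulate_family(config: SimulationConfig) -> SyntheticFamily:
    """Simulate one OBP family; deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    tree = _random_topology(rng, config.n_leaves)
    root_seq, cys_positions = _root_scaffold(rng, config)
    L = config.domain_length

    truth_events: list[LossEvent] = []
    truth_fusions: list[tuple[str, int]] = []
    leaf_state: dict[str, tuple[list[str], bool]] = {}

    def evolve(node, seq: list[str], present: dict[str, bool], fused: bool) -> None:
        seq = list(seq)
        present = dict(present)
        branch = _node_id(node)
        if node.parent_node is not None:
            # tandem fusion: duplicate the current gene in place, once per lineage
            if not fused and config.fusion_probability > 0:
                if rng.random() < config.fusion_probability:
                    fused = True
                    seq = seq + list(seq)
                    truth_fusions.append((branch, L + 1))
            # substitutions at non-scaffold sites (replacements never create
            # a cysteine, so canonical columns stay unambiguous)
            protected = set(cys_positions) | (
                {p + L for p in cys_positions} if fused else set()
            )
            if config.substitution_rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < config.substitution_rate)[0]
                for i in hits:
                    if i + 1 not in protected:
                        seq[i] = NON_CYS[rng.integers(len(NON_CYS))]
            # cysteine losses on the domain-1 scaffold
            lost = _branch_losses(rng, present, config.loss_rate, config.partner_multiplier)
            if lost:
                for c in lost:
                    present[c] = False
                    pos = cys_positions[CYSTEINES.index(c)]
                    seq[pos - 1] = NON_CYS[rng.integers(len(NON_CYS))]
                affected = tuple(
                    sorted(leaf.taxon.label for leaf in node.leaf_iter())
                )
                truth_events.append(LossEvent(branch, frozenset(lost), affected))
        if node.is_leaf():
            leaf_state[node.taxon.label] = (seq, fused)
        else:
            for child in node.child_nodes():
                evolve(child, seq, present, fused)

    evolve(tree.seed_node, root_seq, {c: True for c in CYSTEINES}, False)

    sequences = {sid: "".join(seq) for sid, (seq, _) in sorted(leaf_state.items())}
    # true homology alignment: columns 1..L are domain 1 (shared by all),
    # columns L+1..2L hold domain 2 of fused genes (gaps elsewhere); no
    # indels are simulated, so positions align one-to-one
    any_fused = any(f for _, f in leaf_state.values())
    records = []
    for sid in sorted(leaf_state):
        seq, fused = leaf_state[sid]
        if any_fused and not fused:
            records.append((sid, "".join(seq) + "-" * L))
        else:
            records.append((sid, "".join(seq)))
    alignment = Alignment.from_records(records)
    structures = {
        sid: _make_structure(sid, L, fused) for sid, (seq, fused) in sorted(leaf_state.items())
    }
    return SyntheticFamily(
        config=config,
        tree=tree,
        sequences=sequences,
        alignment=alignment,
        structures=structures,
        truth_events=truth_events,
        truth_fusions=truth_fusions,
        canonical_columns=CanonicalColumns(tuple(cys_positions)),
    )


def write_family(family: SyntheticFamily, out_dir) -> dict[str, Path]:
    """Write a simulated family as plain-text files that round-trip
    through the pipeline readers.

    Emits unaligned and aligned FASTA, Newick, an exon/phase TSV and the
    truth logs; returns the paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": out / "sequences.fasta",
        "alignment": out / "alignment.fasta",
        "tree": out / "tree.nwk",
        "structures": out / "structures.tsv",
        "truth_events": out / "truth_events.tsv",
        "truth_fusions": out / "truth_fusions.tsv",
    }
    with open(paths["sequences"], "w") as fh:
        for sid, seq in family.sequences.items():
            fh.write(f">{sid}\n{seq}\n")
    with open(paths["alignment"], "w") as fh:
        for sid, res in family.alignment.records:
            fh.write(f">{sid}\n{res}\n")
    family.tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    with open(paths["structures"], "w") as fh:
        fh.write("gene_id\texons\tintron_phases\n")
        for sid, st in family.structures.items():
            exons = ";".join(f"{a}-{b}" for a, b in st.exons)
            phases = ";".join(str(p) for p in st.intron_phases)
            fh.write(f"{sid}\t{exons}\t{phases}\n")
    with open(paths["truth_events"], "w") as fh:
        fh.write("branch\tlost_set\taffected_genes\n")
        for ev in family.truth_events:
            fh.write(f"{ev.branch}\t{ev.lost_key}\t{', '.join(ev.affected_genes)}\n")
    with open(paths["truth_fusions"], "w") as fh:
        fh.write("branch\tjunction\n")
        for branch, junction in family.truth_fusions:
            fh.write(f"{branch}\t{junction}\n")
    return paths


def read_structures_tsv(path) -> dict[str, GeneStructure]:
    """Read the exon/phase TSV written by :func:`write_family`."""
    structures: dict[str, GeneStructure] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene_id, exons_s, phases_s = line.split("\t")
            exons = tuple(
                tuple(int(x) for x in part.split("-")) for part in exons_s.split(";")
            )
            phases = tuple(int(p) for p in phases_s.split(";")) if phases_s else ()
            structures[gene_id] = GeneStructure(gene_id, exons, phases)
    return structures
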