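# Methods

## The problem and the model

Classic insect odorant-binding proteins carry six canonical cysteines
(C1–C6) whose disulphide bonds (C1–C3, C2–C5, C4–C6) brace the fold. The
package analyses how this scaffold decays and duplicates over a gene
family's history: which cysteines were lost, on which branches of the gene
tree, whether bonded partners are lost together, and whether a gene carries
one OBP domain or two in tandem.

## Canonical-column location and profiling

Columns of a protein alignment are ranked by cysteine occupancy among
non-gap residues; the six highest-occupancy columns at or above
`min_fraction` (default 0.5) are taken in alignment order. Because the OBP
motif itself varies between reports, only its best-supported hallmark is
enforced: when more than six columns qualify, preference goes to a
six-column set whose second and third columns are separated by exactly
three ungapped residues in a majority of the sequences spanning both. A
reference mode reads the columns directly off designated six-cysteine
sequences instead.

Per sequence, a canonical column holding `C` is *present*; a column inside
a leading/trailing gap run is *unknown* (the sequence is truncated there,
so nothing is observed — such characters are excluded from downstream
inference rather than scored); an internal gap or any other residue is
*absent*, since a deletion removes the cysteine as surely as a
substitution. Columns are 1-based. No signal-peptide prediction is done:
the mature region defaults to alignment column 25 onward (user-overridable),
which is where signal peptides end in the family alignments this layout
follows. `extra_cysteines` counts mature-region cysteines off the canonical
columns; a sequence is plus-C only with ≥ 2 extras (`plus_c_min_extra`),
since two are the minimum for an additional disulphide bond and a single
stray cysteine is more often noise. Any observed absence makes a sequence
minus-C; otherwise it is classic.

## Loss parsimony

Each cysteine is a binary character, ancestrally present. The default
reconstruction is Dollo-style — no regain, biologically motivated by the
improbability of re-evolving a disulphide partner — so a loss on a branch
darkens its entire subtree. The minimum-event reconstruction has a closed
form: the loss branches are the maximal branches whose subtending known
leaves are all absent, walking down from the root. This is also the
root-most of all equally minimal placements, chosen deliberately so each
event groups as many descendant genes as possible; it is deterministic.
Unknown states are excluded per character (a 3'-truncated gene still
informs C1–C4). Multifurcations are hard polytomies: a loss on each child
branch counts separately. Losses of different cysteines on the same branch
merge into one multi-cysteine event; merging regroups but never changes the
number of (branch, cysteine) assignments. A Fitch/Hartigan mode (regain
allowed, ties resolved toward presence) is provided for sensitivity; under
Fitch an all-absent clade may be explained by ancestral absence, so its
event list can be empty where Dollo's is not.

Correctness is checked against an independent exhaustive-search oracle
(enumerating branch subsets by increasing size) on random trees of ≤ 8
leaves, and against the simulator's event log.

## Bond-pair bias test

With six cysteines in three bonds, once one cysteine is lost exactly one
of the five survivors is its partner, so under independent losses a second
same-event loss is a bond hit with probability q = 1/5. Observing y bond
hits among x two-cysteine events, the p-value is the binomial upper tail
P(Y ≥ y), computed via the regularised-incomplete-beta survival function
(stable in the far tail). Events losing one or three cysteines are outside
the test by construction. q is exposed for sensitivity analysis.

## Site-model LRT arithmetic

The package does not fit codon models; it computes χ² upper-tail p-values
from reported likelihood-ratio statistics and degrees of freedom (for
df = 2, p = exp(−statistic/2)). Where a reported statistic disagrees with
2·(lnL_alt − lnL_null) from the reported log-likelihoods, the comparison
object computes the p-value from the reported statistic and sets a
`statistic_consistent = False` flag rather than silently preferring either
number. The packaged M8a-vs-M8 row carries df = 2, the only value
consistent with its reported p-value; the flag machinery keeps such
choices visible.

## Domain architecture

A tandem duplication leaves an off-main-diagonal run in a self-comparison
dotplot. Scores are windowed means of BLOSUM62 substitution scores along
diagonals (window 15, truncated at the ends); runs need a mean ≥ 1.0 per
residue sustained over ≥ 30 positions. These thresholds are not drawn from
any published protocol (the original analyses used interactive dotplot
tools): they were chosen so that exact repeats are always detected while
shuffled and random controls of realistic length yield no runs (≈ +1 per
residue is far above the negative expectation of random pairs), and all
three are exposed as parameters.

A gene is called **double** with two non-overlapping full six-cysteine
scaffold matches, or when it is exceptionally long (> 250 residues, the
published operational cut-off for the wasp family) *and* shows an
off-diagonal run — the second route catches doubles whose decayed domain
has lost its cysteines. **Vestigial double** requires one full scaffold
plus a terminal remnant supported by at least two independent evidence
types (remnant cysteine, a splice site outside the full domain, extra
exons), mirroring the three-evidence argument used for decayed second
domains in the wasp cluster. Everything else is **single**; at
single-domain lengths a false double is structurally impossible under
these rules, which is why the simulator-based false-positive rate is
exactly zero.

The boundary (first residue of domain 2, 1-based) is the start of the
dotplot run's second copy, falling back to the inter-scaffold midpoint;
when the exon layout is known it snaps to the nearest splice-site residue
within 10 residues — fusions inherit a splice site at the junction — but
only if each scaffold stays wholly inside its domain. Splitting at the
boundary and rejoining is the identity on the residue string. Interleaved
scaffolds raise an "ambiguous boundary" error listing the candidates.

## Simulator

`simulate_family` draws a random rooted binary topology (sequential random
joins; exponential branch lengths, unused by the parsimony), a root mature
domain of 160 residues with cysteine positions drawn from spacing ranges
typical of the family (C2–C3 fixed at 3), and evolves it branch by branch:

- **Substitutions**: each non-scaffold site is replaced with probability
  `substitution_rate` (default 0.02/site/branch) by a uniform random
  non-cysteine residue. Replacements never create cysteines and scaffold
  positions are never overwritten, because the pipeline under test reads
  only cysteine identity and windowed similarity; a richer substitution
  model would add cost without adding coverage.
- **Losses**: within a branch (one unit of process time) present cysteines
  are lost by a small Gillespie walk at rate `loss_rate` each (default
  0.05/cysteine/branch); losing a cysteine immediately multiplies its
  partner's rate by `partner_multiplier`. At multiplier 1 the losses are
  independent, so a two-loss event hits a bond pair with probability
  exactly 3/C(6,2) = 1/5 — the binomial null — which the calibration test
  verifies by Monte Carlo; multipliers > 1 enrich bond pairs by
  construction. Lost cysteines are replaced by random non-cysteine
  residues, and each branch with losses is recorded as one truth event.
- **Fusions**: with probability `fusion_probability` per branch a
  non-fused lineage duplicates its current gene in tandem (junction at
  domain_length + 1, recorded); at most one fusion per lineage, matching
  the observed architectures. After fusion both domains substitute
  independently; the loss process continues on domain 1's scaffold.

No indels are simulated, so the true alignment is positional: domain-1
columns shared by all genes, domain-2 columns gapped in single-domain
genes. Gene structures give each domain two exons split by a phase-1
intron, with a phase-0 intron at the fusion junction — so the junction is
always a splice residue, exercising the boundary-snapping rule. Everything
is driven by one `numpy` generator seeded from the config: identical
configs give byte-identical outputs.

What the simulator does **not** emulate: indels and alignment error,
rate heterogeneity and biased amino-acid exchange, cysteine gains (so
plus-C classification is exercised only by constructed profiles),
pseudogenisation, and sequencing incompleteness (unknown states are tested
with constructed alignments instead). Passing the simulator tests
therefore shows the inference machinery is correct under clean homology,
not that it is robust to misalignment.

## Packaged fixtures

Two TSV fixtures transcribe published family tables: the per-gene
annotation of the 90 wasp OBPs (status, EST support, subfamily) and the
22 cysteine-loss events with affected genes. Known internal
inconsistencies of the source tables (pseudogenes listed with full EST
support; one gene labelled minus-C but counted in the double-domain
cluster) are preserved verbatim. The event table's printed line breaks
(one event per line) were not recoverable for multi-event rows, so gene
lists are partitioned into events by species/clade coherence; every
per-row event and gene count is preserved, and those counts are the only
quantities downstream statistics use. The loss-event fixture is integrity-
checked against a recorded sha256 at load time.

## Problem sizes and determinism

Default verification sizes — 1000 random ≤ 8-leaf trees for the
parsimony oracle, 500 simulated 20-leaf families for the null calibration
(≈ 400 two-loss events; the acceptance band is ± 3 binomial standard
errors around 1/5), ~ 200 simulated genes for fusion detection — were
chosen so the checks carry real statistical weight while the whole suite
runs in seconds. All stochastic tests fix their seeds; the acceptance
script derives every stream from its `--seed`.

## Known limitations

- Dollo's root-most tie-break maximises genes per event; a biologically
  different but equally parsimonious placement cannot be distinguished
  from data alone.
- The parameter-recovery guarantee applies when each simulated event's
  branch is the maximal all-absent branch for its cysteines; at high loss
  rates nested or sibling events merge and parsimony undercounts, which is
  inherent to the criterion, not to the implementation.
- Majority-rule column finding assumes the family alignment is dominated
  by scaffold-bearing sequences; families where most members lost a given
  cysteine need reference mode.
- The boundary of a decayed second domain is reported as observed; no
  attempt is made to fix its end when the remnant trails off.
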