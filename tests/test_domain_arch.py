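"""Self-dotplot, scaffold scanning, architecture calls, boundary placement."""

import numpy as np
import pytest

from obpscaffold.domain_arch import (
    GeneStructure,
    ScaffoldMatch,
    delimit_domains,
    detect_architecture,
    find_scaffold_hits,
    self_dotplot,
    split_domains,
)
from obpscaffold.synthetic_data import (
    NON_CYS,
    SimulationConfig,
    simulate_family,
)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), n))


def mutate(rng, seq, fraction):
    out = list(seq)
    for i in rng.choice(len(seq), int(fraction * len(seq)), replace=False):
        out[i] = NON_CYS[rng.integers(len(NON_CYS))]
    return "".join(out)


class TestSelfDotplot:
    def test_exact_tandem_repeat_yields_run_at_domain_offset(self):
        rng = np.random.default_rng(1)
        domain = random_protein(rng, 120, NON_CYS)
        dp = self_dotplot(domain + domain)
        assert any(r.offset == 120 and r.length >= 90 for r in dp.diagonals)

    def test_random_sequence_yields_no_run(self):
        rng = np.random.default_rng(2)
        dp = self_dotplot(random_protein(rng, 200))
        assert dp.diagonals == []

    def test_shuffled_controls_yield_no_runs(self):
        rng = np.random.default_rng(3)
        domain = random_protein(rng, 120, NON_CYS)
        tandem = list(domain + domain)
        for _ in range(5):
            rng.shuffle(tandem)
            assert self_dotplot("".join(tandem)).diagonals == []

    def test_diverged_tandem_domains_detected_at_fusion_offset(self):
        rng = np.random.default_rng(4)
        domain = random_protein(rng, 130, NON_CYS)
        second = mutate(rng, domain, 0.35)  # ~65% identity between domains
        dp = self_dotplot(domain + second)
        run = dp.best_run()
        assert run is not None
        assert abs(run.offset - 130) <= dp.window

    def test_scores_symmetric_and_diagonal_maximal(self):
        rng = np.random.default_rng(5)
        dp = self_dotplot(random_protein(rng, 80), window=7)
        assert np.allclose(dp.scores, dp.scores.T)
        assert np.argmax(dp.scores.max(axis=1)) in range(80)
        assert dp.scores.max() == pytest.approx(np.diag(dp.scores).max())

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            self_dotplot("ACDEF", window=15)


class TestScaffoldHits:
    def test_simulated_single_domain_has_one_full_hit(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        for sid, seq in fam.sequences.items():
            hits = find_scaffold_hits(seq)
            assert len(hits) == 1 and hits[0].is_full
            assert hits[0].cys_positions == fam.canonical_columns.columns

    def test_tandem_scaffold_gives_two_nonoverlapping_hits(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        seq = next(iter(fam.sequences.values()))
        hits = find_scaffold_hits(seq + seq)
        assert len(hits) == 2
        assert all(h.is_full for h in hits)
        assert not hits[0].overlaps(hits[1])


class TestDetectArchitecture:
    def test_simulated_fusion_is_double(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        seq = next(iter(fam.sequences.values()))
        arch = detect_architecture(seq + seq)
        assert arch.call == "double"
        assert arch.evidence["cysteine"]

    def test_single_scaffold_gene_is_single(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        seq = next(iter(fam.sequences.values()))
        assert detect_architecture(seq).call == "single"

    def test_long_gene_with_dotplot_run_is_double_despite_lost_cysteines(self):
        rng = np.random.default_rng(8)
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        seq = next(iter(fam.sequences.values()))
        # strip the second domain's cysteines: length + dotplot still call it
        second = list(seq)
        for p in fam.canonical_columns:
            second[p - 1] = "A"
        arch = detect_architecture(seq + "".join(second))
        assert arch.call == "double"
        assert arch.evidence["length"] and arch.evidence["dotplot"]

    def test_truncated_second_domain_is_vestigial_double(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        sid, seq = next(iter(fam.sequences.items()))
        L = fam.config.domain_length
        # remnant: first exon's worth of domain 2, through its first cysteine
        c1 = fam.canonical_columns[0]
        remnant = seq[: c1 + 3]
        fused_structure = GeneStructure(
            sid, ((1, 3 * L), (3 * L + 1, 3 * (L + len(remnant)))), (0,)
        )
        arch = detect_architecture(seq + remnant, structure=fused_structure)
        assert arch.call == "vestigial_double"
        assert arch.evidence["cysteine"] and arch.evidence["splice"]

    def test_no_structure_no_vestigial_call(self):
        # a lone remnant cysteine without structural evidence stays single
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=21, loss_rate=0.0))
        seq = next(iter(fam.sequences.values()))
        c1 = fam.canonical_columns[0]
        assert detect_architecture(seq + seq[: c1 + 3]).call == "single"


class TestDelimitDomains:
    def test_exact_tandem_repeat_boundary(self):
        rng = np.random.default_rng(10)
        domain = random_protein(rng, 120, NON_CYS)
        seq = domain + domain
        arch = detect_architecture(seq, min_double_length=200)
        arch = delimit_domains(arch, dotplot=self_dotplot(seq))
        assert arch.boundary == 121
        a, b = split_domains(seq, arch.boundary)
        assert a + b == seq

    def test_boundary_snaps_to_splice_site(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=33, loss_rate=0.0))
        sid, seq = next(iter(fam.sequences.items()))
        L = fam.config.domain_length
        fused = seq + seq
        # splice residue at L - 2 (within the 10-residue snap radius of L + 1)
        cut = 3 * (L - 3) + 1
        structure = GeneStructure(sid, ((1, cut), (cut + 1, 6 * L)), (1,))
        arch = detect_architecture(fused, structure=structure)
        arch = delimit_domains(arch, dotplot=self_dotplot(fused), structure=structure)
        assert arch.boundary == L - 2

    def test_distant_splice_site_not_snapped_to(self):
        fam = simulate_family(SimulationConfig(n_leaves=6, seed=33, loss_rate=0.0))
        sid, seq = next(iter(fam.sequences.items()))
        L = fam.config.domain_length
        fused = seq + seq
        # the only splice site sits 30 residues from the junction, beyond
        # the 10-residue snap radius: the dotplot boundary stands
        cut = 3 * (L - 31) + 1
        structure = GeneStructure(sid, ((1, cut), (cut + 1, 6 * L)), (1,))
        arch = detect_architecture(fused, structure=structure)
        arch = delimit_domains(arch, dotplot=self_dotplot(fused), structure=structure)
        assert arch.boundary == L + 1

    def test_single_domain_call_rejected(self):
        with pytest.raises(ValueError, match="double-domain"):
            from obpscaffold.domain_arch import DomainArchitecture

            delimit_domains(DomainArchitecture("g", "single", sequence="ACD"))

    def test_split_roundtrip_is_identity(self):
        rng = np.random.default_rng(11)
        seq = random_protein(rng, 261)
        for boundary in (2, 100, 261):
            a, b = split_domains(seq, boundary)
            assert a + b == seq
            assert len(a) == boundary - 1


class TestGeneStructure:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GeneStructure("g", ((10, 5),), ())
        with pytest.raises(ValueError):
            GeneStructure("g", ((1, 10), (5, 20)), (1,))
        with pytest.raises(ValueError):
            GeneStructure("g", ((1, 10), (11, 20)), ())

    def test_splice_residues(self):
        st = GeneStructure("g", ((1, 241), (242, 480)), (1,))
        assert st.splice_residues() == [81]
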