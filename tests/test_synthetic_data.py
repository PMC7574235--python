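import numpy as np
import pytest

from famtrace import synthetic_data as syn
from famtrace.sequence_io import ProteinRecord, translate
from famtrace.reconciliation import lca_reconcile
from famtrace.sequence_io import read_newick

from conftest import random_protein


class TestMutateProtein:
    def test_identity_one_is_identity(self, seed_protein):
        assert syn.mutate_protein(seed_protein, 1.0, 7).seq == seed_protein.seq

    def test_realized_identity_near_target(self, rng):
        prot = random_protein(rng, 500)
        mut = syn.mutate_protein(prot, 0.7, 1)
        ident = sum(a == b for a, b in zip(prot.seq, mut.seq)) / 500
        assert 0.67 <= ident <= 0.73
        assert "*" not in mut.seq and "X" not in mut.seq

    def test_start_methionine_preserved(self, rng):
        prot = random_protein(rng, 60)
        for s in range(5):
            assert syn.mutate_protein(prot, 0.3, s).seq[0] == "M"

    def test_meaningless_target_rejected(self, seed_protein):
        with pytest.raises(ValueError):
            syn.mutate_protein(seed_protein, 0.01, 0)


class TestPlantGene:
    def test_single_exon_translates_back(self, rng):
        prot = ProteinRecord("p", "MKW")
        contig = syn.random_dna(400, 0.42, rng)
        new, truth = syn.plant_gene(contig, prot, 1, (), 100, "+", rng)
        assert translate(truth.spliced_cds(new)) == "MKW"
        assert len(truth.exons) == 1

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_introns_are_gt_ag(self, rng, strand):
        prot = random_protein(rng, 40)
        contig = syn.random_dna(2000, 0.42, rng)
        new, truth = syn.plant_gene(contig, prot, 3, (60, 80), 300, strand, rng)
        assert len(truth.exons) == 3
        assert translate(truth.spliced_cds(new)) == prot.seq
        # introns lie between consecutive exons on the coding strand
        exons = truth.exons
        for a, b in zip(exons, exons[1:]):
            if strand == "+":
                intron = new[a[1]:b[0]]
            else:
                from famtrace.sequence_io import reverse_complement
                intron = reverse_complement(new[b[1]:a[0]])
            assert intron.startswith("GT") and intron.endswith("AG")
            assert len(intron) >= syn.MIN_INTRON_LENGTH

    def test_contig_too_short_rejected(self, rng):
        prot = random_protein(rng, 100)
        with pytest.raises(ValueError):
            syn.plant_gene("ACGT" * 30, prot, 2, (60, 80), 10, "+", rng)


class TestPseudogenize:
    @pytest.fixture()
    def planted(self, rng):
        prot = random_protein(rng, 60)
        contig = syn.random_dna(3000, 0.42, rng)
        new, truth = syn.plant_gene(contig, prot, 3, (60, 90), 500, "+", rng)
        return new, truth

    def test_premature_stop(self, planted, rng):
        contig, truth = planted
        c2, t2 = syn.pseudogenize(contig, truth, "premature_stop", rng)
        assert t2.status == "pseudogene" and t2.defects == ["premature_stop"]
        prot = translate(t2.spliced_cds(c2))
        assert "*" in prot[:-1]

    def test_frameshift_changes_length_mod3(self, planted, rng):
        contig, truth = planted
        c2, t2 = syn.pseudogenize(contig, truth, "frameshift", rng)
        old = sum(e - s for s, e in truth.exons)
        new = sum(e - s for s, e in t2.exons)
        assert (new - old) % 3 != 0
        assert t2.defects == ["frameshift"]
        assert len(c2) == len(contig)  # compensated, coordinates stable

    def test_truncation_drops_terminal_exon(self, planted, rng):
        contig, truth = planted
        c2, t2 = syn.pseudogenize(contig, truth, "truncated", rng)
        assert len(t2.exons) == len(truth.exons) - 1
        assert t2.defects == ["truncated"]

    def test_one_codon_gene_rejected(self, rng):
        contig = syn.random_dna(200, 0.5, rng)
        new, truth = syn.plant_gene(contig, ProteinRecord("p", "M"), 1, (),
                                    50, "+", rng)
        with pytest.raises(ValueError):
            syn.pseudogenize(new, truth, "premature_stop", rng)


class TestSimulateGenome:
    def _spec(self, seed_protein, seed=0, **kw):
        genes = kw.pop("genes", [
            syn.GenePlan("g1", 0.8, 2, cluster="c1"),
            syn.GenePlan("g2", 0.8, 3, cluster="c1"),
            syn.GenePlan("g3", 0.8, 3, cluster="c1"),
        ])
        return syn.GenomeSpec(seed_protein=seed_protein, genes=genes,
                              contig_length=60_000, seed=seed, **kw)

    def test_no_genes_gives_pure_background(self, seed_protein):
        spec = syn.GenomeSpec(seed_protein=seed_protein, genes=[],
                              contig_length=10_000, place_markers=False, seed=1)
        sim = syn.simulate_genome(spec)
        assert sim.truth == []
        assert all(f.kind not in ("gene", "exon") for f in sim.features)

    def test_deterministic_for_fixed_seed(self, seed_protein):
        s1 = syn.simulate_genome(self._spec(seed_protein, seed=5))
        s2 = syn.simulate_genome(self._spec(seed_protein, seed=5))
        assert s1.genomes[0].seq == s2.genomes[0].seq
        assert s1.truth_table().equals(s2.truth_table())

    def test_tandem_cluster_in_genomic_order(self, seed_protein):
        sim = syn.simulate_genome(self._spec(seed_protein, seed=3))
        spans = [t.span for t in sim.truth]
        assert spans == sorted(spans)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 < s2  # disjoint

    def test_contig_too_small_rejected(self, seed_protein):
        with pytest.raises(ValueError):
            syn.simulate_genome(syn.GenomeSpec(
                seed_protein=seed_protein,
                genes=[syn.GenePlan("g", 0.8, 3)], contig_length=2_000, seed=0))

    def test_planted_translations_over_random_specs(self, seed_protein):
        """Functional genes translate cleanly; premature-stop pseudogenes
        carry at least one internal stop (checked over random specs)."""
        master = np.random.default_rng(2024)
        for _ in range(15):
            seed = int(master.integers(2**31))
            genes = [syn.GenePlan(f"g{i}", float(master.uniform(0.6, 0.95)),
                                  int(master.integers(1, 4)),
                                  status="pseudogene" if i == 0 else "functional",
                                  defect="premature_stop" if i == 0 else None)
                     for i in range(3)]
            sim = syn.simulate_genome(syn.GenomeSpec(
                seed_protein=seed_protein, genes=genes, contig_length=60_000,
                seed=seed))
            contigs = {g.id: g.seq for g in sim.genomes}
            for truth in sim.truth:
                prot = translate(truth.spliced_cds(contigs[truth.contig]))
                if truth.status == "functional":
                    assert "*" not in prot
                elif "premature_stop" in truth.defects:
                    assert "*" in prot[:-1]

    def test_split_contig_artifact(self, seed_protein):
        spec = self._spec(seed_protein, seed=9, split_contig_gene="g2")
        sim = syn.simulate_genome(spec)
        assert len(sim.genomes) == 2
        parts = [t for t in sim.truth if t.gene_id.startswith("g2.part")]
        assert len(parts) == 2
        assert {p.contig for p in parts} == {g.id for g in sim.genomes}
        assert all(p.status == "pseudogene" for p in parts)


class TestSimulateFamily:
    TREE = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_no_events_gives_congruent_tree(self):
        fam = syn.simulate_family(syn.FamilyScenario(self.TREE, 0.0, 0.0, seed=4))
        assert fam.events == []
        assert sorted(fam.leaf_species.values()) == ["A", "B", "C", "D"]

    def test_deterministic(self):
        a = syn.simulate_family(syn.FamilyScenario(self.TREE, 0.5, 0.2, seed=8))
        b = syn.simulate_family(syn.FamilyScenario(self.TREE, 0.5, 0.2, seed=8))
        assert len(a.events) == len(b.events)
        assert sorted(a.leaf_proteins) == sorted(b.leaf_proteins)
        assert all(a.leaf_proteins[k].seq == b.leaf_proteins[k].seq
                   for k in a.leaf_proteins)

    def test_no_death_leaf_count_identity(self):
        """With no losses, every gene-tree leaf beyond one per species is
        accounted for by surviving duplications in the event log."""
        for s in range(10):
            fam = syn.simulate_family(
                syn.FamilyScenario(self.TREE, 0.5, 0.0, seed=s))
            assert fam.n_losses == 0
            rec = lca_reconcile(fam.gene_tree, read_newick(self.TREE))
            assert rec.n_duplications == fam.n_duplications
            assert len(fam.leaf_proteins) >= 4

    def test_polytomous_species_tree_rejected(self):
        with pytest.raises(Exception):
            syn.simulate_family(syn.FamilyScenario("(A,B,C);", 0.1, 0.0, seed=0))
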