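import numpy as np
import pytest

from famtrace import gene_models as gm
from famtrace import synthetic_data as syn
from famtrace import translated_search as ts
from famtrace.sequence_io import GenomeRecord, ProteinRecord

from _oracles import enumerate_splice_optimum, naive_ggxnw_hits
from conftest import random_protein


def _hit(contig="c", strand="+", g=(0, 300), q=(0, 100), score=100):
    return ts.TranslatedHit("q", contig, strand, 0, g[0], g[1], q[0], q[1],
                            score)


class TestClusterHits:
    def test_colinear_hits_within_max_intron_join(self):
        hits = [_hit(g=(1000, 1300), q=(0, 100)),
                _hit(g=(2300, 2600), q=(100, 200))]
        loci = gm.cluster_hits(hits, max_intron=20_000)
        assert len(loci) == 1
        assert loci[0].hit_span == (1000, 2600)

    def test_gap_beyond_max_intron_splits(self):
        hits = [_hit(g=(1000, 1300), q=(0, 100)),
                _hit(g=(2300, 2600), q=(100, 200))]
        loci = gm.cluster_hits(hits, max_intron=500)
        assert len(loci) == 2

    def test_inverted_query_order_splits_tandem(self):
        # downstream hit restarts at the query N-terminus: a second copy
        hits = [_hit(g=(1000, 1600), q=(100, 300)),
                _hit(g=(1500, 2100), q=(0, 200))]
        loci = gm.cluster_hits(hits, max_intron=20_000, min_locus_score=0)
        assert len(loci) == 2

    def test_window_padding_clipped_to_contig(self):
        loci = gm.cluster_hits([_hit(g=(100, 400))], max_intron=1000,
                               contig_lengths={"c": 800})
        assert loci[0].window == (0, 800)

    def test_low_scoring_cluster_dropped(self):
        loci = gm.cluster_hits([_hit(score=10)], min_locus_score=50)
        assert loci == []


def _locus_for(truth, genome, pad=60):
    lo, hi = truth.span
    win = (max(0, lo - pad), min(genome.length, hi + pad))
    return gm.CandidateLocus(genome.id, truth.strand, win, win, [], "q", 0)


class TestSpliceAlign:
    def test_identity_gene_recovers_planted_exons(self, rng):
        prot = random_protein(rng, 80)
        contig = syn.random_dna(4000, 0.42, rng)
        c2, truth = syn.plant_gene(contig, prot, 2, (60, 200), 800, "+", rng)
        genome = GenomeRecord("g", c2)
        model = gm.splice_align(prot, _locus_for(truth, genome), genome)
        assert sorted(model.exons) == sorted(truth.exons)
        assert model.status == "functional"
        assert model.protein == prot.seq

    def test_background_window_rejected(self, rng):
        genome = GenomeRecord("g", syn.random_dna(2000, 0.42, rng))
        locus = gm.CandidateLocus("g", "+", (0, 2000), (0, 2000), [], "q", 0)
        prot = random_protein(rng, 80)
        assert gm.splice_align(prot, locus, genome) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_score_matches_exhaustive_parse_enumeration(self, seed):
        """The splice DP optimum equals brute-force enumeration of all
        GT..AG parse combinations at identity 1."""
        rng = np.random.default_rng(7000 + seed)
        prot = random_protein(rng, int(rng.integers(35, 50)))
        contig = syn.random_dna(900, 0.42, rng)
        n_exons = int(rng.integers(1, 4))
        c2, truth = syn.plant_gene(contig, prot, n_exons, (60, 75), 300,
                                   "+", rng)
        genome = GenomeRecord("g", c2)
        params = gm.GeneModelParams(max_end_extension=0)
        lo, hi = truth.span
        wlo, whi = max(0, lo - 50), min(genome.length, hi + 50)
        locus = gm.CandidateLocus("g", "+", (wlo, whi), (wlo, whi), [], "q", 0)
        model = gm.splice_align(prot, locus, genome, params)
        oracle = enumerate_splice_optimum(
            prot.seq, genome.seq[wlo:whi], params.min_intron,
            params.intron_penalty, max_introns=2)
        assert model.score == oracle

    def test_dp_not_below_single_exon_interpretation(self, rng):
        """Splice DP score >= best ungapped single-frame local score."""
        from _oracles import best_six_frame_score

        prot = random_protein(rng, 60)
        contig = syn.random_dna(3000, 0.42, rng)
        c2, truth = syn.plant_gene(contig, prot, 3, (60, 100), 600, "+", rng)
        genome = GenomeRecord("g", c2)
        model = gm.splice_align(prot, _locus_for(truth, genome), genome)
        lo, hi = truth.span
        single = best_six_frame_score(prot.seq, c2[lo:hi])
        assert model.score >= single


class TestClassifyStatus:
    def _model(self, protein, defects=(), coverage=1.0):
        qlen = 100
        return gm.GeneModel(
            gene_id="g", contig="c", strand="+", exons=[(0, 3 * len(protein))],
            cds="", protein=protein, defects=list(defects),
            q_start=0, q_end=int(coverage * qlen), query_length=qlen)

    def test_internal_stop_is_pseudogene(self):
        status, defects = gm.classify_status(self._model("MKV*LLRW"))
        assert status == "pseudogene" and defects == ["premature_stop"]

    def test_clean_model_is_functional(self):
        status, defects = gm.classify_status(self._model("MKVLLRW"))
        assert (status, defects) == ("functional", [])

    def test_frameshift_parse_is_pseudogene(self):
        status, defects = gm.classify_status(
            self._model("MKVLLRW", defects=["frameshift"]))
        assert status == "pseudogene" and "frameshift" in defects

    def test_missing_start_or_low_coverage_truncated(self):
        status, defects = gm.classify_status(self._model("KVLLRW"))
        assert status == "pseudogene" and "truncated" in defects
        status, defects = gm.classify_status(self._model("MKVLLRW", coverage=0.5))
        assert "truncated" in defects


class TestScanMotifs:
    def test_ggxnw_match(self):
        hits = gm.scan_motifs("AAGGLLLWAA", {"ggxnw": r"GG.{1,5}W"})
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (2, 8)

    def test_no_tryptophan_no_hit(self):
        assert gm.scan_motifs("AAGGLLLAAA", {"ggxnw": r"GG.{1,5}W"}) == []

    def test_malformed_pattern_rejected(self):
        with pytest.raises(ValueError):
            gm.scan_motifs("MKV", {"bad": r"GG(.{1,5}W"})

    def test_agrees_with_naive_scan_on_random_proteins(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            prot = "".join(rng.choice(list("ACDGWLKGG"), 80))
            rx = gm.scan_motifs(prot, {"ggxnw": r"GG.{3,60}?W"})
            naive = naive_ggxnw_hits(prot)
            assert [(h.start, h.end) for h in rx] == naive
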