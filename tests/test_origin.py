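import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orphanforge as of
from orphanforge.synth import _random_dna, _random_orf, _random_protein


@pytest.fixture(scope="module")
def origin_scenario():
    genome, models, ledger = of.synth_genome_with_genes(
        contig_len=120_000, seed=31,
        classes={"conserved": 4, "orphan_unknown": 2, "orphan_dup": 1,
                 "orphan_te": 1, "orphan_overlap": 1, "orphan_denovo": 1})
    proteins = {m.gene_id: of.ProteinRecord(m.gene_id, m.protein_sequence(genome))
                for m in models}
    return genome, models, ledger, proteins


class TestParalogs:
    def test_planted_duplicate_flagged(self, origin_scenario):
        genome, models, ledger, proteins = origin_scenario
        dup = [g for g, c in ledger.origin_class.items() if c == "duplication"]
        hits = of.find_paralogs(proteins[dup[0]], list(proteins.values()))
        assert {h.subject_id for h in hits} >= {dup[1]}

    def test_lone_orphan_not_flagged(self, origin_scenario):
        genome, models, ledger, proteins = origin_scenario
        lone = next(g for g, c in ledger.origin_class.items() if c == "unknown")
        hits = of.find_paralogs(proteins[lone], list(proteins.values()))
        assert hits == []

    def test_self_hit_excluded(self, origin_scenario):
        _, _, _, proteins = origin_scenario
        p = next(iter(proteins.values()))
        assert of.find_paralogs(p, [p]) == []


class TestTEOverlap:
    def test_planted_te_fragment_detected(self, origin_scenario):
        genome, models, ledger, _ = origin_scenario
        te_gene = next(g for g, c in ledger.origin_class.items() if c == "te_derived")
        m = next(m for m in models if m.gene_id == te_gene)
        ev = of.assess_te_overlap(m.cds_sequence(genome), ledger.te_sequences)
        assert ev["te_derived"] and ev["overlap_bp"] >= 140

    def test_no_te_db_means_no_flag(self, origin_scenario):
        genome, models, *_ = origin_scenario
        ev = of.assess_te_overlap(models[0].cds_sequence(genome), {})
        assert not ev["te_derived"]

    def test_dissimilar_te_below_cutoff(self, rng):
        cds = _random_orf(rng, 100, 0.5)
        te = {"TE1": _random_dna(rng, 500, 0.45)}
        ev = of.assess_te_overlap(cds, te)
        assert not ev["te_derived"]

    def test_coordinate_mode(self):
        ev = of.assess_te_overlap(
            "ATG" * 40, cds_intervals=[(100, 220)], contig="c1",
            te_intervals=[of.TEInterval("c1", 200, 400)])
        assert ev["te_derived"] and ev["overlap_bp"] == 20


class TestOverlappingModels:
    def _gene(self, gid, strand, cds):
        return of.GeneModel(gid, "c1", strand, [cds], [cds])

    def test_thirty_nt_opposite_strand_reported(self):
        pairs = of.find_overlapping_models(
            [self._gene("a", "+", (0, 100)), self._gene("b", "-", (70, 200))])
        assert pairs == [("a", "b", 30)]

    def test_twenty_nine_nt_not_reported(self):
        pairs = of.find_overlapping_models(
            [self._gene("a", "+", (0, 100)), self._gene("b", "-", (71, 200))])
        assert pairs == []

    def test_same_strand_overlap_not_reported(self):
        pairs = of.find_overlapping_models(
            [self._gene("a", "+", (0, 100)), self._gene("b", "+", (0, 100))])
        assert pairs == []

    def test_planted_pair_recovered(self, origin_scenario):
        genome, models, ledger, _ = origin_scenario
        expected = {g for g, c in ledger.origin_class.items() if c == "overlapping_model"}
        pairs = of.find_overlapping_models(models)
        found = {g for a, b, _ in pairs for g in (a, b)}
        assert found == expected


class TestDeNovo:
    def _scenario(self, stop_fraction, intact_in=None, seed=41):
        genome, models, ledger = of.synth_genome_with_genes(
            contig_len=40_000, seed=seed, classes={"orphan_denovo": 1})
        genomes = of.synth_related_genomes(
            models, genome, ledger, n_genomes=2, seed=seed + 1,
            disruption_fraction=stop_fraction, intact_in=intact_in)
        m = models[0]
        prot = of.ProteinRecord(m.gene_id, m.protein_sequence(genome))
        return of.assess_de_novo(m.cds_sequence(genome), prot, genomes)

    def test_stop_at_half_means_disrupted(self):
        assessments, flag = self._scenario(0.5)
        assert flag
        assert all(a.verdict == "disrupted" for a in assessments)
        assert all(abs(a.best_fraction - 0.5) < 0.05 for a in assessments)

    def test_stop_at_ninety_percent_still_coding(self):
        assessments, flag = self._scenario(0.9)
        assert not flag
        assert all(a.verdict == "coding" for a in assessments)

    def test_one_intact_genome_vetoes_de_novo(self):
        assessments, flag = self._scenario(0.5, intact_in={"genome2": ["g0001"]})
        verdicts = {a.genome_id: a.verdict for a in assessments}
        assert verdicts == {"genome1": "disrupted", "genome2": "coding"}
        assert not flag

    def test_unmappable_cds_means_no_flag(self, rng):
        genomes = {"genome1": of.GenomeAssembly({"c1": _random_dna(rng, 5000, 0.4)})}
        cds = _random_orf(rng, 100, 0.45)
        prot = of.ProteinRecord("q", str(len(cds) // 3 * "A"))
        assessments, flag = of.assess_de_novo(cds, prot, genomes)
        assert not flag
        assert assessments[0].verdict == "absent"


class TestClassify:
    def test_no_evidence_is_unknown(self):
        call = of.classify_origin("g")
        assert call.primary_class == "unknown"
        assert not any(call.flags.values())

    def test_precedence_duplication_over_te(self, origin_scenario):
        _, _, _, proteins = origin_scenario
        p = next(iter(proteins.values()))
        hit = of.align_local(p, p)
        call = of.classify_origin("g", paralog_hits=[hit],
                                  te_evidence={"te_derived": True, "overlap_bp": 50})
        assert call.primary_class == "duplication"
        assert call.flags["duplication"] and call.flags["te_derived"]

    def test_only_de_novo(self):
        call = of.classify_origin("g", de_novo_flag=True)
        assert call.primary_class == "de_novo"

    def test_deterministic_and_permutation_invariant(self, origin_scenario):
        genome, models, ledger, proteins = origin_scenario
        args = dict(te_evidence={"te_derived": True, "overlap_bp": 10},
                    de_novo_flag=True)
        assert of.classify_origin("g", **args) == of.classify_origin("g", **args)


class TestFeatures:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5)])
    def test_gc_content(self, seq, expected):
        model = of.GeneModel("g", "c1", "+", [(0, 4)], [(0, 4)])
        genome = of.GenomeAssembly({"c1": seq})
        feats = of.compute_gene_features(model, genome, of.ProteinRecord("g", "M"))
        assert feats.gc == expected

    def test_polyglycine_pI_closed_form(self):
        # only the free termini titrate: pI = (8.6 + 3.6) / 2
        assert of.compute_pI("GGGGG") == pytest.approx(6.10, abs=1e-3)

    def test_adding_arginine_raises_pI(self):
        assert of.compute_pI("GGRGG") > of.compute_pI("GGGGG")

    def test_acidic_peptide_below_seven(self):
        assert of.compute_pI("DDDD") < 7

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_pI_monotone_in_charged_residues(self, pep):
        base = of.compute_pI(pep)
        assert of.compute_pI(pep + "R") >= base - 1e-6
        assert of.compute_pI(pep + "D") <= base + 1e-6

    def test_feature_contrast_recovered(self):
        rng = np.random.default_rng(51)
        genome, models, ledger = of.synth_genome_with_genes(
            contig_len=800_000, seed=51,
            classes={"conserved": 40, "orphan_unknown": 40})
        feats = {}
        for m in models:
            p = of.ProteinRecord(m.gene_id, m.protein_sequence(genome))
            feats[m.gene_id] = of.compute_gene_features(m, genome, p)
        orph = [feats[g] for g in feats if ledger.orphan_status[g]]
        cons = [feats[g] for g in feats if not ledger.orphan_status[g]]
        table = of.compare_feature_distributions(orph, cons)
        # defaults plant shorter, fewer-exon, GC-richer orphans
        assert table.loc["length_nt", "direction"] == -1
        assert table.loc["length_nt", "p"] < 0.05
        assert table.loc["exon_count", "direction"] == -1
        assert table.loc["gc", "direction"] == 1
        assert table.loc["gc", "p"] < 0.05

    def test_empty_orphan_set_rejected(self, origin_scenario):
        with pytest.raises(ValueError):
            of.compare_feature_distributions([], [])
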