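import numpy as np
import pytest
from Bio.Seq import Seq

import orphanforge as of
from orphanforge.synth import _random_dna
from _oracles import brute_force_sites

SPACER = "GGCGTGTTCAGAGGCGCTCC"


def as_key_set(sites):
    return {(s.contig, s.start, s.strand, s.mismatch_count) for s in sites}


class TestSiteScan:
    def test_exact_site_found_with_zero_mismatches(self, rng):
        seq = _random_dna(rng, 2000, 0.4) + SPACER + "AGG" + _random_dna(rng, 500, 0.4)
        sites = of.find_candidate_sites(SPACER, of.GenomeAssembly({"c1": seq}))
        exact = [s for s in sites if s.mismatch_count == 0]
        assert len(exact) == 1
        assert exact[0].start == 2000 and exact[0].pam == "AGG"
        assert exact[0].genomic_20mer == SPACER

    def test_six_substitutions_not_reported(self, rng):
        site = list(SPACER)
        for p in (0, 3, 6, 9, 12, 15):
            site[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[p]]
        seq = _random_dna(rng, 1000, 0.4) + "".join(site) + "TGG"
        sites = of.find_candidate_sites(SPACER, of.GenomeAssembly({"c1": seq}),
                                        max_mismatches=5)
        assert all(s.start != 1000 for s in sites)

    def test_pam_required(self, rng):
        seq = _random_dna(rng, 500, 0.4) + SPACER + "ATT" + _random_dna(rng, 100, 0.4)
        sites = of.find_candidate_sites(SPACER, of.GenomeAssembly({"c1": seq}))
        assert all(s.start != 500 for s in sites)

    def test_matches_brute_force_oracle_on_random_genomes(self):
        rng = np.random.default_rng(91)
        for _ in range(10):
            seq = _random_dna(rng, 3000, 0.45)
            genome = of.GenomeAssembly({"c1": seq})
            ours = as_key_set(of.find_candidate_sites(SPACER, genome, max_mismatches=5))
            oracle = brute_force_sites(SPACER, "c1", seq, 5)
            assert ours == oracle

    def test_scan_is_strand_symmetric(self, rng):
        seq = _random_dna(rng, 4000, 0.45)
        genome = of.GenomeAssembly({"c1": seq})
        flipped = of.GenomeAssembly({"c1": str(Seq(seq).reverse_complement())})
        fwd = as_key_set(of.find_candidate_sites(SPACER, genome))
        rev = as_key_set(of.find_candidate_sites(SPACER, flipped))
        L = len(seq)
        mirrored = {(c, L - s - 20, {"+": "-", "-": "+"}[st], m) for c, s, st, m in fwd}
        assert rev == mirrored

    def test_bad_protospacer_rejected(self):
        with pytest.raises(ValueError):
            of.find_candidate_sites("ACGTN", of.GenomeAssembly({"c": "ACGT" * 10}))


class TestHardFilter:
    def _v(self, pos, qual=100.0, **metrics):
        return of.VariantRecord("c1", pos, "A", "T", qual, metrics)

    def test_good_variant_passes(self):
        vs = [self._v(1, QD=25.0, FS=1.0, ReadPosRankSum=0.0)]
        assert of.hard_filter_variants(vs) == vs

    def test_qd_boundary_strict(self):
        vs = [self._v(1, QD=19.9, FS=1.0)]
        assert of.hard_filter_variants(vs) == []

    def test_absent_metric_passes_that_clause(self):
        vs = [self._v(1)]  # no QD/FS/ReadPosRankSum at all
        assert of.hard_filter_variants(vs) == vs

    def test_mean_qual_clause(self):
        lo = self._v(1, qual=10.0, QD=30.0)
        hi = self._v(2, qual=1000.0, QD=30.0)
        assert of.hard_filter_variants([lo, hi]) == [hi]

    def test_clause_by_clause_oracle_on_toy_set(self):
        vs = [
            self._v(1, qual=100, QD=25.0, FS=1.0, ReadPosRankSum=0.0),   # pass
            self._v(2, qual=100, QD=19.9, FS=1.0, ReadPosRankSum=0.0),   # QD fail
            self._v(3, qual=100, QD=25.0, FS=10.1, ReadPosRankSum=0.0),  # FS fail
            self._v(4, qual=100, QD=25.0, FS=1.0, ReadPosRankSum=-8.5),  # RPRS fail
        ]
        mean_q = 100.0
        expected = [v for v in vs if not (
            v.metrics["QD"] < 20.0 or v.metrics["ReadPosRankSum"] < -8.0
            or v.metrics["FS"] > 10.0 or v.qual < mean_q)]
        assert of.hard_filter_variants(vs) == expected


class TestIntersection:
    def _site(self, start):
        return of.CandidateSite("c1", start, start + 20, "+", "TGG", 3,
                                "A" * 20)

    def test_variant_within_flank_supports_site(self):
        site = self._site(1000)
        v = of.VariantRecord("c1", 1000 + 20 + 10 + 1, "A", "T", 500.0)  # 10 bp past end
        (call,) = of.intersect_candidates([site], [v], [])
        assert call.verdict == "off_target_edit"

    def test_variant_outside_flank_ignored(self):
        site = self._site(1000)
        v = of.VariantRecord("c1", 1000 + 20 + 25, "A", "T", 500.0)
        (call,) = of.intersect_candidates([site], [v], [])
        assert call.verdict == "no_variant"

    def test_shared_variant_excluded(self):
        site = self._site(1000)
        v = of.VariantRecord("c1", 1005, "A", "T", 500.0)
        (call,) = of.intersect_candidates([site], [v], [v])
        assert call.verdict == "excluded_shared" and call.in_control

    def test_on_target_verdict(self):
        site = self._site(1000)
        v = of.VariantRecord("c1", 1010, "AT", "A", 500.0)
        (call,) = of.intersect_candidates([site], [v], [],
                                          target_locus=("c1", 1000, 1023))
        assert call.verdict == "on_target_edit"

    def test_adding_control_variants_never_increases_off_targets(self, rng):
        sites = [self._site(s) for s in (100, 500, 900)]
        muts = [of.VariantRecord("c1", s + 5, "A", "T", 500.0) for s in (100, 500, 900)]
        base = of.intersect_candidates(sites, muts, [])
        n_base = sum(c.verdict == "off_target_edit" for c in base)
        grown = of.intersect_candidates(sites, muts, muts[:1])
        n_grown = sum(c.verdict == "off_target_edit" for c in grown)
        assert n_grown <= n_base


class TestEndToEnd:
    def _run(self, **kw):
        ledger = of.TruthLedger()
        ref, edited, mut, ctrl, locus = of.synth_edit_experiment(
            SPACER, seed=92, ledger=ledger, **kw)
        sites = of.find_candidate_sites(SPACER, ref)
        passing = of.hard_filter_variants(mut)
        calls = of.intersect_candidates(sites, passing, ctrl, target_locus=locus)
        return of.build_report(calls, len(passing)), ledger

    def test_planted_off_targets_all_reported(self):
        report, ledger = self._run(n_offtargets=3, n_shared=2)
        assert report["verdicts"]["off_target_edit"] == 3
        assert report["verdicts"]["on_target_edit"] == 1
        assert report["verdicts"]["excluded_shared"] == 2

    def test_no_planted_off_targets_clean_conclusion(self):
        report, _ = self._run(n_offtargets=0, n_shared=2)
        assert report["off_target_edits"] == 0
        assert report["conclusion"] == "no off-target edits detected"

    def test_empty_variant_set_all_sites_no_variant(self):
        ref, _, _, _, _ = of.synth_edit_experiment(SPACER, seed=93)
        sites = of.find_candidate_sites(SPACER, ref)
        calls = of.intersect_candidates(sites, [], [])
        assert all(c.verdict == "no_variant" for c in calls)

    def test_planted_two_bp_deletion_detected_on_target(self):
        report, ledger = self._run(n_offtargets=1, n_shared=1)
        detail = report["detail"]
        on = detail[detail.verdict == "on_target_edit"]
        planted = next(s for s in ledger.planted_sites if s["kind"] == "on_target")
        assert list(on["start"]) == [planted["start"]]
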