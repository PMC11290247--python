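import numpy as np
import pandas as pd
import pytest

import orphanforge as of


def make_ct(rows):
    return of.TabularDataset("ct_values", pd.DataFrame(rows))


class TestRPKM:
    def test_worked_example(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g"])
        rpkm = of.compute_rpkm(counts, {"g": 1000}, {"s1": 1_000_000})
        assert rpkm.df.loc["g", "s1"] == 10.0

    def test_zero_counts_zero_rpkm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        assert of.compute_rpkm(counts, {"g": 500}, {"s1": 10_000}).df.loc["g", "s1"] == 0.0

    def test_doubling_library_halves_rpkm(self):
        counts = pd.DataFrame({"s1": [7], "s2": [7]}, index=["g"])
        rpkm = of.compute_rpkm(counts, {"g": 300}, {"s1": 1_000_000, "s2": 2_000_000})
        assert rpkm.df.loc["g", "s1"] == 2 * rpkm.df.loc["g", "s2"]


class TestExpressionFilters:
    def test_rpkm_exactly_two_not_expressed(self):
        df = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["g"])
        out = of.filter_expression_classes(of.TabularDataset("expression", df))
        assert out["expressed"] == set()

    def test_planted_male_biased_recovered_exactly(self):
        genes = [f"g{i:03d}" for i in range(80)]
        biased = genes[:7]
        expr = of.synth_expression(genes, seed=61, biased_set=biased, fold=5)
        out = of.filter_expression_classes(expr, specificity_fold=5)
        assert out["stage_specific_high"]["male_adult"] == set(biased)

    def test_background_only_filter_empty(self):
        genes = [f"g{i}" for i in range(50)]
        expr = of.synth_expression(genes, seed=62, biased_set=())
        out = of.filter_expression_classes(expr, specificity_fold=5)
        assert out["stage_specific_high"]["male_adult"] == set()

    def test_gene_high_in_two_stages_excluded_from_both(self):
        df = pd.DataFrame({"male_adult": [400.0], "egg": [400.0], "larva": [1.0]},
                          index=["g"])
        out = of.filter_expression_classes(of.TabularDataset("expression", df),
                                           specificity_fold=5)
        assert out["high"] == {"g"}
        assert out["stage_specific_high"]["male_adult"] == set()
        assert out["stage_specific_high"]["egg"] == set()

    def test_filters_idempotent(self):
        genes = [f"g{i}" for i in range(30)]
        expr = of.synth_expression(genes, seed=63, biased_set=genes[:3], fold=5)
        first = of.filter_expression_classes(expr)
        sub = of.TabularDataset("expression", expr.df.loc[sorted(first["expressed"])])
        second = of.filter_expression_classes(sub)
        assert second["expressed"] == first["expressed"]


class TestDDCt:
    def test_worked_example(self):
        ct = make_ct([
            {"sample": "s", "gene": "t", "replicate": "r1", "ct": 20.0},
            {"sample": "s", "gene": "ref", "replicate": "r1", "ct": 18.0},
            {"sample": "cal", "gene": "t", "replicate": "r1", "ct": 21.0},
            {"sample": "cal", "gene": "ref", "replicate": "r1", "ct": 18.0},
        ])
        rel = of.relative_expression_ddct(ct, "t", "ref", calibrator="cal")
        assert rel.sample_values["s"] == pytest.approx(2.0)

    def test_identical_cts_give_unity(self):
        ct = make_ct([
            {"sample": "s", "gene": "t", "replicate": "r1", "ct": 20.0},
            {"sample": "s", "gene": "ref", "replicate": "r1", "ct": 20.0},
        ])
        rel = of.relative_expression_ddct(ct, "t", "ref")
        assert rel.sample_values["s"] == pytest.approx(1.0)

    def test_calibrator_against_itself_is_one(self):
        ct = make_ct([
            {"sample": "cal", "gene": "t", "replicate": "r1", "ct": 23.4},
            {"sample": "cal", "gene": "ref", "replicate": "r1", "ct": 19.9},
        ])
        rel = of.relative_expression_ddct(ct, "t", "ref", calibrator="cal")
        assert rel.sample_values["cal"] == 1.0

    def test_missing_reference_named_in_error(self):
        ct = make_ct([{"sample": "s", "gene": "t", "replicate": "r1", "ct": 20.0}])
        with pytest.raises(ValueError, match="'s'"):
            of.relative_expression_ddct(ct, "t", "ref")

    def test_simulated_fourfold_recovered(self):
        rng = np.random.default_rng(64)
        rows = []
        for r in range(4):
            rows.append({"sample": "treat", "gene": "t", "replicate": f"r{r}",
                         "ct": 20.0 - 2.0 + rng.normal(0, 0.2)})
            rows.append({"sample": "treat", "gene": "ref", "replicate": f"r{r}",
                         "ct": 18.0 + rng.normal(0, 0.2)})
            rows.append({"sample": "cal", "gene": "t", "replicate": f"r{r}",
                         "ct": 20.0 + rng.normal(0, 0.2)})
            rows.append({"sample": "cal", "gene": "ref", "replicate": f"r{r}",
                         "ct": 18.0 + rng.normal(0, 0.2)})
        rel = of.relative_expression_ddct(make_ct(rows), "t", "ref", calibrator="cal")
        assert 3.2 <= rel.sample_values["treat"] <= 5.0


class TestZLinkage:
    def test_noiseless_two_to_one_is_z_linked(self):
        _, ct = of.synth_mating_and_qpcr(0.5, 30, seed=65, copy_ratio=2.0, ct_sd=0.0)
        call = of.call_z_linkage(ct, "target", "Defensin")
        assert call.call == "Z-linked" and call.ratio == pytest.approx(2.0)

    def test_ratio_one_is_autosomal(self):
        assert of.call_z_linkage_from_ratio("g", 1.0).call == "autosomal"

    def test_between_bands_is_ambiguous(self):
        assert of.call_z_linkage_from_ratio("g", 1.45).call == "ambiguous"

    def test_noisy_calls_mostly_correct(self):
        correct = 0
        n = 200
        for i in range(n):
            ratio = 2.0 if i % 2 == 0 else 1.0
            _, ct = of.synth_mating_and_qpcr(0.5, 10, seed=1000 + i,
                                             copy_ratio=ratio, ct_sd=0.2)
            call = of.call_z_linkage(ct, "target", "Defensin")
            expected = "Z-linked" if ratio == 2.0 else "autosomal"
            correct += call.call == expected
        assert correct / n >= 0.95


class TestDEGFilter:
    def test_strict_boundaries(self):
        deg = pd.DataFrame({
            "gene": ["keep", "p_boundary", "lfc_boundary"],
            "padj": [0.049, 0.05, 0.01],
            "log2fc": [1.6, 2.0, -1.5],
        })
        kept = of.filter_deg_table(deg)
        assert list(kept["gene"]) == ["keep"]
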