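"""Genomic qPCR copy-number calling: is a gene Z-linked?

Male Lepidoptera are ZZ and females ZW, so a Z-linked gene shows a 2:1
male:female copy ratio against an autosomal reference gene.
"""

import orphanforge as of

for name, ratio in (("candidate", 2.0), ("autosomal_control", 1.0)):
    _, ct = of.synth_mating_and_qpcr(0.5, 10, seed=10, copy_ratio=ratio,
                                     ct_sd=0.15, target_gene=name)
    call = of.call_z_linkage(ct, name, "Defensin")
    print(f"{name:18} male:female 2^-ddCt = {call.ratio:5.2f}  -> {call.call}")
# A ratio near 2 within the Z band [1.5, 8/3] calls Z-linked; near 1 within
# [0.75, 4/3] calls autosomal; anything between is ambiguous.
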