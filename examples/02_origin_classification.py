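"""Classify orphan origins: duplication, TE-derived, overlapping model,
de novo, or unknown — and contrast gene features against conserved genes."""

import orphanforge as of

genome, models, ledger = of.synth_genome_with_genes(
    contig_len=200_000, seed=3,
    classes={"conserved": 6, "orphan_unknown": 2, "orphan_dup": 1,
             "orphan_te": 1, "orphan_overlap": 1, "orphan_denovo": 1})
proteins = {m.gene_id: of.ProteinRecord(m.gene_id, m.protein_sequence(genome))
            for m in models}
related = of.synth_related_genomes(models, genome, ledger, n_genomes=2, seed=4)
overlap_pairs = {g: other for a, b, _ in of.find_overlapping_models(models)
                 for g, other in ((a, b), (b, a))}

print(f"{'gene':8} {'called':18} {'planted':18}")
for m in models:
    if not ledger.orphan_status[m.gene_id]:
        continue
    cds = m.cds_sequence(genome)
    assessments, dn_flag = of.assess_de_novo(cds, proteins[m.gene_id], related)
    call = of.classify_origin(
        m.gene_id,
        paralog_hits=of.find_paralogs(proteins[m.gene_id], list(proteins.values())),
        te_evidence=of.assess_te_overlap(cds, ledger.te_sequences),
        overlap_partner=overlap_pairs.get(m.gene_id),
        de_novo_flag=dn_flag, de_novo_assessments=assessments)
    print(f"{m.gene_id:8} {call.primary_class:18} "
          f"{ledger.origin_class.get(m.gene_id, '-'):18}")

feats = {g: of.compute_gene_features(m, genome, proteins[g])
         for m in models for g in [m.gene_id]}
orph = [feats[g] for g in feats if ledger.orphan_status[g]]
cons = [feats[g] for g in feats if not ledger.orphan_status[g]]
print("\nfeature contrasts (orphans vs conserved; direction -1 = orphans lower):")
print(of.compare_feature_distributions(orph, cons).round(4).to_string())
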