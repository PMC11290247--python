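# orphanforge

Orphan genes — genes restricted to a single lineage, with no detectable
homolog in any other species — are a recurring source of evolutionary
novelty, and several well-studied cases encode sperm or seminal proteins
that raise male reproductive success. Characterizing one is a long
computational chain: prove the gene has no homologs, work out where it came
from, show when and where it is expressed, rank its protein in the sperm
proteome, quantify its effect on sperm competition, establish its
chromosomal linkage, and audit the CRISPR knockout used to test it.

`orphanforge` implements that whole chain as a tested Python library, paired
with seeded synthetic-data generators that plant a known truth (which genes
are orphans and why, which genes are male-biased, the true protein
abundances, the true paternity share P2, the true copy ratio, the planted
edit sites) so every stage can be scored exactly.

## What it computes

* **Orphan cascade** — a protein is an orphan iff it has no local-alignment
  hit at E ≤ 10⁻³ against related proteomes (BLASTP-like), translated EST
  collections excluding the focal species (tBLASTN-like), or an nr-like
  database. E-values follow Karlin–Altschul: `E = m·n·2^(−(λS − ln K)/ln 2)`.
* **Origin classes** — duplication (paralog at E < 0.001), TE-derived (CDS
  vs TE at E < 10⁻⁵), overlapping gene model (≥ 30 nt CDS overlap, opposite
  strands), de novo (orthologous region found but disrupted by frameshift or
  premature stop in *every* genome where found, "disrupted" meaning no
  stop-free run ≥ 80% of the protein), else unknown. Gene features: GC,
  exon count, length, and pI by bisection of the Henderson–Hasselbalch net
  charge.
* **Expression screens** — RPKM = 10⁹·C/(N·L); expressed (RPKM > 2), highly
  expressed (RPKM > 100), male-adult-specific (additionally ≥ 5× any other
  stage); the DEG cutoff filter (p < 0.05, |log₂FC| > 1.5); comparative
  2^(−ΔΔCt) qPCR; Z-linkage calls from male:female genomic copy ratios
  (expected 2 for ZZ/ZW systems).
* **Sperm proteomics** — NSAF_i = (SpC_i/L_i)/Σ_j(SpC_j/L_j) per replicate,
  found-in-all-replicates confidence filtering, abundance ranking with a
  top-5% flag.
* **Reproductive statistics** — P2 (offense: n_het/(n_het+n_wt); defense:
  n_wt/(n_het+n_wt)) with Clopper–Pearson CIs, sperm-bundle retention
  ratios, exact two-sided Fisher tests, pooled/Welch Student's t, and
  competition-gradient summaries.
* **CRISPR off-target audit** — protospacer scan (≤ 5 mismatches + NGG PAM,
  both strands), GATK-style variant hard filter
  (QD < 20 ‖ ReadPosRankSum < −8 ‖ FS > 10 ‖ QUAL < mean QUAL), 20-bp flank
  intersection with mutant variants, and exclusion of variants shared with
  the unedited control strain.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/` holds one short script per capability. For instance the
expression screen (`examples/03_expression_screen.py`) plants 7
male-adult-biased genes among 100 and recovers exactly those:

```
genes:                100
expressed (RPKM>2):   99
high (RPKM>100):      13
male-adult specific:  7  -> ['g000', 'g001', 'g002', 'g003', 'g004', 'g005', 'g006']
planted biased set:   ['g000', 'g001', 'g002', 'g003', 'g004', 'g005', 'g006']
```

and the sperm-proteome script (`examples/04_sperm_proteome_nsaf.py`) ranks
a planted high-abundance protein first and tests its pre/post-mating
abundance:

```
top of the abundance ranking (NSAF = (SpC/L) / sum(SpC/L)):
         nsaf_pooled  rank  percentile  high_abundance
focal         0.5390     1      0.0196            True
...
before vs after mating: t = 1.20, p = 0.29
the post-mating change is not significant; seminal fluid proteins typically
drop sharply after mating, sperm-bound proteins do not
```

A stable post-mating abundance is one line of evidence that a protein is
sperm-bound rather than a seminal fluid protein.

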