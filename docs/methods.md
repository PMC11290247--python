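# Methods

`orphanforge` reimplements, as a single tested library, the computational
chain used to characterize a lineage-specific ("orphan") gene with a role in
male reproduction in an insect: orphan discovery by homology elimination,
origin classification, expression and sperm-proteome screens, reproductive-
fitness statistics, qPCR copy-number calling, and a CRISPR off-target audit.
Every stage runs on synthetic inputs with planted, ledger-recorded truth, so
each claim the pipeline makes can be scored exactly.

## Homology engine

All similarity searches run on optimal Smith–Waterman local alignment with
affine gaps (Biopython's C Gotoh kernel; BLOSUM62, gap open 11 / extend 1
in the BLAST convention where a gap of length k costs 11 + k). Raw scores
convert to bit scores and E-values with Karlin–Altschul statistics,
`bit = (λS − ln K)/ln 2`, `E = m·n·2^(−bit)`, using the published gapped
BLOSUM62/11/1 constants λ = 0.267, K = 0.041 (configurable). `m` is the
query length and `n` the aggregate residue count of the database being
searched. Nucleotide searches (TE similarity, genome mapping) use 2/−3 with
gap 5/2 and λ = 0.625, K = 0.41. The upstream study names the tools it ran
(BLASTP, tBLASTN, BLAT, BLASTN) but not their scoring parameters; these
defaults are therefore a design decision and are exposed in `ScoringScheme`.
The alignment engine is cross-checked in the test suite against an
independent hand-written quadratic-time DP oracle.

Translated (tBLASTN-style) search aligns the protein query against all six
reading frames of each nucleotide record and reports the best frame per
record. Genome mapping (BLAT stand-in) seeds with exact 11-mers, merges
candidate windows, aligns each window, and returns the best-scoring match
that covers ≥ 50% of the query at ≥ the requested identity; the coverage
floor exists so an isolated exact seed match cannot outrank the real locus.
Heuristic speedups (two-hit seeding, X-drop) are deliberately absent: the
engine targets desk-scale synthetic data, and an adapter seam allows real
BLAST/BLAT executables for full-genome runs.

## Orphan cascade

A focal protein survives to "orphan" only if it has no hit at E ≤ 1e-3 in
(1) any related-species proteome, (2) any translated EST collection
excluding focal-species ESTs, and (3) an nr-like protein database, applied
in that order with early termination — only the existence of a disqualifying
hit matters. Focal sequences leaking into a database are excluded by id.
The stage-2 cutoff mirrors stage 1 (no separate value is published for the
EST screen); both are configurable.

## Origin classification

Four evidence channels are evaluated independently per orphan:

* **duplication** — any non-self hit in the focal proteome at E < 0.001;
* **te_derived** — CDS aligns to a transposable-element sequence at
  E < 1e-5 (similarity mode, default) or intersects TE coordinates
  (coordinate mode); both modes are implemented because the provenance of
  published TE-overlap calls mixes the two;
* **overlapping_model** — CDS-interval overlap ≥ 30 nt (inclusive) with
  another gene model on the opposite strand;
* **de_novo** — an orthologous region exists in ≥ 1 related genome and
  *every* region found is disrupted. A region is scored by its best
  fraction: the longest stop-free translated run from the region start,
  maximized over the three forward frames, divided by the focal protein
  length. `fraction ≥ 0.8` counts as coding (strict reading of the
  "at least 80% of the size" rule); frameshifts are indels of length ≢ 0
  (mod 3) in the gapped CDS-vs-region alignment. Requiring disruption in
  *all* genomes where a region is found is a design decision: one intact
  ortholog implies the gene is not lineage-specific coding.

`primary_class` follows the fixed precedence duplication > te_derived >
overlapping_model > de_novo (the taxonomy is published without precedence);
all flags are retained. No flag ⇒ unknown origin.

Gene features are GC content over the spliced transcript, exon count,
nucleotide/protein lengths, and isoelectric point. pI is the bisection root
of the Henderson–Hasselbalch net charge on [0, 14] to |Q| < 1e-6, with the
EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9,
E 4.1, C 8.5, Y 10.1) since the tool originally used does not publish its
table; the set is configurable. Polyglycine with free termini gives the
one-acid/one-base closed form (8.6 + 3.6)/2 = 6.10, the main numerical
anchor.

## Expression and qPCR

RPKM = 1e9·C/(N·L). The screening thresholds are strict inequalities:
expressed means RPKM > 2 in ≥ 1 sample, high means RPKM > 100 in ≥ 1 stage,
and male-adult-specific additionally requires the male-adult value to be at
least `specificity_fold` (default 5) times the maximum over all other
stages. No numeric specificity rule is published; the fold-based
reconstruction is a documented decision. The differential-expression filter
keeps rows with adjusted p < 0.05 and |log2FC| > 1.5 (both strict); the
differential test itself (dispersion estimation, Wald tests) is out of
scope — the filter takes whichever p column it is given.

Relative qPCR quantity is 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference per
sample and ΔΔCt referenced to a calibrator sample (2^(−ΔCt) without one).
Genomic copy-number calls compare male vs female relative quantity against
an autosomal reference gene: the expected ratio is 2 for a Z-linked gene
(ZZ males, ZW females) and 1 for an autosome. The tolerance bands are
symmetric on the log scale — Z-linked for ratio in [1.5, 8/3], autosomal in
[0.75, 4/3], ambiguous between — because ΔΔCt errors are multiplicative;
with Ct noise of 0.2 cycles and 4 replicates the ΔΔCt standard error is
0.2, giving each class a ≈2σ margin and ≥ 95% correct calls in the
calibration the tests run.

## Sperm proteomics (NSAF)

NSAF_i = (SpC_i/L_i)/Σ_j(SpC_j/L_j) per replicate. Pooled NSAF is computed
from replicate-summed spectral counts (a mean-of-replicate-NSAFs mode is
available). High-confidence proteins must have SpC > 0 in all replicates.
Ranking is by pooled NSAF descending with deterministic tie-break by
protein id; the top ⌈5%·n⌉ are flagged high-abundance, and the percentile
is reported so users can apply their own cut. Zero-count proteins get NSAF
0 with no pseudocounts, the usual spectral-counting convention.

## Reproductive statistics

P2 — the proportion of offspring sired by the last male — is
n_het/(n_het+n_wt) in the offense design (focal genotype mates second) and
n_wt/(n_het+n_wt) in defense, with Clopper–Pearson exact intervals.
Estimates can be per female or over pooled counts (the published pooling is
ambiguous; both modes exist). The sperm-bundle retention ratio is
bundles-after/bundles-before mating. Fisher's exact two-sided p uses the
small-p method — sum over the hypergeometric support of all point
probabilities ≤ the observed one — with exact integer weight comparison,
so there is no floating-point tie tolerance; the test suite checks it to
1e-12 against an exact-rational enumeration oracle and against
scipy.stats.fisher_exact. Student's t is pooled-variance by default
(matching the published naming) with Welch optional.

## Off-target audit

A candidate site is a genomic 20-mer within 5 mismatches (Hamming; genomic
N never matches) of the protospacer with an adjacent NGG on the same
strand; PAM mismatches are not counted and bulges are not modelled. The
scan is vectorized but exactly equivalent to a position-by-position scan,
which the tests verify on random genomes. Variant hard-filtering fails a
record iff QD < 20, ReadPosRankSum < −8, FS > 10, or QUAL below the mean
QUAL of the input set; the ReadPosRankSum sign follows the GATK convention
(the source expression prints "< 8.0", which would discard nearly every
variant) and is configurable; a variant with an absent metric passes that
clause, since it cannot fail on missing evidence. A passing mutant variant
supports a site when its position falls within 20 bp of the site ends
(end-based, a documented choice); variants identical in
(contig, pos, ref, alt) to a control-strain record are excluded as shared
background. The site overlapping the configured target locus is the
on-target edit; everything else with surviving support is an off-target
edit.

## Synthetic data and what it does not show

Generators are pure functions of (parameters, seed). Genes are packed onto
a contig as valid ORFs with per-class length/GC/exon-count distributions
(defaults: conserved ≈160 aa, GC 0.42, ~3 exons; orphans ≈80 aa, GC 0.55,
fewer exons — the qualitative contrasts the feature comparison is meant to
recover; de novo orphans default to ≈150 aa so a chance out-of-frame
stop-free run cannot reach 80% of the protein). Homologs are generated by
per-residue substitution at rate 1 − identity with BLOSUM62-favoured
replacements; background proteins are i.i.d. draws from Robinson–Robinson-
like residue frequencies. Because composition-biased random sequences
occasionally align above the screening cutoff by chance, the proteome
generator verifies every orphan against every generated database and
redraws offending records, making "orphans have no detectable homolog"
true by construction, as the planted-truth contract requires. Spectral
counts are Poisson; Ct noise is Gaussian; offspring genotypes are binomial.

Passing on these data shows the *logic* of each stage is correct — it does
not show robustness to real-data phenomena the generators omit: alignment
heuristics' approximations on diverged homologs, low-complexity and repeat
sequence, EST sequencing error, shared-peptide protein inference, PCR
efficiency differences between primer pairs, or mapping/calling artifacts
upstream of the variant table. Dataset-scale published numbers (e.g. the
counts of orphans or sperm proteins in the original study) depend on
external databases and unreleased raw data and are out of scope by design.

## Problem sizes

The default test and reproduction runs use 100-gene cascades (50 conserved
+ 50 orphans over two related proteomes, one EST collection and an nr-like
set), 100 random 10-kb genomes for the scan oracle, 200 random pairs for
the alignment oracle, all 2×2 tables with margins ≤ 15 for Fisher, 1,000
qPCR trials and 10,000 t-test null pairs — sizes chosen so the full suite
exercises every guarantee in well under a minute per module.
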