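"""Origin classification of orphan genes and gene-feature statistics.

Four origination routes are flagged independently:

* duplication — a paralog elsewhere in the focal proteome (BLASTP-like,
  E < 0.001, self-hit excluded);
* te_derived — the CDS aligns to a transposable-element sequence
  (BLASTN-like, E < 1e-5) or intersects TE coordinates;
* overlapping_model — the CDS overlaps another gene model's CDS by >= 30 nt
  on the opposite strand;
* de_novo — an orthologous region exists in at least one related genome and
  every region found is disrupted (frameshift or premature stop preventing
  translation of >= 80% of the focal protein length).

A gene with no flag set is of unknown origin.  The primary class follows the
fixed precedence duplication > te_derived > overlapping_model > de_novo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import (AlignmentHit, GenomicMatch, ScoringScheme, align_local,
                       map_to_genome, search_protein_db, translate_frame)
from .io_model import GeneModel, GenomeAssembly, ProteinRecord, TEInterval
from .repro_stats import student_t

PRIMARY_PRECEDENCE = ("duplication", "te_derived", "overlapping_model", "de_novo")

# EMBOSS pKa values (the tool the focal study used does not publish its table)
DEFAULT_PKA = {
    "n_term": 8.6, "c_term": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,       # basic side chains
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # acidic side chains
}
BASIC = ("K", "R", "H")
ACIDIC = ("D", "E", "C", "Y")


@dataclass
class OrthologRegionAssessment:
    genome_id: str
    region: GenomicMatch | None
    best_fraction: float = 0.0
    disruptions: list[tuple[str, int]] = field(default_factory=list)
    verdict: str = "absent"  # coding | disrupted | absent


@dataclass
class OriginCall:
    gene_id: str
    flags: dict[str, bool]
    primary_class: str
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GeneFeatures:
    gene_id: str
    gc: float
    exon_count: int
    length_nt: int
    length_aa: int
    pI: float


# ---------------------------------------------------------------------------
# individual evidence channels


def find_paralogs(orphan: ProteinRecord, focal_proteome: Sequence[ProteinRecord],
                  e_cutoff: float = 0.001,
                  scheme: ScoringScheme | None = None) -> list[AlignmentHit]:
    """Paralog hits in the focal proteome (self excluded by id)."""
    return search_protein_db(orphan, focal_proteome, scheme, e_cutoff,
                             exclude_ids=[orphan.protein_id])


def assess_te_overlap(cds_sequence: str,
                      te_sequences: Mapping[str, str] | None = None,
                      e_cutoff: float = 1e-5,
                      cds_intervals: Sequence[tuple[int, int]] | None = None,
                      te_intervals: Sequence[TEInterval] | None = None,
                      contig: str | None = None) -> dict:
    """TE-derivation evidence for one CDS.

    Similarity mode (default): local nucleotide alignment of the CDS against
    each TE sequence; a hit at E < e_cutoff is evidence.  Coordinate mode:
    intersect CDS intervals with TE intervals on the same contig.  Evidence
    from either mode sets the flag; overlap bp recorded.
    """
    scheme = ScoringScheme.nucleotide_default()
    evidence = {"te_derived": False, "overlap_bp": 0, "te_hits": []}
    if te_sequences:
        n_total = sum(len(s) for s in te_sequences.values())
        for tid in sorted(te_sequences):
            hit = align_local(cds_sequence, te_sequences[tid], scheme,
                              query_id="cds", subject_id=tid, db_size=n_total)
            if hit.raw_score > 0 and hit.evalue < e_cutoff:
                evidence["te_derived"] = True
                evidence["te_hits"].append(hit)
                span = hit.query_span
                evidence["overlap_bp"] = max(evidence["overlap_bp"], span[1] - span[0])
    if te_intervals and cds_intervals and contig is not None:
        bp = 0
        for s, e in cds_intervals:
            for te in te_intervals:
                if te.contig == contig:
                    bp += max(0, min(e, te.end) - max(s, te.start))
        if bp > 0:
            evidence["te_derived"] = True
            evidence["overlap_bp"] = max(evidence["overlap_bp"], bp)
    return evidence


def _interval_overlap(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def find_overlapping_models(models: Sequence[GeneModel],
                            min_overlap: int = 30) -> list[tuple[str, str, int]]:
    """Pairs of genes whose CDS overlap by >= min_overlap nt on opposite
    strands ('at least' — boundary inclusive).  Symmetric; each pair once."""
    pairs = []
    for i, g in enumerate(models):
        for h in models[i + 1:]:
            if g.contig != h.contig or g.strand == h.strand:
                continue
            bp = _interval_overlap(g.cds, h.cds)
            if bp >= min_overlap:
                pairs.append((g.gene_id, h.gene_id, bp))
    return pairs


def _assess_region(region: GenomicMatch, region_seq: str, cds: str,
                   protein_len: int) -> OrthologRegionAssessment:
    """Score an orthologous region: longest stop-free translated run from the
    region start over 3 forward frames, relative to the focal protein length;
    frameshifts located from the gapped nucleotide alignment."""
    best_fraction = 0.0
    stops: list[tuple[str, int]] = []
    for frame in (1, 2, 3):
        aa = translate_frame(region_seq, frame)
        run = aa.split("*", 1)[0]
        frac = len(run) / protein_len
        if frac > best_fraction:
            best_fraction = frac
        if "*" in aa and len(run) < protein_len:
            stops.append(("premature_stop", abs(frame) - 1 + 3 * len(run)))
    # frameshift-inducing indels: gap lengths not divisible by 3 in the
    # CDS-vs-region alignment
    scheme = ScoringScheme.nucleotide_default()
    aln_hit = align_local(cds, region_seq, scheme, query_id="cds", subject_id="region")
    disruptions = list(stops)
    if aln_hit.raw_score > 0:
        al = scheme.aligner()
        aln = next(iter(al.align(cds, region_seq)))
        tb, qb = aln.aligned
        for k in range(1, len(tb)):
            gap_t = tb[k][0] - tb[k - 1][1]
            gap_q = qb[k][0] - qb[k - 1][1]
            indel = abs(gap_t - gap_q)
            if indel % 3 != 0:
                disruptions.append(("frameshift", int(tb[k - 1][1])))
    verdict = "coding" if best_fraction >= 0.8 else "disrupted"
    return OrthologRegionAssessment(region.contig, region, best_fraction,
                                    disruptions, verdict)


def assess_de_novo(cds_sequence: str, protein: ProteinRecord,
                   genomes: Mapping[str, GenomeAssembly],
                   min_identity: float = 0.5) -> tuple[list[OrthologRegionAssessment], bool]:
    """De novo origination test against related genomes.

    For each genome, the orthologous region is located by seed-and-extend
    mapping; a found region is 'coding' iff some forward frame translates a
    stop-free run of >= 80% of the focal protein length, else 'disrupted'.
    The de novo flag is true iff a region was found in >= 1 genome and every
    found region is disrupted.
    """
    assessments = []
    for gid in sorted(genomes):
        region = map_to_genome(cds_sequence, genomes[gid], min_identity,
                               query_id=protein.protein_id)
        if region is None:
            assessments.append(OrthologRegionAssessment(gid, None))
            continue
        seq = genomes[gid].fetch(region.contig, *region.span)
        if region.strand == "-":
            from Bio.Seq import Seq
            seq = str(Seq(seq).reverse_complement())
        a = _assess_region(region, seq, cds_sequence, protein.length)
        a.genome_id = gid
        assessments.append(a)
    found = [a for a in assessments if a.verdict != "absent"]
    flag = bool(found) and all(a.verdict == "disrupted" for a in found)
    return assessments, flag


def classify_origin(gene_id: str, *, paralog_hits: Sequence[AlignmentHit] = (),
                    te_evidence: dict | None = None,
                    overlap_partner: str | None = None,
                    de_novo_flag: bool = False,
                    de_novo_assessments: Sequence[OrthologRegionAssessment] = ()) -> OriginCall:
    """Combine evidence channels into an OriginCall.

    Flags are independent; the primary class follows the fixed precedence;
    a gene with no evidence anywhere is of unknown origin.
    """
    flags = {
        "duplication": bool(paralog_hits),
        "te_derived": bool(te_evidence and te_evidence.get("te_derived")),
        "overlapping_model": overlap_partner is not None,
        "de_novo": bool(de_novo_flag),
    }
    primary = next((c for c in PRIMARY_PRECEDENCE if flags[c]), "unknown")
    evidence: dict = {}
    if flags["duplication"]:
        evidence["paralogs"] = list(paralog_hits)
    if flags["te_derived"]:
        evidence["te_overlap_bp"] = te_evidence.get("overlap_bp", 0)
    if flags["overlapping_model"]:
        evidence["partner"] = overlap_partner
    if flags["de_novo"]:
        evidence["ortholog_regions"] = list(de_novo_assessments)
    return OriginCall(gene_id, flags, primary, evidence)


# ---------------------------------------------------------------------------
# gene features


def compute_pI(sequence: str, pka: Mapping[str, float] | None = None,
               tol: float = 1e-6) -> float:
    """Isoelectric point by bisection of the Henderson-Hasselbalch net charge.

    Q(pH) = sum over basic groups n/(1+10^(pH-pKa))
          - sum over acidic groups n/(1+10^(pKa-pH)),
    with free termini plus K/R/H basic and D/E/C/Y acidic side chains.
    X residues carry no charge.  Root found on [0, 14] to |Q| < tol.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = dict(DEFAULT_PKA if pka is None else pka)
    counts = {aa: sequence.count(aa) for aa in BASIC + ACIDIC}

    def net_charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
        for aa in BASIC:
            if counts[aa]:
                q += counts[aa] / (1.0 + 10.0 ** (ph - pka[aa]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
        for aa in ACIDIC:
            if counts[aa]:
                q -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - ph))
        return q

    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_gene_features(model: GeneModel, genome: GenomeAssembly,
                          protein: ProteinRecord | None = None) -> GeneFeatures:
    """GC content, exon count, nucleotide/protein lengths and pI."""
    gene_seq = model.mrna_sequence(genome)
    gc = (gene_seq.count("G") + gene_seq.count("C")) / len(gene_seq)
    prot = protein.sequence if protein else model.protein_sequence(genome)
    return GeneFeatures(model.gene_id, gc, len(model.exons), len(gene_seq),
                        len(prot), compute_pI(prot))


def compare_feature_distributions(orphans: Sequence[GeneFeatures],
                                  conserved: Sequence[GeneFeatures]) -> pd.DataFrame:
    """Two-sample t test per feature (orphans vs conserved) with direction.

    direction is the sign of mean(orphans) - mean(conserved); a negative
    direction on length means orphans are shorter, etc.
    """
    if not orphans or not conserved:
        raise ValueError("both feature sets must be non-empty")
    rows = []
    for feat in ("gc", "exon_count", "length_nt", "length_aa", "pI"):
        x = np.array([getattr(f, feat) for f in orphans], float)
        y = np.array([getattr(f, feat) for f in conserved], float)
        res = student_t(x, y)
        rows.append({
            "feature": feat,
            "mean_orphan": x.mean(),
            "mean_conserved": y.mean(),
            "direction": int(np.sign(x.mean() - y.mean())),
            "t": res["t"],
            "p": res["p"],
        })
    return pd.DataFrame(rows).set_index("feature")
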