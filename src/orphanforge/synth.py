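"""Seeded generators for every input the pipeline consumes, with a truth ledger.

Every generator is a pure function of (parameters, seed).  The planted truth
(orphan status, origin class, male-biased genes, true abundances, true P2,
copy ratios, edit sites) is recorded in a TruthLedger so downstream analyses
can be scored exactly.

Defaults encode the study conditions the pipeline is meant to reproduce:
conserved genes carry detectable homologs in every related proteome, orphans
carry none anywhere; orphan genes are shorter, fewer-exon and GC-richer than
conserved genes; male-adult-biased genes exceed RPKM 100 in male adults at a
configurable fold over all other stages; spectral counts are Poisson draws
around planted abundances over three replicates; offspring genotypes are
binomial in the true P2; genomic qPCR Ct values follow base - log2(copy) with
Gaussian noise; and the edit experiment plants an on-target deletion,
mismatch-carrying off-target sites with mutant-only variants, and background
variants shared with the control strain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_model import GeneModel, GenomeAssembly, ProteinRecord, TabularDataset, VariantRecord

STOPS = {"TAA", "TAG", "TGA"}
# codons whose reverse complement is a stop (forbidden inside two-strand overlaps)
RC_STOPS = {"TTA", "CTA", "TCA"}
AA20 = "ACDEFGHIKLMNPQRSTVWY"
# Robinson-Robinson-like background residue frequencies
AA_FREQ = np.array([0.078, 0.019, 0.053, 0.063, 0.039, 0.072, 0.022, 0.051,
                    0.057, 0.090, 0.022, 0.045, 0.052, 0.042, 0.051, 0.071,
                    0.058, 0.064, 0.013, 0.032])
AA_FREQ = AA_FREQ / AA_FREQ.sum()

_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)

_BLOSUM = substitution_matrices.load("BLOSUM62")


@dataclass
class TruthLedger:
    """Planted ground truth for one synthetic scenario."""

    orphan_status: dict[str, bool] = field(default_factory=dict)
    origin_class: dict[str, str] = field(default_factory=dict)
    disrupted_positions: dict[str, dict[str, int]] = field(default_factory=dict)
    male_biased: list[str] = field(default_factory=list)
    true_abundance: dict[str, float] = field(default_factory=dict)
    dropout_proteins: dict[str, list[str]] = field(default_factory=dict)
    true_p2: dict[str, float] = field(default_factory=dict)
    copy_ratio: dict[str, float] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)
    te_sequences: dict[str, str] = field(default_factory=dict)
    te_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class GeneClassParams:
    mean_len_aa: int = 160
    gc: float = 0.42
    mean_extra_exons: float = 2.0  # exon count = 1 + Poisson(mean_extra_exons)


DEFAULT_CLASS_PARAMS = {
    "conserved": GeneClassParams(160, 0.42, 2.0),
    "orphan": GeneClassParams(80, 0.55, 0.5),
    # long enough that a spurious out-of-frame stop-free run cannot reach 80%
    # of the protein length in an orthologous region
    "orphan_denovo": GeneClassParams(150, 0.55, 0.5),
}


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def _random_codon(rng: np.random.Generator, gc: float, forbid_rc_stop: bool = False) -> str:
    while True:
        c = _random_dna(rng, 3, gc)
        if c in STOPS:
            continue
        if forbid_rc_stop and c in RC_STOPS:
            continue
        return c


def _random_orf(rng: np.random.Generator, n_aa: int, gc: float,
                forbid_rc_stop: bool = False) -> str:
    """ATG + (n_aa - 1) non-stop codons + stop codon."""
    body = "".join(_random_codon(rng, gc, forbid_rc_stop) for _ in range(n_aa - 1))
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + body + stop


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    idx = rng.choice(20, size=n_aa, p=AA_FREQ)
    return "".join(AA20[i] for i in idx)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))] for aa in protein)


def mutate_protein(rng: np.random.Generator, protein: str, identity: float) -> str:
    """Per-residue substitution at rate 1 - identity with BLOSUM62-favoured
    exchanges (replacement probability proportional to exp(score/2))."""
    out = []
    for aa in protein:
        if rng.random() < identity or aa not in AA20:
            out.append(aa)
            continue
        others = [b for b in AA20 if b != aa]
        w = np.array([np.exp(_BLOSUM[aa, b] / 2.0) for b in others])
        out.append(others[rng.choice(len(others), p=w / w.sum())])
    return "".join(out)


# ---------------------------------------------------------------------------
# genome + gene models


def _split_cds(rng: np.random.Generator, cds: str, n_exons: int,
               gc: float) -> tuple[str, list[tuple[int, int]]]:
    """Interleave introns; returns (genomic block, exon offsets within block)."""
    if n_exons <= 1 or len(cds) < 2 * n_exons:
        return cds, [(0, len(cds))]
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
    block, offsets, pos = [], [], 0
    for i, piece in enumerate(pieces):
        block.append(piece)
        offsets.append((pos, pos + len(piece)))
        pos += len(piece)
        if i < len(pieces) - 1:
            intron = _random_dna(rng, int(rng.integers(40, 120)), gc)
            block.append(intron)
            pos += len(intron)
    return "".join(block), offsets


def _place_gene(gene_id: str, contig: str, strand: str, block: str,
                offsets: list[tuple[int, int]], start: int) -> GeneModel:
    B = len(block)
    if strand == "+":
        exons = [(start + a, start + b) for a, b in offsets]
    else:
        exons = sorted((start + B - b, start + B - a) for a, b in offsets)
    return GeneModel(gene_id, contig, strand, exons, list(exons))


def synth_genome_with_genes(contig_len: int, seed: int,
                            n_genes: int | None = None,
                            classes: Mapping[str, int] | None = None,
                            class_params: Mapping[str, GeneClassParams] | None = None,
                            contig_id: str = "chr1",
                            ) -> tuple[GenomeAssembly, list[GeneModel], TruthLedger]:
    """Synthesize a contig carrying valid ORF genes of the requested classes.

    classes maps class labels to counts; labels: 'conserved',
    'orphan_unknown', 'orphan_dup' (each unit plants an orphan plus its
    paralog), 'orphan_te' (CDS contains a TE fragment; TE library recorded in
    the ledger), 'orphan_overlap' (each unit plants an opposite-strand pair
    with a 33-nt CDS overlap), 'orphan_denovo' (disrupted ortholog regions
    are planted later by synth_related_genomes).  With classes=None, n_genes
    conserved genes are generated.  Raises on infeasible packing.
    """
    rng = np.random.default_rng(seed)
    if classes is None:
        if n_genes is None or n_genes < 1:
            raise ValueError("need n_genes >= 1 or a classes mapping")
        classes = {"conserved": n_genes}
    params = dict(DEFAULT_CLASS_PARAMS)
    if class_params:
        params.update(class_params)

    def cls_params(label: str) -> GeneClassParams:
        if label in params:
            return params[label]
        return params["orphan"] if label.startswith("orphan") else params["conserved"]

    ledger = TruthLedger()
    pieces: list[str] = []        # genomic fragments in order
    placed: list[tuple] = []      # (gene_id, strand, block, offsets, rel_start)
    cursor = 0

    def emit_gap(lo: int = 60, hi: int = 200) -> None:
        nonlocal cursor
        gap = _random_dna(rng, int(rng.integers(lo, hi)), 0.40)
        pieces.append(gap)
        cursor += len(gap)

    def emit_gene(gene_id: str, label: str, cds: str | None = None,
                  strand: str | None = None) -> str:
        nonlocal cursor
        p = cls_params(label)
        if cds is None:
            n_aa = max(30, int(rng.normal(p.mean_len_aa, 0.3 * p.mean_len_aa)))
            cds = _random_orf(rng, n_aa, p.gc)
        n_exons = 1 + int(rng.poisson(p.mean_extra_exons))
        block, offsets = _split_cds(rng, cds, n_exons, p.gc)
        strand = strand or ("+" if rng.random() < 0.5 else "-")
        if strand == "-":
            genomic = str(Seq(block).reverse_complement())
        else:
            genomic = block
        emit_gap()
        placed.append((gene_id, strand, block, offsets, cursor))
        pieces.append(genomic)
        cursor += len(genomic)
        ledger.orphan_status[gene_id] = label != "conserved"
        if label != "conserved":
            ledger.origin_class[gene_id] = {
                "orphan_unknown": "unknown", "orphan_dup": "duplication",
                "orphan_te": "te_derived", "orphan_overlap": "overlapping_model",
                "orphan_denovo": "de_novo",
            }.get(label, "unknown")
        return cds

    idx = 0
    te_counter = 0
    for label in sorted(classes):
        for _ in range(classes[label]):
            idx += 1
            gid = f"g{idx:04d}"
            if label == "orphan_dup":
                cds = emit_gene(gid, label)
                idx += 1
                copy_id = f"g{idx:04d}"
                prot = str(Seq(cds).translate())[:-1]
                prot2 = mutate_protein(rng, prot, 0.95)
                cds2 = "ATG" + reverse_translate(rng, prot2[1:]) + "TAA"
                emit_gene(copy_id, label, cds=cds2)
            elif label == "orphan_te":
                te_counter += 1
                te_id = f"TE{te_counter:03d}"
                te_seq = _random_dna(rng, 500, 0.45)
                frag_start = int(rng.integers(0, len(te_seq) - 150))
                frag = te_seq[frag_start : frag_start + 150]
                # keep the inserted fragment stop-free in frame
                codons = [frag[i : i + 3] for i in range(0, 150, 3)]
                codons = [("TGC" if c in STOPS else c) for c in codons]
                frag = "".join(codons)
                te_seq = te_seq[:frag_start] + frag + te_seq[frag_start + 150:]
                ledger.te_sequences[te_id] = te_seq
                p = cls_params(label)
                n_aa = max(80, int(rng.normal(p.mean_len_aa, 0.2 * p.mean_len_aa)))
                head = _random_orf(rng, n_aa, p.gc)
                insert_at = 3 + 3 * int(rng.integers(5, 20))
                cds = head[:insert_at] + frag + head[insert_at:]
                emit_gene(gid, label, cds=cds, strand="+")
            elif label == "orphan_overlap":
                p = cls_params(label)
                # gene A (+ strand): first 10 codons avoid reverse-strand stops,
                # codon 11 is CAT so the partner reads ATG on the minus strand
                n_aa = max(40, int(rng.normal(p.mean_len_aa, 0.2 * p.mean_len_aa)))
                tail = "".join(_random_codon(rng, p.gc) for _ in range(n_aa - 12))
                first10 = "".join(_random_codon(rng, p.gc, forbid_rc_stop=True)
                                  for _ in range(9))
                cds_a = "ATG" + first10 + "CAT" + tail + "TAA"
                emit_gap()
                # partner B (- strand) extends leftwards from gene A's start+33
                n_aa_b = max(40, int(rng.normal(p.mean_len_aa, 0.2 * p.mean_len_aa)))
                left_codons = "".join(_random_codon(rng, p.gc) for _ in range(n_aa_b - 11))
                stop_b = "TAA"
                left_genomic = str(Seq(left_codons + "").reverse_complement())
                left_genomic = str(Seq(stop_b).reverse_complement()) + left_genomic
                a_start_rel = cursor + len(left_genomic)
                pieces.append(left_genomic)
                cursor += len(left_genomic)
                placed.append((gid, "+", cds_a, [(0, len(cds_a))], cursor))
                pieces.append(cds_a)
                cursor += len(cds_a)
                idx += 1
                bid = f"g{idx:04d}"
                b_start = a_start_rel - len(left_genomic)
                b_end = cursor - len(cds_a) + 33
                b_block_len = b_end - b_start
                placed.append((bid, "-", None, [(0, b_block_len)], b_start))
                for g, lab in ((gid, label), (bid, label)):
                    ledger.orphan_status[g] = True
                    ledger.origin_class[g] = "overlapping_model"
            else:
                emit_gene(gid, label)
    emit_gap()
    total = cursor
    if total > contig_len:
        raise ValueError(
            f"infeasible packing: genes need {total} bp, contig_len is {contig_len}")
    pieces.append(_random_dna(rng, contig_len - total, 0.40))
    contig_seq = "".join(pieces)
    genome = GenomeAssembly({contig_id: contig_seq})

    models = []
    for gene_id, strand, _block, offsets, start in placed:
        block_len = max(b for _, b in offsets)
        models.append(_place_gene(gene_id, contig_id, strand,
                                  "N" * block_len, offsets, start))
    models.sort(key=lambda m: m.gene_id)

    # sanity: every gene translates without internal stops
    for m in models:
        prot = m.protein_sequence(genome)
        if "*" in prot:
            raise AssertionError(f"generated gene {m.gene_id} has internal stop")
    return genome, models, ledger


# ---------------------------------------------------------------------------
# related proteomes / ESTs / nr-like database


def synth_related_proteomes(focal: Sequence[ProteinRecord], ledger: TruthLedger,
                            n_species: int = 2, identity: float = 0.8,
                            seed: int = 0, n_background: int = 20,
                            est_only: Sequence[str] = (),
                            focal_species: str = "Pxyl",
                            ) -> tuple[dict[str, list[ProteinRecord]],
                                       dict[str, dict[str, str]],
                                       list[ProteinRecord]]:
    """Related proteomes, EST collections and an nr-like protein database.

    Conserved focal proteins receive a homolog at ~identity in every related
    proteome; ledger-tagged orphans receive none anywhere.  Genes listed in
    est_only are detectable only in the (non-focal) EST collections, so the
    cascade removes them at stage 2.  Focal-species ESTs (excluded by the
    cascade) are also emitted.  Raises when identity is too low for a homolog
    to be distinguishable from background.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if identity < 0.4:
        raise ValueError("identity < 0.4: homologs indistinguishable from background")
    rng = np.random.default_rng(seed)
    est_only = set(est_only)
    conserved = [p for p in focal
                 if not ledger.orphan_status.get(p.protein_id, False)
                 and p.protein_id not in est_only]

    proteomes: dict[str, list[ProteinRecord]] = {}
    for s in range(n_species):
        name = f"species{s + 1}"
        recs = [ProteinRecord(f"{name}|{p.protein_id}",
                              mutate_protein(rng, p.sequence, identity))
                for p in conserved]
        recs += [ProteinRecord(f"{name}|bg{j:03d}",
                               _random_protein(rng, int(rng.integers(80, 300))))
                 for j in range(n_background)]
        proteomes[name] = recs

    ests: dict[str, dict[str, str]] = {"est_db1": {}}
    for p in focal:
        if p.protein_id in est_only:
            hom = mutate_protein(rng, p.sequence, identity)
            ests["est_db1"][f"lepEST|{p.protein_id}"] = reverse_translate(rng, hom)
    # focal-species ESTs: the cascade must ignore these
    for p in list(conserved)[:3]:
        ests["est_db1"][f"{focal_species}|est_{p.protein_id}"] = \
            reverse_translate(rng, p.sequence)
    for j in range(n_background):
        ests["est_db1"][f"lepEST|bg{j:03d}"] = _random_dna(rng, int(rng.integers(300, 900)), 0.45)

    nr_like = [ProteinRecord(f"nr|{p.protein_id}", mutate_protein(rng, p.sequence, identity))
               for p in conserved]
    nr_like += [ProteinRecord(f"nr|bg{j:03d}", _random_protein(rng, int(rng.integers(80, 300))))
                for j in range(n_background)]

    # guarantee the planted truth: no orphan may align to any database record
    # at the screening cutoff (chance similarities between composition-biased
    # random sequences are redrawn)
    orphans = [p for p in focal if ledger.orphan_status.get(p.protein_id, False)]
    if orphans:
        # includes est_only genes so their planted EST stays a true homolog
        by_focal = {p.protein_id: p for p in focal
                    if not ledger.orphan_status.get(p.protein_id, False)}
        for db in list(proteomes.values()) + [nr_like]:
            _scrub_protein_db(rng, db, orphans, by_focal, identity)
        for est_db in ests.values():
            _scrub_est_db(rng, est_db, orphans, by_focal, identity, focal_species)
    return proteomes, ests, nr_like


_SCREEN_E = 1e-3


def _scrub_protein_db(rng, db: list[ProteinRecord], orphans, by_focal, identity,
                      max_tries: int = 30) -> None:
    from .homology import ScoringScheme, search_protein_db

    scheme = ScoringScheme.protein_default()
    for orphan in orphans:
        for _ in range(max_tries):
            hits = search_protein_db(orphan, db, scheme, _SCREEN_E)
            if not hits:
                break
            for h in hits:
                i = next(k for k, r in enumerate(db) if r.protein_id == h.subject_id)
                src = h.subject_id.split("|", 1)[-1]
                if src in by_focal:  # homolog of a conserved gene: remutate
                    seq = mutate_protein(rng, by_focal[src].sequence, identity)
                else:  # background record: redraw
                    seq = _random_protein(rng, len(db[i].sequence))
                db[i] = ProteinRecord(db[i].protein_id, seq)
        else:
            raise RuntimeError(
                f"could not scrub chance hits for orphan {orphan.protein_id}")


def _scrub_est_db(rng, est_db: dict[str, str], orphans, by_focal, identity,
                  focal_species, max_tries: int = 30) -> None:
    from .homology import ScoringScheme, search_translated

    scheme = ScoringScheme.protein_default()
    for orphan in orphans:
        for _ in range(max_tries):
            hits = search_translated(orphan, est_db, scheme, _SCREEN_E)
            hits = [h for h in hits
                    if not h.subject_id.startswith(focal_species + "|")]
            if not hits:
                break
            for h in hits:
                src = h.subject_id.split("|", 1)[-1]
                if src in by_focal:
                    est_db[h.subject_id] = reverse_translate(
                        rng, mutate_protein(rng, by_focal[src].sequence, identity))
                else:
                    est_db[h.subject_id] = _random_dna(
                        rng, len(est_db[h.subject_id]), 0.45)
        else:
            raise RuntimeError(
                f"could not scrub chance EST hits for orphan {orphan.protein_id}")


def synth_related_genomes(models: Sequence[GeneModel], genome: GenomeAssembly,
                          ledger: TruthLedger, n_genomes: int = 2, seed: int = 0,
                          disruption_fraction: float = 0.5,
                          intact_in: Mapping[str, Sequence[str]] | None = None,
                          flank_len: int = 3000) -> dict[str, GenomeAssembly]:
    """Related genomes carrying orthologous regions of the de novo orphans.

    For each ledger gene of class de_novo, every related genome receives a
    copy of its CDS with a premature stop planted at disruption_fraction of
    the protein length (recorded in the ledger).  intact_in maps genome id ->
    gene ids whose copy stays intact there (to exercise the all-found-
    disrupted rule).
    """
    rng = np.random.default_rng(seed)
    intact_in = {k: set(v) for k, v in (intact_in or {}).items()}
    de_novo = [m for m in models if ledger.origin_class.get(m.gene_id) == "de_novo"]
    out = {}
    for g in range(n_genomes):
        gid = f"genome{g + 1}"
        segments = [_random_dna(rng, flank_len, 0.40)]
        for m in de_novo:
            cds = m.cds_sequence(genome)
            region = cds
            if m.gene_id not in intact_in.get(gid, set()):
                n_aa = len(cds) // 3 - 1
                stop_codon_idx = max(1, int(disruption_fraction * n_aa))
                pos = 3 * stop_codon_idx
                region = cds[:pos] + "TAA" + cds[pos + 3:]
                ledger.disrupted_positions.setdefault(m.gene_id, {})[gid] = pos
            segments.append(region)
            segments.append(_random_dna(rng, flank_len, 0.40))
        out[gid] = GenomeAssembly({f"{gid}_c1": "".join(segments)})
    return out


# ---------------------------------------------------------------------------
# expression / spectral counts / mating / qPCR / edit experiment

DEFAULT_STAGES = ("egg", "larva_1", "larva_2", "larva_3", "larva_4_male",
                  "larva_4_female", "pupa_male", "pupa_female",
                  "female_adult", "male_adult")


def synth_expression(gene_ids: Sequence[str], seed: int,
                     stages: Sequence[str] = DEFAULT_STAGES,
                     biased_set: Sequence[str] = (), fold: float = 5.0,
                     background_median: float = 10.0,
                     ledger: TruthLedger | None = None) -> TabularDataset:
    """Stage x sex RPKM matrix with planted male-adult-biased genes.

    Biased genes get male_adult RPKM > 100 and >= fold x their maximum over
    all other stages; background genes are log-normal around
    background_median, and any background gene that would pass the
    male-specific filter by chance is made co-high in a second stage.
    """
    if "male_adult" not in stages:
        raise ValueError("stages must include 'male_adult'")
    if biased_set and fold <= 1:
        raise ValueError("fold must be > 1 for biased genes")
    rng = np.random.default_rng(seed)
    biased = [g for g in gene_ids if g in set(biased_set)]
    df = pd.DataFrame(index=list(gene_ids), columns=list(stages), dtype=float)
    male_col = "male_adult"
    other = [s for s in stages if s != male_col]
    for g in gene_ids:
        base = background_median * rng.lognormal(0.0, 1.0)
        vals = base * rng.lognormal(0.0, 0.5, size=len(stages))
        df.loc[g] = vals
        if g in biased:
            male = rng.uniform(150.0, 500.0)
            df.loc[g, male_col] = male
            for s in other:
                df.loc[g, s] = min(df.loc[g, s], male / (fold * rng.uniform(1.5, 3.0)))
        else:
            row = df.loc[g]
            if row[male_col] > 100 and row[male_col] >= fold * row[other].max():
                df.loc[g, other[int(rng.integers(len(other)))]] = row[male_col]
    if ledger is not None:
        ledger.male_biased = list(biased)
    return TabularDataset("expression", df)


def synth_spectral_counts(protein_lengths: Mapping[str, int], seed: int,
                          abundance: Mapping[str, float] | None = None,
                          n_reps: int = 3, base_abundance: float = 60.0,
                          dropout: Mapping[str, Sequence[str]] | None = None,
                          ledger: TruthLedger | None = None) -> TabularDataset:
    """Replicate spectral counts: SpC ~ Poisson(abundance) per replicate.

    dropout maps protein id -> replicate names forced to zero (to exercise
    the all-replicates confidence filter).
    """
    rng = np.random.default_rng(seed)
    reps = [f"rep{i + 1}" for i in range(n_reps)]
    abundance = dict(abundance or {})
    dropout = {k: set(v) for k, v in (dropout or {}).items()}
    rows = []
    for pid in sorted(protein_lengths):
        mu = abundance.get(pid, base_abundance * rng.lognormal(0.0, 0.6))
        abundance[pid] = mu
        for r in reps:
            spc = 0 if r in dropout.get(pid, ()) else int(rng.poisson(mu))
            rows.append({"protein": pid, "replicate": r, "spc": spc})
    if ledger is not None:
        ledger.true_abundance = {p: float(a) for p, a in abundance.items()}
        ledger.dropout_proteins = {p: sorted(v) for p, v in dropout.items()}
    return TabularDataset("spectral_counts", pd.DataFrame(rows))


def synth_mating_and_qpcr(true_p2: float, n_offspring: int, seed: int,
                          copy_ratio: float = 2.0, ct_sd: float = 0.2,
                          assay: str = "offense", n_replicates: int = 3,
                          n_qpcr_reps: int = 4, target_gene: str = "target",
                          reference_gene: str = "Defensin",
                          ledger: TruthLedger | None = None,
                          ) -> tuple[TabularDataset, TabularDataset]:
    """Mating-outcome genotype counts and genomic-qPCR Ct values.

    Offspring sired by the last male are Binomial(n, true_p2) per replicate
    (hets in the offense design, wild types in defense).  Ct values follow
    Ct = base - log2(copy) + N(0, ct_sd); the reference gene has one copy in
    both sexes, the target has copy_ratio copies in males relative to
    females.
    """
    if not 0 <= true_p2 <= 1:
        raise ValueError("true_p2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    per_rep = n_offspring // n_replicates
    sizes = [per_rep] * (n_replicates - 1) + [n_offspring - per_rep * (n_replicates - 1)]
    rows = []
    for i, n in enumerate(sizes):
        k = int(rng.binomial(n, true_p2))
        n_het, n_wt = (k, n - k) if assay == "offense" else (n - k, k)
        rows.append({"replicate": f"r{i + 1}", "assay": assay,
                     "n_het": n_het, "n_wt": n_wt})
    genotype = TabularDataset("genotype_counts", pd.DataFrame(rows))

    base_target, base_ref = 26.0, 24.0
    ct_rows = []
    for sex in ("female", "male"):
        copies = copy_ratio if sex == "male" else 1.0
        for r in range(n_qpcr_reps):
            ct_rows.append({"sample": sex, "gene": target_gene, "replicate": f"q{r + 1}",
                            "ct": base_target - np.log2(copies) + rng.normal(0, ct_sd)})
            ct_rows.append({"sample": sex, "gene": reference_gene, "replicate": f"q{r + 1}",
                            "ct": base_ref + rng.normal(0, ct_sd)})
    ct = TabularDataset("ct_values", pd.DataFrame(ct_rows))
    if ledger is not None:
        ledger.true_p2[assay] = float(true_p2)
        ledger.copy_ratio[target_gene] = float(copy_ratio)
    return genotype, ct


def synth_edit_experiment(protospacer: str, seed: int,
                          genome_len: int = 50_000, n_offtargets: int = 3,
                          n_shared: int = 2, n_mismatches: int = 3,
                          contig_id: str = "chr1",
                          ledger: TruthLedger | None = None,
                          ) -> tuple[GenomeAssembly, GenomeAssembly,
                                     list[VariantRecord], list[VariantRecord],
                                     tuple[str, int, int]]:
    """Edited-strain scenario: reference genome with planted target sites,
    mutant and control variant sets, and the on-target locus.

    Plants the exact protospacer + PAM at the target locus with a mutant-only
    2-bp deletion; n_offtargets near-match sites (n_mismatches substitutions)
    each carrying a mutant-only SNP within the flank; and n_shared near-match
    sites whose variants appear in both mutant and control (background the
    audit must exclude).  Returns (reference, edited genome, mutant variants,
    control variants, target locus).
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be 20 nt of A/C/G/T")
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(rng, genome_len, 0.40))
    n_sites = 1 + n_offtargets + n_shared
    spacing = genome_len // (n_sites + 1)
    if spacing < 200:
        raise ValueError("genome too short for requested sites")
    loci = [(i + 1) * spacing for i in range(n_sites)]

    def plant(locus: int, mismatches: int) -> str:
        site = list(protospacer)
        if mismatches:
            pos = rng.choice(20, size=mismatches, replace=False)
            for p in pos:
                site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
        planted = "".join(site) + "TGG"
        seq[locus : locus + 23] = planted
        return "".join(site)

    mutant: list[VariantRecord] = []
    control: list[VariantRecord] = []
    metrics = {"QD": 30.0, "FS": 1.0, "ReadPosRankSum": 1.5}

    # on-target: exact match, 2-bp deletion at the cut site (3 bp from PAM)
    on_locus = loci[0]
    plant(on_locus, 0)
    if ledger is not None:
        ledger.planted_sites.append({"kind": "on_target", "start": on_locus,
                                     "mismatches": 0})
    cut = on_locus + 17
    ref_allele = "".join(seq[cut - 1 : cut + 2])
    mutant.append(VariantRecord(contig_id, cut, ref_allele, ref_allele[0],
                                1000.0, metrics))

    for i in range(n_offtargets):
        locus = loci[1 + i]
        plant(locus, n_mismatches)
        vpos = locus + 10 + 1  # 1-based, inside the protospacer
        ref_b = seq[vpos - 1]
        alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
        mutant.append(VariantRecord(contig_id, vpos, ref_b, alt_b, 1000.0, metrics))
        if ledger is not None:
            ledger.planted_sites.append({"kind": "off_target", "start": locus,
                                         "mismatches": n_mismatches})

    for i in range(n_shared):
        locus = loci[1 + n_offtargets + i]
        plant(locus, n_mismatches)
        vpos = locus + 5 + 1
        ref_b = seq[vpos - 1]
        alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
        shared = VariantRecord(contig_id, vpos, ref_b, alt_b, 1000.0, metrics)
        mutant.append(shared)
        control.append(shared)
        if ledger is not None:
            ledger.planted_sites.append({"kind": "shared_background", "start": locus,
                                         "mismatches": n_mismatches})

    reference = GenomeAssembly({contig_id: "".join(seq)})
    edited_seq = "".join(seq[: cut]) + "".join(seq[cut + 2:])  # apply 2-bp deletion
    edited = GenomeAssembly({contig_id: edited_seq})
    target_locus = (contig_id, on_locus, on_locus + 23)
    return reference, edited, mutant, control, target_locus
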