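"""Shared domain types and readers/writers for the formats every stage touches.

Coordinates are 0-based half-open everywhere inside the package; conversion to
and from the 1-based inclusive conventions of GFF3 and VCF happens only at the
I/O boundary.  Sequences are uppercased on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

TABULAR_ROLES = {
    "expression": None,  # wide: gene column + one column per sample/stage
    "spectral_counts": ["protein", "replicate", "spc"],
    "ct_values": ["sample", "gene", "replicate", "ct"],
    "genotype_counts": ["replicate", "assay", "n_het", "n_wt"],
}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class GenomeAssembly:
    """Nucleotide contigs keyed by id (alphabet A/C/G/T/N, uppercase)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {cid!r} has empty sequence")
            bad = set(seq) - NUCLEOTIDE_ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"contig {cid!r}: illegal nucleotide {seq[pos]!r} at position {pos}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


@dataclass
class GeneModel:
    """Gene structure on a contig; exons/CDS are 0-based half-open intervals."""

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    partial: bool = False  # CDS length not divisible by 3

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"gene {self.gene_id}: empty exon interval ({s},{e})")
            if s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))

    def _spliced(self, genome: GenomeAssembly, intervals: Sequence[tuple[int, int]]) -> str:
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in intervals)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def mrna_sequence(self, genome: GenomeAssembly) -> str:
        return self._spliced(genome, self.exons)

    def cds_sequence(self, genome: GenomeAssembly) -> str:
        return self._spliced(genome, self.cds)

    def protein_sequence(self, genome: GenomeAssembly) -> str:
        cds = self.cds_sequence(genome)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.protein_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TEInterval:
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"TE interval on {self.contig}: start must be < end")


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of a VCF row; metrics hold site-level INFO floats."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    qual: float
    metrics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError("variant pos must be >= 1")
        if self.ref == self.alt:
            raise FormatError(f"variant at {self.contig}:{self.pos} has ref == alt")
        if self.qual < 0:
            raise FormatError(f"variant at {self.contig}:{self.pos} has negative QUAL")

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class TabularDataset:
    """Role-tagged table. Long roles carry fixed columns; expression is wide
    (gene index, one column per sample)."""

    role: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in TABULAR_ROLES:
            raise FormatError(f"unknown tabular role {self.role!r}")
        cols = TABULAR_ROLES[self.role]
        if cols is not None:
            missing = [c for c in cols if c not in self.df.columns]
            if missing:
                raise FormatError(f"{self.role} table missing columns {missing}")
        if self.role == "spectral_counts":
            spc = self.df["spc"]
            if (spc < 0).any():
                raise FormatError("spectral counts must be non-negative")
            if not (spc == spc.astype(int)).all():
                raise FormatError("spectral counts must be integers")
            dup = self.df.duplicated(subset=["protein", "replicate"])
            if dup.any():
                raise FormatError("duplicate (protein, replicate) keys")
        elif self.role == "ct_values":
            if (self.df["ct"] <= 0).any():
                raise FormatError("Ct values must be positive")
        elif self.role == "genotype_counts":
            if (self.df[["n_het", "n_wt"]] < 0).to_numpy().any():
                raise FormatError("genotype counts must be non-negative")
        elif self.role == "expression":
            if self.df.index.duplicated().any():
                raise FormatError("duplicate gene ids in expression matrix")


# ---------------------------------------------------------------------------
# readers


def parse_sequences(path: str | Path, kind: str):
    """Parse a FASTA file.

    kind='nucleotide' returns a GenomeAssembly; kind='protein' returns a list
    of ProteinRecord.  Duplicate ids and out-of-alphabet characters are errors.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError("kind must be 'nucleotide' or 'protein'")
    alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - alphabet
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {rec.id!r}: illegal {kind} character {seq[pos]!r} at position {pos}"
            )
        records[rec.id] = seq
    if not records:
        logger.warning("no sequences parsed from %s", path)
        return GenomeAssembly({}) if kind == "nucleotide" else []
    if kind == "nucleotide":
        return GenomeAssembly(records)
    return [ProteinRecord(pid, seq) for pid, seq in records.items()]


def parse_gene_models(path: str | Path, genome: GenomeAssembly) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into GeneModel objects.

    On-disk coordinates are 1-based inclusive; internal are 0-based half-open.
    A CDS whose spliced length is not a multiple of 3 is flagged partial.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for ex in db.children(gene, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))
        for c in db.children(gene, featuretype="CDS"):
            cds.append((c.start - 1, c.end))
        exons.sort()
        cds.sort()
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        contig_len = genome.lengths.get(gene.seqid)
        if contig_len is None:
            raise FormatError(f"gene {gene.id}: contig {gene.seqid!r} not in assembly")
        for s, e in exons:
            if s < 0 or e > contig_len:
                raise FormatError(f"gene {gene.id}: exon ({s},{e}) outside contig")
        model = GeneModel(gene.id, gene.seqid, gene.strand, exons, cds or list(exons))
        model.partial = model.cds_length() % 3 != 0
        models.append(model)
    return models


def parse_tabular(path: str | Path, role: str) -> TabularDataset:
    """Read a TSV with header into a role-validated TabularDataset."""
    if role == "expression":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t")
    return TabularDataset(role, df)


def parse_variants(path: str | Path) -> list[VariantRecord]:
    """Read a VCF (4.x) into VariantRecords, one per ALT allele.

    Site-level INFO metrics QD, FS and ReadPosRankSum are kept as floats when
    present; an absent metric stays absent rather than defaulting to zero.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            try:
                metrics = {}
                for key in ("QD", "FS", "ReadPosRankSum"):
                    if key in rec.info:
                        val = rec.info[key]
                        val = float(val[0] if isinstance(val, tuple) else val)
                        # htslib stores INFO floats in single precision
                        metrics[key] = float(f"{val:.7g}")
                for alt in rec.alts or ():
                    out.append(
                        VariantRecord(
                            rec.contig, rec.pos, rec.ref, alt,
                            float(rec.qual) if rec.qual is not None else 0.0,
                            metrics,
                        )
                    )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: unparsable VCF record #{i + 1}: {exc}") from exc
    return out


def parse_bed(path: str | Path) -> list[TEInterval]:
    """Read a 3+-column BED (0-based half-open) into TEIntervals."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: BED line with fewer than 3 columns")
            out.append(TEInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# writers (used by the synthetic-data generators and for round-tripping)


def write_fasta(records, path: str | Path) -> None:
    """Write ProteinRecords, (id, seq) pairs, or a GenomeAssembly to FASTA."""
    if isinstance(records, GenomeAssembly):
        items = records.contigs.items()
    elif records and isinstance(records[0], ProteinRecord):
        items = [(r.protein_id, r.sequence) for r in records]
    else:
        items = list(records)
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = min(s for s, _ in m.exons) + 1, max(e for _, e in m.exons)
            fh.write(
                f"{m.contig}\torphanforge\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig}\torphanforge\tmRNA\t{gs}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={mid};Parent={m.gene_id}\n"
            )
            for j, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.contig}\torphanforge\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mid}.exon{j};Parent={mid}\n"
                )
            for j, (s, e) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.contig}\torphanforge\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={mid}.cds{j};Parent={mid}\n"
                )


def write_bed(intervals: Iterable[TEInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def write_vcf(variants: Sequence[VariantRecord], path: str | Path,
              contig_lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={cid},length={ln}>\n")
        for key in ("QD", "FS", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda r: (r.contig, r.pos, r.alt)):
            info = ";".join(f"{k}={v.metrics[k]:g}" for k in ("QD", "FS", "ReadPosRankSum")
                            if k in v.metrics) or "."
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:g}\t.\t{info}\n")


def write_tabular(dataset: TabularDataset, path: str | Path) -> None:
    if dataset.role == "expression":
        dataset.df.to_csv(path, sep="\t", index_label="gene")
    else:
        dataset.df.to_csv(path, sep="\t", index=False)
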