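"""Desk-scale local alignment and database search.

The engine computes optimal Smith-Waterman affine-gap alignments (via
Biopython's C implementation of Gotoh's algorithm) and converts raw scores to
bit scores and E-values with Karlin-Altschul statistics:

    bit = (lambda * S - ln K) / ln 2,      E = m * n * 2^(-bit)

where m is the query length and n the total residue count of the database.
Default constants are the published gapped BLOSUM62/11/1 values.  A gap of
length k costs gap_open + k * gap_extend (BLAST convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io_model import GenomeAssembly, ProteinRecord

LN2 = math.log(2.0)


def _nucleotide_matrix(match: int = 2, mismatch: int = -3):
    alpha = "ACGTN"
    m = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in alpha:
        for b in alpha:
            if "N" in (a, b):
                m[a, b] = 0
            else:
                m[a, b] = match if a == b else mismatch
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap costs + Karlin-Altschul constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041
    _matrix: object = field(default=None, repr=False, compare=False)

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        # blastn-style 2/-3 with gap 5/2; published gapped constants
        return cls("NUC.2.-3", gap_open=5, gap_extend=2,
                   karlin_lambda=0.625, karlin_K=0.41,
                   _matrix=_nucleotide_matrix())

    @property
    def matrix(self):
        if self._matrix is not None:
            return self._matrix
        return substitution_matrices.load(self.matrix_name)

    def aligner(self) -> PairwiseAligner:
        al = PairwiseAligner(mode="local")
        al.substitution_matrix = self.matrix
        # Biopython charges open_gap_score at the first gapped position
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def bit_score(self, raw: float) -> float:
        return (self.karlin_lambda * raw - math.log(self.karlin_K)) / LN2

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw))


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    frame: int | None = None  # set by translated searches

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("reported hits must have non-negative raw score")


@dataclass(frozen=True)
class GenomicMatch:
    query_id: str
    contig: str
    span: tuple[int, int]  # genomic, 0-based half-open, forward coordinates
    strand: str
    identity: float
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    # ((qstart, qend), (gstart, gend)) per gapless block; query coordinates are
    # on the reverse complement of the query for '-' strand matches


def _hit_stats(aln) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Identity over alignment columns (internal gaps included) and spans."""
    c = aln.counts()
    internal_gaps = c.internal_insertions + c.internal_deletions
    cols = c.aligned + internal_gaps
    identity = c.identities / cols if cols else 0.0
    tb, qb = aln.aligned  # (target, query) block lists
    tspan = (int(tb[0][0]), int(tb[-1][1]))
    qspan = (int(qb[0][0]), int(qb[-1][1]))
    return identity, tspan, qspan


def align_local(a: str | ProteinRecord, b: str | ProteinRecord,
                scheme: ScoringScheme | None = None,
                query_id: str = "query", subject_id: str = "subject",
                db_size: int | None = None) -> AlignmentHit:
    """Optimal local alignment of a (query) vs b (subject).

    E-value uses m = len(a) and n = db_size (defaulting to len(b)), so a
    database search can supply its aggregate residue count.
    """
    qid, aseq = (a.protein_id, a.sequence) if isinstance(a, ProteinRecord) else (query_id, a)
    sid, bseq = (b.protein_id, b.sequence) if isinstance(b, ProteinRecord) else (subject_id, b)
    if not aseq or not bseq:
        raise ValueError("align_local requires non-empty sequences")
    scheme = scheme or ScoringScheme.protein_default()
    al = scheme.aligner()
    raw = al.score(aseq, bseq)
    n = db_size if db_size is not None else len(bseq)
    if raw <= 0:
        return AlignmentHit(qid, sid, 0, scheme.bit_score(0),
                            scheme.evalue(0, len(aseq), n), 0.0, (0, 0), (0, 0))
    aln = next(iter(al.align(aseq, bseq)))
    identity, qspan, sspan = _hit_stats(aln)
    return AlignmentHit(qid, sid, int(round(raw)), scheme.bit_score(raw),
                        scheme.evalue(raw, len(aseq), n), identity, qspan, sspan)


def search_protein_db(query: ProteinRecord, db: Sequence[ProteinRecord],
                      scheme: ScoringScheme | None = None,
                      evalue_cutoff: float = 1e-3,
                      exclude_ids: Iterable[str] = (),
                      stop_at_first: bool = False) -> list[AlignmentHit]:
    """All hits with E < evalue_cutoff, sorted by (E, subject id).

    n in the E-value is the total residue count of the database (after
    exclusions).  stop_at_first returns as soon as one passing hit exists —
    the cascade only needs existence.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    excluded = set(exclude_ids)
    subjects = sorted((s for s in db if s.protein_id not in excluded),
                      key=lambda s: s.protein_id)
    if not subjects:
        return []
    scheme = scheme or ScoringScheme.protein_default()
    n_total = sum(s.length for s in subjects)
    al = scheme.aligner()
    hits = []
    for subj in subjects:
        raw = al.score(query.sequence, subj.sequence)
        if raw <= 0:
            continue
        ev = scheme.evalue(raw, query.length, n_total)
        if ev < evalue_cutoff:
            hits.append(align_local(query, subj, scheme, db_size=n_total))
            if stop_at_first:
                break
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


FRAMES = (1, 2, 3, -1, -2, -3)


def translate_frame(nt: str, frame: int) -> str:
    """Translate one reading frame (+1..+3, -1..-3); stops appear as '*'."""
    seq = nt if frame > 0 else str(Seq(nt).reverse_complement())
    off = abs(frame) - 1
    sub = seq[off:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate()) if sub else ""


def search_translated(query: ProteinRecord, nt_db: Mapping[str, str],
                      scheme: ScoringScheme | None = None,
                      evalue_cutoff: float = 1e-3,
                      stop_at_first: bool = False) -> list[AlignmentHit]:
    """tBLASTN-style: align the protein query to all 6 frames of each record.

    Per subject the best frame is reported; E-values use the aggregate
    translated residue count of the database.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    scheme = scheme or ScoringScheme.protein_default()
    frames: dict[str, list[tuple[int, str]]] = {}
    n_total = 0
    for sid in sorted(nt_db):
        fr = [(f, translate_frame(nt_db[sid], f)) for f in FRAMES]
        fr = [(f, p) for f, p in fr if p]
        frames[sid] = fr
        n_total += sum(len(p) for _, p in fr)
    if n_total == 0:
        return []
    al = scheme.aligner()
    hits = []
    for sid, fr in frames.items():
        best = None
        for f, prot in fr:
            raw = al.score(query.sequence, prot)
            if raw <= 0:
                continue
            ev = scheme.evalue(raw, query.length, n_total)
            if ev < evalue_cutoff and (best is None or raw > best[0]):
                best = (raw, f, prot)
        if best is not None:
            hit = align_local(query, best[2], scheme, subject_id=sid, db_size=n_total)
            hits.append(replace(hit, frame=best[1]))
            if stop_at_first:
                break
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    windows.sort()
    merged = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def map_to_genome(query: str, genome: GenomeAssembly, min_identity: float = 0.8,
                  query_id: str = "query", seed_k: int = 11,
                  min_coverage: float = 0.5) -> GenomicMatch | None:
    """BLAT-style seed-and-extend mapping of a nucleotide query.

    Exact k-mer seeds nominate candidate windows on both strands; each window
    is aligned locally (2/-3, gap 5/2).  Candidates must align >= min_coverage
    of the query (so an isolated exact seed cannot outrank the real locus) and
    reach identity >= min_identity; the best-scoring survivor is returned,
    or None.
    """
    if len(query) < seed_k:
        raise ValueError(f"query shorter than seed size {seed_k}")
    scheme = ScoringScheme.nucleotide_default()
    al = scheme.aligner()
    best: GenomicMatch | None = None
    best_score = -1.0
    margin = max(20, len(query) // 5)
    for strand in "+-":
        q = query if strand == "+" else str(Seq(query).reverse_complement())
        kmers: dict[str, list[int]] = {}
        for i in range(0, len(q) - seed_k + 1):
            kmers.setdefault(q[i : i + seed_k], []).append(i)
        for contig in sorted(genome.contigs):
            seq = genome.contigs[contig]
            windows = []
            for j in range(len(seq) - seed_k + 1):
                positions = kmers.get(seq[j : j + seed_k])
                if positions:
                    for qoff in positions:
                        start = max(0, j - qoff - margin)
                        end = min(len(seq), j - qoff + len(q) + margin)
                        windows.append((start, end))
            for ws, we in _merge_windows(windows):
                window = seq[ws:we]
                raw = al.score(q, window)
                if raw <= 0:
                    continue
                aln = next(iter(al.align(q, window)))
                identity, qspan, wspan = _hit_stats(aln)
                coverage = (qspan[1] - qspan[0]) / len(q)
                if identity < min_identity or coverage < min_coverage:
                    continue
                qb, wb = aln.aligned
                blocks = tuple(
                    ((int(q0), int(q1)), (ws + int(w0), ws + int(w1)))
                    for (q0, q1), (w0, w1) in zip(qb, wb)
                )
                match = GenomicMatch(query_id, contig, (ws + wspan[0], ws + wspan[1]),
                                     strand, identity, blocks)
                if raw > best_score:
                    best, best_score = match, raw
    return best
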