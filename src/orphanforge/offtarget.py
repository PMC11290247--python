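"""CRISPR off-target audit.

A candidate site is a genomic 20-mer within a configurable Hamming distance
of the protospacer whose 3' adjacent 3-mer matches the NGG PAM on the same
strand (PAM mismatches are not counted; genomic N never matches).  Candidate
sites are intersected with hard-filtered variants of the edited strain within
a flanking window; variants shared with the unedited control strain are
excluded as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_model import GenomeAssembly, VariantRecord

_ENC = np.zeros(128, dtype=np.int8)
for i, base in enumerate("ACGTN"):
    _ENC[ord(base)] = i
_N = 4


@dataclass(frozen=True)
class CandidateSite:
    contig: str
    start: int  # protospacer span, 0-based half-open, forward coordinates
    end: int
    strand: str
    pam: str             # genomic 3-mer on the protospacer's strand
    mismatch_count: int
    genomic_20mer: str   # strand-oriented

    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.start, self.strand)


@dataclass(frozen=True)
class OffTargetCall:
    site: CandidateSite
    variants: tuple[VariantRecord, ...]
    in_control: bool
    verdict: str  # on_target_edit | off_target_edit | excluded_shared | no_variant


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_forward(arr: np.ndarray, proto: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) for windows with PAM xGG at [start+20, start+23)."""
    L = len(arr)
    k = len(proto)
    n_pos = L - k - 3 + 1
    if n_pos <= 0:
        return []
    g = _ENC[ord("G")]
    pam_ok = (arr[k + 1 : k + 1 + n_pos] == g) & (arr[k + 2 : k + 2 + n_pos] == g)
    pam_ok &= arr[k : k + n_pos] != _N  # genomic N never matches the PAM's N
    mm = np.zeros(n_pos, dtype=np.int16)
    for j in range(k):
        col = arr[j : j + n_pos]
        mm += (col != proto[j]) | (col == _N)
    idx = np.nonzero(pam_ok & (mm <= max_mm))[0]
    return [(int(i), int(mm[i])) for i in idx]


def find_candidate_sites(protospacer: str, genome: GenomeAssembly,
                         max_mismatches: int = 5, pam: str = "NGG") -> list[CandidateSite]:
    """Scan both strands for protospacer matches with an adjacent NGG PAM.

    Sites are sorted by (contig, position, strand).  Only the NGG PAM is
    supported; bulges are not modelled.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be 20 nt of A/C/G/T")
    if pam != "NGG":
        raise ValueError("only the NGG PAM is supported")
    proto = _encode(protospacer)
    sites = []
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        arr = _encode(seq)
        L = len(seq)
        for start, mm in _scan_forward(arr, proto, max_mismatches):
            sites.append(CandidateSite(
                contig, start, start + 20, "+",
                seq[start + 20 : start + 23], mm, seq[start : start + 20]))
        rc = str(Seq(seq).reverse_complement())
        rc_arr = _encode(rc)
        for start, mm in _scan_forward(rc_arr, proto, max_mismatches):
            # position i in rc maps to forward interval [L-i-20, L-i)
            fstart = L - start - 20
            sites.append(CandidateSite(
                contig, fstart, fstart + 20, "-",
                rc[start + 20 : start + 23], mm, rc[start : start + 20]))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def hard_filter_variants(variants: Sequence[VariantRecord],
                         qd_min: float = 20.0, rprs_min: float = -8.0,
                         fs_max: float = 10.0,
                         mean_qual: float | None = None) -> list[VariantRecord]:
    """GATK-style hard filter.

    A variant fails iff QD < qd_min, ReadPosRankSum < rprs_min, FS > fs_max,
    or QUAL < the mean QUAL of the input set (computed here unless supplied).
    A variant with an absent metric passes that clause — it cannot fail on
    missing evidence.  All boundaries are strict.
    """
    if not variants:
        return []
    if mean_qual is None:
        mean_qual = float(np.mean([v.qual for v in variants]))
    passing = []
    for v in variants:
        qd = v.metrics.get("QD")
        rprs = v.metrics.get("ReadPosRankSum")
        fs = v.metrics.get("FS")
        fails = (
            (qd is not None and qd < qd_min)
            or (rprs is not None and rprs < rprs_min)
            or (fs is not None and fs > fs_max)
            or v.qual < mean_qual
        )
        if not fails:
            passing.append(v)
    return passing


def intersect_candidates(sites: Sequence[CandidateSite],
                         mutant_variants: Sequence[VariantRecord],
                         control_variants: Sequence[VariantRecord],
                         flank: int = 20,
                         target_locus: tuple[str, int, int] | None = None) -> list[OffTargetCall]:
    """Match mutant variants to candidate sites within a flanking window.

    A variant (1-based pos) supports a site iff its 0-based position lies in
    [start - flank, end + flank).  A variant also present in the control set
    (identical contig/pos/ref/alt) is shared background and excludes the
    call.  A site overlapping target_locus (contig, start, end; 0-based
    half-open) is the on-target edit.
    """
    control_keys = {v.key() for v in control_variants}
    calls = []
    for site in sites:
        lo, hi = site.start - flank, site.end + flank
        support = tuple(v for v in mutant_variants
                        if v.contig == site.contig and lo <= v.pos - 1 < hi)
        if not support:
            calls.append(OffTargetCall(site, (), False, "no_variant"))
            continue
        fresh = tuple(v for v in support if v.key() not in control_keys)
        if not fresh:
            calls.append(OffTargetCall(site, support, True, "excluded_shared"))
            continue
        on_target = (
            target_locus is not None
            and site.contig == target_locus[0]
            and site.start < target_locus[2]
            and site.end > target_locus[1]
        )
        calls.append(OffTargetCall(site, fresh, False,
                                   "on_target_edit" if on_target else "off_target_edit"))
    return calls


def build_report(calls: Sequence[OffTargetCall],
                 n_variants_filtered: int | None = None) -> dict:
    """Verdict tallies plus a per-site detail table (deterministic order)."""
    tallies = {v: 0 for v in ("on_target_edit", "off_target_edit",
                              "excluded_shared", "no_variant")}
    rows = []
    for c in sorted(calls, key=lambda c: c.site.key()):
        tallies[c.verdict] += 1
        rows.append({
            "contig": c.site.contig, "start": c.site.start, "end": c.site.end,
            "strand": c.site.strand, "mismatches": c.site.mismatch_count,
            "pam": c.site.pam, "n_variants": len(c.variants), "verdict": c.verdict,
        })
    detail = pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                         "mismatches", "pam", "n_variants", "verdict"])
    report = {
        "candidate_sites": len(calls),
        "verdicts": tallies,
        "off_target_edits": tallies["off_target_edit"],
        "conclusion": ("no off-target edits detected" if tallies["off_target_edit"] == 0
                       else f"{tallies['off_target_edit']} off-target edit(s) detected"),
        "detail": detail,
    }
    if n_variants_filtered is not None:
        report["variants_after_filter"] = n_variants_filtered
    return report
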