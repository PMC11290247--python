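"""Three-stage elimination cascade defining orphan genes.

A focal protein is screened against (1) related-species proteomes, (2)
translated EST collections excluding the focal species, and (3) an nr-like
protein database.  Any hit at E-value below the cutoff eliminates the gene at
that stage; survivors of all three stages are orphans — genes with no
detectable homology outside the focal lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .homology import ScoringScheme, search_protein_db, search_translated
from .io_model import ProteinRecord, TabularDataset


@dataclass
class OrphanCallAudit:
    gene_id: str
    stage_hits: dict[int, int] = field(default_factory=dict)   # stage -> hit count
    stage_best_e: dict[int, float] = field(default_factory=dict)
    final_status: str = "orphan"  # orphan | eliminated@1 | eliminated@2 | eliminated@3

    @property
    def is_orphan(self) -> bool:
        return self.final_status == "orphan"


def run_orphan_cascade(focal: Sequence[ProteinRecord],
                       related_proteomes: Mapping[str, Sequence[ProteinRecord]],
                       est_dbs: Mapping[str, Mapping[str, str]],
                       nr_like_db: Sequence[ProteinRecord],
                       e_cutoff: float = 1e-3,
                       focal_species: str | None = None,
                       scheme: ScoringScheme | None = None) -> list[OrphanCallAudit]:
    """Run the elimination cascade; one audit per focal protein.

    EST records whose id starts with ``focal_species + '|'`` are excluded from
    stage 2.  Focal sequences leaking into any database are excluded by id.
    A gene eliminated at a stage is not searched at later stages.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    scheme = scheme or ScoringScheme.protein_default()
    focal_ids = {p.protein_id for p in focal}
    est_filtered = {
        name: {eid: seq for eid, seq in db.items()
               if focal_species is None or not eid.startswith(focal_species + "|")}
        for name, db in est_dbs.items()
    }
    audits = []
    for prot in focal:
        audit = OrphanCallAudit(prot.protein_id)
        # stage 1: related proteomes (BLASTP-like)
        n_hits, best_e = 0, float("inf")
        for db in related_proteomes.values():
            hits = search_protein_db(prot, db, scheme, e_cutoff,
                                     exclude_ids=focal_ids, stop_at_first=True)
            n_hits += len(hits)
            if hits:
                best_e = min(best_e, hits[0].evalue)
        audit.stage_hits[1] = n_hits
        if n_hits:
            audit.stage_best_e[1] = best_e
            audit.final_status = "eliminated@1"
            audits.append(audit)
            continue
        # stage 2: translated ESTs, focal species excluded (tBLASTN-like)
        n_hits, best_e = 0, float("inf")
        for db in est_filtered.values():
            hits = search_translated(prot, db, scheme, e_cutoff, stop_at_first=True)
            n_hits += len(hits)
            if hits:
                best_e = min(best_e, hits[0].evalue)
        audit.stage_hits[2] = n_hits
        if n_hits:
            audit.stage_best_e[2] = best_e
            audit.final_status = "eliminated@2"
            audits.append(audit)
            continue
        # stage 3: nr-like protein database
        hits = search_protein_db(prot, nr_like_db, scheme, e_cutoff,
                                 exclude_ids=focal_ids, stop_at_first=True)
        audit.stage_hits[3] = len(hits)
        if hits:
            audit.stage_best_e[3] = hits[0].evalue
            audit.final_status = "eliminated@3"
        audits.append(audit)
    return audits


def summarize_audit(audits: Sequence[OrphanCallAudit],
                    expression: TabularDataset | None = None,
                    expressed_cut: float = 2.0) -> pd.Series:
    """Stage-count summary; counts conserve (input = eliminated + orphans).

    With an expression matrix attached, also reports the fraction of orphans
    expressed (RPKM > expressed_cut in at least one sample).
    """
    counts = {"input": len(audits)}
    for s in (1, 2, 3):
        counts[f"eliminated@{s}"] = sum(a.final_status == f"eliminated@{s}" for a in audits)
    orphans = [a.gene_id for a in audits if a.is_orphan]
    counts["orphans"] = len(orphans)
    if expression is not None and orphans:
        df = expression.df
        present = [g for g in orphans if g in df.index]
        expressed = sum((df.loc[g] > expressed_cut).any() for g in present)
        counts["orphans_expressed"] = expressed
        counts["orphans_expressed_fraction"] = expressed / len(orphans)
    return pd.Series(counts)


def audits_to_frame(audits: Sequence[OrphanCallAudit]) -> pd.DataFrame:
    rows = []
    for a in audits:
        rows.append({
            "gene": a.gene_id,
            "stage1_hits": a.stage_hits.get(1),
            "stage2_hits": a.stage_hits.get(2),
            "stage3_hits": a.stage_hits.get(3),
            "best_e": min(a.stage_best_e.values()) if a.stage_best_e else None,
            "final_status": a.final_status,
        })
    return pd.DataFrame(rows)
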