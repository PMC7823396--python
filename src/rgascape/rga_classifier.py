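"""Candidate prescreen and domain-architecture classification into RLK/RLP classes.

The pipeline order is strict: a gene that fails the similarity prescreen is
never classified, regardless of its domain architecture.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import AnalysisConfig, DomainRecord, GeneModel, SimilarityHit

log = logging.getLogger(__name__)

RGA_CLASSES = (
    "LRR_RLK",
    "LYSM_RLK",
    "RLK_OTHER",
    "LRR_RLP",
    "LYSM_RLP",
    "NON_RGA",
)

#: classes forming the RLK family and the RLP family, respectively
RLK_CLASSES = ("LRR_RLK", "LYSM_RLK", "RLK_OTHER")
RLP_CLASSES = ("LRR_RLP", "LYSM_RLP")


@dataclass(frozen=True)
class DomainArchitecture:
    """Per-gene domain presence summary driving classification."""

    gene_id: str
    has_lrr: bool = False
    has_lysm: bool = False
    has_tm: bool = False
    has_kinase: bool = False
    has_sp: bool = False
    n_lrr_repeats: int = 0


def prescreen_candidates(
    hits_vs_rga_db: Iterable[SimilarityHit], cfg: AnalysisConfig
) -> set[str]:
    """Gene ids with at least one reference-database hit at or below the
    prescreen E-value ceiling."""
    hits = list(hits_vs_rga_db)
    if not hits:
        log.warning("prescreen: empty hit list, no candidates retained")
        return set()
    return {h.query_id for h in hits if h.evalue <= cfg.prescreen_evalue_max}


_CLASS_FLAG = {
    "LRR": "has_lrr",
    "LYSM": "has_lysm",
    "TM": "has_tm",
    "KINASE_STTK": "has_kinase",
    "SIGNAL_PEPTIDE": "has_sp",
}


def build_architecture(
    records: Iterable[DomainRecord],
    gene_id: str,
    cfg: AnalysisConfig | None = None,
) -> DomainArchitecture:
    """Collapse a gene's domain records (passing the per-domain E-value
    ceiling) into boolean presence flags plus an LRR repeat count."""
    cfg = cfg or AnalysisConfig()
    flags = {v: False for v in _CLASS_FLAG.values()}
    n_lrr = 0
    for rec in records:
        if rec.gene_id != gene_id:
            raise ValueError(
                f"record for {rec.gene_id} passed to architecture of {gene_id}"
            )
        if rec.evalue > cfg.domain_evalue_max:
            continue
        flag = _CLASS_FLAG.get(rec.domain_class)
        if flag is None:
            continue  # OTHER: recorded upstream, ignored here
        flags[flag] = True
        if rec.domain_class == "LRR":
            n_lrr += 1
    return DomainArchitecture(gene_id=gene_id, n_lrr_repeats=n_lrr, **flags)


def classify_gene(
    arch: DomainArchitecture,
    prescreened: bool,
    cfg: AnalysisConfig | None = None,
) -> str:
    """Assign exactly one RGA class from the architecture rule table.

    When both ectodomains are present, ``cfg.ectodomain_priority`` decides
    (default: LysM precedence).
    """
    cfg = cfg or AnalysisConfig()
    if not prescreened:
        return "NON_RGA"
    if not arch.has_tm:
        return "NON_RGA"

    lysm_first = cfg.ectodomain_priority == "LYSM"
    if arch.has_kinase:
        if arch.has_lysm and (lysm_first or not arch.has_lrr):
            return "LYSM_RLK"
        if arch.has_lrr:
            return "LRR_RLK"
        if arch.has_lysm:
            return "LYSM_RLK"
        return "RLK_OTHER"
    if arch.has_lysm and (lysm_first or not arch.has_lrr):
        return "LYSM_RLP"
    if arch.has_lrr:
        return "LRR_RLP"
    if arch.has_lysm:
        return "LYSM_RLP"
    return "NON_RGA"


def classify_proteome(
    genes: Iterable[GeneModel],
    domains: Iterable[DomainRecord],
    prescreen_hits: Iterable[SimilarityHit],
    cfg: AnalysisConfig | None = None,
) -> dict[str, str]:
    """Classify every input gene; returns a total partition gene_id -> class."""
    cfg = cfg or AnalysisConfig()
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)

    by_gene: dict[str, list[DomainRecord]] = defaultdict(list)
    skipped = 0
    for rec in domains:
        if rec.gene_id not in known:
            skipped += 1
            continue
        by_gene[rec.gene_id].append(rec)
    if skipped:
        log.warning("%d domain records referenced unknown gene ids; skipped", skipped)

    prescreened = prescreen_candidates(prescreen_hits, cfg)
    result: dict[str, str] = {}
    for gid in gene_ids:
        arch = build_architecture(by_gene.get(gid, []), gid, cfg)
        result[gid] = classify_gene(arch, gid in prescreened, cfg)
    return result


def family_of(rga_class: str) -> str | None:
    """Map a class to its family: RLK, RLP or None for NON_RGA."""
    if rga_class in RLK_CLASSES:
        return "RLK"
    if rga_class in RLP_CLASSES:
        return "RLP"
    return None


def class_counts(classification: Mapping[str, str]) -> dict[str, int]:
    counts = {c: 0 for c in RGA_CLASSES}
    for cls in classification.values():
        counts[cls] += 1
    return counts
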