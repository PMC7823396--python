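"""Cross-species ortholog calling, conservation/gain/loss ledgers and
chromosome-level collinearity chains.

Ortholog calls accept any hit passing the E-value/similarity/coverage
thresholds (many-to-many); an optional best-bidirectional-hit restriction is
available via ``cfg.bbh``.  The conservation ledger closes by construction:
conserved + gained = tetraploid total, conserved + lost = progenitor total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AnalysisConfig, GeneModel, SimilarityHit


@dataclass(frozen=True)
class OrthologPair:
    """One cross-species ortholog link with its supporting hit."""

    gene_tetraploid: str
    gene_progenitor: str
    evidence: SimilarityHit


@dataclass
class ConservationSummary:
    """Per family x sub-genome-vs-progenitor conservation ledger."""

    family: str
    sub_genome: str
    progenitor_species: str
    tetraploid_total: int
    tetraploid_conserved: int
    progenitor_total: int
    progenitor_conserved: int

    @property
    def gained(self) -> int:
        return self.tetraploid_total - self.tetraploid_conserved

    @property
    def lost(self) -> int:
        return self.progenitor_total - self.progenitor_conserved

    def validate(self) -> None:
        assert self.tetraploid_conserved + self.gained == self.tetraploid_total
        assert self.progenitor_conserved + self.lost == self.progenitor_total


@dataclass
class SyntenyChain:
    """Ordered collinear anchors between one tetraploid and one progenitor
    chromosome."""

    chrom_tetraploid: str
    chrom_progenitor: str
    anchors: list[OrthologPair]

    @property
    def length(self) -> int:
        return len(self.anchors)


def _similarity(hit: SimilarityHit, cfg: AnalysisConfig) -> float:
    # identity is the only similarity metric guaranteed by the hit format
    return hit.pct_identity


def call_orthologs(
    cross_species_hits: Iterable[SimilarityHit],
    cfg: AnalysisConfig,
    tetraploid_ids: set[str] | None = None,
) -> list[OrthologPair]:
    """Ortholog pairs from cross-species hits passing all three thresholds.

    The E-value rule is strict (< ortholog_evalue_max).  Hits may run in
    either direction; when ``tetraploid_ids`` is given the pair is oriented
    so that ``gene_tetraploid`` is the tetraploid-side gene, otherwise the
    query is taken as the tetraploid side.
    """
    passing: dict[tuple[str, str], SimilarityHit] = {}
    forward: set[tuple[str, str]] = set()
    reverse: set[tuple[str, str]] = set()
    for h in cross_species_hits:
        if h.is_self:
            continue
        if not (
            h.evalue < cfg.ortholog_evalue_max
            and cfg.passes_min(_similarity(h, cfg), cfg.ortholog_similarity_min)
            and cfg.passes_min(h.query_cov, cfg.ortholog_coverage_min)
            and cfg.passes_min(h.subject_cov, cfg.ortholog_coverage_min)
        ):
            continue
        if tetraploid_ids is not None:
            q_tet = h.query_id in tetraploid_ids
            s_tet = h.subject_id in tetraploid_ids
            if q_tet == s_tet:
                continue  # within-species hit: never an ortholog
            if s_tet:
                tet, prog = h.subject_id, h.query_id
                reverse.add((tet, prog))
            else:
                tet, prog = h.query_id, h.subject_id
                forward.add((tet, prog))
        else:
            tet, prog = h.query_id, h.subject_id
            forward.add((tet, prog))
        key = (tet, prog)
        if key not in passing or (h.evalue, -h.bitscore) < (
            passing[key].evalue,
            -passing[key].bitscore,
        ):
            passing[key] = h

    keys = set(passing)
    if cfg.bbh:
        keys = {k for k in keys if k in forward and k in reverse}
    return [
        OrthologPair(gene_tetraploid=t, gene_progenitor=p, evidence=passing[(t, p)])
        for t, p in sorted(keys)
    ]


def conservation_ledger(
    tetraploid_genes: Sequence[GeneModel],
    progenitor_genes: Sequence[GeneModel],
    orthologs: Iterable[OrthologPair],
    sub_genome: str,
    progenitor_species: str,
    family: str = "",
) -> ConservationSummary:
    """Conservation accounting for one sub-genome vs its progenitor.

    ``tetraploid_genes`` must already be restricted to the sub-genome (and
    family); ``progenitor_genes`` to the paired species.  A gene is conserved
    when it has at least one ortholog within the pairing.
    """
    if not all(g.species == progenitor_species for g in progenitor_genes):
        raise ValueError(
            f"progenitor gene list contains species other than {progenitor_species!r}"
        )
    tet_ids = {g.gene_id for g in tetraploid_genes}
    prog_ids = {g.gene_id for g in progenitor_genes}
    tet_conserved: set[str] = set()
    prog_conserved: set[str] = set()
    for op in orthologs:
        if op.gene_tetraploid in tet_ids and op.gene_progenitor in prog_ids:
            tet_conserved.add(op.gene_tetraploid)
            prog_conserved.add(op.gene_progenitor)
    summary = ConservationSummary(
        family=family,
        sub_genome=sub_genome,
        progenitor_species=progenitor_species,
        tetraploid_total=len(tet_ids),
        tetraploid_conserved=len(tet_conserved),
        progenitor_total=len(prog_ids),
        progenitor_conserved=len(prog_conserved),
    )
    summary.validate()
    return summary


def _lis_anchor_indices(
    t_pos: Sequence[int], p_pos: Sequence[int]
) -> list[int]:
    """Deterministic longest chain strictly increasing in both coordinates.

    Quadratic DP; ties resolved toward the earliest predecessor so the same
    input always yields the same chain.
    """
    n = len(t_pos)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if t_pos[i] < t_pos[j] and p_pos[i] < p_pos[j] and best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best[j], -j))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def synteny_chains(
    orthologs: Iterable[OrthologPair],
    gene_positions: Mapping[str, GeneModel],
    cfg: AnalysisConfig,
) -> tuple[list[SyntenyChain], set[str]]:
    """Collinearity chains per matching chromosome pair, plus the syntenic set.

    Anchors are ortholog pairs whose two genes sit on chromosomes with the
    same name; per chromosome pair the longest subsequence strictly
    increasing in both genomes' positions forms the chain.  Chains of at
    least ``synteny_min_chain`` anchors are reported; a tetraploid gene is
    syntenic iff it anchors a reported chain.
    """
    by_pair: dict[tuple[str, str], list[OrthologPair]] = {}
    for op in orthologs:
        gt = gene_positions.get(op.gene_tetraploid)
        gp = gene_positions.get(op.gene_progenitor)
        if gt is None or gp is None or not gt.placed or not gp.placed:
            continue
        if gt.chromosome != gp.chromosome:
            continue
        by_pair.setdefault((gt.chromosome, gp.chromosome), []).append(op)

    chains: list[SyntenyChain] = []
    syntenic: set[str] = set()
    for (ct, cp), anchors in sorted(by_pair.items()):
        anchors.sort(
            key=lambda op: (
                gene_positions[op.gene_tetraploid].start,
                gene_positions[op.gene_progenitor].start,
                op.gene_tetraploid,
                op.gene_progenitor,
            )
        )
        t_pos = [gene_positions[a.gene_tetraploid].start for a in anchors]
        p_pos = [gene_positions[a.gene_progenitor].start for a in anchors]
        idx = _lis_anchor_indices(t_pos, p_pos)
        if len(idx) >= cfg.synteny_min_chain:
            chain = SyntenyChain(
                chrom_tetraploid=ct,
                chrom_progenitor=cp,
                anchors=[anchors[i] for i in idx],
            )
            chains.append(chain)
            syntenic.update(a.gene_tetraploid for a in chain.anchors)
    return chains, syntenic


def compare_family_sizes(
    per_species_classifications: Mapping[str, Mapping[str, str]],
) -> dict[str, dict[str, int]]:
    """Cross-species family/subfamily counts plus total gene content."""
    if len(per_species_classifications) < 1:
        raise ValueError("at least one classified species is required")
    from .rga_classifier import RLK_CLASSES, RLP_CLASSES, class_counts

    out: dict[str, dict[str, int]] = {}
    for species, classification in per_species_classifications.items():
        counts = class_counts(classification)
        out[species] = {
            "gene_content": len(classification),
            "RLK": sum(counts[c] for c in RLK_CLASSES),
            "RLP": sum(counts[c] for c in RLP_CLASSES),
            **{c: counts[c] for c in (*RLK_CLASSES, *RLP_CLASSES)},
        }
    return out
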