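"""Assembly of stage outputs into report tables with auditable percentages.

Every percentage in every emitted table is built through ``format_percent``
(half-up decimal rounding) and registered in a denominator audit so each
cell can be recomputed from its printed numerator/denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .comparative_orthology import ConservationSummary, OrthologPair, SyntenyChain
from .duplication_analysis import DuplicatePair, DuplicationSummary
from .genome_landscape import ClusterSummary, GeneCluster
from .io_formats import GeneModel
from .rga_classifier import RLK_CLASSES, RLP_CLASSES


@dataclass(frozen=True)
class PercentCell:
    """A formatted percentage that remembers its exact arithmetic."""

    numerator: int
    denominator: int
    formatted: str
    decimals: int = 2


def format_percent(numerator: int, denominator: int, decimals: int = 2) -> PercentCell:
    """Half-up percentage formatting with fixed decimals (default 2).

    A zero denominator is only legal with a zero numerator (renders as 0).
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("numerator and denominator must be nonnegative")
    quantum = Decimal(1).scaleb(-decimals)
    if denominator == 0:
        if numerator > 0:
            raise ValueError("nonzero numerator over zero denominator")
        value = Decimal(0).quantize(quantum)
    else:
        value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            quantum, rounding=ROUND_HALF_UP
        )
    return PercentCell(
        numerator=numerator,
        denominator=denominator,
        formatted=f"{value}%",
        decimals=decimals,
    )


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------


@dataclass
class SpeciesResult:
    """All per-species stage outputs."""

    species: str
    genes: list[GeneModel]
    classification: dict[str, str]
    distribution: dict
    clusters: dict[str, list[GeneCluster]] = field(default_factory=dict)
    cluster_stats: dict[str, ClusterSummary] = field(default_factory=dict)
    duplicate_pairs: dict[str, list[DuplicatePair]] = field(default_factory=dict)
    dup_summary: dict[str, DuplicationSummary] = field(default_factory=dict)
    paralogs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class ResultBundle:
    """A completed pipeline result across species and comparisons."""

    species: dict[str, SpeciesResult] = field(default_factory=dict)
    orthologs: dict[tuple[str, str], list[OrthologPair]] = field(default_factory=dict)
    conservation: list[ConservationSummary] = field(default_factory=list)
    synteny: dict[tuple[str, str], tuple[list[SyntenyChain], set[str]]] = field(
        default_factory=dict
    )


class _Audit:
    def __init__(self) -> None:
        self.rows: list[dict] = []

    def cell(
        self,
        table: str,
        label: str,
        numerator: int,
        denominator: int,
        denominator_def: str,
        decimals: int = 2,
    ) -> str:
        cell = format_percent(numerator, denominator, decimals=decimals)
        self.rows.append(
            {
                "table": table,
                "label": label,
                "numerator": numerator,
                "denominator": denominator,
                "denominator_definition": denominator_def,
                "formatted": cell.formatted,
                "decimals": decimals,
            }
        )
        return cell.formatted

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "table",
                "label",
                "numerator",
                "denominator",
                "denominator_definition",
                "formatted",
                "decimals",
            ],
        )


_FAMILY_ROWS = [
    ("RLK", list(RLK_CLASSES)),
    ("LRR-RLK", ["LRR_RLK"]),
    ("LysM-RLK", ["LYSM_RLK"]),
    ("RLP", list(RLP_CLASSES)),
    ("LRR-RLP", ["LRR_RLP"]),
    ("LysM-RLP", ["LYSM_RLP"]),
]


def build_family_table(
    classifications: Mapping[str, Mapping[str, str]],
    audit: _Audit | None = None,
) -> pd.DataFrame:
    """Family/subfamily counts per species with 3-decimal proportions of
    total gene content."""
    audit = audit or _Audit()
    rows = []
    for species in sorted(classifications):
        classification = classifications[species]
        total = len(classification)
        counts: dict[str, int] = {}
        for cls in classification.values():
            counts[cls] = counts.get(cls, 0) + 1
        for row_name, members in _FAMILY_ROWS:
            n = sum(counts.get(c, 0) for c in members)
            rows.append(
                {
                    "species": species,
                    "family": row_name,
                    "count": n,
                    "gene_content": total,
                    "proportion": audit.cell(
                        "family_counts",
                        f"{species}:{row_name}",
                        n,
                        total,
                        f"total predicted genes in {species}",
                        decimals=3,
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["species", "family", "count", "gene_content", "proportion"])


def _per_chromosome_table(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for species in sorted(bundle.species):
        dist = bundle.species[species].distribution
        for chrom in sorted(dist["per_chromosome"]):
            for cls in sorted(dist["per_chromosome"][chrom]):
                rows.append(
                    {
                        "species": species,
                        "chromosome": chrom,
                        "class": cls,
                        "count": dist["per_chromosome"][chrom][cls],
                    }
                )
        for cls in sorted(dist["unassigned"]):
            rows.append(
                {
                    "species": species,
                    "chromosome": "UNPLACED",
                    "class": cls,
                    "count": dist["unassigned"][cls],
                }
            )
    return pd.DataFrame(rows, columns=["species", "chromosome", "class", "count"])


def _clusters_table(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for species in sorted(bundle.species):
        res = bundle.species[species]
        for family in sorted(res.clusters):
            for c in res.clusters[family]:
                rows.append(
                    {
                        "species": species,
                        "family": family,
                        "cluster_id": c.cluster_id,
                        "chromosome": c.chromosome,
                        "n_genes": len(c),
                        "span_bp": c.span_bp,
                        "homogeneous": c.homogeneous,
                        "tandem": c.tandem,
                        "members": ",".join(c.member_ids),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "family",
            "cluster_id",
            "chromosome",
            "n_genes",
            "span_bp",
            "homogeneous",
            "tandem",
            "members",
        ],
    )


def _duplicates_table(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for species in sorted(bundle.species):
        res = bundle.species[species]
        for family in sorted(res.duplicate_pairs):
            for p in res.duplicate_pairs[family]:
                rows.append(
                    {
                        "species": species,
                        "family": family,
                        "gene_a": p.gene_a,
                        "gene_b": p.gene_b,
                        "positional_type": p.positional_type,
                        "genome_scope": p.genome_scope,
                        "evalue": p.evidence.evalue if p.evidence else "",
                        "pct_identity": p.evidence.pct_identity if p.evidence else "",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "family",
            "gene_a",
            "gene_b",
            "positional_type",
            "genome_scope",
            "evalue",
            "pct_identity",
        ],
    )


def _orthologs_table(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for (family, sub_genome) in sorted(bundle.orthologs):
        for op in bundle.orthologs[(family, sub_genome)]:
            rows.append(
                {
                    "family": family,
                    "sub_genome": sub_genome,
                    "gene_tetraploid": op.gene_tetraploid,
                    "gene_progenitor": op.gene_progenitor,
                    "evalue": op.evidence.evalue,
                    "pct_identity": op.evidence.pct_identity,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "sub_genome",
            "gene_tetraploid",
            "gene_progenitor",
            "evalue",
            "pct_identity",
        ],
    )


def _conservation_table(bundle: ResultBundle, audit: _Audit) -> pd.DataFrame:
    rows = []
    for s in bundle.conservation:
        label = f"{s.family}:{s.sub_genome}~{s.progenitor_species}"
        rows.append(
            {
                "family": s.family,
                "sub_genome": s.sub_genome,
                "progenitor": s.progenitor_species,
                "tetraploid_total": s.tetraploid_total,
                "tetraploid_conserved": s.tetraploid_conserved,
                "tetraploid_conserved_pct": audit.cell(
                    "conservation",
                    f"{label}:tetraploid_conserved",
                    s.tetraploid_conserved,
                    s.tetraploid_total,
                    f"mapped {s.family} genes in sub-genome {s.sub_genome}",
                ),
                "gained": s.gained,
                "progenitor_total": s.progenitor_total,
                "progenitor_conserved": s.progenitor_conserved,
                "progenitor_conserved_pct": audit.cell(
                    "conservation",
                    f"{label}:progenitor_conserved",
                    s.progenitor_conserved,
                    s.progenitor_total,
                    f"{s.family} genes in {s.progenitor_species}",
                ),
                "lost": s.lost,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "sub_genome",
            "progenitor",
            "tetraploid_total",
            "tetraploid_conserved",
            "tetraploid_conserved_pct",
            "gained",
            "progenitor_total",
            "progenitor_conserved",
            "progenitor_conserved_pct",
            "lost",
        ],
    )


def bundle_tables(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """All deterministic report tables for a bundle, audit included."""
    audit = _Audit()
    tables = {
        "family_counts": build_family_table(
            {s: r.classification for s, r in bundle.species.items()}, audit
        ),
        "per_chromosome": _per_chromosome_table(bundle),
        "clusters": _clusters_table(bundle),
        "duplicates": _duplicates_table(bundle),
        "orthologs": _orthologs_table(bundle),
        "conservation": _conservation_table(bundle, audit),
    }
    tables["denominator_audit"] = audit.frame()
    return tables


def build_denominator_audit(bundle: ResultBundle) -> pd.DataFrame:
    """The audit table alone: one row per percentage cell in the bundle's
    report tables, each recomputable from numerator/denominator."""
    return bundle_tables(bundle)["denominator_audit"]
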