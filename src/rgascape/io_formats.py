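"""Typed records and readers/writers for every external format the pipeline touches.

All coordinates are 1-based, fully closed, and are never shifted by any
operation in this package.  Downstream modules operate exclusively on the
record types defined here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import yaml

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Sentinels and controlled vocabularies
# ---------------------------------------------------------------------------

UNPLACED = "UNPLACED"

SUBGENOME_A = "A"
SUBGENOME_B = "B"
SUBGENOME_NONE = "NONE"

DOMAIN_CLASSES = ("LRR", "LYSM", "TM", "KINASE_STTK", "SIGNAL_PEPTIDE", "OTHER")

#: Translation of external annotation signatures to internal domain classes.
#: Unknown signatures fall back to OTHER (never dropped).
DEFAULT_SIGNATURE_MAP: dict[str, str] = {
    # already-internal names pass through
    "LRR": "LRR",
    "LYSM": "LYSM",
    "TM": "TM",
    "KINASE_STTK": "KINASE_STTK",
    "SIGNAL_PEPTIDE": "SIGNAL_PEPTIDE",
    "OTHER": "OTHER",
    # leucine-rich repeat signatures
    "LRR_1": "LRR",
    "LRR_4": "LRR",
    "LRR_8": "LRR",
    "LRRNT_2": "LRR",
    "PF00560": "LRR",
    "PF07723": "LRR",
    "PF07725": "LRR",
    "PF12799": "LRR",
    "PF13306": "LRR",
    "PF13516": "LRR",
    "PF13855": "LRR",
    # lysin motif
    "LysM": "LYSM",
    "LysM_dom": "LYSM",
    "PF01476": "LYSM",
    # transmembrane helix calls
    "TMhelix": "TM",
    "TRANSMEMBRANE": "TM",
    "tmhmm": "TM",
    # serine/threonine kinase
    "Pkinase": "KINASE_STTK",
    "Pkinase_Tyr": "KINASE_STTK",
    "PF00069": "KINASE_STTK",
    "PF07714": "KINASE_STTK",
    "STTK": "KINASE_STTK",
    # signal peptide
    "SignalP": "SIGNAL_PEPTIDE",
    "SIGNAL": "SIGNAL_PEPTIDE",
    "signalp": "SIGNAL_PEPTIDE",
}


class FormatError(ValueError):
    """Raised when an input stream violates a format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with species, placement, interval, strand and sub-genome label."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    sub_genome: str = SUBGENOME_NONE

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass(frozen=True)
class DomainRecord:
    """One protein-domain annotation for a gene (protein residue coordinates)."""

    gene_id: str
    domain_class: str
    p_start: int
    p_end: int
    evalue: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.p_start < 1 or self.p_end < self.p_start:
            raise ValueError(
                f"{self.gene_id}: bad protein coordinates "
                f"[{self.p_start}, {self.p_end}]"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.gene_id}: negative E-value {self.evalue}")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein alignment record (BLAST tabular style).

    ``query_cov``/``subject_cov`` are percentages of the aligned span over the
    full sequence length, clamped to [0, 100].
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_len: int
    subject_len: int
    query_cov: float
    subject_cov: float

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        for name in ("query_cov", "subject_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of range: {v}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


def make_hit(
    query_id: str,
    subject_id: str,
    pct_identity: float,
    aln_length: int,
    evalue: float,
    bitscore: float,
    query_len: int,
    subject_len: int,
    query_span: int | None = None,
    subject_span: int | None = None,
) -> SimilarityHit:
    """Build a hit computing coverages from aligned spans (default: aln_length).

    Spans exceeding the sequence length (possible with gapped alignments)
    clamp the coverage at 100 with a logged warning.
    """
    qspan = aln_length if query_span is None else query_span
    sspan = aln_length if subject_span is None else subject_span
    qcov = 100.0 * qspan / query_len
    scov = 100.0 * sspan / subject_len
    if qcov > 100.0 or scov > 100.0:
        log.warning(
            "alignment span exceeds sequence length for %s/%s; clamping coverage",
            query_id,
            subject_id,
        )
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_length=aln_length,
        evalue=evalue,
        bitscore=bitscore,
        query_len=query_len,
        subject_len=subject_len,
        query_cov=min(100.0, max(0.0, qcov)),
        subject_cov=min(100.0, max(0.0, scov)),
    )


@dataclass
class AnalysisConfig:
    """All numeric thresholds of the analysis, with their published defaults."""

    prescreen_evalue_max: float = 1e-5
    domain_evalue_max: float = 1.0
    dup_identity_min: float = 70.0
    dup_coverage_min: float = 70.0
    paralog_evalue_max: float = 1e-20
    ortholog_evalue_max: float = 1e-45
    ortholog_similarity_min: float = 70.0
    ortholog_coverage_min: float = 70.0
    cluster_min_genes: int = 3
    cluster_max_gap_bp: int = 200_000
    tandem_max_distance_bp: int = 5_000_000
    synteny_min_chain: int = 3
    rng_seed: int = 0
    # deviation switches / reuse knobs
    strict_gt: bool = False
    ectodomain_priority: str = "LYSM"
    gap_anchor: str = "start-start"
    similarity_metric: str = "identity"
    bbh: bool = False
    subgenome_a_pattern: str = r"^A(0[1-9]|10)$"
    subgenome_b_pattern: str = r"^B0[1-8]$"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "prescreen_evalue_max",
            "domain_evalue_max",
            "dup_identity_min",
            "dup_coverage_min",
            "paralog_evalue_max",
            "ortholog_evalue_max",
            "ortholog_similarity_min",
            "ortholog_coverage_min",
            "cluster_min_genes",
            "cluster_max_gap_bp",
            "tandem_max_distance_bp",
            "synteny_min_chain",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        for name in (
            "dup_identity_min",
            "dup_coverage_min",
            "ortholog_similarity_min",
            "ortholog_coverage_min",
        ):
            if getattr(self, name) > 100:
                raise ValueError(f"percentage threshold {name} exceeds 100")
        if self.ectodomain_priority not in ("LYSM", "LRR"):
            raise ValueError("ectodomain_priority must be LYSM or LRR")
        if self.gap_anchor not in ("start-start", "end-start"):
            raise ValueError("gap_anchor must be start-start or end-start")

    # -- threshold comparators ------------------------------------------------
    def passes_min(self, value: float, threshold: float) -> bool:
        """'over X' comparison: >= by default, > when strict_gt is set."""
        return value > threshold if self.strict_gt else value >= threshold

    def subgenome_of(self, chromosome: str) -> str:
        if chromosome == UNPLACED:
            return SUBGENOME_NONE
        if re.match(self.subgenome_a_pattern, chromosome):
            return SUBGENOME_A
        if re.match(self.subgenome_b_pattern, chromosome):
            return SUBGENOME_B
        return SUBGENOME_NONE

    def chromosome_or_unplaced(self, seqid: str) -> str:
        """Map a GFF3 seqid to a chromosome name or the UNPLACED sentinel."""
        if re.match(self.subgenome_a_pattern, seqid) or re.match(
            self.subgenome_b_pattern, seqid
        ):
            return seqid
        return UNPLACED

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


DEFAULT_CONFIG = AnalysisConfig()


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _open_lines(stream: IO[str] | str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            yield from fh
    else:
        yield from stream


def read_gene_models(
    gff3_stream: IO[str] | str | Path | Iterable[str],
    species_tag: str,
    cfg: AnalysisConfig | None = None,
) -> list[GeneModel]:
    """Parse gene features from a GFF3 stream into GeneModel records.

    Only features of type ``gene`` are consumed; each must carry an ID
    attribute.  Sequences not matching the configured chromosome naming
    scheme are mapped to the UNPLACED sentinel.  Output is sorted by
    (chromosome, start, gene_id).
    """
    cfg = cfg or DEFAULT_CONFIG
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_open_lines(gff3_stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != _GFF_COLS:
            raise FormatError(f"line {lineno}: expected 9 GFF3 columns, got {len(parts)}")
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
        if ftype != "gene":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable coordinates") from exc
        if end < start:
            raise FormatError(f"line {lineno}: end ({end}) < start ({start})")
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        gene_id = attr_map.get("ID")
        if not gene_id:
            raise FormatError(f"line {lineno}: gene feature without an ID attribute")
        if gene_id in seen:
            raise FormatError(f"duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        chromosome = cfg.chromosome_or_unplaced(seqid)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=species_tag,
                chromosome=chromosome,
                start=start,
                end=end,
                strand=strand if strand in ("+", "-") else "unknown",
                sub_genome=cfg.subgenome_of(chromosome),
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (gene features only)."""
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ordered:
            seqid = g.chromosome if g.placed else f"Scaffold_{g.gene_id}"
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{seqid}\t{g.species}\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Domain annotation table
# ---------------------------------------------------------------------------

_DOMAIN_HEADER = ["gene_id", "domain_class", "p_start", "p_end", "evalue", "source"]


def read_domain_table(
    tsv_stream: IO[str] | str | Path | Iterable[str],
    signature_map: Mapping[str, str] | None = None,
) -> list[DomainRecord]:
    """Read a tab-separated domain annotation table.

    External signature names are translated through ``signature_map``
    (default: DEFAULT_SIGNATURE_MAP); unknown names map to OTHER and are
    tallied in a warning, never dropped.
    """
    sig_map = DEFAULT_SIGNATURE_MAP if signature_map is None else signature_map
    records: list[DomainRecord] = []
    unknown: dict[str, int] = {}
    for lineno, line in enumerate(_open_lines(tsv_stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[: len(_DOMAIN_HEADER)] == _DOMAIN_HEADER:
            continue  # header row
        if len(parts) < 5:
            raise FormatError(f"line {lineno}: expected >=5 tab-separated columns")
        gene_id, signature = parts[0], parts[1]
        try:
            p_start, p_end = int(parts[2]), int(parts[3])
            evalue = float(parts[4])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numeric field") from exc
        source = parts[5] if len(parts) > 5 else ""
        domain_class = sig_map.get(signature)
        if domain_class is None:
            unknown[signature] = unknown.get(signature, 0) + 1
            domain_class = "OTHER"
        records.append(
            DomainRecord(
                gene_id=gene_id,
                domain_class=domain_class,
                p_start=p_start,
                p_end=p_end,
                evalue=evalue,
                source=source,
            )
        )
    if unknown:
        log.warning(
            "%d domain rows carried unknown signatures (mapped to OTHER): %s",
            sum(unknown.values()),
            dict(sorted(unknown.items())),
        )
    records.sort(key=lambda r: (r.gene_id, r.p_start, r.p_end, r.domain_class))
    return records


def write_domain_table(records: Iterable[DomainRecord], path: str | Path) -> None:
    ordered = sorted(records, key=lambda r: (r.gene_id, r.p_start, r.p_end, r.domain_class))
    with open(path, "w") as fh:
        fh.write("\t".join(_DOMAIN_HEADER) + "\n")
        for r in ordered:
            fh.write(
                f"{r.gene_id}\t{r.domain_class}\t{r.p_start}\t{r.p_end}\t"
                f"{r.evalue:.6g}\t{r.source}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular hits (outfmt "6 std qlen slen")
# ---------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "slen",
]


def read_similarity_hits(
    tabular_stream: IO[str] | str | Path | Iterable[str],
) -> list[SimilarityHit]:
    """Read extended BLAST outfmt-6 rows (12 standard columns + qlen + slen).

    Coverages are computed from the aligned spans over qlen/slen and clamped
    to [0, 100].  Self-hits are retained and flagged via ``is_self``.
    """
    hits: list[SimilarityHit] = []
    for lineno, line in enumerate(_open_lines(tabular_stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < len(BLAST_COLUMNS):
            raise FormatError(
                f"line {lineno}: expected {len(BLAST_COLUMNS)} columns "
                f"({' '.join(BLAST_COLUMNS)}); qlen and slen are required"
            )
        try:
            pident = float(parts[2])
            length = int(parts[3])
            qstart, qend = int(parts[6]), int(parts[7])
            sstart, send = int(parts[8]), int(parts[9])
            evalue = float(parts[10])
            bitscore = float(parts[11])
            qlen, slen = int(parts[12]), int(parts[13])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numeric field") from exc
        hits.append(
            make_hit(
                query_id=parts[0],
                subject_id=parts[1],
                pct_identity=pident,
                aln_length=length,
                evalue=evalue,
                bitscore=bitscore,
                query_len=qlen,
                subject_len=slen,
                query_span=abs(qend - qstart) + 1,
                subject_span=abs(send - sstart) + 1,
            )
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id, h.evalue, -h.bitscore))
    return hits


def write_similarity_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in extended outfmt-6 (spans reconstructed from coverage)."""
    ordered = sorted(hits, key=lambda h: (h.query_id, h.subject_id, h.evalue, -h.bitscore))
    with open(path, "w") as fh:
        for h in ordered:
            qspan = int(round(h.query_cov * h.query_len / 100.0))
            sspan = int(round(h.subject_cov * h.subject_len / 100.0))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.3f}",
                        str(h.aln_length),
                        "0",
                        "0",
                        "1",
                        str(max(1, qspan)),
                        "1",
                        str(max(1, sspan)),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                        str(h.query_len),
                        str(h.subject_len),
                    ]
                )
                + "\n"
            )


def exclude_self_hits(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Drop flagged self-hits prior to relationship calling."""
    return [h for h in hits if not h.is_self]


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def write_report_tables(result_bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the deterministic TSV report set for a completed result bundle.

    Delegates to summary_report for table construction; files are
    byte-stable for identical bundles.
    """
    from .summary_report import bundle_tables  # local import avoids a cycle

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to report directory {out}: {exc}") from exc

    written: dict[str, Path] = {}
    for name, frame in bundle_tables(result_bundle).items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written[name] = path
    return written
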