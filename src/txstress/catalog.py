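"""Gene catalogs parameterizing the lesion/transcription-loss model.

A catalog holds, for every expressed gene i, its genomic length ``l_i``
(longest-transcript span, introns included), a normalized nascent-expression
weight ``alpha_i`` (sum to 1) and the probability ``q_i = l_i / (4 L)`` that a
single lesion placed uniformly on the diploid, double-stranded genome of
haploid length ``L`` lands on the transcribed strand of one specific allele of
gene i (two alleles x two strands = factor 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Haploid genome lengths (bp) used throughout; both are configurable per call.
HUMAN_GENOME_BP = 3_200_000_000
MOUSE_GENOME_BP = 2_650_000_000

#: Default length filters: genes shorter than 5 kb are excluded; the optional
#: upper cut at 750 kb removes the few extremely long genes.
MIN_GENE_LENGTH_BP = 5_000
MAX_GENE_LENGTH_BP = 750_000


class AnnotationParseError(ValueError):
    """Raised when an annotation file has a malformed line."""


@dataclass
class GeneRecord:
    """One gene: identifier, longest-transcript genomic span, raw expression."""

    gene_id: str
    length_bp: int
    expression_raw: float = 0.0
    chrom: str | None = None
    start: int | None = None  # 0-based half-open internally
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"gene {self.gene_id}: length_bp must be >= 1")
        if self.expression_raw < 0:
            raise ValueError(f"gene {self.gene_id}: expression_raw must be >= 0")
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


@dataclass
class FilterReport:
    """Genes retained by :func:`filter_genes` plus per-rule removal counts."""

    records: list[GeneRecord]
    removed_short: int = 0
    removed_long: int = 0
    removed_unexpressed: int = 0

    @property
    def n_removed(self) -> int:
        return self.removed_short + self.removed_long + self.removed_unexpressed


@dataclass
class GeneCatalog:
    """Validated per-gene arrays (lengths, weights alpha, hit probabilities q).

    Invariants: unique gene ids; sum(alpha) == 1; q_i = length_i / (4 L) in
    (0, 1); sum of lengths <= L (required by the uniform-placement simulator).
    """

    gene_ids: np.ndarray
    lengths: np.ndarray
    alpha: np.ndarray
    q: np.ndarray
    genome_length_L: int
    expression_raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.expression_raw is None:
            self.expression_raw = np.full(len(self.gene_ids), np.nan)
        self.validate()

    def __len__(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        n = len(self.gene_ids)
        if not (len(self.lengths) == len(self.alpha) == len(self.q) == n):
            raise ValueError("catalog arrays must have equal length")
        if n == 0:
            raise ValueError("catalog is empty")
        if len(set(self.gene_ids.tolist())) != n:
            raise ValueError("gene ids are not unique")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError(f"alpha must sum to 1, got {self.alpha.sum()!r}")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")
        L = self.genome_length_L
        expected_q = self.lengths / (4.0 * L)
        if not np.allclose(self.q, expected_q, rtol=1e-12, atol=0):
            raise ValueError("q does not equal length/(4L)")
        if np.any(self.q <= 0) or np.any(self.q >= 1):
            raise ValueError("q must lie strictly in (0, 1)")
        if int(self.lengths.sum()) > L:
            raise ValueError(
                "summed gene lengths exceed the genome length; the uniform "
                "lesion-placement simulator requires sum(l_i) <= L"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "length_bp": self.lengths,
                "expression_raw": self.expression_raw,
                "alpha": self.alpha,
                "q": self.q,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.insert(0, "genome_length_L", self.genome_length_L)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        frame = pd.read_csv(path, sep="\t")
        L = int(frame["genome_length_L"].iloc[0])
        records = [
            GeneRecord(str(r.gene_id), int(r.length_bp), float(r.expression_raw))
            for r in frame.itertuples()
        ]
        return build_catalog(records, L)


# ---------------------------------------------------------------------------
# Annotation loading


def load_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a GTF or BED file into one :class:`GeneRecord` per gene.

    Gene length is the genomic span of the gene's longest transcript (ties
    broken by lexicographically smallest transcript id). GTF is 1-based
    inclusive, BED 0-based half-open; both yield identical lengths for
    equivalent intervals. Genes with no transcript are skipped with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".bed"}:
        return _load_bed(path)
    if suffix in {".gtf", ".gff", ".gff3"}:
        return _load_gtf(path)
    # sniff: BED lines have an integer in column 2
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) >= 8 and not fields[3].isdigit():
                return _load_gtf(path)
            return _load_bed(path)
    raise AnnotationParseError(f"{path}: empty annotation file")


def _load_bed(path: Path) -> list[GeneRecord]:
    # BED: chrom start end name [score strand]; 0-based half-open.
    spans: dict[str, list[tuple[int, str, str, int, int, str | None]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED line needs >= 4 columns (chrom, "
                    f"start, end, name), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from exc
            if end <= start:
                raise AnnotationParseError(f"{path}:{lineno}: end <= start")
            name = fields[3]
            strand = fields[5] if len(fields) >= 6 else None
            # each BED interval is one transcript of the named gene
            tx_id = f"{name}.{lineno}"
            spans.setdefault(name, []).append(
                (end - start, tx_id, fields[0], start, end, strand)
            )
    return _longest_per_gene(spans)


def _load_gtf(path: Path) -> list[GeneRecord]:
    _validate_gtf_lines(path)
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans: dict[str, list[tuple[int, str, str, int, int, str | None]]] = {}
    tx_types = [t for t in db.featuretypes() if t in {"transcript", "mRNA"}]
    for tx_type in tx_types:
        for tx in db.features_of_type(tx_type):
            gene_id = (tx.attributes.get("gene_id") or [tx.id])[0]
            tx_id = (tx.attributes.get("transcript_id") or [tx.id])[0]
            # gffutils keeps GTF 1-based inclusive coords; convert to half-open
            start0, end0 = tx.start - 1, tx.end
            spans.setdefault(gene_id, []).append(
                (end0 - start0, tx_id, tx.seqid, start0, end0, tx.strand or None)
            )
    if not tx_types:
        # exon-only GTF: group exons by transcript_id
        tx_span: dict[tuple[str, str], list] = {}
        for exon in db.features_of_type("exon"):
            gene_id = (exon.attributes.get("gene_id") or ["?"])[0]
            tx_id = (exon.attributes.get("transcript_id") or [exon.id])[0]
            key = (gene_id, tx_id)
            entry = tx_span.setdefault(
                key, [exon.seqid, exon.start - 1, exon.end, exon.strand or None]
            )
            entry[1] = min(entry[1], exon.start - 1)
            entry[2] = max(entry[2], exon.end)
        for (gene_id, tx_id), (chrom, s0, e0, strand) in tx_span.items():
            spans.setdefault(gene_id, []).append((e0 - s0, tx_id, chrom, s0, e0, strand))
    # genes declared but without any transcript: skip with a warning
    try:
        for gene in db.features_of_type("gene"):
            gid = (gene.attributes.get("gene_id") or [gene.id])[0]
            if gid not in spans:
                logger.warning("gene %s has no transcript; skipped", gid)
    except Exception:  # pragma: no cover - featuretype absent
        pass
    return _longest_per_gene(spans)


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationParseError(
                    f"{path}:{lineno}: GTF line needs >= 8 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer GTF coordinates"
                ) from exc


def _longest_per_gene(spans: dict) -> list[GeneRecord]:
    records = []
    for gene_id in spans:
        # longest span wins; ties go to the lexicographically smallest tx id
        length, _tx, chrom, start, end, strand = max(
            spans[gene_id], key=lambda item: (item[0], _neg_lex(item[1]))
        )
        records.append(
            GeneRecord(gene_id, length, chrom=chrom, start=start, end=end, strand=strand)
        )
    return records


class _neg_lex(str):
    """Order-reversing wrapper so max() picks the smallest transcript id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Expression tables, filtering, catalog construction


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-level expression table (TSV: gene_id, [length_bp,] count)."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns or "count" not in table.columns:
        raise ValueError("counts table needs 'gene_id' and 'count' columns")
    return table


def attach_expression(
    records: Iterable[GeneRecord], counts: pd.DataFrame
) -> list[GeneRecord]:
    """Merge an expression table onto annotation records (0 where absent)."""
    lookup = dict(zip(counts["gene_id"].astype(str), counts["count"].astype(float)))
    out = []
    for rec in records:
        out.append(
            GeneRecord(
                rec.gene_id,
                rec.length_bp,
                expression_raw=lookup.get(rec.gene_id, 0.0),
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
            )
        )
    return out


def records_from_table(table: pd.DataFrame) -> list[GeneRecord]:
    """Build records straight from a table carrying gene_id, length_bp, count."""
    if "length_bp" not in table.columns:
        raise ValueError("table must carry length_bp when no annotation is given")
    return [
        GeneRecord(str(r.gene_id), int(r.length_bp), float(getattr(r, "count", 0.0)))
        for r in table.itertuples()
    ]


def filter_genes(
    records: Sequence[GeneRecord],
    min_length_bp: int = MIN_GENE_LENGTH_BP,
    max_length_bp: int | None = None,
    require_expressed: bool = False,
) -> FilterReport:
    """Apply the length and expression filters; count removals per rule.

    Genes shorter than ``min_length_bp`` (default 5 kb) are removed; genes
    longer than ``max_length_bp`` are removed when that bound is set; genes
    with zero raw expression are removed when ``require_expressed`` is set.
    """
    kept: list[GeneRecord] = []
    report = FilterReport(records=kept)
    for rec in records:
        if rec.length_bp < min_length_bp:
            report.removed_short += 1
        elif max_length_bp is not None and rec.length_bp > max_length_bp:
            report.removed_long += 1
        elif require_expressed and rec.expression_raw <= 0:
            report.removed_unexpressed += 1
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("all genes removed by filtering; catalog would be empty")
    if report.n_removed:
        logger.info(
            "filter_genes removed %d genes (%d short, %d long, %d unexpressed)",
            report.n_removed,
            report.removed_short,
            report.removed_long,
            report.removed_unexpressed,
        )
    return report


def build_catalog(
    records: Sequence[GeneRecord], genome_length_L: int
) -> GeneCatalog:
    """Normalize expression into weights alpha and derive q_i = l_i/(4L)."""
    if not records:
        raise ValueError("no gene records given")
    lengths = np.array([r.length_bp for r in records], dtype=np.int64)
    expr = np.array([r.expression_raw for r in records], dtype=float)
    if int(lengths.sum()) > genome_length_L:
        raise ValueError(
            f"summed gene lengths ({lengths.sum()}) exceed genome length "
            f"({genome_length_L}); the uniform-placement simulator requires "
            "non-overlapping genes covering at most the haploid genome"
        )
    total = expr.sum()
    if total <= 0:
        raise ValueError("all genes have zero expression; weights undefined")
    alpha = expr / total
    q = lengths / (4.0 * genome_length_L)
    return GeneCatalog(
        gene_ids=np.array([r.gene_id for r in records], dtype=object),
        lengths=lengths,
        alpha=alpha,
        q=q,
        genome_length_L=int(genome_length_L),
        expression_raw=expr,
    )
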