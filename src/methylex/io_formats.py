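"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  On-disk conventions follow
each format's standard: GFF3 is 1-based inclusive, BED is 0-based half-open,
and the per-cytosine report stores 1-based positions (converted on read).

The per-cytosine report is a fixed six-column TSV without header::

    chromosome  position(1-based)  strand(+/-)  context(CG|CHG|CHH)  n_meth  n_unmeth

one row per cytosine residue per strand, mirroring the per-residue count
export of common bisulfite mappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylex")

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

CYTOSINE_COLUMNS = ["chromosome", "position", "strand", "context",
                    "count_methylated", "count_unmethylated"]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (coordinates, context, counts)."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine residue on one strand with its methylation read counts."""

    chromosome: str
    position: int                     # 0-based, forward-strand coordinate
    strand: str                       # "+" or "-"
    context: str                      # CG, CHG or CHH
    count_methylated: int
    count_unmethylated: int

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def fraction_methylated(self) -> float | None:
        """Methylated fraction, or None when the site has no coverage."""
        cov = self.coverage
        return self.count_methylated / cov if cov > 0 else None


@dataclass
class GeneRecord:
    """A stranded gene model: ordered exon intervals plus optional expression.

    Exons are half-open ``(start, end)`` tuples in genomic coordinates,
    sorted ascending and non-overlapping.  The transcriptional start site is
    the leftmost coordinate on "+" genes and the rightmost on "-" genes.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: at least one exon is required")
        exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"gene {self.gene_id}: empty exon interval [{s}, {e})")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        """0-based position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_length(self) -> int:
        return (self.end - self.start) - self.exon_length

    @property
    def exon_count(self) -> int:
        return len(self.exons)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as an upper-cased ``{name: sequence}`` mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    logger.info("read_genome: %d sequences, %d bp total",
                len(genome), sum(len(s) for s in genome.values()))
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write a ``{name: sequence}`` mapping as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# per-cytosine report
# ---------------------------------------------------------------------------

def read_cytosine_table(path: str | Path,
                        genome: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a six-column per-cytosine methylation report.

    Returns a DataFrame with columns ``chromosome, position (0-based),
    strand, context, count_methylated, count_unmethylated`` sorted by
    (chromosome, position).  When *genome* is supplied, each record's
    context call is re-derived from the sequence and mismatches raise
    :class:`ValidationError` naming the first offending position.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CYTOSINE_COLUMNS,
            dtype={"chromosome": str, "position": np.int64, "strand": str,
                   "context": str, "count_methylated": np.int64,
                   "count_unmethylated": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        logger.warning("read_cytosine_table: %s is empty", path)
        return pd.DataFrame(columns=CYTOSINE_COLUMNS).astype(
            {"position": np.int64, "count_methylated": np.int64,
             "count_unmethylated": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed cytosine table ({exc})") from exc

    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        raise ParseError(f"{path}: invalid strand at line {int(np.flatnonzero(bad)[0]) + 1}")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ParseError(f"{path}: invalid context at line {int(np.flatnonzero(bad)[0]) + 1}")
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ParseError(f"{path}: negative read count")

    df["position"] = df["position"] - 1          # file is 1-based
    if (df["position"] < 0).any():
        raise ParseError(f"{path}: position must be >= 1")

    df = df.sort_values(["chromosome", "position", "strand"], kind="mergesort")
    df = df.reset_index(drop=True)

    if genome is not None:
        _validate_contexts(df, genome, str(path))
    logger.info("read_cytosine_table: %d records from %s", len(df), path)
    return df


def _validate_contexts(df: pd.DataFrame, genome: Mapping[str, str], source: str) -> None:
    from .methylome_core import classify_context_array

    for chrom, sub in df.groupby("chromosome", sort=False):
        if chrom not in genome:
            raise ValidationError(f"{source}: chromosome {chrom!r} not in genome")
        n = len(genome[chrom])
        pos = sub["position"].to_numpy()
        if (pos >= n).any():
            first = int(pos[pos >= n][0])
            raise ValidationError(
                f"{source}: position {first + 1} beyond {chrom} length {n}")
        called = classify_context_array(genome[chrom], pos, sub["strand"].to_numpy())
        claimed = sub["context"].to_numpy()
        mism = (called != claimed) & (called != "undefined")
        if mism.any():
            i = int(np.flatnonzero(mism)[0])
            raise ValidationError(
                f"{source}: context mismatch at {chrom}:{pos[i] + 1} "
                f"(file says {claimed[i]}, genome implies {called[i]})")


def write_cytosine_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical six-column report (positions re-emitted 1-based)."""
    out = df[CYTOSINE_COLUMNS].copy()
    out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene models from GFF3 (gene -> mRNA -> exon features).

    When a gene carries several mRNA isoforms, the first one in file order
    is used.  Coordinates are converted from GFF3's 1-based inclusive
    convention to internal 0-based half-open intervals.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:                     # gffutils raises various types
        raise ParseError(f"{path}: failed to parse GFF3 ({exc})") from exc

    # file order of mRNA IDs, to honor the first-isoform rule
    mrna_order: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 9 and cols[2] == "mRNA":
                for attr in cols[8].split(";"):
                    if attr.startswith("ID="):
                        mrna_order.setdefault(attr[3:], len(mrna_order))

    genes: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if not gene.id or gene.id.startswith("gene_"):  # gffutils placeholder
            if "ID" not in gene.attributes:
                raise ParseError(f"{path}: gene without ID attribute at "
                                 f"{gene.seqid}:{gene.start}")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            mrnas.sort(key=lambda m: mrna_order.get(m.id, len(mrna_order)))
            parent = mrnas[0]
        else:
            parent = gene
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        if not exons:
            raise ValidationError(f"{path}: gene {gene.id} has no exon children")
        gene_span = (gene.start - 1, gene.end)
        for s, e in exons:
            if s < gene_span[0] or e > gene_span[1]:
                raise ValidationError(
                    f"{path}: exon [{s}, {e}) of gene {gene.id} lies outside "
                    f"gene span [{gene_span[0]}, {gene_span[1]})")
        genes.append(GeneRecord(gene_id=gene.id, chromosome=gene.seqid,
                                strand=gene.strand, exons=exons))
    logger.info("read_gff3_genes: %d genes from %s", len(genes), path)
    return genes


def write_gff3_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Emit gene/mRNA/exon features in standard GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start + 1, g.end
            fh.write(f"{g.chromosome}\tmethylex\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chromosome}\tmethylex\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.mRNA1;Parent={g.gene_id}\n")
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(f"{g.chromosome}\tmethylex\texon\t{xs + 1}\t{xe}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}.mRNA1\n")


# ---------------------------------------------------------------------------
# expression, GO annotations, repeats
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of ``gene_id<TAB>expression`` (raw scale).

    Duplicated gene ids and negative values are errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "expression"],
                         dtype={"gene_id": str, "expression": np.float64})
    except pd.errors.EmptyDataError:
        logger.warning("read_expression_table: %s is empty", path)
        return {}
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed expression table ({exc})") from exc
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene id {df['gene_id'][dup].iloc[0]!r}")
    if (df["expression"] < 0).any():
        gid = df.loc[df["expression"] < 0, "gene_id"].iloc[0]
        raise ValidationError(f"{path}: negative expression for gene {gid!r}")
    logger.info("read_expression_table: %d genes from %s", len(df), path)
    return dict(zip(df["gene_id"], df["expression"]))


def write_expression_table(expression: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, value in expression.items():
            fh.write(f"{gid}\t{value:.10g}\n")


def read_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read gene-to-GO-term annotations from a long-format two-column TSV."""
    path = Path(path)
    annotations: dict[str, set[str]] = {}
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"],
                         dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("read_go_annotations: %s is empty", path)
        return {}
    for gid, term in zip(df["gene_id"], df["term"]):
        annotations.setdefault(gid, set()).add(term)
    logger.info("read_go_annotations: %d annotated genes from %s",
                len(annotations), path)
    return annotations


def write_go_annotations(annotations: Mapping[str, Iterable[str]],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in annotations:
            for term in sorted(annotations[gid]):
                fh.write(f"{gid}\t{term}\n")


def read_repeats_bed(path: str | Path) -> pd.DataFrame:
    """Read repeat intervals from BED4 (chrom, start, end, family); 0-based half-open."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chromosome", "start", "end", "family"],
                         dtype={"chromosome": str, "start": np.int64,
                                "end": np.int64, "family": str})
    except pd.errors.EmptyDataError:
        logger.warning("read_repeats_bed: %s is empty", path)
        return pd.DataFrame(columns=["chromosome", "start", "end", "family"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed BED ({exc})") from exc
    if (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: BED interval with end <= start")
    logger.info("read_repeats_bed: %d repeats from %s", len(df), path)
    return df


def write_repeats_bed(repeats: pd.DataFrame, path: str | Path) -> None:
    repeats[["chromosome", "start", "end", "family"]].to_csv(
        path, sep="\t", header=False, index=False)


def attach_expression(genes: Sequence[GeneRecord],
                      expression: Mapping[str, float]) -> list[GeneRecord]:
    """Inner-join genes with expression values on gene id.

    Genes without an expression value are dropped (with a logged count),
    mirroring an analysis restricted to genes with expression data.
    """
    kept = []
    for g in genes:
        if g.gene_id in expression:
            g.expression = float(expression[g.gene_id])
            kept.append(g)
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("attach_expression: dropped %d genes without expression", dropped)
    return kept
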