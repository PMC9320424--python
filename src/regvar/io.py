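"""Readers and writers for every external format the pipeline touches.

TSV tables are handled with pandas, FASTA with Bio.SeqIO, and PWM libraries
with Bio.motifs (JASPAR and TRANSFAC dialects).  All readers return the
domain types from :mod:`regvar.types`.
"""
from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .types import (
    AssociationRecord,
    ChromatinSegment,
    GeneAnnotation,
    LDRecord,
    PICSRecord,
    PWMMatrix,
    TFTargetRecord,
    ValidationError,
    Variant,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate conversions (the single place where BED <-> 1-based happens)

def bed_to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start+1, end)."""
    return start + 1, end


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome as {chrom: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(
    genome: Mapping[str, str], chrom: str, start_1based: int, end_inclusive: int
) -> str:
    """Fetch an uppercase subsequence, 1-based inclusive coordinates."""
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if start_1based < 1 or end_inclusive > len(seq) or start_1based > end_inclusive:
        raise IndexError(
            f"{chrom}:{start_1based}-{end_inclusive} outside chromosome bounds (1-{len(seq)})"
        )
    return seq[start_1based - 1 : end_inclusive].upper()


# ---------------------------------------------------------------------------
# PWM libraries

def _motif_to_matrix(m, source_db: str, index: int) -> PWMMatrix:
    counts = np.array([[m.counts[b][j] for b in "ACGT"] for j in range(m.length)])
    matrix_id = getattr(m, "matrix_id", None)
    if not matrix_id and isinstance(m, dict):  # TRANSFAC motifs are dict-like
        matrix_id = m.get("AC") or m.get("ID")
    if not matrix_id:
        matrix_id = m.name or f"matrix_{index}"
    return PWMMatrix(
        matrix_id=str(matrix_id),
        tf_name=str(m.name or matrix_id),
        counts=counts,
        source_db=source_db,
    )


def read_matrix_library(path: str | Path, dialect: str = "jaspar") -> list[PWMMatrix]:
    """Parse a motif library into count matrices.

    ``dialect`` is ``"jaspar"`` or ``"transfac"``.  Counts are preserved
    exactly; records with negative counts or all-zero columns are rejected.
    """
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unsupported matrix dialect {dialect!r}")
    text = Path(path).read_text()
    if not text.strip():
        log.warning("matrix library %s is empty", path)
        return []
    try:
        parsed = motifs.parse(_io.StringIO(text), dialect.replace("transfac", "TRANSFAC"))
        result = [_motif_to_matrix(m, dialect, i) for i, m in enumerate(parsed)]
    except ValidationError:
        raise
    except Exception as exc:  # biopython raises bare ValueError/KeyError
        raise ParseError(f"malformed {dialect} record in {path}: {exc}") from exc
    return result


def write_matrix_library(matrices: Iterable[PWMMatrix], path: str | Path) -> None:
    """Write matrices in JASPAR (4-row) format."""
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.matrix_id} {m.tf_name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{v:.10g}" for v in m.counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, biosample: str = "") -> list[tuple]:
    """Read BED3/BED4 into (chrom, start, end, label) tuples (0-based half-open).

    ``track``/``browser``/``#`` lines are skipped.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start, end, label))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_chromatin_segments(path: str | Path, biosample: str = "") -> list[ChromatinSegment]:
    """ChromHMM segmentation BED4; biosample from argument (file-level metadata)."""
    return [
        ChromatinSegment(chrom=c, start=s, end=e, state_label=label, biosample=biosample)
        for c, s, e, label in read_bed(path)
    ]


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x tissues TPM table from GCT or plain TSV.

    GCT files start with a ``#1.2`` version line and a dimensions line and
    carry Name/Description columns; plain TSV has gene ids in the first
    column.  Duplicate gene ids and negative TPMs are rejected.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1."):
        df = pd.read_csv(path, sep="\t", skiprows=2)
        df = df.set_index(df.columns[0])
        drop = [c for c in df.columns[:1] if c.lower() == "description"]
        df = df.drop(columns=drop)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {path}: {dupes}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError(f"negative TPM values in {path}")
    return df.astype(float)


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(df.columns) + "\n")
        for gene, row in df.iterrows():
            fh.write(gene + "\t" + gene + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# TSV tables for the domain records

def read_variants(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        terms = getattr(row, "consequence_terms", "")
        terms = frozenset(t for t in str(terms).split(",") if t and t != "nan")
        cadd = getattr(row, "cadd_phred", None)
        af = getattr(row, "allele_freq", None)
        out.append(
            Variant(
                id=row.variant_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                allele_freq=None if af is None or pd.isna(af) else float(af),
                consequence_terms=terms,
                cadd_phred=None if cadd is None or pd.isna(cadd) else float(cadd),
            )
        )
    return out


def write_variants(variants: Iterable[Variant], path: str | Path) -> None:
    rows = [
        {
            "variant_id": v.id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "allele_freq": v.allele_freq,
            "consequence_terms": ",".join(sorted(v.consequence_terms)),
            "cadd_phred": v.cadd_phred,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        AssociationRecord(
            variant_id=r.variant_id,
            chrom=r.chrom,
            pos=int(r.pos),
            p_value=float(r.p_value),
            is_index=bool(getattr(r, "is_index", False)),
        )
        for r in df.itertuples(index=False)
    ]


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


#: Default column mapping for PICS tables; snapshot files with other layouts
#: are read by passing their own mapping.
PICS_COLUMNS = {
    "variant_id": "variant_id",
    "locus_id": "locus_id",
    "pics_prob": "pics_prob",
    "source": "source",
    "tissue": "tissue",
    "egene": "egene",
}


def read_pics_table(
    path: str | Path, columns: Mapping[str, str] | None = None, source: str | None = None
) -> list[PICSRecord]:
    """Read a PICS probability table with a configurable column mapping."""
    cols = dict(PICS_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            PICSRecord(
                variant_id=str(row[cols["variant_id"]]),
                locus_id=str(row[cols["locus_id"]]),
                pics_prob=float(row[cols["pics_prob"]]),
                source=source or str(row.get(cols["source"], "gwas")),
                tissue=str(row.get(cols["tissue"], "") or ""),
                egene=str(row.get(cols["egene"], "") or ""),
            )
        )
    return out


def write_pics_table(records: Iterable[PICSRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path) -> list[LDRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        LDRecord(variant_a=r.variant_a, variant_b=r.variant_b, r2=float(r.r2))
        for r in df.itertuples(index=False)
    ]


def write_ld_table(records: Iterable[LDRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(
            gene_id=r.gene_id,
            gene_name=str(getattr(r, "gene_name", r.gene_id)),
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            tss=int(r.tss),
        )
        for r in df.itertuples(index=False)
    ]


def write_genes(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(g) for g in genes]).to_csv(path, sep="\t", index=False)


def read_tftargets(path: str | Path) -> list[TFTargetRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TFTargetRecord(tf_name=r.tf_name, target_gene=r.target_gene, tissue=r.tissue)
        for r in df.itertuples(index=False)
    ]


def write_tftargets(records: Iterable[TFTargetRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)
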