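"""Readers and writers for the external formats the pipeline touches.

Internal conventions
--------------------
* Base coordinates are 1-based inclusive; GFF3 (1-based inclusive) and BED
  (0-based half-open) are both mapped onto this convention.
* All colinearity logic downstream works on ``order_index`` — the 0-based
  rank of a gene along its chromosome — because gap limits are expressed in
  genes, not base pairs.
* The missing-value token in every TSV emitted here is ``.``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("wgdkit")

MISSING = "."


class FormatError(ValueError):
    """A file does not parse under its declared standard."""


class IntegrityError(ValueError):
    """Parsed content violates an internal invariant."""


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome.

    ``genes`` is a DataFrame with columns
    ``gene_id, chromosome, start, end, strand, order_index`` sorted by
    (chromosome, start); ``order_index`` is 0-based and consecutive per
    chromosome.
    """

    genome_id: str
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise IntegrityError(f"duplicate gene_id {dup!r} in genome {self.genome_id}")
        if (g["end"] < g["start"]).any():
            bad = g.loc[g["end"] < g["start"], "gene_id"].iloc[0]
            raise IntegrityError(f"gene {bad!r}: end < start")

    @classmethod
    def from_records(cls, genome_id: str, records: Iterable[tuple]) -> "GenomeAnnotation":
        """Build from (gene_id, chromosome, start, end, strand) tuples."""
        df = pd.DataFrame(records, columns=["gene_id", "chromosome", "start", "end", "strand"])
        df = df.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
        df["order_index"] = df.groupby("chromosome", sort=False).cumcount()
        return cls(genome_id, df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.genes["chromosome"]))

    def order_map(self) -> pd.DataFrame:
        """gene_id-indexed view with chromosome and order_index."""
        return self.genes.set_index("gene_id")[["chromosome", "order_index"]]

    def __len__(self) -> int:
        return len(self.genes)


def read_annotation(path, format: str = "GFF3", genome_id: Optional[str] = None) -> GenomeAnnotation:
    """Read gene models from GFF3 or BED into a :class:`GenomeAnnotation`."""
    path = Path(path)
    genome_id = genome_id or path.stem
    fmt = format.upper()
    records = []
    if fmt == "GFF3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != "gene":
                    continue
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
                gid = None
                for kv in attrs.split(";"):
                    kv = kv.strip()
                    if kv.startswith("ID="):
                        gid = kv[3:]
                        break
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
                records.append((gid, chrom, start_i, end_i, strand if strand in "+-" else "+"))
    elif fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
                chrom, start, end, gid = parts[:4]
                strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
                try:
                    # BED is 0-based half-open -> 1-based inclusive
                    start_i, end_i = int(start) + 1, int(end)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
                records.append((gid, chrom, start_i, end_i, strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not records:
        raise FormatError(f"{path}: no gene features found")
    return GenomeAnnotation.from_records(genome_id, records)


def write_annotation_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.genes.itertuples():
            fh.write(
                f"{row.chromosome}\twgdkit\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------

BLAST6_COLUMNS = [
    "query", "subject", "percent_identity", "alignment_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "alignment_score",
]


@dataclass
class HomologyTable:
    """Deduplicated homologous gene pairs.

    ``pairs`` columns: query, subject, percent_identity, alignment_score,
    e_value (+ optional extra metadata columns such as a true-event label on
    simulated data).  No self pairs; one row per unordered pair (best score).
    """

    pairs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame) -> "HomologyTable":
        df = df[df["query"] != df["subject"]].copy()
        key = np.where(df["query"] < df["subject"],
                       df["query"] + "\t" + df["subject"],
                       df["subject"] + "\t" + df["query"])
        df["_key"] = key
        df = df.sort_values(
            ["_key", "alignment_score", "e_value", "query", "subject"],
            ascending=[True, False, True, True, True], kind="mergesort")
        df = df.drop_duplicates("_key", keep="first").drop(columns="_key")
        return cls(df.reset_index(drop=True))


def read_homology(path) -> HomologyTable:
    """Read 12-column BLAST tabular (outfmt 6) output."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                rows.append((parts[0], parts[1], float(parts[2]), float(parts[10]), float(parts[11])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score field") from None
    df = pd.DataFrame(rows, columns=["query", "subject", "percent_identity", "e_value", "alignment_score"])
    return HomologyTable.from_pairs(df[["query", "subject", "percent_identity", "alignment_score", "e_value"]])


def write_homology_blast6(table: HomologyTable, path) -> None:
    with open(path, "w") as fh:
        for row in table.pairs.itertuples():
            fh.write(
                f"{row.query}\t{row.subject}\t{row.percent_identity:.2f}\t100\t0\t0\t1\t100\t1\t100\t"
                f"{row.e_value:.2e}\t{row.alignment_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# CDS sets
# ---------------------------------------------------------------------------

def read_cds(path) -> dict:
    """Read coding sequences from FASTA into a gene_id -> sequence map."""
    cds = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            raise IntegrityError(f"CDS {rec.id}: length {len(seq)} not divisible by 3")
        if set(seq) - set("ACGTN"):
            raise IntegrityError(f"CDS {rec.id}: alphabet outside ACGTN")
        cds[rec.id] = seq
    return cds


def write_cds(cds: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gid in cds:
            fh.write(f">{gid}\n")
            seq = cds[gid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with a replicate-group map.

    ``groups`` maps sample name -> condition (tissue/stage) label.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise IntegrityError("negative FPKM value")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise IntegrityError(f"samples without replicate group: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.groups[s] for s in self.values.columns))

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per condition (averaging replicates)."""
        cols = {}
        for cond in self.conditions:
            samples = [s for s in self.values.columns if self.groups[s] == cond]
            cols[cond] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols)


def read_expression(path, groups: Mapping[str, str],
                    annotation: Optional[GenomeAnnotation] = None) -> ExpressionMatrix:
    """Read a TSV FPKM matrix (first column gene_id, header of sample names)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isnull().any().any():
        raise FormatError(f"{path}: ragged rows or missing values")
    try:
        df = df.astype(float)
    except ValueError:
        raise FormatError(f"{path}: non-numeric expression value") from None
    if annotation is not None:
        known = set(annotation.genes["gene_id"])
        unmatched = [g for g in df.index if g not in known]
        if unmatched:
            logger.warning("%d expression gene ids not in annotation (kept), e.g. %s",
                           len(unmatched), unmatched[:3])
    return ExpressionMatrix(df, dict(groups))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


# ---------------------------------------------------------------------------
# generic table serialization
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic TSV serialization: fixed column order, '.' for missing,
    6 significant digits for floats."""
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep=MISSING, index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False, **kwargs)


def write_tables(objects: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write a named set of result tables under ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in objects.items():
        p = out_dir / f"{name}.tsv"
        write_tsv(df, p)
        paths.append(p)
    return paths
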