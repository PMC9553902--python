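"""Readers and writers for the pipeline's tabular and sequence formats.

TSV (tab) is the canonical tabular dialect; comma-separated input is accepted
on read. All readers validate rather than coerce: missing columns, duplicate
identifiers, non-numeric cells, empty sequences and out-of-range survival
fields are rejected with specific errors. Outputs carry provenance comment
headers (``# key: value`` lines, skipped on read); coordinates in BED output
are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interactome import GeneRecord
from .mre import SiteHit, hits_to_bed_frame
from .survival import SurvivalCohort

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "gene_records_from_frame",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "read_cohort",
    "write_cohort",
    "write_tsv",
]

GENE_TABLE_COLUMNS = ("gene_id", "reads_mir16", "reads_mirctr", "basal_expr")

def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#", dtype=str)

def write_tsv(df: pd.DataFrame, path, header: Mapping[str, object] | None = None) -> None:
    """Write a TSV with optional ``# key: value`` provenance comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)

def gene_records_from_frame(df: pd.DataFrame) -> list[GeneRecord]:
    """Typed gene records from a validated gene-table DataFrame."""
    logfc_cols = [c for c in df.columns if c.startswith("logfc_")]
    tps = [float(c.removeprefix("logfc_").removesuffix("h")) for c in logfc_cols]
    records = []
    for _, row in df.iterrows():
        records.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                reads_mir16=int(row["reads_mir16"]),
                reads_mirctr=int(row["reads_mirctr"]),
                basal_expr=float(row["basal_expr"]),
                logfc={t: float(row[c]) for t, c in zip(tps, logfc_cols)},
            )
        )
    return records

def read_gene_table(path) -> list[GeneRecord]:
    """Read a pull-down/kinetics gene table (TSV; CSV accepted by extension).

    Requires columns gene_id, reads_mir16, reads_mirctr, basal_expr and at
    least one ``logfc_<t>h`` column. Rejects missing columns (named),
    non-numeric cells (with row and column) and duplicate gene ids.
    """
    df = _read_table(path)
    for col in GENE_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"gene table is missing required column {col!r}")
    logfc_cols = [c for c in df.columns if c.startswith("logfc_")]
    if not logfc_cols:
        raise ValueError("gene table has no logfc_<t>h columns")
    for c in logfc_cols:
        tail = c.removeprefix("logfc_")
        if not tail.endswith("h"):
            raise ValueError(f"malformed logFC column name {c!r} (expected logfc_<t>h)")
        float(tail.removesuffix("h"))
    numeric = ["reads_mir16", "reads_mirctr", "basal_expr", *logfc_cols]
    for c in numeric:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if df[c].isna().any() or bad.any():
            row = int((df[c].isna() | bad).idxmax())
            raise ValueError(f"non-numeric or missing value at row {row}, column {c!r}")
        df[c] = parsed
    dup = df["gene_id"][df["gene_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate gene_id values: {sorted(dup.tolist())}")
    return gene_records_from_frame(df)

def write_gene_table(records: Sequence[GeneRecord] | pd.DataFrame, path,
                     header: Mapping[str, object] | None = None) -> None:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        tps = sorted({t for r in records for t in r.logfc})
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in records],
                "reads_mir16": [r.reads_mir16 for r in records],
                "reads_mirctr": [r.reads_mirctr for r in records],
                "basal_expr": [r.basal_expr for r in records],
                **{
                    f"logfc_{t:g}h": [r.logfc[t] for r in records]
                    for t in tps
                },
            }
        )
    write_tsv(df, path, header)

def read_fasta(path) -> dict[str, str]:
    """FASTA to an id -> sequence map (id = header up to first whitespace).

    Line wrapping is removed; empty sequences and duplicate ids are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        s = str(rec.seq)
        if not s:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        seqs[rec.id] = s
    return seqs

def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)

def write_bed(hits: Sequence[SiteHit], path, header: Mapping[str, object] | None = None) -> None:
    """Write site hits as BED6 (0-based half-open, sense strand)."""
    write_tsv(hits_to_bed_frame(hits), path, header)

def read_bed(path) -> list[SiteHit]:
    df = _read_table(path)
    hits = []
    for _, row in df.iterrows():
        name = str(row["name"])
        stype, _, ibase = name.partition(":")
        hits.append(
            SiteHit(
                transcript_id=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                site_type=stype,
                inserted_base=ibase or None,
                score=float(row["score"]),
            )
        )
    return hits

def read_cohort(path) -> SurvivalCohort:
    """Read a survival cohort TSV: sample_id, time, event, then gene columns.

    Rejects non-positive or missing times, event values outside {0, 1}, and
    duplicate sample ids.
    """
    df = _read_table(path)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate sample_id values: {sorted(dup.tolist())}")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or (time <= 0).any():
        raise ValueError("times must be positive numbers with no missing values")
    event = pd.to_numeric(df["event"], errors="coerce")
    if event.isna().any() or not set(event.unique()) <= {0, 1}:
        raise ValueError("event must be 0 (censored) or 1 (event)")
    gene_cols = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    expr = df[gene_cols].apply(pd.to_numeric, errors="coerce")
    if expr.isna().any().any():
        col = expr.columns[expr.isna().any()][0]
        row = int(expr[col].isna().idxmax())
        raise ValueError(f"non-numeric expression value at row {row}, column {col!r}")
    ids = df["sample_id"].astype(str).tolist()
    expr.index = ids
    return SurvivalCohort(
        sample_ids=ids,
        time=time.to_numpy(dtype=float),
        event=event.to_numpy(dtype=int),
        expression=expr,
    )

def write_cohort(cohort: SurvivalCohort, path, header: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame(
        {"sample_id": cohort.sample_ids, "time": cohort.time, "event": cohort.event}
    )
    df = pd.concat([df, cohort.expression.reset_index(drop=True)], axis=1)
    write_tsv(df, path, header)
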