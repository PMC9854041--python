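"""Readers/writers for the plain-text formats the pipeline exchanges.

All tables are TSV; intervals are BED (0-based half-open); cytosine reports
use the strand-resolved CX dialect (1-based positions).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .genome import GenomeSpec

CX_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "context", "trinucleotide"]
CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")
BASES = ("A", "C", "G", "T")


def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Parse a CX-dialect cytosine report into a validated DataFrame.

    Columns: chrom, pos (1-based), strand, meth_count, unmeth_count, context,
    trinucleotide. Zero-depth sites are retained. Malformed lines raise
    ValueError naming the 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CX_COLUMNS).astype(
            {"pos": np.int64, "meth_count": np.int64, "unmeth_count": np.int64}
        )
    _validate_cx(df, path)
    df["pos"] = df["pos"].astype(np.int64)
    df["meth_count"] = df["meth_count"].astype(np.int64)
    df["unmeth_count"] = df["unmeth_count"].astype(np.int64)
    return df


def _validate_cx(df: pd.DataFrame, path: Path) -> None:
    def fail(mask: pd.Series, reason: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ValueError(f"{path}:{line}: {reason}")

    for col in ("pos", "meth_count", "unmeth_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        fail(numeric.isna(), f"non-numeric {col}")
        fail((numeric % 1) != 0, f"non-integer {col}")
        df[col] = numeric
    fail(df["pos"] < 1, "position must be >= 1")
    fail(df["meth_count"] < 0, "negative methylated count")
    fail(df["unmeth_count"] < 0, "negative unmethylated count")
    fail(~df["strand"].isin(STRANDS), "strand must be '+' or '-'")
    fail(~df["context"].isin(CONTEXTS), "unknown context token")


def write_cx_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Read BED (3+ columns) into chrom/start/end[/name/score/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3]).astype({"start": np.int64, "end": np.int64})
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if genome is not None:
        for chrom, end in zip(df["chrom"], df["end"]):
            if chrom not in genome or end > genome.chrom_sizes[chrom]:
                raise ValueError(f"BED interval on {chrom} ending at {end} outside genome")
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def bed_to_intervals(df: pd.DataFrame, genome: GenomeSpec | None = None) -> IntervalSet:
    return IntervalSet(
        list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int))),
        genome=genome,
    )


def read_gff3_features(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into feature_id/chrom/start/end/kind (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {raw!r}")
            chrom, _src, kind, start, end, _score, _strand, _phase, attrs = parts
            fid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
            rows.append(
                {
                    "feature_id": fid,
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "kind": kind,
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "kind"])


def write_gff3_features(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tecomethyl\t{row.kind}\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.feature_id}\n"
            )


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """SNP TSV: chrom, pos (1-based), col_base, cvi_base. Adds substitution code."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "col_base", "cvi_base"],
        dtype={"chrom": str, "col_base": str, "cvi_base": str},
    )
    df["pos"] = df["pos"].astype(np.int64)
    bad = ~df["col_base"].isin(BASES) | ~df["cvi_base"].isin(BASES)
    if bad.any():
        raise ValueError(f"invalid SNP base at row {int(np.flatnonzero(bad)[0]) + 1}")
    same = df["col_base"] == df["cvi_base"]
    if same.any():
        raise ValueError(f"SNP with identical bases at row {int(np.flatnonzero(same)[0]) + 1}")
    df["substitution"] = df["col_base"] + df["cvi_base"]
    return df


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Cluster-by-sample raw count matrix; first column is the cluster id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)
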