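"""Readers and writers for the formats the pipeline consumes and emits.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  At the boundaries:

* STAR ``SJ.out.tab`` junction rows carry 1-based *inclusive* intron spans;
  a row ``chr1  100  200`` becomes the interval ``[99, 200)``.
* BED is already 0-based half-open and passes through unchanged.
* GTF features are 1-based inclusive; ``[11, 20]`` becomes ``[10, 20)``.

Junction tables are held in long form (one row per junction per sample);
expression matrices are genes x samples DataFrames; skipped-exon event
tables carry explicit exon coordinates from which the three junction keys
(two inclusion, one skipping) are derived.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

__all__ = [
    "DataError",
    "read_junction_table",
    "write_junction_table",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gtf",
    "read_event_table",
    "write_event_table",
]

_STRAND_DECODE = {"0": ".", "1": "+", "2": "-"}

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "count", "sample"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_junction_table(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read a STAR ``SJ.out.tab`` file into a long junction table.

    Columns of the returned frame: chrom, start, end (0-based half-open
    intron span), strand (+/-/.), count (unique-mapping reads, column 7),
    sample.  ``sample`` defaults to the file stem.
    """
    path = Path(path)
    if sample is None:
        sample = path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 9:
                raise DataError(
                    f"{path}:{lineno}: expected >=9 columns, got {len(fields)}"
                )
            chrom, start1, end1 = fields[0], int(fields[1]), int(fields[2])
            if start1 > end1:
                raise DataError(f"{path}:{lineno}: intron start > end")
            strand = _STRAND_DECODE.get(fields[3])
            if strand is None:
                raise DataError(f"{path}:{lineno}: bad strand code {fields[3]!r}")
            count = int(fields[6])
            if count < 0:
                raise DataError(f"{path}:{lineno}: negative read count")
            rows.append((chrom, start1 - 1, end1, strand, count, sample))
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def write_junction_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's junctions in STAR ``SJ.out.tab`` dialect."""
    encode = {".": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start + 1}\t{row.end}\t{encode[row.strand]}"
                f"\t0\t0\t{int(row.count)}\t0\t50\n"
            )


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read peaks from BED6 (optional 7th column = summit coordinate).

    Returns columns chrom, start, end, name, height (BED score), strand,
    summit.  Without an explicit summit the interval midpoint is used.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise DataError(f"{path}:{lineno}: BED6 needs >=6 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end")
            summit = int(f[6]) if len(f) > 6 and f[6] != "." else (start + end) // 2
            if not start <= summit < end:
                raise DataError(f"{path}:{lineno}: summit outside interval")
            rows.append((f[0], start, end, f[3], float(f[4]), f[5], summit))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "height", "strand", "summit"]
    )


def write_bed_peaks(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name", "height", "strand"]
    out = df[cols].copy()
    if "summit" in df.columns:
        out["summit"] = df["summit"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples expression matrix; duplicate gene ids are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GTF into a frame with 0-based half-open coordinates.

    Keeps feature, chrom, start, end, strand plus the gene_id,
    transcript_id and gene_biotype attributes (empty string when absent).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise DataError(f"{path}:{lineno}: GTF needs 9 columns")
            start1, end1 = int(f[3]), int(f[4])
            if start1 > end1:
                raise DataError(f"{path}:{lineno}: start > end")
            attrs = dict(_GTF_ATTR.findall(f[8]))
            rows.append(
                (
                    f[0], f[2], start1 - 1, end1, f[6],
                    attrs.get("gene_id", ""), attrs.get("transcript_id", ""),
                    attrs.get("gene_biotype", ""),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "feature", "start", "end", "strand",
                 "gene_id", "transcript_id", "gene_biotype"],
    )


EVENT_COLUMNS = [
    "event_id", "gene", "chrom", "strand",
    "up_start", "up_end", "alt_start", "alt_end", "dn_start", "dn_end",
]


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"event table {path} missing columns {missing}")
    return df


def write_event_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
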