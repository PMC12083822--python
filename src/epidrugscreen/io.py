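"""Readers and writers for the interchange formats.

Formats are deliberately plain text: long-format CSV for viability, TSV for
count matrices and sample metadata, GMT for gene sets, BED 3+1 for scored
peaks, BED6 for TSSs, JSON for reports. Every writer's output is readable
by its reader (round-trip identity is part of the test suite).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dose_response import VIABILITY_COLUMNS
from .errors import FormatError

log = logging.getLogger("epidrugscreen")


# --- viability -------------------------------------------------------------


def read_viability_csv(path) -> pd.DataFrame:
    """Read a long-format viability table, failing fast with row numbers.

    Header must be exactly ``compound,drug_class,cell_line,dose_M,day,
    replicate,viability``. Doses are molar floats; duplicate
    (compound, line, dose, day, replicate) rows are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != VIABILITY_COLUMNS:
        raise FormatError(
            f"{path}: header must be {','.join(VIABILITY_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    for col, kind in [("dose_M", float), ("day", float), ("replicate", int), ("viability", float)]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {col} {df[col][bad[0]]!r} at row {row}")
        if converted.isna().any():
            row = int(df.index[converted.isna()][0]) + 2
            raise FormatError(f"{path}: missing {col} at row {row}")
        df[col] = converted.astype(kind)
    dup_cols = ["compound", "cell_line", "dose_M", "day", "replicate"]
    dups = df.index[df.duplicated(subset=dup_cols)]
    if len(dups):
        raise FormatError(f"{path}: duplicate observation at row {int(dups[0]) + 2}")
    if (df["viability"] < 0).any():
        row = int(df.index[df["viability"] < 0][0]) + 2
        raise FormatError(f"{path}: negative viability at row {row}")
    if (df["dose_M"] <= 0).any():
        row = int(df.index[df["dose_M"] <= 0][0]) + 2
        raise FormatError(f"{path}: nonpositive dose at row {row}")
    return df


def write_viability_csv(table: pd.DataFrame, path) -> None:
    table[VIABILITY_COLUMNS].to_csv(path, index=False)


# --- counts / samples ------------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes x samples integer matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty count matrix")
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer counts ({exc})") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    df.index.name = "gene"
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"dose_nM": float})
    required = {"cell_line", "compound"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample table needs columns {sorted(required)}")
    df.index.name = "sample"
    df["cell_line"] = df["cell_line"].astype(str)
    return df


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


# --- GMT -------------------------------------------------------------------


def read_gmt(path) -> dict:
    """Order-preserving GMT reader: name -> (description, member list).

    Duplicate set names are an error; duplicate members within a set are
    deduplicated (keeping first occurrence) with a logged warning.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno} has no description field")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                log.warning("%s: set %r has duplicate gene ids; deduplicated", path, name)
            sets[name] = (desc, deduped)
    return sets


def write_gmt(sets: dict, path) -> None:
    """Write name -> (description, members) or name -> members."""
    with open(path, "w") as fh:
        for name, value in sets.items():
            if isinstance(value, tuple):
                desc, members = value
            else:
                desc, members = "", list(value)
            fh.write("\t".join([name, desc, *members]) + "\n")


# --- BED -------------------------------------------------------------------


def read_bed_peaks(path) -> pd.DataFrame:
    """BED 3+1: chrom, start, end, score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno} needs 4 fields (chrom,start,end,score)")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def write_bed_peaks(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in peaks.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r['score']:.6g}\n")


def read_tss_bed(path) -> dict:
    """BED6 TSS table: gene -> (chrom, position, strand)."""
    tss: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno} needs 6 fields")
            chrom, start, _end, gene, _score, strand = parts[:6]
            if gene in tss:
                raise FormatError(f"{path}: duplicate gene {gene!r} at line {lineno}")
            tss[gene] = (chrom, int(start), strand)
    return tss


def write_tss_bed(tss: dict, path) -> None:
    with open(path, "w") as fh:
        for gene, (chrom, pos, strand) in tss.items():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{gene}\t0\t{strand}\n")
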