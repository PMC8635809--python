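"""Readers and writers for the plain-text formats the pipeline touches.

BED3/6, GMT, JASPAR-style PWM text, TSV matrices and TSV sample sheets.
All parsers are strict on their declared grammar and report the offending
line number on malformed input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BASES, GeneSetCollection, GenomicInterval, PWM, SampleSheet

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def _err(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED

def parse_bed(path) -> list[GenomicInterval]:
    """Parse a BED3/6 file into 0-based half-open intervals, order preserved."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, lineno, f"expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise _err(path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}") from None
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name or iv.strand != ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GMT

def parse_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate genes within a line are deduplicated,
    duplicate set names are an error."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, lineno, f"GMT line needs >=3 fields, got {len(fields)}")
            name, desc, *genes = fields
            if name in sets:
                raise _err(path, lineno, f"duplicate gene set name {name!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise _err(path, lineno, f"gene set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR-style PWM text
#
# Records look like:
#   >MA0001.1 NAME
#   A [ 0 3 79 ... ]
#   C [ 94 75 4 ... ]
#   ...
# Bare numeric rows (no base label, no brackets) are accepted; rows are
# stored in A,C,G,T order regardless of file row order.

def parse_jaspar_pwm(path, pseudocount: float = 0.25) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal name, rows, order
        if name is None:
            return
        if len(rows) != 4:
            raise _err(path, lineno, f"motif {name!r} has {len(rows)} base rows, expected 4")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise _err(path, lineno, f"motif {name!r} has unequal row lengths {sorted(lengths)}")
        counts = np.array([rows[b] for b in BASES], dtype=float)
        if (counts < 0).any():
            raise _err(path, lineno, f"motif {name!r} has negative counts")
        pwms.append(PWM(name, counts, pseudocount=pseudocount))
        name, rows, order = None, {}, []

    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno - 1)
            name = line[1:].strip().split()[0] if line[1:].strip() else ""
            if not name:
                raise _err(path, lineno, "motif header has no name")
            start_line = lineno
            continue
        if name is None:
            raise _err(path, lineno, "matrix row before any motif header")
        tokens = line.replace("[", " ").replace("]", " ").split()
        if tokens and tokens[0].upper() in ("A", "C", "G", "T"):
            base = tokens[0].upper()
            tokens = tokens[1:]
        else:
            base = BASES[len(rows)] if len(rows) < 4 else None
            if base is None:
                raise _err(path, lineno, "more than 4 matrix rows")
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            raise _err(path, lineno, f"non-numeric matrix entry in {line!r}") from None
        if base in rows:
            raise _err(path, lineno, f"duplicate row for base {base}")
        rows[base] = values
        order.append(base)
    flush(len(lines))
    if not pwms:
        raise ParseError(f"{path}: no motifs found")
    return pwms


def write_jaspar_pwm(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for base, row in zip(BASES, pwm.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA (writing only; reading goes through pyfaidx)

def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Matrices and sample sheets

def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_matrix(
    path,
    sheet: SampleSheet | None = None,
    kind: str = "beta",
    blocklist=None,
) -> pd.DataFrame:
    """Read a TSV matrix (first column = row id, header = sample ids).

    Columns are reordered to match the sheet. Missing values are rejected
    for count matrices and allowed (with a warning) for beta matrices.
    ``blocklist`` may be a path to a one-id-per-line file or an iterable of
    row ids to drop (e.g. SNP-overlapping probes).
    """
    if kind not in ("beta", "counts", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if mat.index.duplicated().any():
        dups = sorted(set(mat.index[mat.index.duplicated()]))
        raise ParseError(f"{path}: duplicate row ids {dups[:5]}")
    if sheet is not None:
        sheet_samples = sheet.samples
        missing = [s for s in mat.columns if s not in sheet_samples]
        if missing:
            raise ParseError(f"{path}: samples absent from sheet: {missing}")
        absent = [s for s in sheet_samples if s not in mat.columns]
        if absent:
            raise ParseError(f"{path}: sheet samples absent from matrix: {absent}")
        mat = mat[sheet_samples]
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        if kind == "counts":
            raise ParseError(f"{path}: count matrix has {n_missing} missing values")
        log.warning("%s: %d missing beta values", path, n_missing)
    if blocklist is not None:
        if isinstance(blocklist, (str, Path)):
            with open(blocklist) as fh:
                ids = {line.strip() for line in fh if line.strip()}
        else:
            ids = set(blocklist)
        before = len(mat)
        mat = mat.loc[~mat.index.isin(ids)]
        log.info("blocklist dropped %d of %d rows", before - len(mat), before)
    return mat


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t")


def read_rnk(path) -> pd.Series:
    """Read a two-column .rnk file into an ordered gene -> score Series."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    series = pd.Series(frame["score"].to_numpy(float), index=frame["gene"].astype(str))
    if series.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in ranked list")
    return series


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False)
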