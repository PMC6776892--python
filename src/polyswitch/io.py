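"""Readers and writers for the pipeline's plain-text formats.

All interval coordinates are 0-based half-open (BED convention).  Islands are
written in a broadPeak-like BED6+3 dialect: chrom, start, end, name,
min(int(10*score), 1000), strand ".", score, -log10 p, -log10 q.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


class BedParseError(ValueError):
    """A malformed BED record; the message names the offending line number."""


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}: line {ln}: expected 2 columns")
            name, length = parts[0], parts[1]
            try:
                length = int(length)
            except ValueError:
                raise BedParseError(f"{path}: line {ln}: non-integer length {length!r}") from None
            if length <= 0:
                raise BedParseError(f"{path}: line {ln}: length must be positive")
            if name in sizes:
                raise BedParseError(f"{path}: line {ln}: duplicate chromosome {name!r}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path, chrom_sizes: dict[str, int] | None = None) -> list[tuple]:
    """Read BED3/BED6 records as tuples.

    Returns ``(chrom, start, end)`` for 3-column records and
    ``(chrom, start, end, name, score, strand)`` for 6+ columns.  Track and
    comment lines are skipped; coordinate errors name the line number.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {ln}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(f"{path}: line {ln}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedParseError(f"{path}: line {ln}: require 0 <= start < end")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise BedParseError(f"{path}: line {ln}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise BedParseError(f"{path}: line {ln}: end beyond chromosome length")
            if len(parts) >= 6:
                records.append((chrom, start, end, parts[3], parts[4], parts[5]))
            else:
                records.append((chrom, start, end))
    return records


def write_bed(records, path) -> None:
    """Write interval tuples as tab-separated BED (3 or more columns)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def write_broadpeak(islands, path) -> None:
    """Write Island objects in the broadPeak-like BED6+3 dialect."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            display = min(int(10 * isl.score), 1000)
            neglog_p = -np.log10(isl.p_value) if isl.p_value > 0 else _neglog10_from_log(isl.log_p)
            neglog_q = -np.log10(isl.q_value) if isl.q_value > 0 else _neglog10_from_log(isl.log_q)
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland_{i + 1}\t{display}\t.\t"
                f"{isl.score:.4f}\t{neglog_p:.4f}\t{neglog_q:.4f}\n"
            )


def _neglog10_from_log(log_p: float) -> float:
    return -log_p / np.log(10.0)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples counts TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample, state, treatment, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "state", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    bad = set(df["treatment"]) - {"vehicle", "EZH2i"}
    if bad:
        raise ValueError(f"{path}: unknown treatment labels {sorted(bad)}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
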