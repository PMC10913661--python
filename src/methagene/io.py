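"""Readers for methylation-call and annotation formats, plus TSV export.

Supported methylation formats (gzip transparently handled):

* Bismark cytosine report (CX report): ``chrom pos strand count_m count_u
  context trinucleotide`` — 1-based positions.
* CGmap (BS-Seeker family): ``chrom nucleotide pos context dinucleotide
  level count_m count_total`` — strand is derived from the nucleotide column
  (C = plus strand, G = minus strand).
* Bismark coverage: ``chrom start end percent count_m count_u`` with
  1-based ``start == end``.
* bedGraph: ``chrom start end percent`` (0-based half-open); carries no read
  counts, so sites are stored with density-preserving fractional unit counts
  and the sample is flagged low-confidence.

Annotation formats: GFF3 and GTF (1-based inclusive), BED (0-based
half-open) and a simple TSV dialect with header ``id chrom start end
strand`` (1-based inclusive). All features are normalised to 0-based
half-open coordinates at the parser boundary.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from pathlib import Path

import numpy as np
import pandas as pd

from methagene.types import CONTEXTS, FEATURE_COLUMNS, SITE_COLUMNS, SampleTable

__all__ = [
    "FormatError",
    "read_cytosine_report",
    "read_cgmap",
    "read_coverage_or_bedgraph",
    "read_annotation",
    "write_tsv",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _read_raw(path, names: list[str], what: str) -> pd.DataFrame:
    """Read a headerless TSV as strings; raise FormatError on empty input or
    rows with the wrong field count (naming the first offending line)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            dtype=str,
            compression="infer",
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{what}: empty file: {path}") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{what}: malformed input in {path}: {exc}") from None
    if df.shape[1] != len(names):
        bad = (df.notna().sum(axis=1) != len(names)).idxmax() + 1
        raise FormatError(
            f"{what}: expected {len(names)} tab-separated columns, got "
            f"{df.shape[1]} (first offending line {bad}) in {path}"
        )
    df.columns = names
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path, what: str) -> pd.DataFrame:
    """Convert columns to numbers; a non-numeric or missing cell is a
    malformed line, reported with its 1-based line number."""
    out = df.copy()
    bad = df[df.columns[0]].isna()
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad |= vals.isna()
        out[c] = vals
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(f"{what}: malformed line {line} in {path}")
    return out


def _finish_sites(
    df: pd.DataFrame,
    sample_id: str,
    min_coverage: int,
    dropped: int,
    path,
    what: str,
    low_confidence: bool = False,
    warnings: list[str] | None = None,
) -> SampleTable:
    """Apply the shared validity + coverage filters and build the table."""
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise FormatError(f"{what}: malformed line {line} (pos < 1) in {path}")
    if (df["count_m"] < 0).any() or (df["count_u"] < 0).any():
        neg = (df["count_m"] < 0) | (df["count_u"] < 0)
        line = int(df.index[neg][0]) + 1
        raise FormatError(f"{what}: malformed line {line} (negative count) in {path}")

    valid = df["context"].isin(CONTEXTS) & df["strand"].isin(["+", "-"])
    dropped += int((~valid).sum())
    df = df.loc[valid]

    total = df["count_m"] + df["count_u"]
    keep = total >= max(int(min_coverage), 1)  # zero-coverage rows never kept
    filtered = int((~keep).sum())
    df = df.loc[keep]

    df = df.astype({"pos": np.int64})
    return SampleTable.from_frame(
        sample_id,
        df.loc[:, SITE_COLUMNS],
        dropped_records=dropped,
        filtered_records=filtered,
        low_confidence=low_confidence,
        warnings=warnings,
    )


def _default_sample_id(path) -> str:
    name = Path(os.fspath(path)).name
    for suffix in (".gz", ".tsv", ".txt", ".cov", ".bedGraph", ".bedgraph", ".CGmap"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


# ---------------------------------------------------------------------------
# methylation-call readers
# ---------------------------------------------------------------------------


def read_cytosine_report(path, min_coverage: int = 0, sample_id: str | None = None) -> SampleTable:
    """Read a Bismark cytosine report (CX report).

    Parameters
    ----------
    path
        Tab-separated file (optionally gzipped) with columns
        chrom, pos, strand, count_m, count_u, context, trinucleotide.
    min_coverage
        Keep sites with ``count_m + count_u >= min_coverage``. Zero-coverage
        rows (the CX report lists every genomic cytosine) are always
        excluded.

    Returns
    -------
    SampleTable
        Retained sites sorted by (chrom, pos); records with contexts outside
        CG/CHG/CHH (e.g. CN, CHN) or unknown strand tokens are dropped and
        tallied in ``dropped_records``.
    """
    what = "cytosine report"
    names = ["chrom", "pos", "strand", "count_m", "count_u", "context", "trinucleotide"]
    df = _read_raw(path, names, what)
    df = _numeric(df, ["pos", "count_m", "count_u"], path, what)
    df["trinucleotide"] = df["trinucleotide"].fillna("NNN")
    return _finish_sites(
        df, sample_id or _default_sample_id(path), min_coverage, 0, path, what
    )


def read_cgmap(path, min_coverage: int = 0, sample_id: str | None = None) -> SampleTable:
    """Read a CGmap file (BS-Seeker / CGmapTools).

    Strand is derived from the nucleotide column (C on the Watson strand,
    G on the Crick strand); ``count_u = count_total - count_m``. Filtering
    matches :func:`read_cytosine_report`.
    """
    what = "CGmap"
    names = ["chrom", "nuc", "pos", "context", "dinucleotide", "level", "count_m", "count_total"]
    df = _read_raw(path, names, what)
    df = _numeric(df, ["pos", "count_m", "count_total"], path, what)
    over = df["count_m"] > df["count_total"]
    if over.any():
        line = int(np.flatnonzero(over.to_numpy())[0]) + 1
        raise FormatError(f"{what}: malformed line {line} (count_m > count_total) in {path}")
    df["strand"] = df["nuc"].map({"C": "+", "G": "-"}).fillna("?")
    df["count_u"] = df["count_total"] - df["count_m"]
    df["trinucleotide"] = "NNN"
    return _finish_sites(
        df, sample_id or _default_sample_id(path), min_coverage, 0, path, what
    )


def _read_context_companion(path) -> pd.DataFrame:
    """Read context/strand per position from a CX report or CGmap companion
    file (auto-detected by field count)."""
    with _open_text(path) as fh:
        first = fh.readline()
    n_fields = len(first.rstrip("\n").split("\t"))
    if n_fields == 7:
        comp = read_cytosine_report(path, min_coverage=0)
    elif n_fields == 8:
        comp = read_cgmap(path, min_coverage=0)
    else:
        raise FormatError(
            f"context companion {path}: cannot recognise format "
            f"({n_fields} columns; expected 7 for CX report or 8 for CGmap)"
        )
    return comp.sites[["chrom", "pos", "strand", "context", "trinucleotide"]]


def read_coverage_or_bedgraph(
    path,
    dialect: str,
    context_source=None,
    min_coverage: int = 0,
    sample_id: str | None = None,
) -> SampleTable:
    """Read a Bismark coverage file or a bedGraph methylation track.

    Parameters
    ----------
    dialect
        ``"coverage"`` — columns chrom, start, end, percent, count_m,
        count_u with 1-based start == end.
        ``"bedgraph"`` — columns chrom, start, end, percent, 0-based
        half-open. bedGraph stores density only: sites get fractional
        density-preserving unit counts (count_m = percent/100 out of a unit
        total) and the sample is flagged ``low_confidence``.
    context_source
        Optional CX-report or CGmap path giving per-position context and
        strand. Without it every site is labelled CG with a recorded
        warning; sites absent from a provided companion are dropped and
        tallied.
    """
    if dialect not in ("coverage", "bedgraph"):
        raise ValueError(f"dialect must be 'coverage' or 'bedgraph', got {dialect!r}")
    what = dialect
    if dialect == "coverage":
        names = ["chrom", "start", "end", "percent", "count_m", "count_u"]
        df = _read_raw(path, names, what)
        df = _numeric(df, ["start", "end", "percent", "count_m", "count_u"], path, what)
        df["pos"] = df["start"].astype(np.int64)  # 1-based, start == end
    else:
        names = ["chrom", "start", "end", "percent"]
        df = _read_raw(path, names, what)
        df = _numeric(df, ["start", "end", "percent"], path, what)
        df["pos"] = df["start"].astype(np.int64) + 1  # 0-based half-open -> 1-based

    out_of_range = (df["percent"] < 0) | (df["percent"] > 100)
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range.to_numpy())[0]) + 1
        raise FormatError(f"{what}: malformed line {line} (percent outside [0,100]) in {path}")

    if dialect == "bedgraph":
        density = df["percent"] / 100.0
        df["count_m"] = density
        df["count_u"] = 1.0 - density

    dropped = 0
    warnings: list[str] = []
    low_confidence = dialect == "bedgraph"
    if context_source is not None:
        comp = _read_context_companion(context_source)
        df = df.merge(comp, on=["chrom", "pos"], how="left")
        unmatched = df["context"].isna()
        dropped += int(unmatched.sum())
        if dropped:
            warnings.append(
                f"{dropped} sites absent from context companion {context_source}; dropped"
            )
        df = df.loc[~unmatched]
    else:
        warnings.append(
            f"{what} carries no sequence context; all sites labelled CG "
            "(provide context_source for multi-context analysis)"
        )
        df["context"] = "CG"
        df["strand"] = "+"
        df["trinucleotide"] = "NNN"

    return _finish_sites(
        df,
        sample_id or _default_sample_id(path),
        min_coverage,
        dropped,
        path,
        what,
        low_confidence=low_confidence,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------


def _parse_attribute(attrs: pd.Series, key: str, gtf: bool) -> pd.Series:
    if gtf:
        # gene_id "g1"; transcript_id "t1";
        pat = rf'{key}\s+"([^"]*)"'
    else:
        # ID=g1;Name=foo
        pat = rf"(?:^|;)\s*{key}=([^;]*)"
    return attrs.str.extract(pat, expand=False)


def _dedupe_ids(ids: pd.Series) -> pd.Series:
    """Suffix duplicate feature IDs deterministically (_2, _3, ... in file
    order) so every ID is unique within one annotation set."""
    counts = ids.groupby(ids).cumcount()
    dup = counts > 0
    if dup.any():
        ids = ids.where(~dup, ids + "_" + (counts + 1).astype(str))
    return ids


def read_annotation(
    path,
    dialect: str,
    feature_type_filter: str | None = None,
    id_attribute: str | None = None,
) -> pd.DataFrame:
    """Read genomic features from GFF3, GTF, BED or the TSV dialect.

    Returns a DataFrame with columns chrom, start, end, strand, feature_id,
    feature_type — coordinates normalised to 0-based half-open. Features
    that are empty after normalisation (start >= end) are dropped and
    tallied in ``df.attrs["dropped_features"]``.

    Parameters
    ----------
    dialect
        One of ``gff3``, ``gtf``, ``bed``, ``tsv``. GFF3/GTF and the TSV
        dialect are 1-based inclusive; BED is already 0-based half-open.
    feature_type_filter
        For GFF3/GTF: keep only rows whose third column equals this value
        (e.g. ``"gene"``).
    id_attribute
        Attribute carrying the feature ID; defaults to ``ID`` for GFF3 and
        ``gene_id`` for GTF. Ignored for BED (column 4) and TSV (column
        ``id``). Missing IDs are synthesised as ``chrom:start-end``.
    """
    if dialect not in ("gff3", "gtf", "bed", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    if dialect in ("gff3", "gtf"):
        names = ["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"]
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#", dtype=str, names=names,
                compression="infer",
            )
        except pd.errors.EmptyDataError:
            raise FormatError(f"annotation: empty file: {path}") from None
        df = df.dropna(subset=["chrom", "start", "end"])
        if feature_type_filter is not None:
            df = df[df["type"] == feature_type_filter]
        attr_key = id_attribute or ("ID" if dialect == "gff3" else "gene_id")
        ids = _parse_attribute(df["attributes"].fillna(""), attr_key, gtf=dialect == "gtf")
        start = pd.to_numeric(df["start"]).astype(np.int64) - 1
        end = pd.to_numeric(df["end"]).astype(np.int64)
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(),
                "start": start.to_numpy(),
                "end": end.to_numpy(),
                "strand": df["strand"].fillna(".").to_numpy(),
                "feature_id": ids.to_numpy(),
                "feature_type": df["type"].fillna(".").to_numpy(),
            }
        )
    elif dialect == "bed":
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, comment="#", dtype=str, compression="infer"
            )
        except pd.errors.EmptyDataError:
            raise FormatError(f"annotation: empty file: {path}") from None
        if df.shape[1] < 3:
            raise FormatError(f"BED: need at least 3 columns in {path}")
        out = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0].to_numpy(),
                "start": pd.to_numeric(df.iloc[:, 1]).astype(np.int64).to_numpy(),
                "end": pd.to_numeric(df.iloc[:, 2]).astype(np.int64).to_numpy(),
                "strand": (
                    df.iloc[:, 5].fillna(".").to_numpy() if df.shape[1] >= 6
                    else np.full(len(df), ".")
                ),
                "feature_id": (
                    df.iloc[:, 3].to_numpy() if df.shape[1] >= 4 else np.full(len(df), None)
                ),
                "feature_type": np.full(len(df), "region"),
            }
        )
    else:  # tsv dialect: header id, chrom, start, end, strand; 1-based inclusive
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
        except pd.errors.EmptyDataError:
            raise FormatError(f"annotation: empty file: {path}") from None
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"id", "chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"TSV annotation {path}: header must contain {sorted(required)}"
            )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(),
                "start": (pd.to_numeric(df["start"]).astype(np.int64) - 1).to_numpy(),
                "end": pd.to_numeric(df["end"]).astype(np.int64).to_numpy(),
                "strand": (
                    df["strand"].fillna(".").to_numpy()
                    if "strand" in df.columns
                    else np.full(len(df), ".")
                ),
                "feature_id": df["id"].to_numpy(),
                "feature_type": np.full(len(df), "region"),
            }
        )

    # shared normalisation
    empty = out["start"] >= out["end"]
    dropped = int(empty.sum())
    out = out.loc[~empty].reset_index(drop=True)
    missing = out["feature_id"].isna() | (out["feature_id"] == "")
    if missing.any():
        synth = out["chrom"].astype(str) + ":" + out["start"].astype(str) + "-" + out["end"].astype(str)
        out.loc[missing, "feature_id"] = synth[missing]
    out["feature_id"] = _dedupe_ids(out["feature_id"].astype(str))
    bad_strand = ~out["strand"].isin(["+", "-", "."])
    if bad_strand.any():
        out.loc[bad_strand, "strand"] = "."
    out = out.loc[:, FEATURE_COLUMNS]
    out.attrs["dropped_features"] = dropped
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_tsv(table, path) -> None:
    """Write a tabular result as UTF-8 TSV with a header row.

    Accepts a DataFrame or any object with a ``to_frame()`` method
    (BinnedDensityMatrix, MetageneProfile, RankedHeatmap, ...). Floats are
    written with 6 significant digits; NaN cells as ``NA``. Writing the
    read-back of a file reproduces it byte for byte.
    """
    if hasattr(table, "to_frame") and not isinstance(table, pd.DataFrame):
        table = table.to_frame()
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot serialise {type(table).__name__} as TSV")
    if table.empty:
        raise ValueError("refusing to write an empty table")
    buf = _io.StringIO()
    table.to_csv(buf, sep="\t", index=False, float_format="%.6g", na_rep="NA",
                 lineterminator="\n")
    data = buf.getvalue().encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(data)


def read_tsv(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tsv` (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
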