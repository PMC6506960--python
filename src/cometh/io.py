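"""Reading and writing per-CpG methylation tables and derived products.

The native table layout is tab-separated with columns chromosome, 1-based
position, sequencing coverage and MC ratio; annotated tables append the
methylation state and the forward distance to the next CpG.  A second
dialect accepts Bismark-style coverage files (chrom, start, end,
%methylation, methylated count, unmethylated count), from which coverage
and MC ratio are reconstructed from the read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UsageError, ValidationError
from .track import MethylationTrack

logger = logging.getLogger(__name__)

ANNOTATED_HEADER = ["chrom", "position", "coverage", "mc_ratio", "state", "distance"]


@dataclass(frozen=True)
class Dialect:
    """How an input methylation table is laid out.

    name
        ``"native"`` (chrom, position, coverage, mc_ratio) or
        ``"bismark-cov"`` (chrom, start, end, %meth, count_M, count_U).
    delimiter
        Field separator, tab by default.
    header
        Whether the first line is a header row.
    na_literal
        Literal marking a missing MC ratio (and missing distances on output).
    """

    name: str = "native"
    delimiter: str = "\t"
    header: bool = True
    na_literal: str = "NA"


NATIVE = Dialect()
BISMARK_COV = Dialect(name="bismark-cov", header=False)

DIALECTS = {"native": NATIVE, "bismark-cov": BISMARK_COV}


def _parse_column(raw: pd.Series, name: str, kind: str, na_literal: str,
                  offset: int) -> np.ndarray:
    """Convert a string column, raising ParseError naming the 1-based line."""
    s = raw.astype(str).str.strip()
    is_na = s.eq(na_literal) | s.eq("") | s.eq("nan")
    vals = pd.to_numeric(s.mask(is_na), errors="coerce")
    bad = vals.isna() & ~is_na
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + offset
        raise ParseError(
            f"line {line}: cannot parse {name} value {s[bad].iloc[0]!r}"
        )
    if kind == "int":
        if is_na.any():
            line = int(np.argmax(is_na.to_numpy())) + offset
            raise ParseError(f"line {line}: missing {name} value")
        frac = vals.to_numpy(dtype=float)
        if (frac != np.round(frac)).any():
            line = int(np.argmax(frac != np.round(frac))) + offset
            raise ParseError(f"line {line}: {name} is not an integer")
        return vals.to_numpy(dtype=np.int64)
    # numpy's parser is correctly rounded (pandas' fast path is not), which
    # makes written ratios round-trip bit-exactly
    return np.asarray(s.mask(is_na, "nan"), dtype=float)


def read_methylation_table(
    path: str | Path,
    dialect: Dialect = NATIVE,
    sample_id: str | None = None,
) -> MethylationTrack:
    """Read one sample's per-CpG table into a :class:`MethylationTrack`.

    Input sorted by position is preserved as-is; unsorted input is sorted
    with a warning; duplicate positions are a hard error.  Reverse-strand
    records (a ``strand`` column containing ``-``) are dropped with a
    logged count — the analysis models the forward strand only.  Records
    from more than one chromosome are rejected: a track is one chromosome.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        raw = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.header else None,
            dtype=str,
            comment=None,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    offset = 2 if dialect.header else 1  # 1-based line number of first data row

    if dialect.name == "bismark-cov":
        df, chrom = _from_bismark(raw, dialect, offset, path)
    else:
        df, chrom = _from_native(raw, dialect, offset, path)

    # drop reverse-strand records if a strand column is present
    if "strand" in df.columns:
        rev = df["strand"].astype(str).str.strip().eq("-")
        if rev.any():
            logger.warning(
                "%s: dropped %d reverse-strand records", path, int(rev.sum())
            )
            df = df.loc[~rev]
        df = df.drop(columns=["strand"])

    if len(df) and not df["position"].is_monotonic_increasing:
        logger.warning("%s: positions not sorted; sorting by position", path)
        df = df.sort_values("position", kind="mergesort")
    if df["position"].duplicated().any():
        dup = int(df["position"][df["position"].duplicated()].iloc[0])
        raise ValidationError(f"{path}: duplicate position {dup}")
    df = df.reset_index(drop=True)

    ratio = df["mc_ratio"].to_numpy(dtype=float)
    present = ~np.isnan(ratio)
    if ((ratio[present] < 0) | (ratio[present] > 1)).any():
        bad = np.flatnonzero(present & ((ratio < 0) | (ratio > 1)))[0]
        raise ValidationError(
            f"{path}: mc_ratio {ratio[bad]} outside [0, 1] at position "
            f"{int(df['position'].iloc[bad])}"
        )
    return MethylationTrack(sample_id, chrom, df)


def _resolve_native_columns(raw: pd.DataFrame, header: bool) -> pd.DataFrame:
    aliases = {
        "chrom": "chrom", "chr": "chrom", "chromosome": "chrom",
        "position": "position", "pos": "position",
        "coverage": "coverage", "sequence coverage": "coverage",
        "sequence_coverage": "coverage",
        "mc_ratio": "mc_ratio", "mc ratio": "mc_ratio", "ratio": "mc_ratio",
        "strand": "strand",
    }
    if header:
        cols = {}
        for c in raw.columns:
            key = aliases.get(str(c).strip().lower())
            if key and key not in cols:
                cols[key] = c
        needed = ["chrom", "position", "coverage", "mc_ratio"]
        missing = [c for c in needed if c not in cols]
        if missing:
            raise ParseError(f"cannot resolve columns {missing} in header {list(raw.columns)}")
        keep = needed + (["strand"] if "strand" in cols else [])
        out = raw[[cols[c] for c in keep]].copy()
        out.columns = keep
        return out
    if raw.shape[1] < 4:
        raise ParseError(
            f"native dialect needs at least 4 columns, found {raw.shape[1]}"
        )
    out = raw.iloc[:, :4].copy()
    out.columns = ["chrom", "position", "coverage", "mc_ratio"]
    return out


def _single_chrom(chroms: pd.Series, path: Path) -> str:
    uniq = chroms.astype(str).str.strip().unique()
    if len(uniq) > 1:
        raise ValidationError(
            f"{path}: records span {len(uniq)} chromosomes ({uniq[:3]}...); "
            "a track holds a single chromosome"
        )
    return str(uniq[0]) if len(uniq) else ""


def _from_native(raw, dialect, offset, path):
    if raw.empty:
        empty = pd.DataFrame({"position": np.array([], dtype=np.int64),
                              "coverage": np.array([], dtype=np.int64),
                              "mc_ratio": np.array([], dtype=float)})
        return empty, ""
    sel = _resolve_native_columns(raw, dialect.header)
    chrom = _single_chrom(sel["chrom"], path)
    df = pd.DataFrame({
        "position": _parse_column(sel["position"], "position", "int",
                                  dialect.na_literal, offset),
        "coverage": _parse_column(sel["coverage"], "coverage", "int",
                                  dialect.na_literal, offset),
        "mc_ratio": _parse_column(sel["mc_ratio"], "mc_ratio", "float",
                                  dialect.na_literal, offset),
    })
    if "strand" in sel.columns:
        df["strand"] = sel["strand"].to_numpy()
    return df, chrom


def _from_bismark(raw, dialect, offset, path):
    if raw.empty:
        empty = pd.DataFrame({"position": np.array([], dtype=np.int64),
                              "coverage": np.array([], dtype=np.int64),
                              "mc_ratio": np.array([], dtype=float)})
        return empty, ""
    if raw.shape[1] < 6:
        raise ParseError(
            f"bismark-cov dialect needs 6 columns, found {raw.shape[1]}"
        )
    sel = raw.iloc[:, :6].copy()
    sel.columns = ["chrom", "start", "end", "pct", "count_m", "count_u"]
    chrom = _single_chrom(sel["chrom"], path)
    count_m = _parse_column(sel["count_m"], "methylated count", "int",
                            dialect.na_literal, offset)
    count_u = _parse_column(sel["count_u"], "unmethylated count", "int",
                            dialect.na_literal, offset)
    cov = count_m + count_u
    with np.errstate(invalid="ignore"):
        ratio = np.where(cov > 0, count_m / np.maximum(cov, 1), np.nan)
    df = pd.DataFrame({
        "position": _parse_column(sel["start"], "position", "int",
                                  dialect.na_literal, offset),
        "coverage": cov,
        "mc_ratio": ratio,
    })
    return df, chrom


# ----------------------------------------------------------------------
def _format_ratio(x: float, na_literal: str) -> str:
    if np.isnan(x):
        return na_literal
    return np.format_float_positional(x, trim="-")


def write_annotated_table(
    track: MethylationTrack,
    path: str | Path,
    na_literal: str = "NA",
) -> None:
    """Write an annotated track as a six-column TSV.

    Columns: chrom, position, coverage, mc_ratio, state, distance.  The
    last site's distance (and any missing ratio) is written as the NA
    literal.  Integer fields round-trip as exact text; ratios round-trip
    in value (shortest unique decimal representation).
    """
    track.require_annotated("write_annotated_table")
    df = track.df
    lines = ["\t".join(ANNOTATED_HEADER)]
    dist = df["distance"].to_numpy(dtype=float)
    ratio = df["mc_ratio"].to_numpy(dtype=float)
    for i in range(len(df)):
        d = na_literal if np.isnan(dist[i]) else str(int(dist[i]))
        lines.append(
            f"{track.chrom}\t{int(df['position'].iloc[i])}\t"
            f"{int(df['coverage'].iloc[i])}\t{_format_ratio(ratio[i], na_literal)}\t"
            f"{df['state'].iloc[i]}\t{d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_smr_bed(smrset, path: str | Path) -> None:
    """Write an SMR set as BED6.

    Native coordinates are 1-based inclusive; BED is 0-based half-open, so
    start = first_position - 1 and end = last_position + 1, which covers
    the G of the final CpG.  Name = state, score = CG count, strand = "+".
    """
    lines = []
    for row in smrset.df.itertuples(index=False):
        lines.append(
            f"{smrset.chrom}\t{row.first_position - 1}\t{row.last_position + 1}\t"
            f"{row.state}\t{row.cg_count}\t+"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
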