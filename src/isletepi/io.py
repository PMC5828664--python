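"""Shared readers/writers and a small vectorised interval engine.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based external table must be converted at the boundary.
Chromosome names are passed through verbatim — no "chr" normalisation is
attempted, and mismatches surface as empty overlaps or explicit errors
rather than silently dropped intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a DataFrame with 0-based half-open intervals.

    Optional 4th/5th columns are preserved as ``name`` and ``score``.
    Intervals are sorted by (chrom, start, end) on read. Lines where
    ``end <= start`` raise :class:`FormatError` naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start ({start}, {end})")
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) > 3:
                row["name"] = fields[3]
            if len(fields) > 4:
                try:
                    row["score"] = float(fields[4])
                except ValueError:
                    row["score"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows, columns=BED_COLUMNS + [c for c in ("name", "score") if rows and c in rows[0]])
    if df.empty:
        df = pd.DataFrame(columns=BED_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write intervals (plus any extra columns) as a tab-separated BED file."""
    cols = BED_COLUMNS + [c for c in df.columns if c not in BED_COLUMNS]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a headered TSV table (the package's interchange format)."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Interval engine (numpy, per-chromosome searchsorted)
# ---------------------------------------------------------------------------

def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    if df.empty:
        return df[BED_COLUMNS].copy()
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def _per_chrom_arrays(intervals: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals)
    return {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in merged.groupby("chrom", sort=False)
    }


def intervals_overlap_mask(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Boolean mask over query rows: overlaps any target interval by >=1 bp."""
    lut = _per_chrom_arrays(target)
    mask = np.zeros(len(query), dtype=bool)
    for chrom, grp in query.groupby("chrom", sort=False):
        if chrom not in lut:
            continue
        t_start, t_end = lut[chrom]
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # first merged target whose end is > query start
        j = np.searchsorted(t_end, s, side="right")
        hit = (j < len(t_start)) & (t_start[np.minimum(j, len(t_start) - 1)] < e)
        mask[grp.index.to_numpy()] = hit
    return mask


def points_in_intervals(chroms, positions, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: point (chrom, pos) lies inside an interval [start, end)."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    lut = _per_chrom_arrays(intervals)
    mask = np.zeros(len(positions), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in lut:
            continue
        t_start, t_end = lut[chrom]
        sel = chroms == chrom
        pos = positions[sel]
        j = np.searchsorted(t_start, pos, side="right") - 1
        ok = (j >= 0) & (pos < t_end[np.maximum(j, 0)])
        mask[sel] = ok
    return mask


def assign_interval_labels(chroms, positions, intervals: pd.DataFrame,
                           label_col: str = "name", default: str = "Other") -> np.ndarray:
    """Label each point with the ``label_col`` of the interval containing it.

    Intervals are assumed non-overlapping (e.g. a chromatin-state tiling);
    if a point falls in no interval it gets ``default``.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    labels = np.full(len(positions), default, dtype=object)
    srt = intervals.sort_values(["chrom", "start"])
    for chrom, grp in srt.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        t_start = grp["start"].to_numpy()
        t_end = grp["end"].to_numpy()
        names = grp[label_col].to_numpy()
        pos = positions[sel]
        j = np.searchsorted(t_start, pos, side="right") - 1
        ok = (j >= 0) & (pos < t_end[np.maximum(j, 0)])
        lab = labels[sel]
        lab[ok] = names[j[ok]]
        labels[sel] = lab
    return labels
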