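"""Core genomic-interval data model and BED-family I/O.

Coordinates are 0-based half-open throughout (BED convention). "Overlap"
always means at least one shared base pair; abutting half-open intervals do
not overlap. Interval collections are kept sorted by (chrom, start) and are
backed by a pandas DataFrame so that the sweep-style overlap operations can
stay vectorised.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

_BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed or fails validation."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return interval_center(self)


def interval_center(a: GenomicInterval) -> int:
    """Midpoint floor((start + end) / 2); always inside [start, end)."""
    return (a.start + a.end) // 2


def any_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class Genome:
    """Ordered chromosome-name -> length (bp) map."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if int(length) <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._sizes: dict[str, int] = {name: int(length) for name, length in items}

    @classmethod
    def from_file(cls, path: str | Path) -> "Genome":
        """Read a two-column chrom-sizes TSV (name, length)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={0: str})
        return cls(zip(df["chrom"], df["length"].astype(int)))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes


class IntervalSet:
    """A labelled, sorted collection of genomic intervals.

    Backed by a DataFrame with columns chrom/start/end/id/score/strand;
    extra columns (e.g. binding-site metadata) are carried through sorting
    and I/O untouched.
    """

    def __init__(self, label: str, df: pd.DataFrame | None = None):
        if not label:
            raise ValueError("label must be non-empty")
        self.label = label
        if df is None:
            df = pd.DataFrame(columns=_BED_COLUMNS)
        df = df.copy()
        for col, default in (("id", None), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        front = [c for c in _BED_COLUMNS if c in df.columns]
        rest = [c for c in df.columns if c not in front]
        df = df[front + rest]
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
                raise ValueError(
                    f"invalid interval at input row {bad}: require 0 <= start < end"
                )
            if not df["strand"].isin(STRANDS).all():
                raise ValueError("invalid strand value")
            df = df.sort_values(["chrom", "start", "end"], kind="stable")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_intervals(cls, label: str, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "id": iv.id, "score": np.nan if iv.score is None else iv.score,
             "strand": iv.strand}
            for iv in intervals
        ]
        return cls(label, pd.DataFrame(rows, columns=_BED_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            score = getattr(row, "score", np.nan)
            yield GenomicInterval(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                strand=row.strand if row.strand in STRANDS else ".",
                score=None if pd.isna(score) else float(score),
                id=None if row.id is None or (isinstance(row.id, float) and np.isnan(row.id)) else str(row.id),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.df[_BED_COLUMNS], other.df[_BED_COLUMNS]
        return self.label == other.label and a.equals(b)

    def by_chrom(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.df.groupby("chrom", sort=True)

    @property
    def has_scores(self) -> bool:
        return len(self.df) > 0 and self.df["score"].notna().any()

    @property
    def has_strands(self) -> bool:
        return len(self.df) > 0 and (self.df["strand"] != ".").any()

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def centers(self) -> pd.DataFrame:
        """(chrom, center) per interval, in set order."""
        out = self.df[["chrom"]].copy()
        out["center"] = (self.df["start"] + self.df["end"]) // 2
        return out


def _format_score(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_bed(path: str | Path | io.TextIOBase, label: str | None = None) -> IntervalSet:
    """Read a 3-6 column BED file into a sorted IntervalSet.

    Score (column 5) and strand (column 6) are parsed when present. Raises
    :class:`BedParseError` naming the offending line on malformed input.
    """
    if label is None:
        label = Path(path).stem if not isinstance(path, io.TextIOBase) else "bed"
    fh = path if isinstance(path, io.TextIOBase) else open(path)
    rows = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid coordinates start={start} end={end}"
                )
            row = {"chrom": fields[0], "start": start, "end": end,
                   "id": None, "score": np.nan, "strand": "."}
            if len(fields) >= 4 and fields[3] != ".":
                row["id"] = fields[3]
            if len(fields) >= 5 and fields[4] != ".":
                try:
                    row["score"] = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}: line {lineno}: non-numeric score") from exc
            if len(fields) >= 6:
                if fields[5] not in STRANDS:
                    raise BedParseError(f"{path}: line {lineno}: invalid strand {fields[5]!r}")
                row["strand"] = fields[5]
            rows.append(row)
    finally:
        if fh is not path:
            fh.close()
    return IntervalSet(label, pd.DataFrame(rows, columns=_BED_COLUMNS))


def write_bed(iv_set: IntervalSet, path: str | Path) -> None:
    """Write BED3/BED5/BED6 depending on which optional fields are present.

    Round-trips exactly through :func:`read_bed`.
    """
    n_cols = 3
    if iv_set.has_scores or iv_set.df["id"].notna().any():
        n_cols = 5
    if iv_set.has_strands:
        n_cols = 6
    with open(path, "w") as fh:
        for row in iv_set.df.itertuples(index=False):
            fields = [row.chrom, str(int(row.start)), str(int(row.end))]
            if n_cols >= 5:
                fields.append("." if row.id is None or pd.isna(row.id) else str(row.id))
                fields.append("." if pd.isna(row.score) else _format_score(row.score))
            if n_cols >= 6:
                fields.append(row.strand)
            fh.write("\t".join(fields) + "\n")


def merge_intervals(iv_set: IntervalSet, gap: int = 0) -> IntervalSet:
    """Fuse overlapping or within-`gap` intervals per chromosome.

    Output is sorted, pairwise disjoint and idempotent under re-merging.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(iv_set) == 0:
        return IntervalSet(iv_set.label)
    merged_rows = []
    for chrom, sub in iv_set.by_chrom():
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_start, cur_end = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_end + gap:
                cur_end = max(cur_end, e)
            else:
                merged_rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = s, e
        merged_rows.append((chrom, cur_start, cur_end))
    df = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    return IntervalSet(iv_set.label, df)


def overlap_membership(sites: IntervalSet, regions: IntervalSet) -> np.ndarray:
    """Boolean flag per site: does it overlap >=1 region by any-overlap?

    Runs in O((n + m) log m) via merged sorted regions + binary search, in
    site-set order.
    """
    flags = np.zeros(len(sites), dtype=bool)
    if len(sites) == 0 or len(regions) == 0:
        return flags
    merged = merge_intervals(regions, gap=0)
    by_chrom = {chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for chrom, sub in merged.by_chrom()}
    site_df = sites.df
    for chrom, sub in site_df.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        rs, re = by_chrom[chrom]
        a = sub["start"].to_numpy()
        b = sub["end"].to_numpy()
        # index of last region starting before the site end
        j = np.searchsorted(rs, b, side="left") - 1
        ok = j >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = re[j[ok]] > a[ok]
        flags[sub.index.to_numpy()] = hit
    return flags


def complement(iv_set: IntervalSet, genome: Genome, label: str | None = None) -> IntervalSet:
    """Genome-wide complement of the merged input intervals."""
    merged = merge_intervals(iv_set, gap=0)
    by_chrom = {chrom: sub for chrom, sub in merged.by_chrom()}
    rows = []
    for chrom, length in genome.items():
        pos = 0
        if chrom in by_chrom:
            for row in by_chrom[chrom].itertuples(index=False):
                if row.start > pos:
                    rows.append((chrom, pos, min(row.start, length)))
                pos = max(pos, row.end)
        if pos < length:
            rows.append((chrom, pos, length))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(label or f"not_{iv_set.label}", df)
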