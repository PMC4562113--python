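"""Partition a binding-site catalog by in-vivo evidence.

A site is a candidate in-vivo hotspot when it overlaps an H3K4me3 peak (from
the reference strain) or a DSB (DMC1) peak. Candidates whose H3K4me3 signal
is shared by both strains with no DMC1 peak are promoter-like and classified
ambiguous; the remaining candidates are in_vivo and everything else is
in_vitro_only. Overlap means >=1 shared bp throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_membership

IN_VIVO = "in_vivo"
IN_VITRO_ONLY = "in_vitro_only"
AMBIGUOUS = "ambiguous"
STATUSES = (IN_VIVO, IN_VITRO_ONLY, AMBIGUOUS)


@dataclass(frozen=True)
class BindingSite:
    """One in-vitro binding site: interval + oriented motif + affinity (ppm)."""
    chrom: str
    start: int
    end: int
    affinity_ppm: float
    motif_start: int
    motif_strand: str

    def __post_init__(self):
        if self.affinity_ppm < 0:
            raise ValueError("affinity_ppm must be >= 0")
        if self.motif_strand not in ("+", "-"):
            raise ValueError("motif_strand must be + or -")
        if not self.start <= self.motif_start < self.end:
            raise ValueError("motif must start inside the site interval")


@dataclass
class ClassifiedSites:
    """Per-site status plus the count summary; the partition is exhaustive."""
    sites: pd.DataFrame          # site columns + "status"
    n_total: int
    n_overlapping: int
    n_ambiguous: int
    n_in_vivo: int
    n_in_vitro_only: int

    def __post_init__(self):
        assert self.n_in_vivo + self.n_ambiguous == self.n_overlapping
        assert self.n_in_vivo + self.n_in_vitro_only + self.n_ambiguous == self.n_total

    @property
    def status(self) -> pd.Series:
        return self.sites["status"]

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_overlapping": self.n_overlapping,
            "n_ambiguous": self.n_ambiguous,
            "n_in_vivo": self.n_in_vivo,
            "n_in_vitro_only": self.n_in_vitro_only,
        }


def _check_sorted(iv_set: IntervalSet, name: str) -> None:
    df = iv_set.df
    if len(df) and not df.groupby("chrom", sort=False)["start"].apply(
            lambda s: s.is_monotonic_increasing).all():
        raise ValueError(f"{name} is not sorted by (chrom, start)")


def classify_sites(sites: IntervalSet, h3k4me3_a: IntervalSet,
                   h3k4me3_b: IntervalSet, dmc1: IntervalSet) -> ClassifiedSites:
    """Assign in_vivo / in_vitro_only / ambiguous status to every site.

    `h3k4me3_a` is the reference-strain H3K4me3 peak set that (with DMC1)
    defines candidacy; `h3k4me3_b` is the second strain used only for the
    ambiguity rule.
    """
    for iv_set, name in ((sites, "sites"), (h3k4me3_a, "h3k4me3_a"),
                         (h3k4me3_b, "h3k4me3_b"), (dmc1, "dmc1")):
        _check_sorted(iv_set, name)
    in_a = overlap_membership(sites, h3k4me3_a)
    in_b = overlap_membership(sites, h3k4me3_b)
    in_dmc1 = overlap_membership(sites, dmc1)

    candidate = in_a | in_dmc1
    ambiguous = candidate & in_a & in_b & ~in_dmc1
    status = np.where(~candidate, IN_VITRO_ONLY, np.where(ambiguous, AMBIGUOUS, IN_VIVO))

    df = sites.df.copy()
    df["status"] = status
    return ClassifiedSites(
        sites=df,
        n_total=len(df),
        n_overlapping=int(candidate.sum()),
        n_ambiguous=int(ambiguous.sum()),
        n_in_vivo=int((status == IN_VIVO).sum()),
        n_in_vitro_only=int((status == IN_VITRO_ONLY).sum()),
    )


@dataclass
class ChipMatch:
    """Summary of matching ChIP peaks against the site catalog."""
    n_peaks: int
    n_matched: int
    percent_matched: int
    center_offsets: np.ndarray   # signed peak-center - site-center, matched pairs


def percent_of(numerator: int, denominator: int) -> int:
    """Rounded integer percentage; errors on a zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return int(round(100.0 * numerator / denominator))


def match_chip_peaks(chip_peaks: IntervalSet, sites: IntervalSet) -> ChipMatch:
    """Count ChIP peaks overlapping >=1 site; report the match percentage and
    the signed center offset to the nearest-center overlapping site."""
    _check_sorted(chip_peaks, "chip_peaks")
    _check_sorted(sites, "sites")
    if len(chip_peaks) == 0:
        raise ZeroDivisionError("percentage undefined: no ChIP peaks")
    matched = overlap_membership(chip_peaks, sites)

    site_by_chrom = {
        chrom: ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2,
                sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in sites.df.groupby("chrom", sort=False)
    }
    offsets = []
    for row, hit in zip(chip_peaks.df.itertuples(index=False), matched):
        if not hit:
            continue
        centers, starts, ends = site_by_chrom[row.chrom]
        peak_center = (row.start + row.end) // 2
        overlapping = (starts < row.end) & (ends > row.start)
        diffs = peak_center - centers[overlapping]
        offsets.append(diffs[np.argmin(np.abs(diffs))])
    return ChipMatch(
        n_peaks=len(chip_peaks),
        n_matched=int(matched.sum()),
        percent_matched=percent_of(int(matched.sum()), len(chip_peaks)),
        center_offsets=np.array(offsets, dtype=np.int64),
    )


def write_classification(classified: ClassifiedSites, tsv_path, json_path=None) -> None:
    """Per-site TSV (id, status, affinity) plus optional JSON count summary."""
    cols = [c for c in ("id", "chrom", "start", "end", "status", "score") if c in classified.sites]
    out = classified.sites[cols].rename(columns={"score": "affinity_ppm"})
    out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        import json
        with open(json_path, "w") as fh:
            json.dump(classified.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
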