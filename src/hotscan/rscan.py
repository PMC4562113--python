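"""r-scan detection of hotspot-deficient genomic regions.

The r-scan statistic R_i^(r) is the base-pair span covering r consecutive
inter-event distances, R_i^(r) = sum_{j=i..i+r-1} U_j = pos_{i+r} - pos_i
(Karlin-Macken). Unusually long spans indicate dispersion (event-depleted
regions); unusually short ones indicate clustering. Significance is assessed
empirically against replicate position sets drawn either from a background
catalog (without replacement) or uniformly along each chromosome, preserving
the per-chromosome event counts so chromosome ends are accounted for. The
top k_max ranked spans per scan order r are tested, p-values carry the
+1/(n+1) permutation correction, and Benjamini-Hochberg FDR is applied
across the tested family (jointly over all (r, k) by default).

Significant spans are merged into clusters; each cluster is then localized
to the union of its spans of the smallest significant order r*, because
higher-order spans that merely contain an extreme low-order gap add no
independent localization (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import Genome, IntervalSet, merge_intervals, overlap_membership

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RscanConfig:
    r_max: int = 24
    k_max: int = 10
    n_null: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    null_source: str = "background_set"     # or "uniform"
    bh_scope: str = "joint"                 # or "per_r"
    direction: str = "dispersion"           # or "clustering"

    def __post_init__(self):
        if self.r_max < 1 or self.k_max < 1:
            raise ValueError("r_max and k_max must be >= 1")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.null_source not in ("background_set", "uniform"):
            raise ValueError(f"unknown null_source {self.null_source!r}")
        if self.bh_scope not in ("joint", "per_r"):
            raise ValueError(f"unknown bh_scope {self.bh_scope!r}")
        if self.direction not in ("dispersion", "clustering"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class RscanResult:
    """Tested extreme spans with p-values plus merged deficient regions."""
    spans: pd.DataFrame            # r, k, chrom, start, end, length, p_raw, p_adj, significant
    regions: IntervalSet           # merged deficient regions (disjoint)
    config: RscanConfig
    null_extremes: np.ndarray | None = None   # (n_null, r_max, k_max)
    n_removed_gap_overlap: int = 0


def positions_from_intervals(iv_set: IntervalSet) -> dict:
    """Per-chromosome sorted interval-center positions."""
    return {chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
            for chrom, sub in iv_set.df.groupby("chrom", sort=True)}


def interhotspot_distances(positions: np.ndarray) -> np.ndarray:
    """Adjacent distances U_1..U_{n-1} of one chromosome's positions."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    return np.diff(pos)


def rscan_lengths(U: np.ndarray, r: int) -> np.ndarray:
    """Sums of r consecutive inter-event distances; len(U) - r + 1 values."""
    if r < 1:
        raise ValueError("r must be >= 1")
    U = np.asarray(U)
    if r > len(U):
        return np.empty(0, dtype=U.dtype)
    c = np.concatenate([[0], np.cumsum(U)])
    return c[r:] - c[:-r]


def extreme_spans(positions_by_chrom: dict, r: int, k_max: int,
                  direction: str = "dispersion") -> pd.DataFrame:
    """The k_max most extreme r-scan spans pooled over all chromosomes.

    Dispersion ranks descending (longest first), clustering ascending; ties
    are broken by (chrom, start). Returns all spans ranked if fewer than
    k_max exist.
    """
    rows = []
    for chrom in sorted(positions_by_chrom):
        pos = np.sort(np.asarray(positions_by_chrom[chrom], dtype=np.int64))
        if len(pos) <= r:
            continue
        lengths = pos[r:] - pos[:-r]
        for i, length in enumerate(lengths):
            rows.append((chrom, int(pos[i]), int(pos[i + r]), int(length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])
    ascending = direction == "clustering"
    df = df.sort_values(["length", "chrom", "start"],
                        ascending=[ascending, True, True], kind="stable")
    df = df.head(k_max).reset_index(drop=True)
    df.insert(0, "r", r)
    df.insert(1, "k", np.arange(1, len(df) + 1))
    return df


def _draw_positions(n_reps: int, count: int, background: np.ndarray | None,
                    chrom_length: int | None, source: str,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_reps, count) sorted replicate position sets for one chromosome."""
    if source == "background_set":
        if background is None:
            raise ValueError("background_set null requires a background catalog")
        if count > len(background):
            raise ValueError("background smaller than test count on a chromosome")
        if count == len(background):
            return np.broadcast_to(np.sort(background), (n_reps, count)).copy()
        keys = rng.random((n_reps, len(background)))
        idx = np.argpartition(keys, count - 1, axis=1)[:, :count]
        return np.sort(np.asarray(background)[idx], axis=1)
    if chrom_length is None:
        raise ValueError("uniform null requires chromosome lengths")
    return np.sort(rng.integers(0, chrom_length, size=(n_reps, count)), axis=1)


def empirical_null(test_counts: dict, config: RscanConfig,
                   background_by_chrom: dict | None = None,
                   genome: Genome | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distributions of the extreme spans m_k^(r).

    Returns an array of shape (n_null, r_max, k_max) holding, per replicate,
    the k-th most extreme pooled r-scan span; NaN where a replicate yields
    fewer than k spans. Per-chromosome counts of the test set are preserved
    in every replicate. Deterministic given config.seed (or the supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = {c: int(n) for c, n in test_counts.items() if int(n) >= 2}
    total = sum(counts.values())
    out = np.full((config.n_null, config.r_max, config.k_max), np.nan)
    if total == 0:
        return out
    chunk = max(1, min(config.n_null, int(4_000_000 // max(total, 1)) + 1))
    descending = config.direction == "dispersion"
    done = 0
    while done < config.n_null:
        n_reps = min(chunk, config.n_null - done)
        mats = {}
        for chrom, count in counts.items():
            bg = None if background_by_chrom is None else np.asarray(background_by_chrom[chrom])
            length = None if genome is None else genome[chrom]
            mats[chrom] = _draw_positions(n_reps, count, bg, length,
                                          config.null_source, rng)
        for r in range(1, config.r_max + 1):
            parts = [P[:, r:] - P[:, :-r] for P in mats.values() if P.shape[1] > r]
            if not parts:
                continue
            spans = np.concatenate(parts, axis=1).astype(np.float64)
            spans.sort(axis=1)
            if descending:
                spans = spans[:, ::-1]
            k = min(config.k_max, spans.shape[1])
            out[done:done + n_reps, r - 1, :k] = spans[:, :k]
        done += n_reps
    return out


def _p_values(observed: pd.DataFrame, null: np.ndarray, config: RscanConfig) -> pd.DataFrame:
    """Empirical permutation p-values with the +1/(n+1) correction, BH-adjusted."""
    df = observed.copy()
    n_null = null.shape[0]
    p_raw = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        dist = null[:, row.r - 1, row.k - 1]
        if config.direction == "dispersion":
            hits = np.count_nonzero(dist >= row.length)
        else:
            hits = np.count_nonzero(dist <= row.length)
        p_raw[i] = (1.0 + hits) / (n_null + 1.0)
    df["p_raw"] = p_raw
    df["p_adj"] = np.nan
    if len(df):
        if config.bh_scope == "joint":
            df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        else:
            for r, idx in df.groupby("r").groups.items():
                df.loc[idx, "p_adj"] = multipletests(df.loc[idx, "p_raw"],
                                                     method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < config.alpha
    return df


def _localized_regions(spans: pd.DataFrame, label: str) -> IntervalSet:
    """Merge significant spans, then reduce each cluster to the union of its
    smallest-significant-order spans (tightest localization)."""
    sig = spans[spans["significant"]]
    if sig.empty:
        return IntervalSet(label)
    clusters = merge_intervals(IntervalSet("sig", sig[["chrom", "start", "end"]]), gap=0)
    sig_set = IntervalSet("sig", sig[["chrom", "start", "end", "r"]].assign(
        score=-np.log10(sig["p_adj"].clip(lower=1e-300))))
    rows = []
    for cluster in clusters:
        sub = sig_set.df
        inside = (sub["chrom"] == cluster.chrom) & (sub["start"] < cluster.end) & \
                 (sub["end"] > cluster.start)
        members = sig_set.df[inside]
        r_star = members["r"].min()
        core = members[members["r"] == r_star]
        merged_core = merge_intervals(IntervalSet("core", core[["chrom", "start", "end"]]), gap=0)
        best = float(members["score"].max())
        for region in merged_core:
            rows.append((region.chrom, region.start, region.end, best))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return IntervalSet(label, df)


def call_deficient_regions(test_positions: dict, config: RscanConfig,
                           background_by_chrom: dict | None = None,
                           genome: Genome | None = None,
                           gap_annotations: IntervalSet | None = None,
                           keep_null: bool = True) -> RscanResult:
    """Full r-scan dispersion analysis of a test position set.

    `test_positions` maps chromosome -> positions (bp). Chromosomes with
    fewer than two positions are skipped with a warning. Regions overlapping
    `gap_annotations` (assembly gaps / low mappability) are removed from the
    output.
    """
    positions = {}
    for chrom, pos in test_positions.items():
        pos = np.sort(np.asarray(pos, dtype=np.int64))
        if len(pos) < 2:
            logger.warning("chromosome %s has <2 positions; skipped", chrom)
            continue
        positions[chrom] = pos
    empty_spans = pd.DataFrame(columns=["r", "k", "chrom", "start", "end", "length",
                                        "p_raw", "p_adj", "significant"])
    if not positions:
        logger.warning("empty test set; no r-scan analysis performed")
        return RscanResult(empty_spans, IntervalSet("deficient_regions"), config)

    observed = pd.concat(
        [extreme_spans(positions, r, config.k_max, config.direction)
         for r in range(1, config.r_max + 1)],
        ignore_index=True)
    if observed.empty:
        return RscanResult(empty_spans, IntervalSet("deficient_regions"), config)

    counts = {chrom: len(pos) for chrom, pos in positions.items()}
    null = empirical_null(counts, config, background_by_chrom, genome)
    spans = _p_values(observed, null, config)
    regions = _localized_regions(spans, "deficient_regions")

    n_removed = 0
    if gap_annotations is not None and len(regions) and len(gap_annotations):
        hit = overlap_membership(regions, gap_annotations)
        n_removed = int(hit.sum())
        regions = IntervalSet("deficient_regions", regions.df[~hit])
    return RscanResult(spans, regions, config,
                       null_extremes=null if keep_null else None,
                       n_removed_gap_overlap=n_removed)


def cross_reference_deficiency(regions: IntervalSet, sites: IntervalSet,
                               genome: Genome,
                               threshold_fraction: float = 0.5) -> pd.DataFrame:
    """Per-region binding-site density vs the genome-wide average.

    A called region is `truly_deficient` (in in-vivo usage, not in binding
    sites) when its site density is at least `threshold_fraction` of the
    genome-wide site density: binding sites are present but unused there.
    """
    if len(regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "span_mb", "density", "truly_deficient"])
    genome_density = len(sites) / (genome.total_bp / 1e6)
    by_chrom = {chrom: (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
                for chrom, sub in sites.df.groupby("chrom", sort=False)}
    rows = []
    for region in regions:
        span_bp = region.end - region.start
        if span_bp <= 0:
            raise ValueError("zero-length region")
        starts, ends = by_chrom.get(region.chrom, (np.empty(0), np.empty(0)))
        n = int(np.searchsorted(starts, region.end, side="left")
                - np.searchsorted(ends, region.start, side="right"))
        density = n / (span_bp / 1e6)
        rows.append((region.chrom, region.start, region.end, n,
                     span_bp / 1e6, density,
                     density >= threshold_fraction * genome_density))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "span_mb", "density", "truly_deficient"])
    return df
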