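"""Usage enrichment by genomic category, affinity quintile and score metrics.

Usage of a category = (in-vivo sites in category) / (all non-ambiguous sites
in category), with a Poisson standard error on the numerator count. The
affinity-quintile analysis asks whether strong binding overcomes the
heterochromatin barrier: quintiles are cut on all sites genome-wide, then
per quintile the closed-chromatin usage is divided by the open-chromatin
usage; a ratio of 1 means heterochromatin has no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Genome, IntervalSet, complement, overlap_membership
from .classify import AMBIGUOUS, IN_VIVO, ClassifiedSites


@dataclass(frozen=True)
class CategoryUsage:
    label: str
    n_total: int
    n_used: int
    fraction: float
    se: float


def fraction_with_poisson_se(n_used: int, n_total: int) -> tuple[float, float]:
    """Used fraction with Poisson SE on the numerator: sqrt(n_used)/n_total."""
    if n_total == 0:
        raise ZeroDivisionError("usage fraction undefined for an empty category")
    if n_used < 0 or n_used > n_total:
        raise ValueError("need 0 <= n_used <= n_total")
    return n_used / n_total, np.sqrt(n_used) / n_total


def fraction_with_binomial_se(n_used: int, n_total: int) -> tuple[float, float]:
    f, _ = fraction_with_poisson_se(n_used, n_total)
    return f, np.sqrt(f * (1.0 - f) / n_total)


def usage_fraction(classified: ClassifiedSites, category: IntervalSet,
                   label: str | None = None, se_kind: str = "poisson") -> CategoryUsage:
    """Fraction of in-vivo-used sites among non-ambiguous sites in a category."""
    keep = classified.sites["status"] != AMBIGUOUS
    sites = IntervalSet("sites", classified.sites[keep])
    inside = overlap_membership(sites, category)
    n_total = int(inside.sum())
    n_used = int((inside & (sites.df["status"] == IN_VIVO).to_numpy()).sum())
    se_fn = fraction_with_poisson_se if se_kind == "poisson" else fraction_with_binomial_se
    fraction, se = se_fn(n_used, n_total)
    return CategoryUsage(label or category.label, n_total, n_used, fraction, se)


def binary_usage(classified: ClassifiedSites, category: IntervalSet,
                 label: str | None = None,
                 se_kind: str = "poisson") -> tuple[CategoryUsage, CategoryUsage]:
    """Usage inside vs outside a category as a true binary partition.

    The negative class is defined as "does not overlap the category", so a
    site straddling a boundary counts once (in the positive class) and the
    two totals sum exactly to the non-ambiguous site count.
    """
    keep = classified.sites["status"] != AMBIGUOUS
    sites = IntervalSet("sites", classified.sites[keep])
    inside = overlap_membership(sites, category)
    used = (sites.df["status"] == IN_VIVO).to_numpy()
    name = label or category.label
    se_fn = fraction_with_poisson_se if se_kind == "poisson" else fraction_with_binomial_se
    out = []
    for flags, suffix in ((inside, "+"), (~inside, "-")):
        n_total = int(flags.sum())
        n_used = int((flags & used).sum())
        fraction, se = se_fn(n_used, n_total)
        out.append(CategoryUsage(f"{name}{suffix}", n_total, n_used, fraction, se))
    return tuple(out)


def expression_quartiles(genes: IntervalSet) -> list[IntervalSet]:
    """Split genes into four equal-count bins by expression (score column).

    Returns [q1(lowest) .. q4(highest)]; ties broken by stable input order,
    so zero-expression genes land in the bottom bin(s). Bin sizes differ by
    at most one.
    """
    if len(genes) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    values = genes.df["score"].to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    bins = np.array_split(order, 4)
    out = []
    for q, idx in enumerate(bins, start=1):
        sub = genes.df.iloc[np.sort(idx)]
        out.append(IntervalSet(f"{genes.label}_q{q}", sub))
    return out


def affinity_quintile_ratio(classified: ClassifiedSites, closed: IntervalSet,
                            genome: Genome) -> pd.DataFrame:
    """Closed/open usage ratio per affinity quintile.

    Quintiles are equal-count bins of all non-ambiguous sites by affinity
    (score). Per quintile, usage = used/total is computed separately inside
    `closed` chromatin (e.g. merged H3K9me2/3 domains) and in its genomic
    complement, and the ratio (closed usage) / (open usage) is reported with
    a delta-method SE from the Poisson errors of both numerator counts. A
    quintile with no sites (or no used sites) on one side yields NaN.
    """
    keep = classified.sites["status"] != AMBIGUOUS
    df = classified.sites[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError("no classified sites")
    sites = IntervalSet("sites", df)
    df = sites.df
    in_closed = overlap_membership(sites, closed)
    used = (df["status"] == IN_VIVO).to_numpy()
    affinity = df["score"].to_numpy(dtype=float)

    order = np.argsort(affinity, kind="stable")
    quintile = np.empty(len(df), dtype=int)
    for q, idx in enumerate(np.array_split(order, 5), start=1):
        quintile[idx] = q

    rows = []
    for q in range(1, 6):
        sel = quintile == q
        lo, hi = affinity[sel].min(), affinity[sel].max()
        nc, uc = int((sel & in_closed).sum()), int((sel & in_closed & used).sum())
        no, uo = int((sel & ~in_closed).sum()), int((sel & ~in_closed & used).sum())
        if nc == 0 or no == 0 or uo == 0:
            ratio = se = np.nan
        else:
            f_c, f_o = uc / nc, uo / no
            ratio = f_c / f_o
            # delta method on the two Poisson numerators
            rel_var = (1.0 / uc if uc else 0.0) + 1.0 / uo
            se = ratio * np.sqrt(rel_var) if uc else np.nan
        rows.append((q, lo, hi, nc, uc, no, uo, ratio, se))
    return pd.DataFrame(rows, columns=["quintile", "affinity_min", "affinity_max",
                                       "n_closed", "used_closed", "n_open",
                                       "used_open", "ratio", "se"])


def rank_sum_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison (U statistic, p).

    Exact enumeration when n_a * n_b <= 400 and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ppm_normalize(read_counts, library_size: float) -> np.ndarray:
    """Reads-per-million normalization: count * 1e6 / library_size."""
    counts = np.asarray(read_counts, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if np.any(counts < 0):
        raise ValueError("read counts must be >= 0")
    return counts * 1e6 / library_size


def site_density(n_sites: int, span_mb: float) -> float:
    """Sites per Mb, reported to 2 decimals."""
    if span_mb <= 0:
        raise ValueError("span_mb must be > 0")
    return round(n_sites / span_mb, 2)


def recombination_rate(n_recombinants: int, n_progeny: int, interval_mb: float) -> float:
    """cM/Mb = 100 * (recombinant fraction) / interval size, to 3 decimals."""
    if n_progeny <= 0:
        raise ValueError("n_progeny must be > 0")
    if interval_mb <= 0:
        raise ValueError("interval_mb must be > 0")
    if n_recombinants < 0 or n_recombinants > n_progeny:
        raise ValueError("need 0 <= n_recombinants <= n_progeny")
    return round(100.0 * (n_recombinants / n_progeny) / interval_mb, 3)


def closed_chromatin(domains: dict, genome: Genome,
                     keys: tuple = ("h3k9me2", "h3k9me3")) -> tuple[IntervalSet, IntervalSet]:
    """(closed, open) partition: union of heterochromatin domain sets and its
    genomic complement."""
    frames = [domains[k].df[["chrom", "start", "end"]] for k in keys if k in domains]
    closed = IntervalSet("closed", pd.concat(frames, ignore_index=True)
                         if frames else None)
    from .intervals import merge_intervals
    closed = merge_intervals(closed, gap=0)
    closed.label = "closed"
    return closed, complement(closed, genome, label="open")
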