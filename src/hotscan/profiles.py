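"""Positional aggregation around binding sites.

Composite coverage metaplots, nucleotide-frequency matrices along oriented
motifs, SNP-density ratio profiles, and binned log2 enrichment tracks.
Orientation: minus-strand sites are reversed (sequence windows
reverse-complemented) before aggregation, so profiles read 5'->3' along the
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import Genome, IntervalSet

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")
NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class ProfileMatrix:
    """Per-offset channels aggregated across n_sites oriented sites."""
    offsets: np.ndarray                 # bp relative to the anchor
    channels: dict = field(default_factory=dict)   # name -> np.ndarray
    n_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format (offset, channel, value, n) table, plot-ready."""
        rows = []
        for name, values in self.channels.items():
            rows.append(pd.DataFrame({
                "offset": self.offsets, "channel": name,
                "value": values, "n": self.n_sites,
            }))
        return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# bedGraph plumbing

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            v = float(row.value)
            text = str(int(v)) if v == int(v) else repr(v)
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{text}\n")


def bedgraph_to_arrays(df: pd.DataFrame, genome: Genome) -> dict:
    """Dense per-chromosome value arrays (positions absent from the track = 0)."""
    bad = set(df["chrom"]) - set(genome)
    if bad:
        raise ValueError(f"track chromosomes not in genome: {sorted(bad)}")
    arrays = {chrom: np.zeros(length, dtype=np.float64) for chrom, length in genome.items()}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = arrays[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[max(0, s):min(len(arr), e)] = v
    return arrays


def arrays_to_bedgraph(arrays: dict) -> pd.DataFrame:
    """Run-length encode dense arrays, dropping zero-valued runs."""
    rows = []
    for chrom in arrays:
        arr = np.asarray(arrays[chrom])
        if len(arr) == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                rows.append((chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _as_arrays(coverage, genome: Genome) -> dict:
    if isinstance(coverage, dict):
        bad = set(coverage) - set(genome)
        if bad:
            raise ValueError(f"track chromosomes not in genome: {sorted(bad)}")
        return {chrom: coverage.get(chrom, np.zeros(length))
                for chrom, length in genome.items()}
    return bedgraph_to_arrays(coverage, genome)


# --------------------------------------------------------------------------
# metaprofiles

def composite_profile(coverage, sites: IntervalSet, half_width: int,
                      genome: Genome, anchor: str = "center") -> ProfileMatrix:
    """Mean coverage per offset across oriented sites.

    `coverage` is a bedGraph DataFrame or a dict of dense arrays. The anchor
    is the interval center (default) or the motif start. Sites whose window
    would be truncated at a chromosome end are excluded.
    """
    if len(sites) == 0:
        raise ValueError("empty site set")
    arrays = _as_arrays(coverage, genome)
    df = sites.df
    if anchor == "center":
        anchors = ((df["start"] + df["end"]) // 2).to_numpy()
    elif anchor == "motif_start":
        anchors = df["motif_start"].to_numpy(dtype=np.int64)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    width = 2 * half_width + 1
    total = np.zeros(width, dtype=np.float64)
    n_used = 0
    strands = df["strand"].to_numpy()
    for chrom, a, strand in zip(df["chrom"], anchors, strands):
        arr = arrays[chrom]
        lo, hi = a - half_width, a + half_width + 1
        if lo < 0 or hi > len(arr):
            continue
        window = arr[lo:hi]
        total += window[::-1] if strand == "-" else window
        n_used += 1
    if n_used == 0:
        raise ValueError("no site window fits inside the genome")
    offsets = np.arange(-half_width, half_width + 1)
    return ProfileMatrix(offsets, {"coverage": total / n_used}, n_used)


def _load_sequences(source) -> dict:
    if isinstance(source, dict):
        return source
    from pyfaidx import Fasta
    fa = Fasta(str(source))
    return {name: str(fa[name][:]) for name in fa.keys()}


def nucleotide_frequency_profile(sequence_source, sites: IntervalSet,
                                 flank: int = 10) -> ProfileMatrix:
    """Per-position A/C/G/T frequencies along motif-aligned oriented sites.

    Sites are aligned on their motif start; minus-strand windows are
    reverse-complemented so the motif reads 5'->3'. Offsets run from -flank
    to motif_length - 1 + flank relative to the motif start. Sites whose
    window exceeds the contig are skipped (count kept in channel metadata).
    """
    seqs = _load_sequences(sequence_source)
    df = sites.df
    if "motif_start" not in df.columns:
        raise ValueError("sites must carry motif_start/motif_end columns")
    m_len = int((df["motif_end"] - df["motif_start"]).iloc[0])
    width = m_len + 2 * flank
    counts = np.zeros((4, width), dtype=np.int64)
    n_used = n_skipped = 0
    code = np.full(256, -1, dtype=np.int8)
    for i, nt in enumerate(NUCLEOTIDES):
        code[ord(nt)] = i
        code[ord(nt.lower())] = i
    for row in df.itertuples(index=False):
        seq = seqs.get(row.chrom)
        lo = int(row.motif_start) - flank
        hi = int(row.motif_end) + flank
        if seq is None or lo < 0 or hi > len(seq):
            n_skipped += 1
            continue
        window = seq[lo:hi]
        if row.strand == "-":
            window = window.translate(_COMPLEMENT)[::-1]
        codes = code[np.frombuffer(window.encode(), dtype=np.uint8)]
        ok = codes >= 0
        counts[codes[ok], np.flatnonzero(ok)] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable sites for the nucleotide profile")
    col_totals = counts.sum(axis=0)
    freqs = np.divide(counts, col_totals, where=col_totals > 0,
                      out=np.zeros_like(counts, dtype=np.float64))
    offsets = np.arange(-flank, m_len + flank)
    channels = {nt: freqs[i] for i, nt in enumerate(NUCLEOTIDES)}
    pm = ProfileMatrix(offsets, channels, n_used)
    pm.n_skipped = n_skipped
    return pm


def snp_density_profile(snps: IntervalSet, sites: IntervalSet,
                        window: int = 2000, smooth: int | None = None) -> ProfileMatrix:
    """SNP frequency per offset around oriented site centers, expressed as a
    ratio over the regional (whole-window) average; the profile mean is 1 by
    construction. `window` bp spans [-window/2, window/2) around the center.

    Optional smoothing is a centered moving average with an odd width.
    """
    half = window // 2
    pos_by_chrom = {chrom: np.sort(sub["start"].to_numpy())
                    for chrom, sub in snps.df.groupby("chrom", sort=False)}
    df = sites.df
    counts = np.zeros(window, dtype=np.int64)
    centers = ((df["start"] + df["end"]) // 2).to_numpy()
    for chrom, c, strand in zip(df["chrom"], centers, df["strand"].to_numpy()):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        i0 = np.searchsorted(pos, c - half, side="left")
        i1 = np.searchsorted(pos, c + half, side="left")
        offs = pos[i0:i1] - c
        if strand == "-":
            offs = -offs - 1          # reflection keeps offsets in [-half, half)
        np.add.at(counts, offs + half, 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no SNPs fall in any site window")
    ratio = counts / counts.mean()
    if smooth is not None:
        if smooth % 2 == 0 or smooth < 1:
            raise ValueError("smoothing window must be a positive odd integer")
        kernel = np.ones(smooth) / smooth
        ratio = np.convolve(ratio, kernel, mode="same")
    offsets = np.arange(-half, half)
    pm = ProfileMatrix(offsets, {"ratio": ratio, "count": counts.astype(float)}, len(df))
    return pm


def binned_log2_enrichment(sample, control, genome: Genome, bin_size: int = 2000,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-bin log2((sample + pc) / (control + pc)) after scaling both tracks
    to equal totals; returns a bedGraph frame with one row per bin."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    s_arr = _as_arrays(sample, genome)
    c_arr = _as_arrays(control, genome)
    t_s = sum(float(a.sum()) for a in s_arr.values())
    t_c = sum(float(a.sum()) for a in c_arr.values())
    mean_total = 0.5 * (t_s + t_c)
    f_s = mean_total / t_s if t_s > 0 else 1.0
    f_c = mean_total / t_c if t_c > 0 else 1.0
    rows = []
    for chrom, length in genome.items():
        n_bins = (length + bin_size - 1) // bin_size
        for b in range(n_bins):
            lo, hi = b * bin_size, min((b + 1) * bin_size, length)
            s = f_s * float(s_arr[chrom][lo:hi].sum())
            c = f_c * float(c_arr[chrom][lo:hi].sum())
            rows.append((chrom, lo, hi, np.log2((s + pseudocount) / (c + pseudocount))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
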