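"""Synthetic dataset generator for the binding-site usage analysis.

Emulates the statistical structure of an in-vitro binding-site catalog and
its in-vivo readouts on a toy genome: log-normally distributed binding
affinities (ppm), heterochromatin / lamina / gene domain mosaics, a logistic
chromatin-barrier activation model, H3K4me3 / DMC1 / protein-ChIP peak
tracks, SNPs enriched at historically active motifs, and trapezoidal
fragment-coverage peaks of span 2L - m around each site.

The generator is the ground-truth harness for every downstream estimator:
all of its parameters are explicit and every realisation is deterministic
given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import Genome, IntervalSet, overlap_membership, write_bed
from .profiles import arrays_to_bedgraph, write_bedgraph

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _default_consensus(length: int = 31) -> str:
    """Default motif consensus with the five near-invariant positions
    (1-based 8, 11, 13, 15, 16) set to G, G, T, C, T."""
    base = ("ACGT" * ((length // 4) + 1))[:length]
    cons = list(base)
    for pos, nt in ((7, "G"), (10, "G"), (12, "T"), (14, "C"), (15, "T")):
        if pos < length:
            cons[pos] = nt
    return "".join(cons)


def _default_weights(length: int = 31) -> tuple[float, ...]:
    w = np.full(length, 0.5)
    for pos in (7, 10, 12, 14, 15):
        if pos < length:
            w[pos] = 0.9
    return tuple(w)


@dataclass(frozen=True)
class DomainSpec:
    """Target genome fraction and mean segment length (bp) of a domain mosaic."""
    fraction: float
    mean_length: float


@dataclass(frozen=True)
class ActivationModel:
    """Logistic model for in-vivo activation of a binding site.

    logit p = baseline + affinity_coeff * ln(affinity_ppm)
              - sum(barrier_penalty[d] * in_domain_d)
              + expression_coeff * in_top_quartile_expressed_gene

    A negative penalty acts as a bonus (used for gene bodies).
    """
    baseline_logodds: float = -1.0
    affinity_coeff: float = 1.0
    barrier_penalty: dict = field(default_factory=lambda: {
        "h3k9me2": 1.2, "h3k9me3": 2.0, "cLAD": 0.8, "gene": -0.4,
    })
    expression_coeff: float = 0.6


@dataclass(frozen=True)
class SnpModel:
    """Poisson SNP placement: background rate per bp, multiplied by
    `enrichment` within the central motif span of historically active sites."""
    rate: float = 0.004
    enrichment: float = 3.0


@dataclass(frozen=True)
class SynthConfig:
    genome: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_sites: int = 2000
    affinity_lognormal: tuple = (1.6, 1.0)   # (mu, sigma) of ln(ppm)
    site_length: int = 300
    motif_length: int = 31
    fragment_length: int = 177
    domain_specs: dict = field(default_factory=lambda: {
        "h3k9me2": DomainSpec(0.35, 200_000.0),
        "h3k9me3": DomainSpec(0.15, 150_000.0),
        "cLAD": DomainSpec(0.30, 200_000.0),
        "gene": DomainSpec(0.40, 30_000.0),
    })
    activation: ActivationModel = field(default_factory=ActivationModel)
    snp: SnpModel = field(default_factory=SnpModel)
    ambiguous_fraction: float = 0.04
    gaps: tuple = ()                          # ((chrom, start, end), ...)
    coverage_depth: int = 0                   # fragments per site; 0 = skip track
    write_fasta: bool = False
    motif_consensus: str = ""
    motif_weights: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not self.motif_consensus:
            object.__setattr__(self, "motif_consensus", _default_consensus(self.motif_length))
        if not self.motif_weights:
            object.__setattr__(self, "motif_weights", _default_weights(self.motif_length))
        self.validate()

    def validate(self) -> None:
        genome = dict(self.genome)
        if self.motif_length >= self.fragment_length:
            raise ValueError("motif_length must be < fragment_length")
        if self.motif_length > self.site_length:
            raise ValueError("motif must fit inside the site interval")
        if len(self.motif_consensus) != self.motif_length:
            raise ValueError("motif_consensus length != motif_length")
        if len(self.motif_weights) != self.motif_length:
            raise ValueError("motif_weights length != motif_length")
        for name, spec in self.domain_specs.items():
            if not 0.0 <= spec.fraction <= 1.0:
                raise ValueError(f"domain {name}: fraction outside [0, 1]")
            if spec.mean_length <= 0:
                raise ValueError(f"domain {name}: mean_length must be > 0")
        if self.snp.enrichment < 1.0:
            raise ValueError("snp enrichment must be >= 1")
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ValueError("ambiguous_fraction outside [0, 1)")
        for chrom, start, end in self.gaps:
            if chrom not in genome:
                raise ValueError(f"gap on unknown chromosome {chrom}")
            if not 0 <= start < end <= genome[chrom]:
                raise ValueError(f"gap [{start},{end}) outside {chrom}")
        if self.n_sites < 2 * len(genome):
            raise ValueError("need n_sites >= 2 per chromosome")

    @property
    def genome_obj(self) -> Genome:
        return Genome(self.genome)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset (for recovery tests)."""
    config: SynthConfig
    sites: IntervalSet                 # score = affinity ppm; extra columns below
    domains: dict                      # name -> IntervalSet
    genes: IntervalSet                 # score = expression
    peaks: dict                        # assay -> IntervalSet
    snps: IntervalSet                  # 1-bp intervals
    sequences: dict | None = None      # chrom -> str (when write_fasta)

    @property
    def activated(self) -> np.ndarray:
        return self.sites.df["activated"].to_numpy(dtype=bool)

    @property
    def p_activation(self) -> np.ndarray:
        return self.sites.df["p_activation"].to_numpy(dtype=float)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _available_segments(chrom: str, length: int, margin: int, gaps) -> list[tuple[int, int]]:
    """Complement of implanted gaps, shrunk by `margin` at chromosome ends."""
    blocks = sorted((s, e) for c, s, e in gaps if c == chrom)
    segs, pos = [], margin
    for s, e in blocks:
        if s > pos:
            segs.append((pos, min(s, length - margin)))
        pos = max(pos, e)
    if pos < length - margin:
        segs.append((pos, length - margin))
    return [(a, b) for a, b in segs if b > a]


def _sample_mosaic(length: int, spec: DomainSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Alternating-state renewal mosaic with exponential segment lengths hitting
    the target in-state fraction in expectation."""
    if spec.fraction <= 0.0:
        return []
    if spec.fraction >= 1.0:
        return [(0, length)]
    mean_in = spec.mean_length
    mean_out = spec.mean_length * (1.0 - spec.fraction) / spec.fraction
    segs, pos = [], 0
    state_in = rng.random() < spec.fraction
    while pos < length:
        mean = mean_in if state_in else mean_out
        seg = max(1, int(round(rng.exponential(mean))))
        end = min(pos + seg, length)
        if state_in:
            segs.append((pos, end))
        pos = end
        state_in = not state_in
    return segs


def _peaks_around(centers: np.ndarray, chroms: np.ndarray, width_mean: float,
                  width_sd: float, jitter_sd: float, genome: Genome,
                  rng: np.random.Generator, label: str) -> IntervalSet:
    n = len(centers)
    widths = np.maximum(200, rng.normal(width_mean, width_sd, n)).astype(np.int64)
    mids = centers + rng.normal(0.0, jitter_sd, n).astype(np.int64)
    starts = mids - widths // 2
    ends = starts + widths
    rows = []
    for chrom, s, e in zip(chroms, starts, ends):
        length = genome[chrom]
        s, e = max(0, int(s)), min(length, int(e))
        if e > s:
            rows.append((chrom, s, e))
    return IntervalSet(label, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def simulate_dataset(config: SynthConfig, outdir: str | Path | None = None) -> SyntheticTruth:
    """Generate one full synthetic dataset; write tracks to `outdir` if given.

    Deterministic and byte-identical on disk for a fixed config (including
    seed). See the module docstring for what each track emulates.
    """
    config.validate()
    genome = config.genome_obj
    (rng_sites, rng_aff, rng_dom, rng_act, rng_peaks,
     rng_amb, rng_snp, rng_seq, rng_cov) = _streams(config.seed, 9)

    # --- site positions: uniform over the genome outside implanted gaps ----
    margin = config.site_length
    seg_by_chrom = {c: _available_segments(c, L, margin, config.gaps)
                    for c, L in genome.items()}
    avail = {c: sum(b - a for a, b in segs) for c, segs in seg_by_chrom.items()}
    chrom_names = list(genome)
    weights = np.array([avail[c] for c in chrom_names], dtype=float)
    counts = rng_sites.multinomial(config.n_sites, weights / weights.sum())

    rows = []
    for chrom, n_c in zip(chrom_names, counts):
        segs = seg_by_chrom[chrom]
        lens = np.array([b - a for a, b in segs], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        offs = np.sort(rng_sites.integers(0, cum[-1], size=n_c))
        seg_idx = np.searchsorted(cum, offs, side="right") - 1
        centers = np.array([segs[i][0] for i in seg_idx]) + (offs - cum[seg_idx])
        half = config.site_length // 2
        for c in centers:
            rows.append((chrom, int(c - half), int(c - half + config.site_length)))
    sites_df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    n = len(sites_df)
    sites_df["id"] = [f"site_{i:05d}" for i in range(n)]

    mu, sigma = config.affinity_lognormal
    sites_df["score"] = np.exp(rng_aff.normal(mu, sigma, n))        # affinity ppm
    sites_df["strand"] = np.where(rng_sites.random(n) < 0.5, "+", "-")
    center = (sites_df["start"] + sites_df["end"]) // 2
    sites_df["motif_start"] = center - config.motif_length // 2
    sites_df["motif_end"] = sites_df["motif_start"] + config.motif_length

    sites = IntervalSet("affinity_sites", sites_df)
    sites_df = sites.df  # sorted order from here on

    # --- chromatin / gene domain mosaics ----------------------------------
    domains: dict[str, IntervalSet] = {}
    for name, spec in config.domain_specs.items():
        rows = []
        for chrom, length in genome.items():
            rows += [(chrom, a, b) for a, b in _sample_mosaic(length, spec, rng_dom)]
        domains[name] = IntervalSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    genes = domains.pop("gene", IntervalSet("gene"))
    expr = np.where(rng_dom.random(len(genes)) < 0.3, 0.0,
                    np.exp(rng_dom.normal(1.5, 1.5, len(genes))))
    gdf = genes.df.copy()
    gdf["score"] = expr
    gdf["id"] = [f"gene_{i:05d}" for i in range(len(gdf))]
    genes = IntervalSet("gene", gdf)

    # --- logistic activation model ----------------------------------------
    act = config.activation
    logit = act.baseline_logodds + act.affinity_coeff * np.log(sites_df["score"].to_numpy())
    for name, penalty in act.barrier_penalty.items():
        dom = genes if name == "gene" else domains.get(name)
        if dom is None or len(dom) == 0:
            continue
        inside = overlap_membership(sites, dom)
        sites_df[f"in_{name}"] = inside
        logit = logit - penalty * inside
    if len(genes):
        q75 = np.quantile(genes.df["score"].to_numpy(), 0.75)
        top_genes = IntervalSet("top_gene", genes.df[genes.df["score"] >= q75])
        in_top = overlap_membership(sites, top_genes)
    else:
        in_top = np.zeros(n, dtype=bool)
    sites_df["in_top_expressed_gene"] = in_top
    logit = logit + act.expression_coeff * in_top
    p_act = 1.0 / (1.0 + np.exp(-logit))
    activated = rng_act.random(n) < p_act
    sites_df["p_activation"] = p_act
    sites_df["activated"] = activated

    # --- in-vivo peak tracks ----------------------------------------------
    centers = ((sites_df["start"] + sites_df["end"]) // 2).to_numpy()
    chroms = sites_df["chrom"].to_numpy()
    a_idx = np.flatnonzero(activated)
    # marks of one activated site share a jittered midpoint, and the DSB
    # (DMC1) interval contains both strains' H3K4me3 intervals, so a site
    # reached by activation-derived H3K4me3 always carries DMC1 evidence
    # (the ambiguous class then comes only from seeded promoter-like peaks)
    n_act = len(a_idx)
    mids = centers[a_idx] + rng_peaks.normal(0.0, 50.0, n_act).astype(np.int64)
    w_a = np.maximum(200, rng_peaks.normal(900, 100, n_act)).astype(np.int64)
    w_b = np.maximum(200, rng_peaks.normal(900, 100, n_act)).astype(np.int64)
    w_d = np.maximum(w_a, w_b) + 100
    peaks = {}
    for key, widths in (("h3k4me3_a", w_a), ("h3k4me3_b", w_b), ("dmc1", w_d)):
        rows = []
        for chrom, mid, w in zip(chroms[a_idx], mids, widths):
            s, e = max(0, int(mid - w // 2)), min(genome[chrom], int(mid - w // 2 + w))
            if e > s:
                rows.append((chrom, s, e))
        peaks[key] = IntervalSet(key, pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    # protein ChIP detects only the top affinity decile of activated sites
    ppm = sites_df["score"].to_numpy()
    chip_idx = np.array([], dtype=int)
    if len(a_idx):
        n_chip = max(1, int(round(0.10 * len(a_idx))))
        order = a_idx[np.argsort(-ppm[a_idx], kind="stable")]
        chip_idx = np.sort(order[:n_chip])
    peaks["prdm9_chip"] = _peaks_around(centers[chip_idx], chroms[chip_idx], 400, 50, 30,
                                        genome, rng_peaks, "prdm9_chip")
    sites_df["chip_detected"] = np.isin(np.arange(n), chip_idx)

    # promoter-like peaks shared by both strains with no DMC1: the ambiguous
    # class, seeded at a configurable fraction of otherwise-silent sites
    inactive = np.flatnonzero(~activated)
    n_amb = int(round(config.ambiguous_fraction * len(a_idx)))
    amb_idx = np.sort(rng_amb.choice(inactive, size=min(n_amb, len(inactive)),
                                     replace=False)) if n_amb else np.array([], dtype=int)
    sites_df["ambiguous_seeded"] = np.isin(np.arange(n), amb_idx)
    if len(amb_idx):
        for key in ("h3k4me3_a", "h3k4me3_b"):
            extra = _peaks_around(centers[amb_idx], chroms[amb_idx], 900, 100, 50,
                                  genome, rng_amb, key)
            peaks[key] = IntervalSet(key, pd.concat([peaks[key].df, extra.df]))

    # --- SNPs: Poisson background, enriched at historically active motifs --
    snp_rows = []
    for chrom, length in genome.items():
        n_bg = rng_snp.poisson(config.snp.rate * length)
        snp_rows += [(chrom, int(p), int(p) + 1)
                     for p in rng_snp.integers(0, length, size=n_bg)]
    extra_rate = (config.snp.enrichment - 1.0) * config.snp.rate
    for i in a_idx:
        m0 = int(sites_df["motif_start"].iloc[i])
        n_extra = rng_snp.poisson(extra_rate * config.motif_length)
        for p in rng_snp.integers(m0, m0 + config.motif_length, size=n_extra):
            snp_rows.append((sites_df["chrom"].iloc[i], int(p), int(p) + 1))
    snps = IntervalSet("snps", pd.DataFrame(snp_rows, columns=["chrom", "start", "end"]))

    # --- genome sequence with implanted motifs ----------------------------
    sequences = None
    if config.write_fasta:
        sequences = _simulate_sequences(config, genome, sites_df, rng_seq)

    truth = SyntheticTruth(config=config, sites=IntervalSet("affinity_sites", sites_df),
                           domains=domains, genes=genes, peaks=peaks, snps=snps,
                           sequences=sequences)

    if outdir is not None:
        _write_outputs(truth, Path(outdir), rng_cov)
    return truth


def _simulate_sequences(config: SynthConfig, genome: Genome, sites_df: pd.DataFrame,
                        rng: np.random.Generator) -> dict[str, str]:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    cons_codes = np.frombuffer(config.motif_consensus.encode(), dtype=np.uint8)
    weights = np.asarray(config.motif_weights)
    seqs: dict[str, str] = {}
    for chrom, length in genome.items():
        arr = alphabet[rng.integers(0, 4, size=length)]
        sub = sites_df[sites_df["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            take = rng.random(config.motif_length) < weights
            motif = np.where(take, cons_codes,
                             alphabet[rng.integers(0, 4, size=config.motif_length)])
            if row.strand == "-":
                motif = np.frombuffer(bytes(motif).translate(_COMPLEMENT),
                                      dtype=np.uint8)[::-1]
            m0 = int(row.motif_start)
            if 0 <= m0 and m0 + config.motif_length <= length:
                arr[m0:m0 + config.motif_length] = motif
        seqs[chrom] = arr.tobytes().decode()
    return seqs


def simulate_affinity_coverage(sites: IntervalSet | pd.DataFrame, fragment_length: int,
                               depth_per_site: int, genome: Genome,
                               rng: np.random.Generator | int = 0,
                               stratified: bool = True) -> pd.DataFrame:
    """Fragment-pileup coverage around each site's motif, as a bedGraph frame.

    Every retained fragment of length L fully contains the site's motif of
    length m, so admissible fragment starts span L - m + 1 offsets and the
    aggregate per-site coverage is a trapezoid of total span 2L - m bp,
    maximal over the motif. With `stratified` the depth is spread evenly over
    the admissible offsets (remainder assigned at random without
    replacement), making the coverage integral exactly depth x L per site.
    """
    df = sites.df if isinstance(sites, IntervalSet) else sites
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if "motif_start" in df.columns:
        m_starts = df["motif_start"].to_numpy(dtype=np.int64)
        m_lens = (df["motif_end"] - df["motif_start"]).to_numpy(dtype=np.int64)
    else:  # fall back to the whole interval as the protected motif
        m_starts = df["start"].to_numpy(dtype=np.int64)
        m_lens = (df["end"] - df["start"]).to_numpy(dtype=np.int64)
    L = int(fragment_length)
    if np.any(L <= m_lens):
        raise ValueError("fragment_length must exceed the motif length")

    diffs = {chrom: np.zeros(length + L + 1, dtype=np.int64) for chrom, length in genome.items()}
    chroms = df["chrom"].to_numpy()
    for chrom, m0, m in zip(chroms, m_starts, m_lens):
        n_off = L - m + 1
        if stratified:
            counts = np.full(n_off, depth_per_site // n_off, dtype=np.int64)
            rem = depth_per_site % n_off
            if rem:
                counts[rng.choice(n_off, size=rem, replace=False)] += 1
        else:
            counts = np.bincount(rng.integers(0, n_off, size=depth_per_site), minlength=n_off)
        starts = m0 + m - L + np.arange(n_off)
        lo = np.clip(starts, 0, None)
        hi = np.clip(starts + L, 0, len(diffs[chrom]) - 1)
        np.add.at(diffs[chrom], lo, counts)
        np.add.at(diffs[chrom], hi, -counts)
    arrays = {chrom: np.cumsum(d)[: genome[chrom]] for chrom, d in diffs.items()}
    return arrays_to_bedgraph(arrays)


def _write_outputs(truth: SyntheticTruth, outdir: Path, rng_cov: np.random.Generator) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    genome = config.genome_obj
    write_bed(truth.sites, outdir / "sites.bed")
    for name, dom in truth.domains.items():
        write_bed(dom, outdir / f"domain_{name}.bed")
    write_bed(truth.genes, outdir / "genes.bed")
    for name, pk in truth.peaks.items():
        write_bed(pk, outdir / f"peaks_{name}.bed")
    write_bed(truth.snps, outdir / "snps.bed")
    genome.to_file(outdir / "chrom.sizes")
    truth.sites.df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    if config.coverage_depth > 0:
        bg = simulate_affinity_coverage(truth.sites, config.fragment_length,
                                        config.coverage_depth, genome, rng_cov)
        write_bedgraph(bg, outdir / "affinity_coverage.bedgraph")
    if truth.sequences is not None:
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in truth.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def _config_to_dict(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["domain_specs"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
                         for k, v in config.domain_specs.items()}
    d["genome"] = [list(x) for x in config.genome]
    d["gaps"] = [list(x) for x in config.gaps]
    d["motif_weights"] = [float(w) for w in config.motif_weights]
    return d
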