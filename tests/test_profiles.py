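"""Metaprofiles: composite coverage, nucleotide frequencies, SNP ratios,
binned log2 enrichment."""

import numpy as np
import pandas as pd
import pytest

from hotscan import Genome, IntervalSet, SynthConfig, simulate_dataset
from hotscan.profiles import (binned_log2_enrichment, composite_profile,
                              nucleotide_frequency_profile, read_bedgraph,
                              snp_density_profile, write_bedgraph)
from hotscan.synth import SnpModel, simulate_affinity_coverage


@pytest.fixture()
def toy_genome():
    return Genome({"chr1": 100_000})


def _sites(rows, extra=()):
    cols = ["chrom", "start", "end", "strand", *extra]
    return IntervalSet("sites", pd.DataFrame(rows, columns=cols))


class TestCompositeProfile:
    def test_delta_coverage_gives_spike_at_zero(self, toy_genome):
        sites = _sites([("chr1", s, s + 100, "+") for s in (1000, 5000, 9000)])
        arrays = {"chr1": np.zeros(100_000)}
        for s in (1050, 5050, 9050):
            arrays["chr1"][s] = 1.0
        pm = composite_profile(arrays, sites, half_width=200, genome=toy_genome)
        assert pm.channels["coverage"][pm.offsets == 0] == pytest.approx(1.0)
        assert pm.channels["coverage"].sum() == pytest.approx(1.0)

    def test_uniform_coverage_gives_flat_profile(self, toy_genome):
        sites = _sites([("chr1", 1000, 1100, "+"), ("chr1", 5000, 5100, "-")])
        arrays = {"chr1": np.full(100_000, 2.5)}
        pm = composite_profile(arrays, sites, half_width=100, genome=toy_genome)
        assert np.allclose(pm.channels["coverage"], 2.5)

    def test_simulated_coverage_gives_centered_trapezoid(self, toy_genome):
        sites = _sites([("chr1", 4850, 5150, "+", 4983, 5017)],
                       extra=("motif_start", "motif_end"))
        L, m = 100, 34
        bg = simulate_affinity_coverage(sites, L, 2000, toy_genome, rng=0)
        pm = composite_profile(bg, sites, half_width=150, genome=toy_genome)
        v = pm.channels["coverage"]
        assert int((v > 0).sum()) == 2 * L - m
        plateau = v[(pm.offsets >= -17) & (pm.offsets < 17)]  # the motif
        assert np.allclose(plateau, v.max())

    def test_truncated_sites_excluded(self, toy_genome):
        sites = _sites([("chr1", 0, 100, "+"), ("chr1", 5000, 5100, "+")])
        arrays = {"chr1": np.ones(100_000)}
        pm = composite_profile(arrays, sites, half_width=200, genome=toy_genome)
        assert pm.n_sites == 1

    def test_empty_sites_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            composite_profile({"chr1": np.ones(10)}, IntervalSet("s"), 5, toy_genome)


class TestNucleotideProfile:
    def test_single_shared_sequence_gives_unit_frequencies(self):
        seq = "A" * 100 + "ACGTACGT" + "A" * 100
        sites = _sites([("chr1", 95, 115, "+", 100, 108)],
                       extra=("motif_start", "motif_end"))
        pm = nucleotide_frequency_profile({"chr1": seq}, sites, flank=2)
        motif = [pm.channels[nt][(pm.offsets >= 0) & (pm.offsets < 8)]
                 for nt in "ACGT"]
        assert np.array_equal(motif[0], [1, 0, 0, 0, 1, 0, 0, 0])  # A positions
        assert np.array_equal(motif[2], [0, 0, 1, 0, 0, 0, 1, 0])  # G positions

    def test_minus_strand_reverse_complemented(self):
        # plus-strand genome holds revcomp(ACGT)=ACGT... use an asymmetric motif
        seq = "T" * 50 + "AAAC" + "T" * 50   # revcomp = GTTT
        sites = _sites([("chr1", 45, 60, "-", 50, 54)],
                       extra=("motif_start", "motif_end"))
        pm = nucleotide_frequency_profile({"chr1": seq}, sites, flank=0)
        aligned = "".join("ACGT"[int(np.argmax([pm.channels[nt][i] for nt in "ACGT"]))]
                          for i in range(4))
        assert aligned == "GTTT"

    def test_channels_sum_to_one(self, default_truth):
        cfg = SynthConfig(seed=41, genome=(("chr1", 2_000_000),), n_sites=400,
                          write_fasta=True)
        t = simulate_dataset(cfg)
        pm = nucleotide_frequency_profile(t.sequences, t.sites, flank=10)
        totals = sum(pm.channels[nt] for nt in "ACGT")
        assert np.allclose(totals, 1.0, atol=1e-9)

    def test_recovers_implanted_invariant_positions(self):
        cfg = SynthConfig(seed=42, genome=(("chr1", 2_000_000),), n_sites=500,
                          write_fasta=True)
        t = simulate_dataset(cfg)
        pm = nucleotide_frequency_profile(t.sequences, t.sites, flank=10)
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos in (7, 10, 12, 14, 15):   # 1-based 8, 11, 13, 15, 16
            nt = cfg.motif_consensus[pos]
            freq = pm.channels[nt][pm.offsets == pos][0]
            assert freq >= 0.85
        # flanks stay near the uniform background
        for nt in "ACGT":
            assert np.abs(pm.channels[nt][pm.offsets < 0] - 0.25).max() < 0.1


class TestSnpProfile:
    def test_uniform_snps_flat_ratio_with_mean_one(self, rng, toy_genome):
        snps = IntervalSet("snps", pd.DataFrame({
            "chrom": "chr1", "start": (s := rng.integers(0, 100_000, 20_000)),
            "end": s + 1}))
        sites = _sites([("chr1", c - 150, c + 150, "+")
                        for c in range(2000, 98_000, 4000)])
        pm = snp_density_profile(snps, sites, window=2000)
        assert pm.channels["ratio"].mean() == pytest.approx(1.0)
        assert pm.channels["ratio"].std() < 0.5

    def test_enrichment_recovered_against_closed_form(self):
        e, m, W = 3.0, 31, 2000
        cfg = SynthConfig(seed=31, snp=SnpModel(rate=0.01, enrichment=e))
        t = simulate_dataset(cfg)
        active = IntervalSet("act", t.sites.df[t.sites.df["activated"]])
        pm = snp_density_profile(t.snps, active, window=W)
        oracle = e / (1 + (e - 1) * m / W)
        # plateau offsets enriched under both orientations
        half = m // 2
        mask = (pm.offsets >= -half) & (pm.offsets <= m - half - 2)
        measured = pm.channels["ratio"][mask].mean()
        counts = pm.channels["count"][mask]
        se = measured / np.sqrt(counts.sum())
        assert abs(measured - oracle) < 3 * se

    def test_no_snps_in_windows_rejected(self, toy_genome):
        snps = IntervalSet("snps", pd.DataFrame(
            [("chr2", 5, 6)], columns=["chrom", "start", "end"]))
        sites = _sites([("chr1", 5000, 5100, "+")])
        with pytest.raises(ValueError):
            snp_density_profile(snps, sites)

    def test_smoothing_requires_odd_window(self, rng):
        snps = IntervalSet("snps", pd.DataFrame({
            "chrom": "chr1", "start": (s := rng.integers(0, 100_000, 1000)), "end": s + 1}))
        sites = _sites([("chr1", 5000, 5100, "+")])
        with pytest.raises(ValueError):
            snp_density_profile(snps, sites, smooth=4)


class TestBinnedLog2:
    def test_equal_tracks_give_zero(self, toy_genome):
        arr = {"chr1": np.arange(100_000, dtype=float)}
        out = binned_log2_enrichment(arr, {"chr1": arr["chr1"].copy()}, toy_genome)
        assert np.allclose(out["value"], 0.0)
        assert len(out) == 50  # 100 kb / 2 kb bins

    def test_doubled_sample_after_scaling_is_zero_then_unscaled_is_one(self, toy_genome):
        base = {"chr1": np.full(100_000, 10.0)}
        double = {"chr1": np.full(100_000, 20.0)}
        # library scaling equalises a global doubling
        out = binned_log2_enrichment(double, base, toy_genome)
        assert np.allclose(out["value"], 0.0, atol=1e-6)
        # a local doubling on half the genome survives scaling
        local = {"chr1": np.full(100_000, 10.0)}
        local["chr1"][:50_000] *= 2
        out2 = binned_log2_enrichment(local, base, toy_genome, pseudocount=1e-9)
        vals = out2["value"].to_numpy()
        assert np.allclose(vals[:25] - vals[25:], 1.0, atol=1e-3)

    def test_zero_bins_guarded_by_pseudocount(self, toy_genome):
        z = {"chr1": np.zeros(100_000)}
        out = binned_log2_enrichment(z, z, toy_genome)
        assert np.isfinite(out["value"]).all()
        assert np.allclose(out["value"], 0.0)

    def test_mismatched_genomes_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            binned_log2_enrichment({"chr9": np.ones(10)},
                                   {"chr1": np.ones(10)}, toy_genome)


def test_bedgraph_round_trip(tmp_path, toy_genome):
    df = pd.DataFrame([("chr1", 0, 10, 1.5), ("chr1", 20, 40, 2.0)],
                      columns=["chrom", "start", "end", "value"])
    p = tmp_path / "x.bedgraph"
    write_bedgraph(df, p)
    back = read_bedgraph(p)
    pd.testing.assert_frame_equal(df, back)
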