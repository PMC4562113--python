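# hotscan

Tools for asking how much of a protein's in-vitro DNA-binding repertoire is
actually used in vivo, and what blocks the rest. The motivating system is
meiotic recombination: a zinc-finger protein (PRDM9-like) binds thousands
of genomic sites in vitro with measurable relative affinities, but only
about half of them ever become recombination hotspots in vivo — the others
are silenced by prior chromatin state (H3K9me2/3 heterochromatin, lamina
association), with strong binding increasingly able to overcome the
barrier.

The package implements the full analysis chain as a library plus numbered
analysis drivers, exercised end-to-end on a synthetic-data generator that
emulates the study's data structure:

- **intervals** — 0-based half-open genomic intervals, BED3/5/6 and
  bedGraph I/O, any-overlap membership, merging.
- **synth** — toy genome with log-normal site affinities (ppm), chromatin
  domain mosaics, a logistic chromatin-barrier activation model emitting
  H3K4me3/DMC1/ChIP peaks, SNPs enriched at historically active motifs,
  and trapezoidal fragment-coverage peaks of span 2L − m.
- **classify** — sites → in_vivo / in_vitro_only / ambiguous from overlap
  with in-vivo mark peaks; ChIP-peak matching.
- **rscan** — detection of hotspot-deficient regions via the r-scan span
  statistic R_i^(r) = pos_{i+r} − pos_i with an empirical permutation null
  (10,000 position sets drawn from a background catalog or uniformly),
  +1/(n+1) p-values, BH-FDR over the top-10 spans of each order r ≤ 24,
  merge-then-localize region calling, and cross-referencing against
  binding-site density.
- **enrich** — usage fractions by genomic category with Poisson errors,
  affinity-quintile closed/open ratios, expression quartiles, Mann–Whitney
  comparisons, ppm normalization, sites/Mb and cM/Mb metrics.
- **profiles** — composite coverage metaplots, motif-aligned nucleotide
  frequencies, SNP-density ratio profiles, binned log2 enrichment tracks.
- **pipeline / cli** — one-config orchestration with a reproducibility
  manifest; `hotscan` console script with per-stage subcommands.

## Worked example

```bash
python analysis/01_simulate.py --seed 0 --out results/analysis/synthetic
python analysis/02_classify.py --seed 0
python analysis/03_rscan.py    --seed 0
python analysis/04_enrichment.py --seed 0
python analysis/05_profiles.py --seed 0
```

Stage 2 prints, for the default 2,000-site toy catalog:

```
2000 sites: 1008 in vivo, 951 in vitro only, 41 ambiguous
usage fraction (ambiguous excluded): 51.5 % +/- 1.6 %
protein ChIP: 95/95 peaks match catalog sites (100 %); ...
```

i.e. roughly half the catalog activates (the generator is calibrated to the
~48 % usage regime) and the sparse protein-ChIP peaks sit on catalog sites.
Stage 4 shows the chromatin barrier and its affinity dependence:

```
  gene+          478/839   = 0.570 +/- 0.026
  gene-          530/1120  = 0.473 +/- 0.021
closed/open usage ratio by affinity quintile (1 = heterochromatin has no effect):
  q1=0.28  q2=0.48  q3=0.46  q4=0.47  q5=0.66
affinity, in-vivo vs in-vitro-only: Mann-Whitney p = 4.84e-42 (medians 6.73 vs 3.72 ppm)
```

Usage is higher in gene bodies, suppressed in closed chromatin, and the
suppression fades toward the strongest affinity quintile. Stage 3 calls
hotspot-deficient regions whose in-vitro site density stays normal
(usage-deficient, not binding-deficient), and stage 5 recovers the
per-site coverage span 2L − m, the ≥0.85-frequency invariant motif
positions, and the ~3× SNP-density plateau at active motifs.

The same pipeline runs from one config via
`hotscan run-all --config config.yaml --seed 0 --out run/`.

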