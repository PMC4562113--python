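"""End-to-end orchestration: simulate -> classify -> rscan -> enrich -> profiles.

One RunConfig (optionally loaded from YAML) drives all stages into a single
output directory with a manifest recording the seed, a hash of the
configuration and a hash of every written file. Reruns with the same config
are byte-identical; no stage mutates another stage's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import enrich as _enrich
from . import profiles as _profiles
from . import rscan as _rscan
from . import synth as _synth
from .intervals import write_bed

STAGES = ("simulate", "classify", "rscan", "enrich", "profiles")


@dataclass
class RunConfig:
    outdir: str = "hotscan_run"
    seed: int = 0
    synth: _synth.SynthConfig = field(default_factory=_synth.SynthConfig)
    rscan: _rscan.RscanConfig = field(default_factory=lambda: _rscan.RscanConfig(n_null=2000))
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    snp_window: int = 2000
    profile_half_width: int = 1000
    nucleotide_flank: int = 10

    def __post_init__(self):
        # one run seed governs every stochastic component
        self.synth = replace(self.synth, seed=self.seed)
        self.rscan = replace(self.rscan, seed=self.seed + 1)
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("outdir", "seed", "snp_window", "profile_half_width", "nucleotide_flank"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            stages = {s: True for s in STAGES}
            stages.update(raw["stages"])
            kwargs["stages"] = stages
        if "synth" in raw:
            sy = dict(raw["synth"])
            if "domain_specs" in sy:
                sy["domain_specs"] = {k: _synth.DomainSpec(**v)
                                      for k, v in sy["domain_specs"].items()}
            if "activation" in sy:
                sy["activation"] = _synth.ActivationModel(**sy["activation"])
            if "snp" in sy:
                sy["snp"] = _synth.SnpModel(**sy["snp"])
            for key in ("genome", "gaps"):
                if key in sy:
                    sy[key] = tuple(tuple(x) for x in sy[key])
            kwargs["synth"] = _synth.SynthConfig(**sy)
        if "rscan" in raw:
            kwargs["rscan"] = _rscan.RscanConfig(**raw["rscan"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = _jsonable(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run all enabled stages; returns the output directory.

    Fails fast if a later stage is enabled without the stage that produces
    its inputs (the synthetic dataset).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if config.stages.get(s, True)]
    if enabled and enabled[0] != "simulate" and not (outdir / "synthetic" / "sites.bed").exists():
        raise FileNotFoundError("downstream stages need the simulate stage (or its outputs)")

    ran: list[str] = []
    truth = None
    if "simulate" in enabled:
        truth = _synth.simulate_dataset(config.synth, outdir / "synthetic")
        ran.append("simulate")
    else:
        truth = _synth.simulate_dataset(config.synth)  # in-memory reconstruction

    classified = None
    if "classify" in enabled:
        classified = _classify.classify_sites(truth.sites, truth.peaks["h3k4me3_a"],
                                              truth.peaks["h3k4me3_b"], truth.peaks["dmc1"])
        _classify.write_classification(classified, outdir / "classification.tsv",
                                       outdir / "classification_summary.json")
        match = _classify.match_chip_peaks(truth.peaks["prdm9_chip"], truth.sites)
        with open(outdir / "chip_match.json", "w") as fh:
            json.dump({"n_peaks": match.n_peaks, "n_matched": match.n_matched,
                       "percent_matched": match.percent_matched}, fh, indent=2)
            fh.write("\n")
        ran.append("classify")

    if "rscan" in enabled:
        if classified is None:
            classified = _classify.classify_sites(truth.sites, truth.peaks["h3k4me3_a"],
                                                  truth.peaks["h3k4me3_b"], truth.peaks["dmc1"])
        in_vivo = _rscan.positions_from_intervals(
            _int_set("in_vivo", classified.sites[classified.sites["status"] == "in_vivo"]))
        background = _rscan.positions_from_intervals(truth.sites)
        result = _rscan.call_deficient_regions(in_vivo, config.rscan,
                                               background_by_chrom=background,
                                               genome=config.synth.genome_obj,
                                               keep_null=False)
        result.spans.to_csv(outdir / "rscan_spans.tsv", sep="\t", index=False)
        write_bed(result.regions, outdir / "deficient_regions.bed")
        xref = _rscan.cross_reference_deficiency(result.regions, truth.sites,
                                                 config.synth.genome_obj)
        xref.to_csv(outdir / "deficiency_crossref.tsv", sep="\t", index=False)
        ran.append("rscan")

    if "enrich" in enabled:
        if classified is None:
            classified = _classify.classify_sites(truth.sites, truth.peaks["h3k4me3_a"],
                                                  truth.peaks["h3k4me3_b"], truth.peaks["dmc1"])
        genome = config.synth.genome_obj
        rows = []
        categories = dict(truth.domains)
        categories["gene"] = truth.genes
        for name, dom in categories.items():
            if len(dom) == 0:
                continue
            for u in _enrich.binary_usage(classified, dom, label=name):
                rows.append(dataclasses.asdict(u))
        if len(truth.genes) >= 4:
            for q, sub in enumerate(_enrich.expression_quartiles(truth.genes), start=1):
                u = _enrich.usage_fraction(classified, sub, label=f"expression_q{q}")
                rows.append(dataclasses.asdict(u))
        pd.DataFrame(rows).to_csv(outdir / "category_usage.tsv", sep="\t", index=False)

        closed, _open = _enrich.closed_chromatin(truth.domains, genome)
        quint = _enrich.affinity_quintile_ratio(classified, closed, genome)
        quint.to_csv(outdir / "quintile_ratios.tsv", sep="\t", index=False)
        ran.append("enrich")

    if "profiles" in enabled:
        pm = _profiles.snp_density_profile(truth.snps, truth.sites, window=config.snp_window)
        pm.to_frame().to_csv(outdir / "snp_profile.tsv", sep="\t", index=False)
        if truth.sequences is not None:
            nf = _profiles.nucleotide_frequency_profile(truth.sequences, truth.sites,
                                                        flank=config.nucleotide_flank)
            nf.to_frame().to_csv(outdir / "nucleotide_profile.tsv", sep="\t", index=False)
        if config.synth.coverage_depth > 0:
            import numpy as np
            cov = _synth.simulate_affinity_coverage(
                truth.sites, config.synth.fragment_length, config.synth.coverage_depth,
                config.synth.genome_obj, rng=np.random.default_rng(config.seed + 2))
            cp = _profiles.composite_profile(cov, truth.sites,
                                             config.profile_half_width,
                                             config.synth.genome_obj)
            cp.to_frame().to_csv(outdir / "composite_profile.tsv", sep="\t", index=False)
        ran.append("profiles")

    files = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "stages_run": ran,
        "stages_skipped": [s for s in STAGES if s not in ran],
        "files": {f: _sha256(outdir / f) for f in files},
    }
    manifest["run_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _int_set(label, df):
    from .intervals import IntervalSet
    return IntervalSet(label, df)
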