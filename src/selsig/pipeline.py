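"""End-to-end orchestration: QC → ROH/F_ROH/islands and LD decay per
population (within-population arm), SNP intersection → varLD scan → region
calling → annotation (between-population arm).

Every run writes a ``manifest.json`` carrying the package version and a hash
of the configuration; stages that re-use intermediates refuse to proceed on
a hash mismatch.  All tables are TSV with fixed float formatting, so reruns
on identical inputs are byte-identical (plots exempt).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import overlap_annotate, read_features_bed
from .io import GenotypePanel, genome_map, read_plink, write_regions_bed
from .ld import binned_decay, decay_curve, ld_pairs
from .qc import QcThresholds, apply_qc, intersect_snps
from .roh import (DEFAULT_CLASS_RULES, call_islands, detect_roh_panel,
                  froh_table, roh_incidence)
from .varld import VarLdConfig, call_varld_regions, varld_scan
from . import plots

logger = logging.getLogger("selsig")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration for a full two-population run."""

    input_prefixes: dict[str, str]        # population name -> PLINK prefix
    output_dir: str
    roh_qc: QcThresholds = field(default_factory=lambda: QcThresholds(apply_maf=False))
    ld_qc: QcThresholds = field(default_factory=QcThresholds)
    island_top_fraction: float = 0.01
    island_merge_gap_snps: int = 0
    varld: VarLdConfig = field(default_factory=VarLdConfig)
    features_bed: str | None = None
    annotate_flank_bp: int = 0
    max_ld_dist_bp: int = 1_000_000
    seed: int = 0
    write_pairs: bool = False             # the pair table is large
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("roh_qc", QcThresholds), ("ld_qc", QcThresholds),
                         ("varld", VarLdConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _write_manifest(outdir: Path, cfg: RunConfig, stage: str) -> None:
    manifest = {"tool": "selsig", "version": __version__,
                "config_hash": cfg.config_hash(), "stage": stage}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def check_manifest(outdir: Path, cfg: RunConfig) -> None:
    """Refuse to mix intermediates produced under a different config."""
    path = Path(outdir) / "manifest.json"
    if path.exists():
        manifest = json.loads(path.read_text())
        if manifest.get("config_hash") != cfg.config_hash():
            raise RuntimeError(
                f"{path}: intermediates were produced under config hash "
                f"{manifest.get('config_hash')} != {cfg.config_hash()}; "
                "refusing to proceed")


def _load(cfg: RunConfig, name: str) -> GenotypePanel:
    return read_plink(cfg.input_prefixes[name])


def run_within(cfg: RunConfig) -> dict:
    """Per-population arm: QC (both profiles), ROH, F_ROH, islands, LD decay."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    check_manifest(outdir, cfg)
    results = {}
    decay_curves = {}
    for name in cfg.input_prefixes:
        pop_dir = outdir / name
        pop_dir.mkdir(exist_ok=True)
        panel = _load(cfg, name)
        logger.info("[%s] loaded %d samples x %d SNPs", name,
                    panel.n_samples, panel.n_snps)

        roh_panel, roh_report = apply_qc(panel, cfg.roh_qc)
        roh_report.to_tsv(pop_dir / "qc_report_roh_profile.tsv")
        ld_panel, ld_report = apply_qc(panel, cfg.ld_qc)
        ld_report.to_tsv(pop_dir / "qc_report_ld_profile.tsv")

        genome = genome_map(roh_panel)
        per_sample, summary = froh_table(roh_panel, genome)
        _write_tsv(per_sample, pop_dir / "froh.tsv")
        summary.to_csv(pop_dir / "froh_summary.tsv", sep="\t",
                       float_format=FLOAT_FORMAT)

        segments = detect_roh_panel(roh_panel, DEFAULT_CLASS_RULES[1],
                                    class_label=1)
        _write_tsv(segments, pop_dir / "roh_segments_1mb.tsv")
        track = roh_incidence(segments, roh_panel.markers, roh_panel.n_samples)
        islands, threshold = call_islands(track, cfg.island_top_fraction,
                                          cfg.island_merge_gap_snps)
        incidence_df = track.markers.assign(count=track.counts)
        _write_tsv(incidence_df, pop_dir / "roh_incidence.tsv")
        write_regions_bed(islands, pop_dir / "roh_islands.bed")

        pairs = ld_pairs(ld_panel, cfg.max_ld_dist_bp)
        if cfg.write_pairs:
            _write_tsv(pairs, pop_dir / "ld_pairs.tsv")
        curve = decay_curve(pairs)
        _write_tsv(curve, pop_dir / "ld_decay.tsv")
        decay_curves[name] = binned_decay(pairs, n_bins=20,
                                          max_dist_bp=cfg.max_ld_dist_bp)

        if cfg.make_plots:
            plots.manhattan(track.markers["chrom"], track.markers["pos_bp"],
                            track.counts, thresholds=[threshold],
                            ylabel="samples in ROH",
                            path=pop_dir / "roh_islands.png", title=name)
        results[name] = {
            "roh_panel": roh_panel, "ld_panel": ld_panel,
            "froh": per_sample, "froh_summary": summary,
            "segments": segments, "islands": islands,
            "island_threshold": threshold, "decay": curve,
        }
    if cfg.make_plots and decay_curves:
        plots.decay_plot(decay_curves, path=outdir / "ld_decay.png")
    _write_manifest(outdir, cfg, stage="within")
    return results


def run_between(cfg: RunConfig, within: dict | None = None) -> dict:
    """Between-population arm on the intersected LD-profile panels."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    check_manifest(outdir, cfg)
    names = list(cfg.input_prefixes)
    if len(names) != 2:
        raise ValueError("the between-population arm needs exactly 2 panels")
    if within is None:
        within = run_within(cfg)
    panel_a, panel_b = (within[n]["ld_panel"] for n in names)
    panel_a, panel_b = intersect_snps(panel_a, panel_b)
    logger.info("intersected marker set: %d SNPs", panel_a.n_snps)

    track = varld_scan(panel_a, panel_b, cfg.varld)
    _write_tsv(track, outdir / "varld_track.tsv")
    regions = call_varld_regions(track, cfg.varld.top_fractions)
    for frac, regs in regions.items():
        write_regions_bed(regs, outdir / f"varld_regions_top{frac:g}.bed")

    annotations = pd.DataFrame()
    if cfg.features_bed:
        features = read_features_bed(cfg.features_bed)
        all_regions = [r for n in names for r in within[n]["islands"]]
        all_regions += [r for regs in regions.values() for r in regs]
        annotations = overlap_annotate(all_regions, features,
                                       cfg.annotate_flank_bp)
        _write_tsv(annotations, outdir / "annotations.tsv")

    if cfg.make_plots:
        thresholds = [track["std_score"].quantile(1 - f)
                      for f in cfg.varld.top_fractions]
        plots.manhattan(track["chrom"], track["anchor_pos_bp"],
                        track["std_score"], thresholds=thresholds,
                        ylabel="standardized varLD score",
                        path=outdir / "varld.png")
    _write_manifest(outdir, cfg, stage="between")
    return {"track": track, "regions": regions, "annotations": annotations}


def run_all(cfg: RunConfig) -> dict:
    within = run_within(cfg)
    between = run_between(cfg, within)
    return {"within": within, "between": between}
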