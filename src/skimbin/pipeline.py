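"""End-to-end orchestration with a single validated JSON config.

Stages run in dependency order (simulate -> code/screen -> bins ->
breakpoints -> impute/hold-out -> map -> scan), exchanging plain files
(TSV/VCF/JSON) so each stage can also be run on its own.  A run manifest
records the tool version, config hash, per-stage output checksums and
wall-clock times; deterministic stages reproduce identical checksums under
the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from skimbin import __version__, vcfio
from skimbin.bins import BinConfig, bin_matrix, make_bins
from skimbin.breakpoints import (
    BreakpointConfig,
    detect_breakpoints,
    summarize_recombination,
)
from skimbin.codes import code_to_str
from skimbin.genmap import MapConfig, build_map
from skimbin.impute import ImputeConfig, holdout_accuracy, impute_matrix
from skimbin.qtl import ScanConfig, permutation_threshold, pool_phenotype, single_marker_scan
from skimbin.ril_calls import screen_heterozygous_lines
from skimbin.simulate import (
    GenomeSpec,
    QTLSpec,
    SimConfig,
    scaled_preset,
    simulate_parents,
    simulate_phenotypes,
    simulate_ril_population,
    simulate_skim_calls,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageToggles", "validate_config", "run_pipeline"]


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulate: bool = True
    bins: bool = True
    breakpoints: bool = True
    impute: bool = True
    holdout: bool = True
    genetic_map: bool = True
    scan: bool = False


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    stages: StageToggles = Field(default_factory=StageToggles)
    genome: Optional[GenomeSpec] = None
    sim: SimConfig = Field(default_factory=SimConfig)
    qtl: Optional[QTLSpec] = None
    trait: str = "trait"
    bin: BinConfig = Field(default_factory=BinConfig)
    breakpoint: BreakpointConfig = Field(default_factory=BreakpointConfig)
    impute: ImputeConfig = Field(default_factory=ImputeConfig)
    genetic_map: MapConfig = Field(default_factory=MapConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    max_h_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    write_vcf: bool = False
    # inputs used when the simulate stage is off
    key_tsv: Optional[str] = None
    coded_tsv: Optional[str] = None
    lengths_tsv: Optional[str] = None
    pheno_tsv: Optional[str] = None


def validate_config(path: str) -> PipelineConfig:
    """Load, default-fill and validate a pipeline config file.

    Unknown keys are rejected (naming the key); if the simulate stage is off
    the downstream stages need explicit input paths, which must exist.
    """
    raw = json.loads(Path(path).read_text())
    cfg = PipelineConfig.model_validate(raw)  # raises naming unknown keys
    if not cfg.stages.simulate:
        needed = {"key_tsv": cfg.key_tsv, "coded_tsv": cfg.coded_tsv,
                  "lengths_tsv": cfg.lengths_tsv}
        if cfg.stages.scan:
            needed["pheno_tsv"] = cfg.pheno_tsv
        for name, p in needed.items():
            if p is None:
                raise ValueError(
                    f"simulate stage is off but input {name} is not set"
                )
            if not Path(p).exists():
                raise ValueError(f"input path {name}={p!r} does not exist")
    if cfg.stages.scan and cfg.stages.simulate and cfg.qtl is None:
        raise ValueError("scan stage with simulated data requires a qtl spec")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: Dict = {
        "tool": "skimbin",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            cfg.model_dump_json().encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage: str, t0: float, paths: List[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in paths},
        }
        log.info("stage %s done (%.2fs)", stage, time.time() - t0)

    if cfg.stages.simulate:
        t0 = time.time()
        genome = cfg.genome or scaled_preset()
        sim = cfg.sim.model_copy(update={"seed": cfg.seed})
        key = simulate_parents(genome, seed=cfg.seed)
        truth = simulate_ril_population(key, sim, genome)
        coded = simulate_skim_calls(truth, key, sim, keep_read_counts=cfg.write_vcf)
        lengths = genome.length_map
        vcfio.write_key_tsv(key, out / "key.tsv")
        vcfio.write_lengths_tsv(lengths, out / "lengths.tsv")
        vcfio.write_coded_tsv(coded.drop(columns=[c for c in ("ad_p1", "ad_p2") if c in coded], errors="ignore"), out / "coded.tsv")
        truth.crossovers(parental_only=False).to_csv(
            out / "truth_breakpoints.tsv", sep="\t", index=False
        )
        paths = [out / "key.tsv", out / "lengths.tsv", out / "coded.tsv",
                 out / "truth_breakpoints.tsv"]
        if cfg.write_vcf:
            vcfio.write_key_vcf(key, out / "key.vcf", lengths=lengths)
            vcfio.write_progeny_vcf(key, coded, out / "progeny.vcf", lengths=lengths)
            paths += [out / "key.vcf", out / "progeny.vcf"]
        pheno = None
        if cfg.qtl is not None:
            pheno = simulate_phenotypes(truth, cfg.qtl, seed=cfg.seed, trait=cfg.trait)
            vcfio.write_phenotypes_tsv(pheno, out / "phenotypes.tsv")
            paths.append(out / "phenotypes.tsv")
        coded = coded[["line", "chrom", "pos", "code"]]
        record("simulate", t0, paths)
    else:
        key = vcfio.read_key_tsv(cfg.key_tsv)
        coded = vcfio.read_coded_tsv(cfg.coded_tsv)
        lengths = vcfio.read_lengths_tsv(cfg.lengths_tsv)
        pheno = vcfio.read_phenotypes_tsv(cfg.pheno_tsv) if cfg.pheno_tsv else None

    t0 = time.time()
    qc, coded = screen_heterozygous_lines(coded, cfg.max_h_fraction)
    qc.to_csv(out / "line_qc.tsv", sep="\t", index=False)
    record("screen", t0, [out / "line_qc.tsv"])

    binmat = None
    if cfg.stages.bins:
        t0 = time.time()
        idx = make_bins(lengths, cfg.bin)
        binmat = bin_matrix(coded, idx, cfg.bin)
        binmat.to_tsv(out / "bins.tsv")
        binmat.counts_to_tsv(out / "bin_counts.tsv")
        record("bins", t0, [out / "bins.tsv", out / "bin_counts.tsv"])

    if cfg.stages.breakpoints:
        t0 = time.time()
        bps = detect_breakpoints(coded, lengths, cfg.breakpoint)
        bp_out = bps.copy()
        for col in ("left_state", "right_state"):
            bp_out[col] = [code_to_str(c) for c in bp_out[col]]
        bp_out.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        summary = summarize_recombination(
            bps, coded["line"].nunique(), lengths
        )
        vcfio.write_json(summary.to_dict(), out / "recombination_summary.json")
        record("breakpoints", t0,
               [out / "breakpoints.tsv", out / "recombination_summary.json"])

    if cfg.stages.impute:
        t0 = time.time()
        imp = cfg.impute.model_copy(update={"seed": cfg.seed})
        imputed, conflicts = impute_matrix(coded, key, imp)
        vcfio.write_coded_tsv(imputed, out / "imputed.tsv")
        paths = [out / "imputed.tsv"]
        if cfg.stages.holdout:
            report = holdout_accuracy(coded, key, imp)
            vcfio.write_json(
                {**report.to_dict(), "n_conflicts": conflicts},
                out / "holdout_report.json",
            )
            paths.append(out / "holdout_report.json")
        record("impute", t0, paths)

    if cfg.stages.genetic_map and binmat is not None:
        t0 = time.time()
        gmap = build_map(binmat, cfg.genetic_map)
        gmap.table.to_csv(out / "genetic_map.tsv", sep="\t", index=False)
        gmap.removal_log.to_csv(out / "marker_removal.tsv", sep="\t", index=False)
        vcfio.write_json(
            {
                "total_cm": gmap.total_cm,
                "total_cm_uncorrected": gmap.total_cm_uncorrected,
                "per_chromosome_cm": gmap.totals,
            },
            out / "genetic_map_summary.json",
        )
        record("genetic_map", t0,
               [out / "genetic_map.tsv", out / "marker_removal.tsv",
                out / "genetic_map_summary.json"])

    if cfg.stages.scan and binmat is not None and pheno is not None:
        t0 = time.time()
        scan_cfg = cfg.scan.model_copy(update={"seed": cfg.seed})
        y = pool_phenotype(pheno, cfg.trait)
        thr, _ = permutation_threshold(binmat, y, scan_cfg)
        res = single_marker_scan(binmat, y, scan_cfg, threshold=thr)
        res.table.to_csv(out / f"scan_{cfg.trait}.tsv", sep="\t", index=False)
        vcfio.write_json(
            {
                "trait": cfg.trait,
                "threshold": thr,
                "significant": res.significant.to_dict(orient="records"),
            },
            out / f"scan_{cfg.trait}_summary.json",
        )
        record("scan", t0,
               [out / f"scan_{cfg.trait}.tsv", out / f"scan_{cfg.trait}_summary.json"])

    vcfio.write_json(manifest, out / "manifest.json")
    return manifest
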