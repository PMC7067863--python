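"""End-to-end pipeline: windows -> detectors -> consensus -> counting -> diffmeth.

`PipelineConfig` mirrors every threshold of the method with the published
values as defaults; `run()` chains the stages on in-memory objects and (when
an output directory is given) writes the intermediate artifacts plus a JSON
manifest with checksums, so that reruns under the same config and seed are
byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import detectors as det
from . import diffmeth as dm
from . import genomic_io as gio
from . import synthetic as syn
from . import windows as win
from .defaults import DEFAULTS

log = logging.getLogger("meripseq")


@dataclass
class PipelineConfig:
    """Paths plus every stage parameter; defaults are the published values."""

    genome_fasta: str | None = None
    gtf: str | None = None
    samples_tsv: str | None = None
    coverage_dir: str | None = None  # {sample_id}.bedgraph
    output_dir: str = "merip_out"
    truth_tsv: str | None = None
    narrowpeak_dir: str | None = None  # optional external MACS2 {ip_sample}.narrowPeak

    window_size: int = DEFAULTS["window_size"]
    window_step: int = DEFAULTS["window_step"]
    read_length: int = DEFAULTS["read_length"]
    min_ip_reads: int = DEFAULTS["min_ip_reads"]
    fisher_alpha: float = DEFAULTS["fisher_alpha"]
    rpmf_threshold: float = DEFAULTS["rpmf_threshold"]
    rpmf_mode: str = "difference"
    pom_min: float = DEFAULTS["pom_min"]
    poi_min: float = DEFAULTS["poi_min"]
    poisson_qmax: float = DEFAULTS["poisson_qmax"]
    min_samples: int = DEFAULTS["min_samples"]
    min_techniques: int = DEFAULTS["min_techniques"]
    peak_width: int = DEFAULTS["peak_width"]
    min_cpm: float = DEFAULTS["min_cpm"]
    min_cpm_samples: int = DEFAULTS["min_cpm_samples"]
    lfc_threshold: float = DEFAULTS["lfc_threshold"]
    adj_p_threshold: float = DEFAULTS["adj_p_threshold"]
    condition_ref: str | None = None
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "window_size", "window_step", "read_length", "peak_width",
            "min_samples", "min_techniques",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        nonneg = ["min_ip_reads", "min_cpm", "min_cpm_samples", "lfc_threshold"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"config: {name} must be non-negative")
        for name in ("fisher_alpha", "poisson_qmax", "adj_p_threshold"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"config: {name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    peaks: list[gio.ConsensusPeak]
    sites_per_technique: dict
    peak_diff: pd.DataFrame | None
    gene_diff: pd.DataFrame | None
    classification: pd.DataFrame | None
    scores: dict[str, float] | None
    manifest: dict[str, str] = field(default_factory=dict)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def call_peaks(
    tracks: Mapping[str, gio.CoverageTrack],
    samples: Sequence[gio.SampleMetadata],
    genes: Sequence[gio.GeneModel],
    cfg: PipelineConfig | None = None,
    genome: Mapping[str, str] | None = None,
    external_narrowpeaks: Mapping[str, Sequence[dict]] | None = None,
) -> tuple[list[gio.ConsensusPeak], dict]:
    """The consensus peak caller: windows, four detectors per IP/Input pair,
    occurrence filter, per-technique merge+recentre, technique consensus."""
    cfg = cfg or PipelineConfig()
    pairs = gio.pair_samples(samples)
    grid = win.generate_windows(genes, cfg.window_size, cfg.window_step)
    log.info("windows: %d over %d genes", len(grid), len(genes))
    all_results: list[det.DetectionResult] = []
    for ip_s, in_s in pairs:
        pair_tracks = [tracks[ip_s.sample_id], tracks[in_s.sample_id]]
        m = win.count_reads_in_windows(pair_tracks, grid, cfg.read_length)
        mf = win.filter_min_ip_coverage(m, ip_s.sample_id, cfg.min_ip_reads)
        log.info(
            "pair %s: %d/%d windows pass >%d-read IP filter",
            ip_s.pair_id, len(mf.windows), len(grid), cfg.min_ip_reads,
        )
        all_results += det.fisher_detect(mf, ip_s.sample_id, in_s.sample_id,
                                         cfg.fisher_alpha)
        all_results += det.rpmf_detect(mf, ip_s.sample_id, in_s.sample_id,
                                       cfg.rpmf_threshold, cfg.rpmf_mode)
        all_results += det.poi_detect(
            tracks[ip_s.sample_id], tracks[in_s.sample_id], genes, mf.windows,
            cfg.pom_min, cfg.poi_min,
        )
        if external_narrowpeaks and ip_s.sample_id in external_narrowpeaks:
            all_results += det.narrowpeak_to_results(
                external_narrowpeaks[ip_s.sample_id], mf.windows, ip_s.sample_id
            )
        else:
            all_results += det.poisson_enrich_detect(
                mf, ip_s.sample_id, in_s.sample_id, cfg.poisson_qmax
            )
    kept = cns.occurrence_filter(all_results, cfg.min_samples)
    support = cns.window_support(all_results)
    ip_tracks = [tracks[ip.sample_id] for ip, _ in pairs]
    med = cns.median_ip_coverage(ip_tracks)
    sites = cns.merge_and_recenter(kept, grid, med, support, cfg.peak_width)
    for tech, slist in sites.items():
        log.info("technique %s: %d candidate sites", tech, len(slist))
    chrom_lengths = {c: int(arr.size) for c, arr in med.items()}
    peaks = cns.combine_techniques(sites, med, cfg.min_techniques,
                                   cfg.peak_width, chrom_lengths)
    cns.annotate_peaks(peaks, genes, genome)
    log.info("consensus peaks: %d", len(peaks))
    return peaks, sites


def run_differential(
    tracks: Mapping[str, gio.CoverageTrack],
    samples: Sequence[gio.SampleMetadata],
    genes: Sequence[gio.GeneModel],
    peaks: Sequence[gio.ConsensusPeak],
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None, pd.DataFrame | None]:
    """Peak-level (IP counts) and gene-level (Input counts) differential stage."""
    cfg = cfg or PipelineConfig()
    ip_samples = [s for s in samples if s.role == "IP"]
    input_samples = [s for s in samples if s.role == "Input"]
    conditions = sorted({s.condition for s in samples})
    ref = cfg.condition_ref or ("CONV" if "CONV" in conditions else conditions[0])
    others = [c for c in conditions if c != ref]
    if not others:
        return None, None, None
    contrast_cond = others[0]

    gene_feats = [(g.gene_id, g.chrom, g.start, g.end) for g in genes]
    gene_counts = win.count_reads_in_features(
        [tracks[s.sample_id] for s in input_samples], gene_feats, cfg.read_length
    )
    peak_ids = [f"peak_{i + 1}" for i in range(len(peaks))]
    peak_feats = [
        (pid, p.chrom, p.start, p.end) for pid, p in zip(peak_ids, peaks)
    ]
    peak_counts = win.count_reads_in_features(
        [tracks[s.sample_id] for s in ip_samples], peak_feats, cfg.read_length
    )

    gene_diff = peak_diff = classification = None
    gf = dm.filter_by_cpm(gene_counts, input_samples, cfg.min_cpm, cfg.min_cpm_samples)
    log.info("genes kept by CPM filter: %d/%d", gf.shape[0], gene_counts.shape[0])
    if gf.shape[0] >= 2:
        gene_model = dm.DifferentialModel(gf, list(input_samples), condition_ref=ref)
        gene_diff = gene_model.fit().contrast(
            contrast_cond, lfc=cfg.lfc_threshold, alpha=cfg.adj_p_threshold
        )
    if len(peak_feats) >= 2:
        pf = dm.filter_by_cpm(
            peak_counts, ip_samples, cfg.min_cpm, cfg.min_cpm_samples,
            ip_procedure_rule=True,
        )
        log.info("peaks kept by CPM filters: %d/%d", pf.shape[0], peak_counts.shape[0])
        if pf.shape[0] >= 2:
            peak_model = dm.DifferentialModel(pf, list(ip_samples), condition_ref=ref)
            peak_diff = peak_model.fit().contrast(
                contrast_cond, lfc=cfg.lfc_threshold, alpha=cfg.adj_p_threshold
            )
    if gene_diff is not None and peak_diff is not None:
        peak_gene = {pid: p.gene_id for pid, p in zip(peak_ids, peaks)}
        classification = dm.classify_peaks_vs_expression(peak_diff, gene_diff, peak_gene)
    return peak_diff, gene_diff, classification


STAGES = ("windows", "detect", "consensus", "count", "diffmeth", "score")


def run(cfg: PipelineConfig, from_stage: str = "windows") -> PipelineResult:
    """Execute the pipeline from disk inputs, writing artifacts + manifest."""
    cfg.validate()
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; stages: {STAGES}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = gio.read_sample_table(cfg.samples_tsv)
    genes = gio.read_gene_models(cfg.gtf)
    cov_dir = Path(cfg.coverage_dir)
    tracks = {
        s.sample_id: gio.read_coverage(cov_dir / f"{s.sample_id}.bedgraph", s)
        for s in samples
    }
    genome = None
    if cfg.genome_fasta:
        from pyfaidx import Fasta

        fa = Fasta(cfg.genome_fasta)
        genome = {name: str(fa[name][:]) for name in fa.keys()}
    external = None
    if cfg.narrowpeak_dir:
        external = {}
        for s in samples:
            if s.role != "IP":
                continue
            np_path = Path(cfg.narrowpeak_dir) / f"{s.sample_id}.narrowPeak"
            if np_path.exists():
                external[s.sample_id] = gio.read_narrowpeak(np_path)

    peaks_bed = out / "consensus_peaks.bed"
    if from_stage in ("windows", "detect", "consensus") or not peaks_bed.exists():
        peaks, sites = call_peaks(tracks, samples, genes, cfg, genome, external)
        gio.write_peaks_bed(peaks, peaks_bed)
    else:
        peaks = gio.read_peaks_bed(peaks_bed)
        sites = {}
        log.info("resuming from %s: reusing %d peaks", from_stage, len(peaks))

    peak_diff, gene_diff, classification = run_differential(
        tracks, samples, genes, peaks, cfg
    )
    artifacts = [peaks_bed]
    if peak_diff is not None:
        p = out / "differential_peaks.tsv"
        peak_diff.to_csv(p, sep="\t", index=False)
        artifacts.append(p)
    if gene_diff is not None:
        p = out / "differential_genes.tsv"
        gene_diff.to_csv(p, sep="\t", index=False)
        artifacts.append(p)
    if classification is not None:
        p = out / "peak_vs_expression.tsv"
        classification.to_csv(p, sep="\t", index=False)
        artifacts.append(p)

    scores = None
    if cfg.truth_tsv:
        truth = syn.read_truth(cfg.truth_tsv)
        scores = syn.score_peaks_against_truth(peaks, truth)
        p = out / "scores.tsv"
        pd.DataFrame([scores]).to_csv(p, sep="\t", index=False)
        artifacts.append(p)

    manifest = {str(a.relative_to(out)): _checksum(a) for a in artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(peaks, sites, peak_diff, gene_diff, classification,
                          scores, manifest)


def simulate_to_dir(cfg: syn.SimulationConfig, out_dir: str | Path) -> PipelineConfig:
    """Run the simulator and write FASTA/GTF/bedGraph/metadata/truth to disk.

    Returns a PipelineConfig pointing at the written inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txm = syn.simulate_transcriptome(cfg)
    exp = syn.simulate_experiment(cfg, txm)
    syn.write_fasta(txm.genome, out / "genome.fa")
    gio.write_gene_models(txm.genes, out / "genes.gtf")
    cov = out / "coverage"
    cov.mkdir(exist_ok=True)
    for sid, track in exp.tracks.items():
        gio.write_coverage_bedgraph(track, cov / f"{sid}.bedgraph")
    gio.write_sample_table(exp.samples, out / "samples.tsv")
    syn.write_truth(exp.truth, out / "truth.tsv")
    return PipelineConfig(
        genome_fasta=str(out / "genome.fa"),
        gtf=str(out / "genes.gtf"),
        samples_tsv=str(out / "samples.tsv"),
        coverage_dir=str(cov),
        truth_tsv=str(out / "truth.tsv"),
        output_dir=str(out / "results"),
        seed=cfg.seed,
    )
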