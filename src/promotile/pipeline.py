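"""End-to-end orchestration: simulate/load -> scan -> segment -> co-localize.

``run_all`` executes the whole validation workflow from one configuration
and returns a report of counts at every stage: promoter hits in the
stringent (p < 1e-4) and relaxed (1e-4 <= p < 1e-3) significance bands,
TARs per strand, TSS annotation categories, co-localized matches per band
and the permutation/Fisher statistics.  The relaxed band is only consulted
for TSSs left unmatched at high stringency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import scan as sc
from . import simulate as sim
from . import tars as tt
from . import tiling as tl
from .colocalize import (
    NullDistribution,
    colocalize,
    log10_fisher_cooccurrence,
    matches_to_dataframe,
    permutation_null,
)
from .genome import intergenic_spans, read_annotation, read_genome
from .motifs import sigma70_pwm
from .pwm import build_pwm, read_sites, spacer_variants

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    # inputs; leave None with simulate=True to generate synthetic data
    genome_fasta: str | None = None
    annotation_gff: str | None = None
    sites_file: str | None = None  # aligned promoter sites; None -> consensus model
    probe_table: str | None = None
    simulate: bool = True
    sim_params: dict = field(default_factory=dict)
    # stage parameters
    upstream_window: int = 100
    upstream_min_len: int = 25
    p_stringent: float = 1e-4
    p_relaxed: float = 1e-3
    spacer_lengths: tuple[int, int] = (16, 22)
    native_spacer: int = 17
    location_filter: str = "keep_all"
    alpha: float = 1e-6
    pool_strands: bool = False
    max_gap: int = 60
    min_tar_len: int = 120
    coloc_cutoff: int = 40
    tss_drop_groups: tuple = ()  # e.g. ("E",) to exclude low-expression TSSs
    n_reps: int = 10000
    flank_window: int = 140
    seed: int = 1
    outdir: str | None = None


@dataclass
class PipelineResult:
    report: dict
    hits_stringent: list
    hits_relaxed: list
    tars: dict
    tss: list
    matches: list
    null: NullDistribution
    truth: sim.SyntheticTruth | None = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**data)
    if isinstance(cfg.spacer_lengths, list):
        cfg.spacer_lengths = tuple(cfg.spacer_lengths)
    return cfg


def _stage(log, name, msg):
    if log is not None:
        log(f"[{name}] {msg}")


def run_all(config: PipelineConfig, log=None) -> PipelineResult:
    report: dict = {"seed": config.seed}
    truth = None

    # ---- inputs
    if config.simulate:
        params = sim.SimulationParams(seed=config.seed, **config.sim_params)
        genome, genes, truth = sim.simulate_genome(params)
        tracks_raw = sim.simulate_tiling(truth)
        _stage(log, "simulate", f"genome {genome.length} nt, {len(genes)} genes, "
               f"{len(truth.promoters)} planted promoters")
        report["planted_promoters"] = len(truth.promoters)
    else:
        if not (config.genome_fasta and config.annotation_gff and config.probe_table):
            raise ValueError("without --simulate, genome, annotation and probes are required")
        genome = read_genome(config.genome_fasta)
        genes = read_annotation(config.annotation_gff, genome)
        tracks_raw = tl.read_probe_table(config.probe_table)
    _, intergenic_frac = intergenic_spans(genome, genes)
    report["genome_length"] = genome.length
    report["n_genes"] = len(genes)
    report["intergenic_fraction"] = round(intergenic_frac, 4)

    # ---- promoter model (background = genome mononucleotide frequencies,
    # so scan p-values are calibrated to the scanned composition)
    counts = np.array([genome.sequence.count(b) for b in "ACGT"], dtype=float)
    bg = counts / counts.sum()
    if config.sites_file:
        sites = read_sites(config.sites_file)
        base = build_pwm(sites, name="sigma70", background=bg)
        if not base.spacer_cols:
            raise ValueError("sites-derived matrix needs spacer columns; use the TSV format")
    else:
        base = sigma70_pwm(config.native_spacer, background=bg)
    pwms = spacer_variants(base, range(config.spacer_lengths[0], config.spacer_lengths[1] + 1))
    report["n_matrices"] = len(pwms)

    # ---- scan at the relaxed cutoff, then split into bands
    hits_all = sc.scan_genome(genome, pwms, p_cutoff=config.p_relaxed)
    hits_all = sc.bonferroni(hits_all, sc.default_n_tests(genome, pwms))
    hits_all = sc.classify_location(hits_all, genes, config.location_filter)
    hits_all = sc.dedup_overlaps(hits_all)
    hits_str = [h for h in hits_all if h.pvalue < config.p_stringent]
    hits_rel = [h for h in hits_all if config.p_stringent <= h.pvalue < config.p_relaxed]
    report["hits_stringent"] = len(hits_str)
    report["hits_relaxed_band"] = len(hits_rel)
    report["hits_bonferroni_significant"] = sum(
        1 for h in hits_str if h.corrected_pvalue is not None and h.corrected_pvalue < 0.05
    )
    _stage(log, "scan", f"{len(hits_str)} stringent + {len(hits_rel)} relaxed-band hits")

    # ---- tiling signal
    tracks = {s: tl.normalize(reps) for s, reps in tracks_raw.items()}
    if config.pool_strands:
        pooled = np.concatenate([tracks[s].signal for s in sorted(tracks)])
        bg_all = tl.estimate_background(
            tl.ProbeTrack("+", np.arange(len(pooled)), pooled)
        )
        bgs = {s: bg_all for s in tracks}
    else:
        bgs = {s: tl.estimate_background(t) for s, t in tracks.items()}
    thresholds = {s: tl.global_threshold(bgs[s], config.alpha) for s in tracks}
    report["background"] = {
        s: {"mode": round(bgs[s].mode, 4), "sd": round(bgs[s].sd, 4),
            "threshold": round(thresholds[s], 4)}
        for s in sorted(tracks)
    }

    # ---- TARs and TSSs
    tars = {
        s: tt.segment_tars(tracks[s], thresholds[s], config.max_gap, config.min_tar_len)
        for s in tracks
    }
    report["tars"] = {s: len(tars[s]) for s in sorted(tars)}
    report["tars_total"] = sum(len(v) for v in tars.values())
    tss_list = [
        tt.infer_tss(tar, tracks[s], bgs[s]) for s in sorted(tars) for tar in tars[s]
    ]
    tss_list = tt.annotate_tss(tss_list, genes)
    if len(tss_list) >= 5:
        tss_list = tt.group_tss(tss_list, tracks, config.flank_window)
    if config.tss_drop_groups:
        tss_list = tt.filter_tss_by_group(tss_list, config.tss_drop_groups)
        report["tss_after_group_filter"] = len(tss_list)
    report["tss_total"] = len(tss_list)
    for cat in ("sense", "antisense", "noncoding"):
        report[f"tss_{cat}"] = sum(1 for t in tss_list if t.category == cat)
    _stage(log, "tss", f"{len(tss_list)} TSSs from {report['tars_total']} TARs")

    # ---- co-localization: stringent first, relaxed band for the remainder
    matches = colocalize(hits_str, tss_list, config.coloc_cutoff)
    matched_ids = {id(m.tss) for m in matches}
    unmatched = [t for t in tss_list if id(t) not in matched_ids]
    matches_rel = colocalize(hits_rel, unmatched, config.coloc_cutoff)
    report["matched_stringent"] = len(matches)
    report["matched_relaxed_band"] = len(matches_rel)
    report["unmatched_tss"] = len(tss_list) - len(matches) - len(matches_rel)

    null = permutation_null(
        tss_list,
        n_promoters=len(hits_str),
        genome_length=genome.length,
        cutoff=config.coloc_cutoff,
        n_reps=config.n_reps,
        seed=config.seed,
    )
    report["null_expected_fraction"] = round(null.expected_fraction, 5)
    if tss_list and hits_str:
        log10p = log10_fisher_cooccurrence(len(matches), len(tss_list), null)
        report["fisher_log10_pvalue"] = round(log10p, 3)
    _stage(log, "colocalize",
           f"{len(matches)} stringent matches, expected fraction "
           f"{null.expected_fraction:.4f}")

    result = PipelineResult(
        report=report,
        hits_stringent=hits_str,
        hits_relaxed=hits_rel,
        tars=tars,
        tss=tss_list,
        matches=matches,
        null=null,
        truth=truth,
    )
    if config.outdir:
        _write_outputs(result, tracks, genome, genes, config)
    return result


def _write_outputs(result: PipelineResult, tracks, genome, genes, config) -> None:
    from .genome import write_genes_gff3

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc.write_hits_tsv(result.hits_stringent, out / "hits_stringent.tsv")
    sc.write_hits_tsv(result.hits_relaxed, out / "hits_relaxed_band.tsv")
    sc.write_hits_gff3(result.hits_stringent, out / "hits_stringent.gff3", seqid=genome.id)
    for s, tars in result.tars.items():
        tag = "plus" if s == "+" else "minus"
        tt.write_tars_gff3(tars, out / f"tars_{tag}.gff3", seqid=genome.id)
        tl.write_track_tsv(tracks[s], out / f"track_{tag}.tsv")
    tt.write_tss_tsv(result.tss, out / "tss.tsv")
    matches_to_dataframe(result.matches).to_csv(out / "matches.tsv", sep="\t", index=False)
    write_genes_gff3(genes, out / "genes.gff3", seqid=genome.id)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        for k, v in result.report.items():
            fh.write(f"{k}\t{v}\n")
    if result.truth is not None:
        sim.write_truth_tables(result.truth, out)
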