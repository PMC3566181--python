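"""End-to-end orchestration: simulate → filter → uniqueome → venn →
classify → false-positive estimate → report.

A run is fully determined by its configuration and seed; outputs are
written to one run directory named by the configuration hash and seed, and
the machine-readable report contains no timestamps so repeated runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .concordance import (
    MissCategory,
    aggregate_platform_totals,
    classify_missed_site,
    estimate_false_positives,
    indel_overlap,
    summarize_categories,
    venn_partition,
)
from .core import AnalysisConfig, Callset, GenomicSite
from .coverage import depth_histogram, gc_coverage_windows, mark_duplicates
from .filters import apply_platform_filter
from .io import write_bed, write_evidence, write_fasta, write_variant_calls
from .mappability import compute_uniqueome, filter_by_regions
from .synthetic import (
    PLATFORM_MODELS,
    PlatformModel,
    PlatformSimulation,
    classifier_recovery,
    clean_evidence_at,
    generate_reference,
    plant_truth_variants,
    simulate_platform,
)

logger = logging.getLogger("concordkit")

__all__ = ["SimulationSpec", "RunReport", "run_full_analysis"]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: genome, truth rates, platforms, uniqueome params."""

    genome_length: int = 200_000
    gc_target: float = 0.45
    repeat_spec: tuple[tuple[int, int], ...] = ((1_000, 2), (500, 3))
    snp_rate: float = 1e-3
    indel_rate: float = 2e-4
    platforms: tuple[str, ...] = ("roche454", "illumina", "solid")
    fragment_length: int = 100
    max_divergence: float = 0.05


@dataclass
class RunReport:
    """Machine-readable summary of one full analysis run."""

    version: str
    seed: int
    config_hash: str
    coverage: dict = field(default_factory=dict)
    duplicates: dict = field(default_factory=dict)
    callset_sizes: dict = field(default_factory=dict)
    retained_sizes: dict = field(default_factory=dict)
    venn_cells: dict = field(default_factory=dict)
    venn_totals: dict = field(default_factory=dict)
    uniqueome_bases: int = 0
    uniqueome_venn_cells: dict = field(default_factory=dict)
    category_tables: dict = field(default_factory=dict)
    classifier_recovery: dict = field(default_factory=dict)
    false_positives: dict = field(default_factory=dict)
    indel_matches: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "coverage": self.coverage,
            "duplicates": self.duplicates,
            "callset_sizes": self.callset_sizes,
            "retained_sizes": self.retained_sizes,
            "venn_cells": self.venn_cells,
            "venn_totals": self.venn_totals,
            "uniqueome_bases": self.uniqueome_bases,
            "uniqueome_venn_cells": self.uniqueome_venn_cells,
            "category_tables": self.category_tables,
            "classifier_recovery": self.classifier_recovery,
            "false_positives": self.false_positives,
            "indel_matches": self.indel_matches,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _cell_key(cell: frozenset) -> str:
    return "+".join(sorted(cell))


def _config_hash(config: AnalysisConfig, sim: SimulationSpec) -> str:
    blob = repr((config, sim)).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_full_analysis(
    config: AnalysisConfig,
    sim_spec: Optional[SimulationSpec] = None,
    out_dir: Optional[Path] = None,
    seed: Optional[int] = None,
    models: Optional[Mapping[str, PlatformModel]] = None,
) -> RunReport:
    """Run the whole concordance analysis on simulated multi-platform data.

    Deterministic given ``config`` + ``seed``; when ``out_dir`` is given,
    every stage's outputs are written under
    ``out_dir/run_<confighash>_<seed>/``.
    """
    sim_spec = sim_spec or SimulationSpec()
    seed = config.random_seed if seed is None else seed
    models = models or PLATFORM_MODELS
    report = RunReport(version=__version__, seed=seed,
                       config_hash=_config_hash(config, sim_spec))

    run_dir: Optional[Path] = None
    if out_dir is not None:
        run_dir = Path(out_dir) / f"run_{report.config_hash}_{seed}"
        run_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name: str):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- simulate -----------------------------------------------------------
    t0 = _stage("simulate")
    reference = generate_reference(sim_spec.genome_length, sim_spec.gc_target,
                                   sim_spec.repeat_spec, seed=seed)
    truth = plant_truth_variants(reference, sim_spec.snp_rate,
                                 sim_spec.indel_rate, seed=seed + 1)
    sims: dict[str, PlatformSimulation] = {}
    for i, pid in enumerate(sim_spec.platforms):
        sims[pid] = simulate_platform(truth, reference, models[pid], config,
                                      seed=seed + 10 + i)
    logger.info("simulate: %d truth variants, %.2fs", len(truth.variants),
                time.perf_counter() - t0)
    if run_dir:
        write_fasta(reference.sequences, run_dir / "reference.fa")
        write_variant_calls(Callset("truth", truth.variants), run_dir / "truth.vcf")

    # --- coverage profiles and duplicates ----------------------------------
    t0 = _stage("coverage")
    for pid, sim in sims.items():
        depths = np.concatenate(list(sim.depth.values()))
        hist = depth_histogram(depths)
        report.coverage[pid] = {
            "mean_depth": round(float(depths.mean()), 2),
            "genome_bases": int(depths.size),
            "histogram_max_depth": int(depths.max()),
        }
        _flags, n_dup = mark_duplicates(sim.alignment_coords)
        report.duplicates[pid] = {
            "records": int(len(sim.alignment_coords)),
            "duplicates": n_dup,
        }
        if run_dir:
            windows = gc_coverage_windows(reference.sequences, sim.depth,
                                          config.gc_window_bp)
            with open(run_dir / f"{pid}.gc_windows.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tgc_fraction\tmean_depth\n")
                for w in windows:
                    fh.write(f"{w.interval.chrom}\t{w.interval.start}\t"
                             f"{w.interval.end}\t{w.gc_fraction:.4f}\t"
                             f"{w.mean_depth:.3f}\n")
            with open(run_dir / f"{pid}.depth_hist.tsv", "w") as fh:
                fh.write("depth\tfraction\n")
                for d, f in sorted(hist.fractions.items()):
                    fh.write(f"{d}\t{f:.6g}\n")
    logger.info("coverage: %.2fs", time.perf_counter() - t0)

    # --- filter -------------------------------------------------------------
    t0 = _stage("filter")
    retained: dict[str, Callset] = {}
    for pid, sim in sims.items():
        kept, rejections = apply_platform_filter(sim.callset, sim.evidence,
                                                 config.platforms[pid], config)
        retained[pid] = kept
        report.callset_sizes[pid] = len(sim.callset)
        report.retained_sizes[pid] = len(kept)
        if run_dir:
            write_variant_calls(sim.callset, run_dir / f"{pid}.calls.vcf")
            write_variant_calls(kept, run_dir / f"{pid}.retained.vcf")
            write_evidence(sim.evidence.values(), run_dir / f"{pid}.evidence.tsv")
            with open(run_dir / f"{pid}.rejections.tsv", "w") as fh:
                fh.write("chrom\tpos\treason\n")
                for r in rejections:
                    fh.write(f"{r.call.site.chrom}\t{r.call.site.pos + 1}\t"
                             f"{r.reason.value}\n")
    logger.info("filter: %.2fs", time.perf_counter() - t0)

    # --- uniqueome ----------------------------------------------------------
    t0 = _stage("uniqueome")
    unique = compute_uniqueome(reference.sequences, sim_spec.fragment_length,
                               sim_spec.max_divergence)
    report.uniqueome_bases = sum(len(iv) for iv in unique)
    if run_dir:
        write_bed(unique, run_dir / "uniqueome.bed")
    logger.info("uniqueome: %d bases, %.2fs", report.uniqueome_bases,
                time.perf_counter() - t0)

    # --- venn ---------------------------------------------------------------
    t0 = _stage("venn")
    subs = {pid: cs.substitutions() for pid, cs in retained.items()}
    partition = venn_partition(list(subs.values()))
    report.venn_cells = {_cell_key(k): v for k, v in partition.cell_sizes().items()}
    report.venn_totals = _plain(aggregate_platform_totals(partition))
    filtered_subs = [filter_by_regions(cs, unique) for cs in subs.values()]
    uq_partition = venn_partition(filtered_subs)
    report.uniqueome_venn_cells = {
        _cell_key(k): v for k, v in uq_partition.cell_sizes().items()
    }
    logger.info("venn: union %d, %.2fs", report.venn_totals["union"],
                time.perf_counter() - t0)

    # --- classify -----------------------------------------------------------
    t0 = _stage("classify")
    union_sites = partition.union_sites()
    evidence_full: dict[str, dict[GenomicSite, object]] = {}
    for i, (pid, sim) in enumerate(sims.items()):
        have = set(sim.evidence)
        missing = sorted(union_sites - have, key=lambda s: (s.chrom, s.pos))
        backfill = clean_evidence_at(missing, reference, models[pid], config,
                                     seed=seed + 100 + i)
        evidence_full[pid] = {**sim.evidence, **backfill}
    classified: dict[tuple[GenomicSite, str], MissCategory] = {}
    for pid in sims:
        called = subs[pid].sites()
        for site in union_sites - called:
            classified[(site, pid)] = classify_missed_site(
                evidence_full[pid][site], config.platforms[pid],
                config.chrom_class(site.chrom),
            )
    summary = summarize_categories(classified)
    for pid, group in summary.groupby("platform"):
        report.category_tables[pid] = {
            rec["category"]: int(rec["count"]) for rec in group.to_dict("records")
        }
    for pid, sim in sims.items():
        report.classifier_recovery[pid] = classifier_recovery(sim, config)
    if run_dir:
        summary.to_csv(run_dir / "miss_categories.tsv", sep="\t", index=False)
    logger.info("classify: %d (site, platform) pairs, %.2fs", len(classified),
                time.perf_counter() - t0)

    # --- false positives ----------------------------------------------------
    t0 = _stage("fp")
    for pid in sims:
        singletons = partition.cell(pid)
        others = {p: evidence_full[p] for p in sims if p != pid}
        est = estimate_false_positives(singletons, others, config)
        report.false_positives[pid] = {
            "singletons": len(singletons),
            "plausible_true": est.plausible_true,
            "putative_fp": est.putative_fp,
        }
    logger.info("fp: %.2fs", time.perf_counter() - t0)

    # --- indels -------------------------------------------------------------
    t0 = _stage("indels")
    indel_ivs = {
        pid: [c.interval() for c in cs.indels()] for pid, cs in retained.items()
    }
    pids = list(sims)
    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            a, b = pids[i], pids[j]
            res = indel_overlap(indel_ivs[a], indel_ivs[b], config.indel_slop_bp)
            report.indel_matches[f"{a}_vs_{b}"] = {
                "exact": res.n_exact,
                "slop_only": res.n_slop_only,
                "unmatched": res.n_unmatched,
            }
    logger.info("indels: %.2fs", time.perf_counter() - t0)

    if run_dir:
        (run_dir / "report.json").write_text(report.to_json())
    return report


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = dict(v) if isinstance(v, dict) else v
    return out
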