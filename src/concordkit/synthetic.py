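"""Synthetic multi-platform data generator.

Emulates the statistical structure the concordance analysis assumes: a
small reference with controllable GC composition and planted exact repeats,
a diploid truth set of substitutions and indels, and per-platform callsets
with evidence tables in which every missed truth site carries an engineered,
classifier-recoverable miss cause.

Per-base depth is Poisson with a log-linear GC bias: within each analysis
window w, the rate is ``mean_depth * exp(gc_beta * (gc(w) - 0.5))``. Platform
archetypes differ in mean depth, GC-bias strength, error profile
(homopolymer-adjacent false calls for the pyrosequencing-like platform,
generic substitution errors for the short-read platforms), duplicate
fraction, and whether the aligner assigns mapping qualities.

Planted miss-cause evidence keeps a margin of at least 2 units from every
integer threshold and 5 units from every quality threshold, so the
rule-based classifier recovers the planted label exactly (the one
exception: a platform with minimum depth 2 can only plant LOW_COVERAGE at
depth 1; the integer rule still recovers it deterministically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .concordance import MissCategory
from .core import (
    AnalysisConfig,
    Callset,
    ChromClass,
    EvidenceRecord,
    GenomicSite,
    Interval,
    PlatformConfig,
    VariantCall,
    VariantKind,
    Zygosity,
)

__all__ = [
    "PlatformModel",
    "TruthSet",
    "PlatformSimulation",
    "PLATFORM_MODELS",
    "SyntheticReference",
    "generate_reference",
    "plant_truth_variants",
    "simulate_platform",
    "homopolymer_runs",
    "clean_evidence_at",
    "classifier_recovery",
]

Label = Union[MissCategory, str]  # MissCategory | "called" | "fp"

# deterministic GC modulation so windows span a range of GC fractions
_GC_PERIOD_BP = 3_000
_GC_AMPLITUDE = 0.08

_INT_MARGIN = 2
_QUAL_MARGIN = 5.0
_GOOD_MAPQ = 50.0


@dataclass(frozen=True)
class PlatformModel:
    """Generative parameters for one platform archetype."""

    platform_id: str
    mean_depth: float
    gc_beta: float
    substitution_error_rate: float
    homopolymer_fp_rate: float
    duplicate_fraction: float
    repeat_mapq_penalty: float
    has_mapq: bool
    miss_rate: float = 0.15
    category_weights: Mapping[MissCategory, float] = field(default_factory=dict)
    homopolymer_threshold: int = 4
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("substitution_error_rate", "homopolymer_fp_rate",
                     "duplicate_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


def _weights(**kv: float) -> dict[MissCategory, float]:
    return {MissCategory[k]: v for k, v in kv.items()}


#: Platform archetypes. Mean depths mirror a long-read pyrosequencing run at
#: ~10x against short-read runs at ~59x and ~79x; duplicate fractions are the
#: corresponding aligned-read duplicate rates (~3%, ~7%, ~27%); the GC-bias
#: coefficients are illustrative (minor for the pyrosequencing-like platform,
#: strong coverage loss in GC-rich windows for the short-read platforms).
#: Category weights echo the relative prevalence of miss causes reported for
#: each platform class.
PLATFORM_MODELS: Mapping[str, PlatformModel] = {
    "roche454": PlatformModel(
        platform_id="roche454", mean_depth=10.0, gc_beta=-0.2,
        substitution_error_rate=5e-5, homopolymer_fp_rate=0.02,
        duplicate_fraction=0.027, repeat_mapq_penalty=0.0, has_mapq=False,
        miss_rate=0.18, read_length=350,
        category_weights=_weights(
            NO_COVERAGE=0.02, LOW_COVERAGE=0.14, EXCESS_COVERAGE=0.02,
            ALT_NOT_SEEN=0.10, ALT_SEEN_ONCE=0.33, SNP_CLUSTER=0.02,
            NEAR_INDEL=0.01, NON_UNIQUE=0.36,
        ),
    ),
    "illumina": PlatformModel(
        platform_id="illumina", mean_depth=59.0, gc_beta=-2.0,
        substitution_error_rate=4e-5, homopolymer_fp_rate=0.0,
        duplicate_fraction=0.066, repeat_mapq_penalty=30.0, has_mapq=True,
        miss_rate=0.11, read_length=101,
        category_weights=_weights(
            NO_COVERAGE=0.01, LOW_COVERAGE=0.02, EXCESS_COVERAGE=0.57,
            ALT_NOT_SEEN=0.05, ALT_SEEN_ONCE=0.05, SNP_CLUSTER=0.02,
            NEAR_INDEL=0.01, LOW_RMS_MAPQ=0.05, LOW_SNP_QUAL=0.22,
        ),
    ),
    "solid": PlatformModel(
        platform_id="solid", mean_depth=79.0, gc_beta=-2.0,
        substitution_error_rate=1.5e-5, homopolymer_fp_rate=0.0,
        duplicate_fraction=0.27, repeat_mapq_penalty=30.0, has_mapq=True,
        miss_rate=0.21, read_length=50,
        category_weights=_weights(
            NO_COVERAGE=0.03, LOW_COVERAGE=0.08, EXCESS_COVERAGE=0.08,
            ALT_NOT_SEEN=0.17, ALT_SEEN_ONCE=0.19, SNP_CLUSTER=0.01,
            NEAR_INDEL=0.01, LOW_RMS_MAPQ=0.18, LOW_SNP_QUAL=0.25,
        ),
    ),
}


@dataclass
class SyntheticReference:
    """Generated reference: sequences plus the coordinates of every planted
    repeat copy (source and destinations)."""

    sequences: dict[str, str]
    repeat_intervals: list[Interval] = field(default_factory=list)

    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class TruthSet:
    """Planted variants; per-platform outcome labels are attached by
    :func:`simulate_platform` runs."""

    variants: list[VariantCall]

    def substitutions(self) -> list[VariantCall]:
        return [v for v in self.variants if v.is_substitution]

    def indels(self) -> list[VariantCall]:
        return [v for v in self.variants if not v.is_substitution]


@dataclass
class PlatformSimulation:
    """One platform's simulated outputs."""

    platform_id: str
    callset: Callset
    evidence: dict[GenomicSite, EvidenceRecord]
    labels: dict[GenomicSite, Label]
    depth: dict[str, np.ndarray]
    alignment_coords: pd.DataFrame
    fp_sites: set[GenomicSite]


# ---------------------------------------------------------------------------
# Reference and truth generation
# ---------------------------------------------------------------------------

def generate_reference(length: int, gc_target: float,
                       repeat_spec: Sequence[tuple[int, int]] = (),
                       seed: int = 0, chrom: str = "chr1") -> SyntheticReference:
    """Random reference with sinusoidally modulated GC and planted repeats.

    The local GC probability oscillates around ``gc_target`` (period 3 kb,
    amplitude 0.08) so that analysis windows span a range of GC fractions;
    the overall GC stays within +/-2 percentage points of the target for
    sequences of 10 kb and longer. Each ``(copy_length, copy_count)`` entry
    plants ``copy_count`` exact copies of one random segment at recorded,
    non-overlapping coordinates.
    """
    if length < 1_000:
        raise ValueError("length must be >= 1,000")
    if not (0.0 < gc_target < 1.0):
        raise ValueError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    x = np.arange(length)
    p_gc = np.clip(
        gc_target + _GC_AMPLITUDE * np.sin(2 * np.pi * x / _GC_PERIOD_BP),
        0.02, 0.98,
    )
    is_gc = rng.random(length) < p_gc
    second = rng.random(length) < 0.5
    codes = np.where(is_gc, np.where(second, 0, 1), np.where(second, 2, 3))
    seq = np.array(list("GCAT"))[codes]

    repeat_intervals: list[Interval] = []
    occupied: list[tuple[int, int]] = []

    def _free(start: int, clen: int) -> bool:
        return all(start + clen <= s or start >= e for s, e in occupied)

    for copy_length, copy_count in repeat_spec:
        if copy_length * copy_count > length or copy_length > length:
            raise ValueError(
                f"repeat spec ({copy_length} x {copy_count}) exceeds sequence length"
            )
        placed: list[int] = []
        tries = 0
        while len(placed) < copy_count:
            start = int(rng.integers(0, length - copy_length + 1))
            if _free(start, copy_length):
                placed.append(start)
                occupied.append((start, start + copy_length))
            tries += 1
            if tries > 10_000:
                raise ValueError("could not place requested repeats")
        source = placed[0]
        unit = seq[source:source + copy_length].copy()
        for start in placed:
            seq[start:start + copy_length] = unit
            repeat_intervals.append(Interval(chrom, start, start + copy_length))

    return SyntheticReference(
        sequences={chrom: "".join(seq)},
        repeat_intervals=sorted(repeat_intervals),
    )


def plant_truth_variants(reference: SyntheticReference, snp_rate: float,
                         indel_rate: float, seed: int = 0,
                         het_hom_ratio: float = 2.0) -> TruthSet:
    """Plant heterozygous/homozygous substitutions and short indels.

    Variant positions are Bernoulli draws at the given per-bp rates, thinned
    so no two variants are within 1 bp of each other. The heterozygous to
    homozygous ratio defaults to 2:1 (a diploid outbred expectation).
    """
    if snp_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    if snp_rate + indel_rate >= 0.1:
        raise ValueError("snp_rate + indel_rate must be < 0.1")
    rng = np.random.default_rng(seed)
    p_het = het_hom_ratio / (het_hom_ratio + 1.0)
    variants: list[VariantCall] = []
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for chrom, seq in reference.sequences.items():
        n = len(seq)
        hits = np.flatnonzero(rng.random(n) < (snp_rate + indel_rate))
        last = -10
        for pos in hits:
            pos = int(pos)
            if pos - last < 2 or pos >= n - 8:
                continue
            last = pos
            geno = Zygosity.HET if rng.random() < p_het else Zygosity.HOM
            ref_base = seq[pos]
            is_snp = rng.random() < snp_rate / (snp_rate + indel_rate)
            if is_snp:
                alt = others[ref_base][int(rng.integers(3))]
                variants.append(VariantCall(
                    site=GenomicSite(chrom, pos), ref_allele=ref_base,
                    alt_allele=alt, kind=VariantKind.SUBSTITUTION,
                    genotype=geno, quality=99.0,
                ))
            else:
                ilen = int(rng.integers(1, 6))
                if rng.random() < 0.5:  # deletion
                    variants.append(VariantCall(
                        site=GenomicSite(chrom, pos),
                        ref_allele=seq[pos:pos + 1 + ilen], alt_allele=ref_base,
                        kind=VariantKind.DELETION, genotype=geno, quality=99.0,
                    ))
                else:  # insertion
                    ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, ilen))
                    variants.append(VariantCall(
                        site=GenomicSite(chrom, pos), ref_allele=ref_base,
                        alt_allele=ref_base + ins, kind=VariantKind.INSERTION,
                        genotype=geno, quality=99.0,
                    ))
    return TruthSet(variants=sorted(variants, key=lambda v: (v.site.chrom, v.site.pos)))


def homopolymer_runs(seq: str, min_length: int = 4) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of single-nucleotide runs >= min_length."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_length and seq[start] in "ACGT":
                runs.append((start, i))
            start = i
    return runs


# ---------------------------------------------------------------------------
# Platform simulation
# ---------------------------------------------------------------------------

def _window_rates(seq: str, model: PlatformModel, window_bp: int) -> np.ndarray:
    """Per-base Poisson rate from the window's GC fraction (log-linear bias)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    rates = np.empty(len(seq))
    for start in range(0, len(seq), window_bp):
        end = min(start + window_bp, len(seq))
        gc = float(is_gc[start:end].mean())
        rates[start:end] = model.mean_depth * np.exp(model.gc_beta * (gc - 0.5))
    return rates


def _safe_depth_band(pc: PlatformConfig, chrom_class: ChromClass) -> tuple[int, int]:
    lo = pc.min_depth + _INT_MARGIN
    hi = pc.max_depth(chrom_class) - _INT_MARGIN
    if hi < lo:
        hi = lo
    return lo, hi


def _engineer_miss(rng: np.random.Generator, site: GenomicSite,
                   category: MissCategory, pc: PlatformConfig,
                   chrom_class: ChromClass, lam: float) -> EvidenceRecord:
    """Evidence consistent with exactly one classifier rule, with margins."""
    lo, hi = _safe_depth_band(pc, chrom_class)
    depth = int(np.clip(rng.poisson(lam), lo, hi))
    good_qual = (pc.min_qual or 20.0) + 4 * _QUAL_MARGIN
    mapq: Optional[float] = _GOOD_MAPQ if pc.has_mapq else None
    kv: dict = dict(depth=depth, alt_count=max(2, min(depth, int(rng.binomial(depth, 0.5)))),
                    rms_mapq=mapq, snp_qual=good_qual, nearby_snp_count=0,
                    nearest_indel_distance=None, in_unique_region=True)
    if category is MissCategory.NO_COVERAGE:
        kv.update(depth=0, alt_count=0, rms_mapq=None, snp_qual=None)
    elif category is MissCategory.LOW_COVERAGE:
        d = max(1, pc.min_depth - _INT_MARGIN)
        kv.update(depth=d, alt_count=min(1, d))
    elif category is MissCategory.EXCESS_COVERAGE:
        d = pc.max_depth(chrom_class) + _INT_MARGIN + 3
        kv.update(depth=d, alt_count=d // 2)
    elif category is MissCategory.ALT_NOT_SEEN:
        kv.update(alt_count=0)
    elif category is MissCategory.ALT_SEEN_ONCE:
        kv.update(alt_count=1)
    elif category is MissCategory.SNP_CLUSTER:
        kv.update(nearby_snp_count=pc.cluster_max_snps + _INT_MARGIN + 1)
    elif category is MissCategory.NEAR_INDEL:
        kv.update(nearest_indel_distance=max(0, pc.indel_distance_bp - _INT_MARGIN))
    elif category is MissCategory.LOW_RMS_MAPQ:
        kv.update(rms_mapq=max(0.0, pc.min_rms_mapq - _QUAL_MARGIN))
    elif category is MissCategory.NON_UNIQUE:
        kv.update(in_unique_region=False, rms_mapq=None)
    elif category is MissCategory.LOW_SNP_QUAL:
        kv.update(snp_qual=max(0.0, (pc.min_qual or 20.0) - _QUAL_MARGIN))
    else:
        raise ValueError(f"cannot plant category {category}")
    return EvidenceRecord(site=site, **kv)


def _called_evidence(rng: np.random.Generator, site: GenomicSite,
                     genotype: Zygosity, pc: PlatformConfig,
                     chrom_class: ChromClass, lam: float, quality: float,
                     in_repeat: bool = False) -> EvidenceRecord:
    lo, hi = _safe_depth_band(pc, chrom_class)
    depth = int(np.clip(rng.poisson(lam), lo, hi))
    p_alt = 0.95 if genotype is Zygosity.HOM else 0.5
    alt = int(np.clip(rng.binomial(depth, p_alt), 1, depth))
    return EvidenceRecord(
        site=site, depth=depth, alt_count=alt,
        rms_mapq=_GOOD_MAPQ if pc.has_mapq else None,
        snp_qual=quality, nearby_snp_count=0,
        nearest_indel_distance=None, in_unique_region=not in_repeat,
    )


def _sample_category(rng: np.random.Generator,
                     weights: Mapping[MissCategory, float]) -> MissCategory:
    cats = list(weights)
    p = np.asarray([weights[c] for c in cats], dtype=float)
    p /= p.sum()
    return cats[int(rng.choice(len(cats), p=p))]


def simulate_platform(truth: TruthSet, reference: SyntheticReference,
                      model: PlatformModel, config: AnalysisConfig,
                      seed: int = 0) -> PlatformSimulation:
    """Simulate one platform's callset, evidence table and outcome labels.

    Truth substitutions inside planted repeats are always missed with the
    mapping-ambiguity cause (LOW_RMS_MAPQ when the aligner has mapping
    qualities, NON_UNIQUE otherwise); elsewhere each truth site is missed
    with probability ``model.miss_rate`` and the cause is drawn from the
    platform's category weights, with evidence engineered to match. False
    substitution calls are injected adjacent to homopolymer runs (at
    ``homopolymer_fp_rate`` per run) and genome-wide (at
    ``substitution_error_rate`` per bp). Truth indels are called with
    probability ``1 - miss_rate`` with a small coordinate jitter.
    """
    rng = np.random.default_rng(seed)
    pc = config.platforms[model.platform_id]
    weights = dict(model.category_weights)
    if not weights:
        weights = {MissCategory.ALT_NOT_SEEN: 0.5, MissCategory.LOW_COVERAGE: 0.5}
    # drop categories this platform cannot exhibit
    if pc.min_qual is None:
        weights.pop(MissCategory.LOW_SNP_QUAL, None)
    if pc.has_mapq:
        weights.pop(MissCategory.NON_UNIQUE, None)
    else:
        weights.pop(MissCategory.LOW_RMS_MAPQ, None)

    depth: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    for chrom, seq in reference.sequences.items():
        r = _window_rates(seq, model, config.gc_window_bp)
        rates[chrom] = r
        depth[chrom] = rng.poisson(r).astype(np.int32)

    repeat_by_chrom: dict[str, list[Interval]] = {}
    for iv in reference.repeat_intervals:
        repeat_by_chrom.setdefault(iv.chrom, []).append(iv)

    def _in_repeat(site: GenomicSite) -> bool:
        return any(iv.contains(site) for iv in repeat_by_chrom.get(site.chrom, []))

    calls: list[VariantCall] = []
    evidence: dict[GenomicSite, EvidenceRecord] = {}
    labels: dict[GenomicSite, Label] = {}
    fp_sites: set[GenomicSite] = set()
    qual_floor = (pc.min_qual or 20.0) + 15.0

    for v in truth.substitutions():
        site = v.site
        cls = config.chrom_class(site.chrom)
        lam = float(rates[site.chrom][site.pos])
        if _in_repeat(site):
            category = (MissCategory.LOW_RMS_MAPQ if pc.has_mapq
                        else MissCategory.NON_UNIQUE)
            ev = _engineer_miss(rng, site, category, pc, cls, lam)
            if category is MissCategory.LOW_RMS_MAPQ and model.repeat_mapq_penalty > 0:
                penalized = max(0.0, _GOOD_MAPQ - model.repeat_mapq_penalty)
                if penalized <= pc.min_rms_mapq - _INT_MARGIN:
                    ev = EvidenceRecord(**{**ev.__dict__, "rms_mapq": penalized})
            evidence[site] = ev
            labels[site] = category
        elif rng.random() < model.miss_rate:
            category = _sample_category(rng, weights)
            evidence[site] = _engineer_miss(rng, site, category, pc, cls, lam)
            labels[site] = category
        else:
            quality = float(rng.uniform(qual_floor, 95.0))
            evidence[site] = _called_evidence(rng, site, v.genotype, pc, cls,
                                              lam, quality)
            labels[site] = "called"
            calls.append(VariantCall(
                site=site, ref_allele=v.ref_allele, alt_allele=v.alt_allele,
                kind=v.kind, genotype=v.genotype, quality=quality,
            ))

    # false substitution calls
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

    def _inject_fp(chrom: str, pos: int) -> None:
        site = GenomicSite(chrom, pos)
        if site in evidence:
            return
        ref_base = reference.sequences[chrom][pos]
        if ref_base not in others:
            return
        cls = config.chrom_class(chrom)
        quality = float(rng.uniform(qual_floor, 70.0))
        ev = _called_evidence(rng, site, Zygosity.HET, pc, cls,
                              float(rates[chrom][pos]), quality)
        if ev.alt_count < 2:
            ev = EvidenceRecord(**{**ev.__dict__, "alt_count": 2})
        evidence[site] = ev
        labels[site] = "fp"
        fp_sites.add(site)
        calls.append(VariantCall(
            site=site, ref_allele=ref_base,
            alt_allele=others[ref_base][int(rng.integers(3))],
            kind=VariantKind.SUBSTITUTION, genotype=Zygosity.HET,
            quality=quality,
        ))

    for chrom, seq in reference.sequences.items():
        if model.homopolymer_fp_rate > 0:
            for start, end in homopolymer_runs(seq, model.homopolymer_threshold):
                if rng.random() < model.homopolymer_fp_rate and end < len(seq):
                    _inject_fp(chrom, end)
        if model.substitution_error_rate > 0:
            n_fp = rng.binomial(len(seq), model.substitution_error_rate)
            for pos in sorted(int(p) for p in rng.integers(0, len(seq), n_fp)):
                _inject_fp(chrom, pos)

    # indels: called with probability 1 - miss_rate, with coordinate jitter
    jitter_values = np.array([-2, -1, 0, 1, 2])
    jitter_probs = np.array([0.05, 0.15, 0.60, 0.15, 0.05])
    for v in truth.indels():
        if rng.random() < model.miss_rate:
            continue
        shift = int(rng.choice(jitter_values, p=jitter_probs))
        pos = max(0, v.site.pos + shift)
        quality = float(rng.uniform(qual_floor, 95.0))
        site = GenomicSite(v.site.chrom, pos)
        calls.append(VariantCall(
            site=site, ref_allele=v.ref_allele, alt_allele=v.alt_allele,
            kind=v.kind, genotype=v.genotype, quality=quality,
        ))
        if site not in evidence:
            evidence[site] = _called_evidence(
                rng, site, v.genotype, pc, config.chrom_class(site.chrom),
                float(rates[site.chrom][min(pos, len(rates[site.chrom]) - 1)]),
                quality,
            )

    # alignment coordinate table with re-emitted duplicates
    coords = _alignment_coords(rng, reference, model)

    return PlatformSimulation(
        platform_id=model.platform_id,
        callset=Callset(model.platform_id, calls),
        evidence=evidence,
        labels=labels,
        depth=depth,
        alignment_coords=coords,
        fp_sites=fp_sites,
    )


def _alignment_coords(rng: np.random.Generator, reference: SyntheticReference,
                      model: PlatformModel) -> pd.DataFrame:
    rows = []
    for chrom, seq in reference.sequences.items():
        n_reads = max(1, int(len(seq) * model.mean_depth / model.read_length))
        starts = rng.integers(0, max(1, len(seq) - model.read_length), n_reads)
        strands = rng.random(n_reads) < 0.5
        for s, st in zip(starts, strands):
            rows.append((chrom, int(s), "+" if st else "-"))
            if rng.random() < model.duplicate_fraction:
                rows.append((chrom, int(s), "+" if st else "-"))
    return pd.DataFrame(rows, columns=["chrom", "start", "strand"])


def clean_evidence_at(sites: Sequence[GenomicSite], reference: SyntheticReference,
                      model: PlatformModel, config: AnalysisConfig,
                      seed: int = 0) -> dict[GenomicSite, EvidenceRecord]:
    """Non-variant evidence (in-bounds depth, zero alternate reads) at the
    given sites — used to complete other platforms' evidence at sites only
    one platform called."""
    rng = np.random.default_rng(seed)
    pc = config.platforms[model.platform_id]
    out: dict[GenomicSite, EvidenceRecord] = {}
    rates = {c: _window_rates(s, model, config.gc_window_bp)
             for c, s in reference.sequences.items()}
    for site in sites:
        cls = config.chrom_class(site.chrom)
        lo, hi = _safe_depth_band(pc, cls)
        d = int(np.clip(rng.poisson(rates[site.chrom][site.pos]), lo, hi))
        out[site] = EvidenceRecord(
            site=site, depth=d, alt_count=0,
            rms_mapq=_GOOD_MAPQ if pc.has_mapq else None,
            snp_qual=None, nearby_snp_count=0,
            nearest_indel_distance=None, in_unique_region=True,
        )
    return out


def classifier_recovery(sim: PlatformSimulation, config: AnalysisConfig) -> float:
    """Fraction of planted miss labels the rule classifier reproduces."""
    from .concordance import classify_missed_site

    pc = config.platforms[sim.platform_id]
    total = 0
    agree = 0
    for site, label in sim.labels.items():
        if not isinstance(label, MissCategory):
            continue
        total += 1
        got = classify_missed_site(sim.evidence[site], pc,
                                   config.chrom_class(site.chrom))
        if got is label:
            agree += 1
    return 1.0 if total == 0 else agree / total
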