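"""Per-platform call-retention rules.

A call is retained iff its post-deduplication depth lies inside the
platform's inclusive depth bounds for the chromosome class, its quality
meets the platform minimum (when the platform defines one), and — on sex
chromosomes and the mitochondrion — it is homozygous. Rejections cite the
first failing rule, evaluated in the fixed order depth-low, depth-high,
quality, zygosity-class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

from .core import (
    AnalysisConfig,
    Callset,
    ChromClass,
    EvidenceRecord,
    GenomicSite,
    PlatformConfig,
    VariantCall,
    Zygosity,
)
from .coverage import poisson_depth_bounds

__all__ = [
    "RejectionReason",
    "Rejection",
    "zygosity_call",
    "apply_platform_filter",
    "derive_depth_limits",
    "DepthLimits",
]


class RejectionReason(str, enum.Enum):
    DEPTH_LOW = "depth_low"
    DEPTH_HIGH = "depth_high"
    QUALITY = "quality"
    ZYGOSITY_CLASS = "zygosity_class"


@dataclass(frozen=True)
class Rejection:
    call: VariantCall
    reason: RejectionReason


def zygosity_call(alt_fraction: float, threshold: float) -> Zygosity:
    """Homozygous iff strictly more than ``threshold`` of reads support the
    alternate allele (default threshold 0.8)."""
    if not (0.0 <= alt_fraction <= 1.0):
        raise ValueError("alt_fraction must be in [0, 1]")
    return Zygosity.HOM if alt_fraction > threshold else Zygosity.HET


def apply_platform_filter(
    callset: Callset,
    evidence: Mapping[GenomicSite, EvidenceRecord],
    platform_config: PlatformConfig,
    config: AnalysisConfig,
) -> tuple[Callset, list[Rejection]]:
    """Split a callset into retained calls and a rejection log.

    Every call must have an evidence record; retained and rejected calls
    partition the input. Filtering is idempotent: re-filtering the retained
    set changes nothing.
    """
    retained: list[VariantCall] = []
    rejections: list[Rejection] = []
    for call in callset:
        ev = evidence.get(call.site)
        if ev is None:
            raise KeyError(
                f"no evidence record for {call.site.chrom}:{call.site.pos} "
                f"({callset.platform_id})"
            )
        chrom_class = config.chrom_class(call.site.chrom)
        reason = _first_failure(call, ev, platform_config, chrom_class)
        if reason is None:
            retained.append(call)
        else:
            rejections.append(Rejection(call, reason))
    return Callset(callset.platform_id, retained), rejections


def _first_failure(call: VariantCall, ev: EvidenceRecord,
                   pc: PlatformConfig, chrom_class: ChromClass
                   ) -> Optional[RejectionReason]:
    if ev.depth < pc.min_depth:
        return RejectionReason.DEPTH_LOW
    if ev.depth > pc.max_depth(chrom_class):
        return RejectionReason.DEPTH_HIGH
    if pc.min_qual is not None and call.quality < pc.min_qual:
        return RejectionReason.QUALITY
    if chrom_class in (ChromClass.SEX, ChromClass.MITO) and call.genotype is not Zygosity.HOM:
        return RejectionReason.ZYGOSITY_CLASS
    return None


@dataclass(frozen=True)
class DepthLimits:
    autosome: tuple[int, int]
    sex: tuple[int, int]
    mito: tuple[int, int]


def derive_depth_limits(mean_depth: float, alpha: float,
                        platform_config: Optional[PlatformConfig] = None,
                        model: bool = True) -> DepthLimits:
    """Depth limits per chromosome class.

    In model mode the autosomal limits come from a two-tailed
    Poisson(mean_depth) interval, the sex-class limits from
    Poisson(mean_depth / 2) (haploid coverage), and the mitochondrial upper
    limit is effectively unbounded (10,000). In fixed-threshold mode the
    supplied platform configuration is passed through unchanged.
    """
    if not model:
        if platform_config is None:
            raise ValueError("fixed-threshold mode requires a platform_config")
        pc = platform_config
        return DepthLimits(
            autosome=(pc.min_depth, pc.max_depth_autosome),
            sex=(pc.min_depth, pc.max_depth_sex),
            mito=(pc.min_depth, pc.max_depth_mito),
        )
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    auto = poisson_depth_bounds(mean_depth, alpha)
    sex = poisson_depth_bounds(mean_depth / 2.0, alpha)
    return DepthLimits(autosome=auto, sex=sex, mito=(auto[0], 10_000))
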