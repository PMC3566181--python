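"""Core domain types for multi-platform variant-concordance analysis.

Coordinates are 0-based half-open everywhere inside the package; the VCF
reader/writer converts to and from 1-based positions at the boundary.
Site identity for cross-platform matching is ``(chrom, pos)`` only — two
platforms calling different alternate alleles at the same location are
treated as concordant at that location (allele mismatches are surfaced
separately in reports).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicSite",
    "VariantKind",
    "Zygosity",
    "ChromClass",
    "VariantCall",
    "Callset",
    "EvidenceRecord",
    "Interval",
    "PlatformConfig",
    "AnalysisConfig",
    "PLATFORM_DEFAULTS",
    "default_config",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single genomic location: chromosome name and 0-based position."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")


class VariantKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


class Zygosity(str, enum.Enum):
    HOM = "hom"
    HET = "het"


class ChromClass(str, enum.Enum):
    """Chromosome class used to select depth limits and zygosity rules."""

    AUTOSOME = "autosome"
    SEX = "sex"
    MITO = "mito"


@dataclass(frozen=True)
class VariantCall:
    """One substitution or indel call with genotype and Phred-scaled quality.

    ``quality`` is the call quality: the Phred-scaled likelihood that the
    called genotype is identical to the reference.
    """

    site: GenomicSite
    ref_allele: str
    alt_allele: str
    kind: VariantKind
    genotype: Zygosity
    quality: float

    def __post_init__(self) -> None:
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")
        if not set(self.ref_allele) <= _DNA:
            raise ValueError(f"ref_allele must be over ACGT, got {self.ref_allele!r}")
        if self.kind is VariantKind.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must both have length 1")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution alleles must differ")

    @property
    def is_substitution(self) -> bool:
        return self.kind is VariantKind.SUBSTITUTION

    def interval(self) -> "Interval":
        """Reference footprint of the call as a half-open interval.

        Substitutions and insertions span a single reference base; deletions
        span the deleted reference bases (VCF-style padded representation,
        excluding the anchor base).
        """
        if self.kind is VariantKind.DELETION and len(self.ref_allele) > 1:
            return Interval(self.site.chrom, self.site.pos + 1,
                            self.site.pos + len(self.ref_allele))
        return Interval(self.site.chrom, self.site.pos, self.site.pos + 1)


class Callset:
    """An ordered collection of calls from one platform, sorted by (chrom, pos).

    No two substitution calls may share a site; indels at a substitution's
    site are permitted (they describe a different event class).
    """

    def __init__(self, platform_id: str, calls: Iterable[VariantCall]) -> None:
        if not platform_id:
            raise ValueError("platform_id must be non-empty")
        self.platform_id = platform_id
        self.calls: list[VariantCall] = sorted(
            calls, key=lambda c: (c.site.chrom, c.site.pos)
        )
        seen: set[GenomicSite] = set()
        for c in self.calls:
            if c.is_substitution:
                if c.site in seen:
                    raise ValueError(
                        f"duplicate substitution call at {c.site.chrom}:{c.site.pos}"
                    )
                seen.add(c.site)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Callset):
            return NotImplemented
        return self.platform_id == other.platform_id and self.calls == other.calls

    def __repr__(self) -> str:
        return f"Callset({self.platform_id!r}, n={len(self.calls)})"

    def substitutions(self) -> "Callset":
        return Callset(self.platform_id, (c for c in self.calls if c.is_substitution))

    def indels(self) -> "Callset":
        return Callset(self.platform_id, (c for c in self.calls if not c.is_substitution))

    def sites(self) -> set[GenomicSite]:
        return {c.site for c in self.calls}


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-site, per-platform pileup summary used for filtering and
    reason-for-miss classification.

    depth
        Non-duplicate reads covering the site (post-deduplication).
    alt_count
        Reads showing the queried alternate allele.
    rms_mapq
        Root-mean-square mapping quality; ``None`` for aligners that do not
        assign mapping qualities.
    snp_qual
        Call quality at the site, if the caller emitted one.
    nearby_snp_count
        Other candidate SNPs within the configured cluster window.
    nearest_indel_distance
        Distance in bp to the nearest high-quality indel; ``None`` if none.
    in_unique_region
        Whether the site lies in the uniquely-mappable region for this
        platform's read length.
    """

    site: GenomicSite
    depth: int
    alt_count: int
    rms_mapq: Optional[float] = None
    snp_qual: Optional[float] = None
    nearby_snp_count: int = 0
    nearest_indel_distance: Optional[int] = None
    in_unique_region: bool = True

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_count < 0 or self.nearby_snp_count < 0:
            raise ValueError("counts must be >= 0")
        if self.alt_count > self.depth:
            raise ValueError(
                f"alt_count ({self.alt_count}) exceeds depth ({self.depth})"
            )


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open 0-based genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, site: GenomicSite) -> bool:
        return site.chrom == self.chrom and self.start <= site.pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "Interval") -> int:
        """Bases strictly between the two intervals; 0 when they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class PlatformConfig:
    """Call-retention thresholds and classifier parameters for one platform.

    Depth bounds are inclusive on both ends; ``min_qual=None`` disables the
    quality rule (callers such as Newbler that emit no comparable quality).
    """

    min_depth: int
    max_depth_autosome: int
    max_depth_sex: int
    max_depth_mito: int
    min_qual: Optional[float]
    hom_fraction_threshold: float = 0.8
    has_mapq: bool = True
    cluster_window_bp: int = 10
    cluster_max_snps: int = 2
    indel_distance_bp: int = 3
    min_rms_mapq: float = 25.0

    def __post_init__(self) -> None:
        for name in ("max_depth_autosome", "max_depth_sex", "max_depth_mito"):
            if self.min_depth > getattr(self, name):
                raise ValueError(f"min_depth exceeds {name}")
        if not (0.0 < self.hom_fraction_threshold < 1.0):
            raise ValueError("hom_fraction_threshold must be in (0, 1)")

    def max_depth(self, chrom_class: ChromClass) -> int:
        return {
            ChromClass.AUTOSOME: self.max_depth_autosome,
            ChromClass.SEX: self.max_depth_sex,
            ChromClass.MITO: self.max_depth_mito,
        }[chrom_class]


#: Default retention thresholds for the three platform archetypes.
#: The 454-like profile keeps calls with depth in [2, 30] and has no mapping
#: quality; the Illumina-like profile requires depth in [4, 60] (45 on sex
#: chromosomes, effectively unlimited on the mitochondrion) and quality >= 20;
#: the SOLiD-like profile is the same with an autosomal ceiling of 100
#: (60 on sex chromosomes).
PLATFORM_DEFAULTS: Mapping[str, PlatformConfig] = {
    "roche454": PlatformConfig(
        min_depth=2, max_depth_autosome=30, max_depth_sex=30, max_depth_mito=30,
        min_qual=None, has_mapq=False,
    ),
    "illumina": PlatformConfig(
        min_depth=4, max_depth_autosome=60, max_depth_sex=45, max_depth_mito=10_000,
        min_qual=20.0,
    ),
    "solid": PlatformConfig(
        min_depth=4, max_depth_autosome=100, max_depth_sex=60, max_depth_mito=10_000,
        min_qual=20.0,
    ),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Whole-analysis configuration.

    Chromosome classes come from configuration rather than name heuristics so
    the pipeline is species-agnostic; every chromosome appearing in an input
    must have a class (unlisted chromosomes default to autosome).
    """

    platforms: Mapping[str, PlatformConfig] = field(
        default_factory=lambda: dict(PLATFORM_DEFAULTS)
    )
    chrom_classes: Mapping[str, ChromClass] = field(default_factory=dict)
    gc_window_bp: int = 50_000
    indel_slop_bp: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.gc_window_bp <= 0:
            raise ValueError("gc_window_bp must be > 0")
        if self.indel_slop_bp < 0:
            raise ValueError("indel_slop_bp must be >= 0")

    def chrom_class(self, chrom: str) -> ChromClass:
        return self.chrom_classes.get(chrom, ChromClass.AUTOSOME)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def default_config(**overrides) -> AnalysisConfig:
    """An :class:`AnalysisConfig` with the three default platform profiles."""
    return AnalysisConfig(**overrides)


def sites_of(calls: Sequence[VariantCall]) -> set[GenomicSite]:
    return {c.site for c in calls}
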