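"""Cross-platform concordance analysis.

Venn partitioning assigns every variant location to the cell of exactly the
platforms that called it. For locations supported by some platforms but not
all, a nine-rule classifier assigns the missing platform's reason for the
miss, in three groups: coverage issues (none / too little / more than
expected), alternate-allele issues (not seen / seen only once), and
variant-calling filters (SNP cluster, nearby high-quality indel, low RMS
mapping quality — or non-unique placement for aligners without mapping
qualities — and low call quality). Locations supported by a single platform
feed a false-positive estimate: a singleton is plausibly real only if every
other platform either had compromised coverage there or saw the alternate
allele at least once.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    Callset,
    ChromClass,
    EvidenceRecord,
    GenomicSite,
    Interval,
    PlatformConfig,
)

__all__ = [
    "MissCategory",
    "VennPartition",
    "venn_partition",
    "aggregate_platform_totals",
    "aggregate_cell_counts",
    "classify_missed_site",
    "summarize_categories",
    "FalsePositiveEstimate",
    "estimate_false_positives",
    "IndelMatchResult",
    "indel_overlap",
]


class MissCategory(enum.Enum):
    """Why a platform failed to call a site another platform supports.

    Members carry the report slot (1-9); NON_UNIQUE shares slot 8 with
    LOW_RMS_MAPQ — it is the analogous condition for aligners that do not
    assign mapping qualities and instead drop multiply-placed reads.
    UNEXPLAINED (slot 0) is the explicit residual so the classifier is total.
    """

    NO_COVERAGE = 1
    LOW_COVERAGE = 2
    EXCESS_COVERAGE = 3
    ALT_NOT_SEEN = 4
    ALT_SEEN_ONCE = 5
    SNP_CLUSTER = 6
    NEAR_INDEL = 7
    LOW_RMS_MAPQ = 8
    NON_UNIQUE = 8.5
    LOW_SNP_QUAL = 9
    UNEXPLAINED = 0

    @property
    def slot(self) -> int:
        return int(self.value)


@dataclass
class VennPartition:
    """Disjoint assignment of every variant location to the subset of
    platforms calling it."""

    platforms: tuple[str, ...]
    cells: dict[frozenset, set]  # frozenset[str] -> set[GenomicSite]

    def cell(self, *platform_ids: str) -> set[GenomicSite]:
        return self.cells.get(frozenset(platform_ids), set())

    def cell_sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.cells.items() if v}

    def union_sites(self) -> set[GenomicSite]:
        out: set[GenomicSite] = set()
        for sites in self.cells.values():
            out |= sites
        return out


def venn_partition(callsets: Sequence[Callset]) -> VennPartition:
    """Partition the union of callset sites by exactly-which-platforms-called-it."""
    if len(callsets) < 2:
        raise ValueError("need at least 2 callsets")
    ids = [cs.platform_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate platform ids in {ids}")
    membership: dict[GenomicSite, set[str]] = {}
    for cs in callsets:
        for site in cs.sites():
            membership.setdefault(site, set()).add(cs.platform_id)
    cells: dict[frozenset, set] = {}
    for site, supporters in membership.items():
        cells.setdefault(frozenset(supporters), set()).add(site)
    return VennPartition(platforms=tuple(ids), cells=cells)


def aggregate_cell_counts(cell_counts: Mapping[frozenset, int],
                          platforms: Sequence[str]) -> dict:
    """Per-platform totals, union and discordant-location count from disjoint
    Venn cell sizes.

    A platform's total is the sum of the cells containing it; the union is
    the sum of all cells; discordant locations are those outside the cell
    shared by every platform.
    """
    totals = {p: 0 for p in platforms}
    union = 0
    full = frozenset(platforms)
    shared = 0
    for cell, n in cell_counts.items():
        union += n
        if cell == full:
            shared += n
        for p in cell:
            totals[p] += n
    return {
        "per_platform": totals,
        "union": union,
        "shared_by_all": shared,
        "discordant": union - shared,
    }


def aggregate_platform_totals(partition: VennPartition) -> dict:
    return aggregate_cell_counts(partition.cell_sizes(), partition.platforms)


def classify_missed_site(
    evidence: EvidenceRecord,
    platform_config: PlatformConfig,
    chrom_class: ChromClass = ChromClass.AUTOSOME,
) -> MissCategory:
    """Assign the single reason the platform missed this site.

    The first matching rule wins, in the fixed precedence coverage →
    alternate allele → calling filters (cluster, indel, mapping quality or
    uniqueness, call quality); anything else is UNEXPLAINED.
    """
    pc = platform_config
    ev = evidence
    if ev.depth == 0:
        return MissCategory.NO_COVERAGE
    if ev.depth < pc.min_depth:
        return MissCategory.LOW_COVERAGE
    if ev.depth > pc.max_depth(chrom_class):
        return MissCategory.EXCESS_COVERAGE
    if ev.alt_count == 0:
        return MissCategory.ALT_NOT_SEEN
    if ev.alt_count == 1:
        return MissCategory.ALT_SEEN_ONCE
    if ev.nearby_snp_count > pc.cluster_max_snps:
        return MissCategory.SNP_CLUSTER
    if (ev.nearest_indel_distance is not None
            and ev.nearest_indel_distance <= pc.indel_distance_bp):
        return MissCategory.NEAR_INDEL
    if pc.has_mapq:
        if ev.rms_mapq is not None and ev.rms_mapq < pc.min_rms_mapq:
            return MissCategory.LOW_RMS_MAPQ
    elif not ev.in_unique_region:
        return MissCategory.NON_UNIQUE
    if (pc.min_qual is not None and ev.snp_qual is not None
            and ev.snp_qual < pc.min_qual):
        return MissCategory.LOW_SNP_QUAL
    return MissCategory.UNEXPLAINED


def summarize_categories(
    classified: Mapping[tuple[GenomicSite, str], MissCategory],
) -> pd.DataFrame:
    """Counts and fractions per missing platform and category.

    Returns a tidy frame with columns platform, category, slot, count,
    fraction; fractions sum to 1 within each platform. Empty input yields an
    empty frame with the same columns.
    """
    columns = ["platform", "category", "slot", "count", "fraction"]
    if not classified:
        return pd.DataFrame(columns=columns)
    rows: dict[tuple[str, MissCategory], int] = {}
    for (_site, platform), cat in classified.items():
        rows[(platform, cat)] = rows.get((platform, cat), 0) + 1
    records = []
    totals: dict[str, int] = {}
    for (platform, _), n in rows.items():
        totals[platform] = totals.get(platform, 0) + n
    for (platform, cat), n in sorted(
        rows.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        records.append({
            "platform": platform,
            "category": cat.name,
            "slot": cat.slot,
            "count": n,
            "fraction": n / totals[platform],
        })
    return pd.DataFrame(records, columns=columns)


@dataclass
class FalsePositiveEstimate:
    plausible_true: int
    putative_fp: int
    plausible_true_sites: set = field(default_factory=set)
    putative_fp_sites: set = field(default_factory=set)


def _coverage_compromised(ev: EvidenceRecord, pc: PlatformConfig,
                          chrom_class: ChromClass) -> bool:
    return (ev.depth == 0 or ev.depth < pc.min_depth
            or ev.depth > pc.max_depth(chrom_class))


def estimate_false_positives(
    singleton_sites: Iterable[GenomicSite],
    other_evidence: Mapping[str, Mapping[GenomicSite, EvidenceRecord]],
    config: AnalysisConfig,
) -> FalsePositiveEstimate:
    """Estimate how many single-platform calls are false positives.

    A singleton is counted plausibly true iff, for EACH other platform, that
    platform's coverage at the site was compromised (zero, below its
    minimum, or above its class maximum) OR it observed the alternate allele
    at least once. Everything else is a putative false positive.
    """
    true_sites: set[GenomicSite] = set()
    fp_sites: set[GenomicSite] = set()
    for site in singleton_sites:
        excused = True
        for platform, ev_map in other_evidence.items():
            ev = ev_map.get(site)
            if ev is None:
                raise KeyError(
                    f"no {platform} evidence for singleton {site.chrom}:{site.pos}"
                )
            pc = config.platforms[platform]
            cls = config.chrom_class(site.chrom)
            if not (_coverage_compromised(ev, pc, cls) or ev.alt_count >= 1):
                excused = False
                break
        (true_sites if excused else fp_sites).add(site)
    return FalsePositiveEstimate(
        plausible_true=len(true_sites),
        putative_fp=len(fp_sites),
        plausible_true_sites=true_sites,
        putative_fp_sites=fp_sites,
    )


@dataclass
class IndelMatchResult:
    """Disjoint categorisation of every A-interval against set B."""

    exact: list  # list[tuple[Interval, Interval]]
    slop_only: list  # list[tuple[Interval, Interval]]
    unmatched: list  # list[Interval]

    @property
    def n_exact(self) -> int:
        return len(self.exact)

    @property
    def n_slop_only(self) -> int:
        return len(self.slop_only)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)


def indel_overlap(set_a: Sequence[Interval], set_b: Sequence[Interval],
                  slop_bp: int) -> IndelMatchResult:
    """Match each A-interval to its nearest B-interval with +/- slop tolerance.

    An A-interval is an exact match when it intersects its nearest B-interval
    directly, a slop-only match when the gap between them is positive but at
    most ``slop_bp`` (i.e. they intersect only after +/- slop expansion), and
    unmatched otherwise. Nearest is by gap; ties go to the leftmost
    B-interval. The three categories are disjoint and cover A.
    """
    if slop_bp < 0:
        raise ValueError("slop_bp must be >= 0")
    by_chrom: dict[str, list[Interval]] = {}
    for b in sorted(set_b):
        by_chrom.setdefault(b.chrom, []).append(b)
    b_arrays = {
        chrom: (np.asarray([b.start for b in bs]), np.asarray([b.end for b in bs]))
        for chrom, bs in by_chrom.items()
    }
    exact, slop_only, unmatched = [], [], []
    for a in set_a:
        bs = by_chrom.get(a.chrom)
        if not bs:
            unmatched.append(a)
            continue
        starts, ends = b_arrays[a.chrom]
        gaps = np.maximum(0, np.maximum(a.start, starts) - np.minimum(a.end, ends))
        i = int(np.argmin(gaps))  # argmin takes the first (leftmost) minimum
        gap = int(gaps[i])
        if gap == 0:
            exact.append((a, bs[i]))
        elif gap <= slop_bp:
            slop_only.append((a, bs[i]))
        else:
            unmatched.append(a)
    return IndelMatchResult(exact=exact, slop_only=slop_only, unmatched=unmatched)
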