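"""Standard-format I/O: VCF (subset), BED3, evidence/label TSV, FASTA, TOML config.

External files use the conventions of their formats (VCF and the tabular
dialects are 1-based; BED is 0-based half-open); everything is converted to
the package's internal 0-based half-open coordinates at this boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import (
    PLATFORM_DEFAULTS,
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

logger = logging.getLogger("concordkit")

PathLike = Union[str, Path]

#: Column order of the tab-separated variant dialect (``pos`` is 1-based).
TSV_CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "kind", "genotype", "quality"]

#: Column order of the evidence table (``pos`` is 1-based; missing optional
#: values are written as ``.``).
EVIDENCE_COLUMNS = [
    "chrom", "pos", "depth", "alt_count", "rms_mapq", "snp_qual",
    "nearby_snp_count", "nearest_indel_distance", "in_unique_region",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


def _classify_alleles(ref: str, alt: str) -> VariantKind:
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SUBSTITUTION
    if len(alt) > len(ref):
        return VariantKind.INSERTION
    return VariantKind.DELETION


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

def read_variant_calls(path: PathLike, dialect: str = "vcf",
                       platform_id: Optional[str] = None) -> Callset:
    """Read a callset from a VCF (subset) or the tab-separated dialect.

    1-based file positions become internal 0-based positions. Unsorted input
    is re-sorted with a logged notice.
    """
    path = Path(path)
    if platform_id is None:
        platform_id = path.stem
    if dialect == "vcf":
        calls = _read_vcf(path)
    elif dialect == "tsv":
        calls = _read_tsv_calls(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'tsv'")
    keys = [(c.site.chrom, c.site.pos) for c in calls]
    if keys != sorted(keys):
        logger.info("input %s was not coordinate-sorted; re-sorting", path)
    return Callset(platform_id, calls)


def _read_vcf(path: Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        for rec in vf:
            try:
                alt = rec.alts[0] if rec.alts else ""
                gt = Zygosity.HET
                if rec.samples:
                    sample = rec.samples[0]
                    alleles = sample.get("GT", (None, None))
                    if alleles and None not in alleles and len(set(alleles)) == 1:
                        gt = Zygosity.HOM
                calls.append(VariantCall(
                    site=GenomicSite(rec.chrom, rec.pos - 1),
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    kind=_classify_alleles(rec.ref, alt),
                    genotype=gt,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                ))
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}: bad record at {rec.chrom}:{rec.pos}: {exc}") from exc
    return calls


def _read_tsv_calls(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(TSV_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(VariantCall(
                site=GenomicSite(str(row.chrom), int(row.pos) - 1),
                ref_allele=row.ref,
                alt_allele=row.alt,
                kind=VariantKind(row.kind),
                genotype=Zygosity(row.genotype),
                quality=float(row.quality),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return calls


def write_variant_calls(callset: Callset, path: PathLike, dialect: str = "vcf",
                        contigs: Optional[Sequence[str]] = None) -> None:
    """Write a callset as a minimal VCF 4.2 (CHROM POS REF ALT QUAL GT) or TSV."""
    path = Path(path)
    if dialect == "tsv":
        rows = [
            {
                "chrom": c.site.chrom, "pos": c.site.pos + 1,
                "ref": c.ref_allele, "alt": c.alt_allele,
                "kind": c.kind.value, "genotype": c.genotype.value,
                "quality": c.quality,
            }
            for c in callset
        ]
        pd.DataFrame(rows, columns=TSV_CALL_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    if contigs is None:
        contigs = sorted({c.site.chrom for c in callset})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=concordkit platform={callset.platform_id}\n")
        for ctg in contigs:
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{callset.platform_id}\n")
        for c in callset:
            gt = "1/1" if c.genotype is Zygosity.HOM else "0/1"
            fh.write(
                f"{c.site.chrom}\t{c.site.pos + 1}\t.\t{c.ref_allele}\t"
                f"{c.alt_allele}\t{c.quality:g}\t.\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[Interval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: PathLike) -> list[Interval]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": int, "end": int})
    except pd.errors.EmptyDataError:
        return []
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(Interval(row.chrom, int(row.start), int(row.end)))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Evidence and label tables
# ---------------------------------------------------------------------------

def _fmt_opt(value) -> str:
    return "." if value is None else f"{value:g}" if isinstance(value, float) else str(value)


def write_evidence(records: Iterable[EvidenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.site.chrom, r.site.pos)):
            fh.write("\t".join([
                r.site.chrom, str(r.site.pos + 1), str(r.depth), str(r.alt_count),
                _fmt_opt(r.rms_mapq), _fmt_opt(r.snp_qual),
                str(r.nearby_snp_count), _fmt_opt(r.nearest_indel_distance),
                "1" if r.in_unique_region else "0",
            ]) + "\n")


def read_evidence(path: PathLike) -> dict[GenomicSite, EvidenceRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: dict[GenomicSite, EvidenceRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            site = GenomicSite(str(row.chrom), int(row.pos) - 1)
            out[site] = EvidenceRecord(
                site=site,
                depth=int(row.depth),
                alt_count=int(row.alt_count),
                rms_mapq=None if pd.isna(row.rms_mapq) else float(row.rms_mapq),
                snp_qual=None if pd.isna(row.snp_qual) else float(row.snp_qual),
                nearby_snp_count=int(row.nearby_snp_count),
                nearest_indel_distance=(
                    None if pd.isna(row.nearest_indel_distance)
                    else int(float(row.nearest_indel_distance))
                ),
                in_unique_region=row.in_unique_region == "1",
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"random_seed", "gc_window_bp", "indel_slop_bp", "chromosomes", "platforms"}
_PLATFORM_KEYS = {f.name for f in dataclasses.fields(PlatformConfig)}


def load_config(path: PathLike) -> AnalysisConfig:
    """Load a TOML configuration, filling unspecified fields with defaults.

    An empty file yields the three default platform profiles (454-like,
    Illumina-like, SOLiD-like). Platform tables may override any
    :class:`PlatformConfig` field; unknown keys are rejected with the list of
    valid keys.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> AnalysisConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    platforms: dict[str, PlatformConfig] = dict(PLATFORM_DEFAULTS)
    for name, overrides in raw.get("platforms", {}).items():
        unknown = set(overrides) - _PLATFORM_KEYS
        if unknown:
            raise ValueError(
                f"unknown platform keys {sorted(unknown)} for {name!r}; "
                f"valid keys: {sorted(_PLATFORM_KEYS)}"
            )
        base = platforms.get(name)
        if base is not None:
            platforms[name] = dataclasses.replace(base, **overrides)
        else:
            platforms[name] = PlatformConfig(**overrides)
    chrom_classes = {
        chrom: ChromClass(value)
        for chrom, value in raw.get("chromosomes", {}).items()
    }
    return AnalysisConfig(
        platforms=platforms,
        chrom_classes=chrom_classes,
        gc_window_bp=int(raw.get("gc_window_bp", 50_000)),
        indel_slop_bp=int(raw.get("indel_slop_bp", 10)),
        random_seed=int(raw.get("random_seed", 0)),
    )
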