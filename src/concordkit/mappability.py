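"""Uniquely-mappable region ("uniqueome") computation by self-tiling.

The reference is broken into fragments of the read length L, adjacent
fragments overlapping by L/2. Every gapless placement of every fragment on
either strand of the reference with at most ``floor(max_divergence * L)``
mismatches increments a per-base counter under the placement. A base is
uniquely mappable iff its counter does not exceed its tile multiplicity —
the number of tiles that cover it (2 for interior bases, 1 near chromosome
ends covered by a single tile) — since those home placements always match.

Matching is mismatch-only (no gaps). Placement search uses a pigeonhole
seed filter: a placement with <= k mismatches must contain at least one of
k+1 disjoint exact seeds, so exact-seed lookup followed by Hamming
verification enumerates every qualifying placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Callset, GenomicSite, Interval

__all__ = [
    "Fragment",
    "MappabilityTrack",
    "tile_reference",
    "count_fragment_alignments",
    "unique_intervals",
    "merge_intervals",
    "filter_by_regions",
    "compute_uniqueome",
]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Sequence as uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


@dataclass(frozen=True)
class Fragment:
    interval: Interval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("fragment sequence length must equal interval length")


@dataclass
class MappabilityTrack:
    """Per-base placement counters plus the tile multiplicity they are
    compared against."""

    counters: dict[str, np.ndarray]
    tile_multiplicity: dict[str, np.ndarray]
    fragment_length: int
    max_divergence: float


def tile_reference(reference: Mapping[str, str], fragment_length: int) -> list[Fragment]:
    """Fragments of length L starting at 0, L/2, L, ...; if the final regular
    start leaves a tail uncovered, one extra fragment is anchored at
    chrom_length - L. No duplicate fragments are emitted."""
    L = fragment_length
    if L < 2 or L % 2 != 0:
        raise ValueError("fragment_length must be even and >= 2")
    fragments: list[Fragment] = []
    for chrom, seq in reference.items():
        n = len(seq)
        if n < L:
            raise ValueError(
                f"chromosome {chrom} (length {n}) is shorter than fragment length {L}"
            )
        starts = list(range(0, n - L + 1, L // 2))
        if starts[-1] + L < n:
            starts.append(n - L)
        for s in starts:
            fragments.append(Fragment(Interval(chrom, s, s + L), seq[s:s + L]))
    return fragments


def _tile_multiplicity(chrom_lengths: Mapping[str, int],
                       fragments: Sequence[Fragment], L: int) -> dict[str, np.ndarray]:
    mult = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for f in fragments:
        mult[f.interval.chrom][f.interval.start:f.interval.end] += 1
    return mult


def _seed_index(enc: np.ndarray, q: int) -> dict[bytes, np.ndarray]:
    """Map each q-gram of the encoded chromosome to its start positions."""
    n = enc.size
    grams: dict[bytes, list[int]] = {}
    buf = enc.tobytes()
    for p in range(n - q + 1):
        grams.setdefault(buf[p:p + q], []).append(p)
    return {g: np.asarray(ps, dtype=np.int64) for g, ps in grams.items()}


def _placements(frag: np.ndarray, enc: np.ndarray,
                index: dict[bytes, np.ndarray], q: int, k: int) -> np.ndarray:
    """Start positions on one chromosome where ``frag`` places with <= k
    mismatches (pigeonhole-complete seed search)."""
    L = frag.size
    n = enc.size
    fbuf = frag.tobytes()
    cands: set[int] = set()
    for i in range(k + 1):
        off = i * q
        hits = index.get(fbuf[off:off + q])
        if hits is not None:
            for p in (hits - off):
                if 0 <= p <= n - L:
                    cands.add(int(p))
    if not cands:
        return np.empty(0, dtype=np.int64)
    cand = np.fromiter(cands, dtype=np.int64)
    windows = enc[cand[:, None] + np.arange(L)]
    mism = (windows != frag).sum(axis=1)
    return np.sort(cand[mism <= k])


def count_fragment_alignments(reference: Mapping[str, str],
                              fragments: Sequence[Fragment],
                              max_divergence: float) -> MappabilityTrack:
    """Count, for every reference base, the gapless placements (both strands,
    <= floor(max_divergence * L) mismatches) of all fragments covering it."""
    if not fragments:
        raise ValueError("no fragments")
    L = len(fragments[0].interval)
    k = int(max_divergence * L)
    q = L // (k + 1)
    if q < 1:
        raise ValueError("max_divergence too high for this fragment length")
    enc = {c: encode(s) for c, s in reference.items()}
    index = {c: _seed_index(e, q) for c, e in enc.items()}
    # difference arrays: +1 at each placement start, -1 past its end
    deltas = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in reference.items()}
    for f in fragments:
        fe = encode(f.sequence)
        for strand_codes in (fe, revcomp_codes(fe)):
            for chrom, e in enc.items():
                ps = _placements(strand_codes, e, index[chrom], q, k)
                if ps.size:
                    np.add.at(deltas[chrom], ps, 1)
                    np.add.at(deltas[chrom], ps + L, -1)
    counters = {c: np.cumsum(d[:-1]) for c, d in deltas.items()}
    mult = _tile_multiplicity({c: len(s) for c, s in reference.items()}, fragments, L)
    return MappabilityTrack(
        counters=counters,
        tile_multiplicity=mult,
        fragment_length=L,
        max_divergence=max_divergence,
    )


def unique_intervals(track: MappabilityTrack) -> list[Interval]:
    """Maximal runs of uniquely-mappable bases (counter <= tile multiplicity)
    as half-open intervals, sorted by (chrom, start)."""
    out: list[Interval] = []
    for chrom in sorted(track.counters):
        unique = track.counters[chrom] <= track.tile_multiplicity[chrom]
        out.extend(_runs_to_intervals(chrom, unique))
    return out


def _runs_to_intervals(chrom: str, mask: np.ndarray) -> list[Interval]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [Interval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or adjacent same-chromosome intervals."""
    merged: list[Interval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def filter_by_regions(callset: Callset, intervals: Iterable[Interval]) -> Callset:
    """Retain exactly the calls whose site lies inside some interval."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    for chrom in by_chrom:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.asarray([iv.start for iv in ivs]),
            np.asarray([iv.end for iv in ivs]),
        )

    def _inside(site: GenomicSite) -> bool:
        se = by_chrom.get(site.chrom)
        if se is None:
            return False
        starts, ends = se
        i = int(np.searchsorted(starts, site.pos, side="right")) - 1
        return i >= 0 and site.pos < ends[i]

    return Callset(callset.platform_id, (c for c in callset if _inside(c.site)))


def compute_uniqueome(reference: Mapping[str, str], fragment_length: int,
                      max_divergence: float = 0.05) -> list[Interval]:
    """Tile, count and extract uniquely-mappable intervals in one call."""
    frags = tile_reference(reference, fragment_length)
    track = count_fragment_alignments(reference, frags, max_divergence)
    return unique_intervals(track)
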