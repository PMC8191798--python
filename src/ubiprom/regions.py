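"""Core genomic-interval arithmetic, signal aggregation and sampling.

Coordinates are 0-based half-open (BED convention) throughout the package.
The interval center is ``floor((start + end) / 2)`` and all center-based
operations (resizing, meta-profiles) are left-biased on parity mismatches so
that every operation is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import __version__

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open region on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 when disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def resize_center(region: GenomicInterval, width: int) -> GenomicInterval:
    """Return a ``width``-bp interval sharing ``region``'s center.

    The new start is ``center - floor(width / 2)`` (left-biased). A resize
    that would cross the chromosome origin is clipped at zero and flagged
    with a warning; the returned interval is then shorter than ``width``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    center = region.center
    new_start = center - width // 2
    new_end = new_start + width
    if new_start < 0:
        warnings.warn(
            f"resize of {region.chrom}:{region.start}-{region.end} to {width} bp "
            "clipped at chromosome origin",
            stacklevel=2,
        )
        new_start = 0
    return replace(region, start=new_start, end=new_end)


def oriented_flanks(
    region: GenomicInterval, flank: int
) -> tuple[GenomicInterval, GenomicInterval]:
    """Upstream/downstream ``flank``-bp windows in transcription orientation.

    On ``+`` the upstream flank precedes ``start`` and the downstream flank
    follows ``end``; on ``-`` the two are mirrored.  Unstranded regions are
    rejected because orientation is required.  Flanks crossing the origin
    are clipped at zero with a warning.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if region.strand not in ("+", "-"):
        raise ValueError("oriented_flanks requires a stranded region (+ or -)")

    def _make(lo: int, hi: int, tag: str) -> GenomicInterval:
        if lo < 0:
            warnings.warn(
                f"{tag} flank of {region.chrom}:{region.start}-{region.end} "
                "clipped at chromosome origin",
                stacklevel=3,
            )
            lo = 0
        rid = f"{region.id}_{tag}" if region.id else None
        return GenomicInterval(region.chrom, lo, hi, region.strand, rid)

    if region.strand == "+":
        upstream = _make(region.start - flank, region.start, "up")
        downstream = _make(region.end, region.end + flank, "down")
    else:
        upstream = _make(region.end, region.end + flank, "up")
        downstream = _make(region.start - flank, region.start, "down")
    return upstream, downstream


class SignalTrack:
    """Sparse run-length signal over chromosomes (bedGraph semantics).

    Positions not covered by any run have implicit value 0.  Runs within a
    chromosome must be sorted and non-overlapping.
    """

    def __init__(self, runs: dict[str, Sequence[tuple[int, int, float]]] | None = None):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, triples in runs.items():
                self.set_chrom(chrom, triples)

    def set_chrom(self, chrom: str, triples: Sequence[tuple[int, int, float]]) -> None:
        if not triples:
            return
        arr = sorted(triples)
        starts = np.array([t[0] for t in arr], dtype=np.int64)
        ends = np.array([t[1] for t in arr], dtype=np.int64)
        values = np.array([t[2] for t in arr], dtype=float)
        if np.any(ends <= starts):
            raise ValueError("runs must have end > start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping runs on {chrom}")
        self._runs[chrom] = (starts, ends, values)

    def chroms(self) -> list[str]:
        return list(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end), uncovered positions counting as 0."""
        if end <= start:
            raise ValueError("end must exceed start")
        starts, ends, values = self.runs(chrom)
        if starts.size == 0:
            return 0.0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, values[lo:hi]) / (end - start))


@dataclass
class MetaProfile:
    """Average signal around region centers, transcription-oriented.

    ``bin_offsets`` are the left edges (bp, signed, relative to center) of
    equal-width bins covering exactly [-window, +window).
    """

    bin_offsets: np.ndarray
    mean_signal: np.ndarray
    n_regions: int
    bin_width: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_regions <= 0:
            raise ValueError("MetaProfile requires n_regions > 0")

    def peak_offset(self) -> float:
        """Offset (bin center, bp) of the maximal bin."""
        i = int(np.argmax(self.mean_signal))
        return float(self.bin_offsets[i]) + self.bin_width / 2.0


def _oriented_bin_bounds(
    center: int, strand: str, window: int, bin_width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Genomic [lo, hi) bounds of each profile bin for one region.

    Bin k covers offsets [-window + k*bw, -window + (k+1)*bw) downstream of
    transcription; for minus-strand regions the genomic coordinates run in
    the opposite direction.
    """
    offs = np.arange(-window, window, bin_width, dtype=np.int64)
    if strand == "-":
        hi = center - offs
        lo = hi - bin_width
    else:
        lo = center + offs
        hi = lo + bin_width
    return lo, hi


def average_signal_over_regions(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    window: int = 2000,
    bin_width: int = 10,
) -> MetaProfile:
    """Mean track signal in a +/-``window`` profile centered on each region.

    Minus-strand regions are flipped so positive offsets always point
    downstream of transcription; unstranded regions are treated as plus.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if window % bin_width != 0:
        raise ValueError("window must be divisible by bin_width")
    offs = np.arange(-window, window, bin_width, dtype=np.int64)
    acc = np.zeros(offs.size, dtype=float)
    for region in regions:
        lo, hi = _oriented_bin_bounds(region.center, region.strand, window, bin_width)
        for k in range(offs.size):
            if hi[k] <= 0:
                continue
            acc[k] += track.mean(region.chrom, max(lo[k], 0), hi[k])
    acc /= len(regions)
    return MetaProfile(offs, acc, len(regions), bin_width)


def length_matched_sample(
    pool: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    bin_width: int = 25,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Sample from ``pool`` to match ``reference``'s binned length histogram.

    The returned subset realizes the largest histogram proportional to the
    reference's that the pool can supply: the common scale is the minimum
    pool/reference count ratio over occupied reference bins.  Reference bins
    the pool cannot serve at all are dropped with a warning (the remaining
    bins keep their relative proportions).  Deterministic for a given seed.
    """
    if not pool or not reference:
        raise ValueError("pool and reference must be non-empty")
    rng = np.random.default_rng(seed)
    ref_counts: dict[int, int] = {}
    for r in reference:
        ref_counts[len(r) // bin_width] = ref_counts.get(len(r) // bin_width, 0) + 1
    pool_bins: dict[int, list[GenomicInterval]] = {}
    for p in sorted(pool, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id or "")):
        pool_bins.setdefault(len(p) // bin_width, []).append(p)

    servable = {b: n for b, n in ref_counts.items() if pool_bins.get(b)}
    missing = set(ref_counts) - set(servable)
    if missing:
        warnings.warn(
            f"{len(missing)} reference length bin(s) have no pool candidates; "
            "matched histogram downscaled over the remaining bins",
            stacklevel=2,
        )
    if not servable:
        return []
    scale = min(len(pool_bins[b]) / n for b, n in servable.items())
    if scale < 1:
        warnings.warn(
            f"pool cannot match the reference histogram at full size; "
            f"downscaling by {scale:.3f}",
            stacklevel=2,
        )
    out: list[GenomicInterval] = []
    for b in sorted(servable):
        take = int(np.floor(scale * servable[b] + 1e-9))
        take = min(take, len(pool_bins[b]))
        idx = rng.choice(len(pool_bins[b]), size=take, replace=False)
        out.extend(pool_bins[b][i] for i in sorted(idx))
    return out


def shift_reads_3prime(
    read_positions: Iterable[tuple[int, str]], shift: int
) -> tuple[list[int], int]:
    """Shift 5'-end read positions 3'-ward by ``shift`` bp.

    Plus-strand reads move right, minus-strand reads move left.  Returns the
    shifted positions and the number of reads dropped for falling below the
    chromosome origin.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    out: list[int] = []
    dropped = 0
    for pos, strand in read_positions:
        new = pos + shift if strand == "+" else pos - shift
        if new < 0:
            dropped += 1
        else:
            out.append(new)
    return out, dropped


# ---------------------------------------------------------------------------
# I/O: BED6, bedGraph, MetaProfile TSV


def _header(params: str) -> str:
    return f"# ubiprom {__version__} {params}\n"


def read_bed6(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed6(path: str, regions: Iterable[GenomicInterval], params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(f"bed6 {params}".strip()))
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id or '.'}\t0\t{r.strand}\n")


def read_bedgraph(path: str) -> SignalTrack:
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.rstrip("\n").split("\t")[:4]
            runs.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return SignalTrack(runs)


def write_bedgraph(path: str, track: SignalTrack, params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(f"bedgraph {params}".strip()))
        for chrom in sorted(track.chroms()):
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_metaprofile(path: str, profile: MetaProfile, params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(f"metaprofile n_regions={profile.n_regions} {params}".strip()))
        fh.write("offset\tmean\tn\n")
        for off, mean in zip(profile.bin_offsets, profile.mean_signal):
            fh.write(f"{off}\t{mean:.6g}\t{profile.n_regions}\n")


def read_metaprofile(path: str) -> MetaProfile:
    offs: list[int] = []
    means: list[float] = []
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("offset"):
                continue
            o, m, nn = line.rstrip("\n").split("\t")
            offs.append(int(o))
            means.append(float(m))
            n = int(nn)
    offsets = np.array(offs)
    width = int(offsets[1] - offsets[0]) if offsets.size > 1 else 0
    return MetaProfile(offsets, np.array(means), n, width)
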