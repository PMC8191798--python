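"""Ubiquity calling and cCRE classification from DNase Z-score matrices.

A "high" signal is a Z-score strictly above 1.64 (the upper-tail 5% point
of the standard normal, i.e. a one-sided Z-test at P = 0.05).  An element
is ubiquitous when it is high in at least ``min_samples`` biosamples —
in the human ENCODE compendium 500 of 517, in mouse 90 of 94, both
~95% of the assayed biosamples, which is the default when ``min_samples``
is not given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import ceil

import numpy as np
import pandas as pd

from .regions import GenomicInterval

Z_HIGH_THRESHOLD = 1.64

CCRE_CLASSES = (
    "PLS",
    "pELS",
    "dELS",
    "DNase-H3K4me3",
    "CTCF-only",
    "DNase-only",
)


class SignalZMatrix:
    """Elements x biosamples matrix of DNase signal Z-scores."""

    def __init__(self, z: pd.DataFrame):
        if z.isna().any().any():
            raise ValueError("Z matrix must have no missing cells")
        self.z = z

    @property
    def element_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def biosample_ids(self) -> list[str]:
        return list(self.z.columns)

    @property
    def n_biosamples(self) -> int:
        return self.z.shape[1]

    @classmethod
    def from_tsv(cls, path: str) -> "SignalZMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0, comment="#"))

    def to_tsv(self, path: str) -> None:
        self.z.to_csv(path, sep="\t")


@dataclass(frozen=True)
class CcreRecord:
    """A candidate cis-regulatory element with its classification inputs."""

    interval: GenomicInterval
    h3k4me3_high: bool
    h3k27ac_high: bool
    ctcf_high: bool
    tss_distance: int
    ccre_class: str = "DNase-only"
    ubiquitous: bool = False

    def __post_init__(self) -> None:
        if self.tss_distance < 0:
            raise ValueError("tss_distance must be >= 0")

    @property
    def id(self) -> str | None:
        return self.interval.id


def count_high_samples(
    matrix: SignalZMatrix, z_threshold: float = Z_HIGH_THRESHOLD
) -> pd.Series:
    """Number of biosamples with Z strictly above the threshold, per element."""
    if not np.isfinite(z_threshold):
        raise ValueError("z_threshold must be finite")
    return (matrix.z > z_threshold).sum(axis=1)


def call_ubiquitous(counts: pd.Series, min_samples: int) -> pd.Series:
    """Boolean ubiquity call: high in ``min_samples`` or more biosamples."""
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    if len(counts) and min_samples > counts.max() and min_samples > 0:
        # Not an error: an over-strict threshold legitimately yields no calls,
        # but it usually signals a unit mistake, so say something.
        if min_samples > counts.max():
            warnings.warn(
                f"min_samples={min_samples} exceeds the largest observed count "
                f"({counts.max()}); no elements will be called",
                stacklevel=2,
            )
    return counts >= min_samples


def default_min_samples(n_biosamples: int, fraction: float = 0.95) -> int:
    """ceil(fraction * n_biosamples): the >=95%-of-biosamples rule."""
    return ceil(fraction * n_biosamples)


def classify_ccre(
    h3k4me3_high: bool, h3k27ac_high: bool, ctcf_high: bool, tss_distance: int
) -> str:
    """Assign a cCRE class by signature flags and TSS distance.

    Precedence: PLS > pELS > dELS > DNase-H3K4me3 > CTCF-only > DNase-only.
    PLS needs high H3K4me3 with a TSS within 200 bp of the element center;
    pELS/dELS need high H3K27ac and split at 2 kb; DNase-H3K4me3 is high
    H3K4me3 away from TSSs without H3K27ac; CTCF-only is high CTCF with
    neither histone mark.
    """
    if tss_distance < 0:
        raise ValueError("tss_distance must be >= 0")
    if h3k4me3_high and tss_distance <= 200:
        return "PLS"
    if h3k27ac_high and tss_distance <= 2000:
        return "pELS"
    if h3k27ac_high:
        return "dELS"
    if h3k4me3_high and tss_distance > 200:
        return "DNase-H3K4me3"
    if ctcf_high:
        return "CTCF-only"
    return "DNase-only"


def classify_records(records: list[CcreRecord]) -> list[CcreRecord]:
    """Return records with ``ccre_class`` filled in from their flags."""
    return [
        replace(
            r,
            ccre_class=classify_ccre(
                r.h3k4me3_high, r.h3k27ac_high, r.ctcf_high, r.tss_distance
            ),
        )
        for r in records
    ]


def biosample_specific_nonubi(
    ccres: list[CcreRecord],
    matrix: SignalZMatrix,
    biosample: str,
    z_threshold: float = Z_HIGH_THRESHOLD,
) -> list[CcreRecord]:
    """Non-ubiquitous PLS elements with a high DNase signal in one biosample.

    These are the biosample-matched comparison set for ubiquitous PLSs:
    promoter-class elements that are open in the given sample but not open
    nearly everywhere.
    """
    if biosample not in matrix.z.columns:
        raise KeyError(f"biosample {biosample!r} not in Z matrix")
    col = matrix.z[biosample]
    out = []
    for r in ccres:
        if r.ccre_class != "PLS" or r.ubiquitous:
            continue
        rid = r.id
        if rid is not None and rid in col.index and col[rid] > z_threshold:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# I/O: BED6+3 (class, flags, ubiquitous)


def write_ccres(path: str, records: list[CcreRecord]) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ubiprom {__version__} ccre bed6+3\n")
        for r in records:
            iv = r.interval
            flags = "".join(
                "1" if b else "0"
                for b in (r.h3k4me3_high, r.h3k27ac_high, r.ctcf_high)
            )
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}"
                f"\t{r.ccre_class}\t{flags}\t{int(r.ubiquitous)}\n"
            )


def read_ccres(path: str) -> list[CcreRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(
                f[0], int(f[1]), int(f[2]), f[5], None if f[3] == "." else f[3]
            )
            flags = f[7]
            out.append(
                CcreRecord(
                    interval=iv,
                    h3k4me3_high=flags[0] == "1",
                    h3k27ac_high=flags[1] == "1",
                    ctcf_high=flags[2] == "1",
                    tss_distance=0,
                    ccre_class=f[6],
                    ubiquitous=f[8] == "1",
                )
            )
    return out
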