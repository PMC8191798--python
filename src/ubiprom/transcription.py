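"""Expression conventions and TSS peak-shape classification.

Expression values are TPM, logged with a pseudocount of 0.1.  The
tissue-specificity index tau of an expression profile x over N biosamples is
``sum(1 - x_i/max(x)) / (N - 1)``: 0 for uniform expression, 1 for
single-biosample expression.  Profiles are quantile-normalized across
features within each sample before tau is computed.

A TSS peak (rPeak) is classified per biosample from the 5'-end positions of
its reads: fewer than 10 reads leaves it unclassified; if fewer than 50% of
reads fall within +/-2 nt of the summit it is dispersed; otherwise it is
narrow when the peak length is <= 9 nt and broad when longer.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr, fisher_exact
from .regions import GenomicInterval

SHAPES = ("narrow", "broad", "dispersed")
MIN_READS = 10
SUMMIT_HALF_WINDOW = 2
NARROW_MAX_LENGTH = 9
# Consensus/tie-break precedence, most conservative toward narrow-vs-dispersed
# contrasts first.
SHAPE_PRECEDENCE = ("dispersed", "broad", "narrow")


def tpm_log(values, pseudocount: float = 0.1) -> np.ndarray:
    """Natural log of TPM + pseudocount (base recorded here: e)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("TPM values must be >= 0")
    return np.log(arr + pseudocount)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so each has the same sorted values.

    The reference distribution is the across-column mean of the sorted
    columns; within a column, tied values all receive the mean of the
    reference values at their ranks.  Idempotent and rank-preserving.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    ref = np.sort(matrix.values, axis=0).mean(axis=1)
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        x = matrix[col].values
        order = np.argsort(x, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the assigned reference values over ties
        s = pd.Series(assigned).groupby(pd.Series(x)).transform("mean")
        out[col] = s.values
    return out


def tissue_specificity_index(profile) -> float:
    """Tau in [0, 1]: 0 = uniform across biosamples, 1 = single-biosample.

    Requires at least one strictly positive value and N >= 2; all-zero
    profiles are undefined and return NaN with a warning (callers exclude
    them).
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 biosamples")
    m = x.max()
    if m <= 0:
        warnings.warn("all-zero profile: tissue-specificity undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


@dataclass(frozen=True)
class RampageReadSet:
    """5'-end read positions within one rPeak in one biosample."""

    rpeak: GenomicInterval
    biosample: str
    five_prime_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        for p in self.five_prime_positions:
            if not self.rpeak.contains(p):
                raise ValueError(
                    f"read position {p} outside rPeak "
                    f"{self.rpeak.chrom}:{self.rpeak.start}-{self.rpeak.end}"
                )


@dataclass(frozen=True)
class PeakShapeCall:
    shape: str  # narrow | broad | dispersed | unclassified
    summit: int | None
    n_reads: int
    summit_fraction: float


def find_summit(positions) -> int:
    """Position with the most 5' ends; leftmost on ties."""
    if len(positions) == 0:
        raise ValueError("cannot find the summit of an empty read set")
    counts = Counter(positions)
    best = max(counts.values())
    return min(p for p, c in counts.items() if c == best)


def classify_peak_shape(
    readset: RampageReadSet,
    min_reads: int = MIN_READS,
    length_mode: str = "rpeak",
) -> PeakShapeCall:
    """Classify one rPeak in one biosample as narrow/broad/dispersed.

    ``length_mode`` selects the peak-length definition for the narrow/broad
    split: "rpeak" (default) uses the fixed rPeak interval width; "span"
    uses the read-supported span (max - min read position + 1).
    """
    n = len(readset.five_prime_positions)
    if n < min_reads:
        return PeakShapeCall("unclassified", None, n, 0.0)
    summit = find_summit(readset.five_prime_positions)
    within = sum(
        1
        for p in readset.five_prime_positions
        if abs(p - summit) <= SUMMIT_HALF_WINDOW
    )
    frac = within / n
    if frac < 0.5:
        return PeakShapeCall("dispersed", summit, n, frac)
    if length_mode == "rpeak":
        length = len(readset.rpeak)
    elif length_mode == "span":
        length = max(readset.five_prime_positions) - min(
            readset.five_prime_positions
        ) + 1
    else:
        raise ValueError("length_mode must be 'rpeak' or 'span'")
    shape = "narrow" if length <= NARROW_MAX_LENGTH else "broad"
    return PeakShapeCall(shape, summit, n, frac)


def consensus_shape(calls) -> str:
    """Modal classified shape across biosamples.

    Ties break by dispersed > broad > narrow; with no classified call the
    consensus is unclassified.
    """
    counts = Counter(c.shape for c in calls if c.shape in SHAPES)
    if not counts:
        return "unclassified"
    best = max(counts.values())
    for shape in SHAPE_PRECEDENCE:
        if counts.get(shape) == best:
            return shape
    raise AssertionError("unreachable")


def shape_enrichment(
    ubi_calls: dict[str, list[str]], nonubi_calls: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-biosample, per-shape enrichment of ubiquitous promoters.

    Inputs map biosample -> shape assignments (classified shapes only are
    used).  For each biosample and shape: fold change of the shape's
    fraction in the ubiquitous set over the non-ubiquitous set, a two-sided
    Fisher exact p on the 2x2 (shape vs not, ubi vs non-ubi), and BH
    q-values across all biosample x shape tests — the volcano-plot axes.
    Biosamples with no classified peak in either group are skipped with a
    warning.
    """
    rows = []
    for bs in sorted(set(ubi_calls) & set(nonubi_calls)):
        u = [s for s in ubi_calls[bs] if s in SHAPES]
        v = [s for s in nonubi_calls[bs] if s in SHAPES]
        if not u or not v:
            warnings.warn(f"biosample {bs!r}: empty classified group, skipped",
                          stacklevel=2)
            continue
        for shape in SHAPES:
            a = sum(1 for s in u if s == shape)
            b = len(u) - a
            c = sum(1 for s in v if s == shape)
            d = len(v) - c
            frac_u = a / len(u)
            frac_v = c / len(v)
            if frac_v > 0:
                fold = frac_u / frac_v
            else:
                # a shape absent from both groups has equal (zero) proportions
                fold = 1.0 if frac_u == 0 else float("inf")
            _, p = fisher_exact([[a, b], [c, d]])
            rows.append(
                {
                    "biosample": bs,
                    "shape": shape,
                    "frac_ubi": frac_u,
                    "frac_nonubi": frac_v,
                    "fold": fold,
                    "log2_fold": np.log2(fold) if 0 < fold < np.inf else
                    (np.inf if fold == np.inf else -np.inf),
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].values)
    return df


# ---------------------------------------------------------------------------
# I/O


def read_rampage_tsv(path: str, rpeaks: dict[str, GenomicInterval]):
    """Read (rpeak_id, biosample, position, count) TSV into RampageReadSets."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for (rid, bs), grp in df.groupby(["rpeak_id", "biosample"], sort=True):
        positions: list[int] = []
        for _, row in grp.iterrows():
            positions.extend([int(row["position"])] * int(row["count"]))
        out.append(RampageReadSet(rpeaks[str(rid)], str(bs), tuple(positions)))
    return out


def write_rampage_tsv(path: str, readsets) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ubiprom {__version__} rampage 5' ends\n")
        fh.write("rpeak_id\tbiosample\tposition\tcount\n")
        for rs in readsets:
            for pos, cnt in sorted(Counter(rs.five_prime_positions).items()):
                fh.write(f"{rs.rpeak.id}\t{rs.biosample}\t{pos}\t{cnt}\n")


def rank_correlation_with_expression(counts, scores) -> float:
    """Pearson r between ubiquity breadth and an essentiality score."""
    return float(stats.pearsonr(np.asarray(counts, float),
                                np.asarray(scores, float))[0])
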