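"""Promoter sequence features: CG enrichment, PWM scanning, TATA calling.

The normalized CG content of a sequence is the observed CG-dinucleotide
fraction divided by its expectation under independence,
``[(fracC + fracG)/2]^2``; values >= 0.5 mark CpG-rich promoters.

Motif matches are scored as log-likelihood ratios in bits against a
background model, with exact match p-values computed by dynamic programming
over the discretized per-position score distribution (the same semantics as
FIMO-style scanners).  General scans use p <= 1e-4 on both strands;
TATA-box calling scans the forward strand only at p <= 1e-3 and requires
the site to start 25-35 bp upstream of the TSS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regions import GenomicInterval

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceComposition:
    length: int
    frac_C: float
    frac_G: float
    frac_CpG: float
    normalized_cg: float


def normalized_cg_content(sequence: str) -> SequenceComposition:
    """Observed/expected CG-dinucleotide ratio of a DNA sequence.

    Case-insensitive.  ``N`` positions are excluded from the mononucleotide
    denominators and any dinucleotide window touching an ``N`` is excluded
    from both the CG count and the window count, so the numerator and
    denominator see the same effective sequence.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    n_valid = sum(1 for c in seq if c != "N")
    n_c = seq.count("C")
    n_g = seq.count("G")
    frac_c = n_c / n_valid if n_valid else 0.0
    frac_g = n_g / n_valid if n_valid else 0.0
    n_windows = 0
    n_cg = 0
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a == "N" or b == "N":
            continue
        n_windows += 1
        if a == "C" and b == "G":
            n_cg += 1
    frac_cpg = n_cg / n_windows if n_windows else 0.0
    expected = ((frac_c + frac_g) / 2.0) ** 2
    norm = frac_cpg / expected if expected > 0 else 0.0
    return SequenceComposition(len(seq), frac_c, frac_g, frac_cpg, norm)


class PWM:
    """A position-weight matrix with background model and pseudocount.

    ``probabilities`` is an (L, 4) array over A,C,G,T.  Construction adds
    ``pseudocount * background`` to every cell and renormalizes, so JASPAR
    matrices with zero counts score finitely everywhere.  Scores are
    log2(p / background) summed over positions ("bits").
    """

    def __init__(
        self,
        probabilities: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 0.01,
        name: str = "",
    ):
        probs = np.asarray(probabilities, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probabilities must be (L, 4)")
        bg = np.asarray(background, dtype=float)
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        probs = probs + pseudocount * bg[None, :]
        probs = probs / probs.sum(axis=1, keepdims=True)
        self.probabilities = probs
        self.background = bg
        self.pseudocount = pseudocount
        self.name = name
        self.log_odds = np.log2(probs / bg[None, :])
        self._survival_cache: dict[float, tuple[np.ndarray, int]] = {}
        self._exact_cache: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return self.probabilities.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=1, keepdims=True), **kw)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probabilities[::-1, ::-1].copy(),
            self.background[::-1],
            pseudocount=0.0,
            name=f"{self.name}_rc" if self.name else "",
        )

    # -- exact p-value machinery ------------------------------------------

    def _survival(self, granularity: float) -> tuple[np.ndarray, int]:
        """Survival function of the integerized background score distribution.

        Returns (sf, qmin): ``sf[k]`` is P(Q >= qmin + k) where Q is the sum
        over positions of per-position scores rounded to ``granularity``
        bits, under independent draws from the background.
        """
        if granularity in self._survival_cache:
            return self._survival_cache[granularity]
        q = np.rint(self.log_odds / granularity).astype(np.int64)
        dist = np.array([1.0])
        offset = 0
        for j in range(len(self)):
            qj = q[j]
            lo, hi = int(qj.min()), int(qj.max())
            pos_dist = np.zeros(hi - lo + 1)
            for b in range(4):
                pos_dist[qj[b] - lo] += self.background[b]
            dist = np.convolve(dist, pos_dist)
            offset += lo
        sf = np.cumsum(dist[::-1])[::-1]
        self._survival_cache[granularity] = (sf, offset)
        return sf, offset

    def _exact_survival(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact (scores, survival) pairs by DP over per-position sums.

        State space is the set of attainable partial-sum scores; feasible
        for short matrices (used up to length 10, <= 4^10 states).
        """
        if self._exact_cache is not None:
            return self._exact_cache
        dist: dict[float, float] = {0.0: 1.0}
        for j in range(len(self)):
            nxt: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = s + self.log_odds[j, b]
                    nxt[key] = nxt.get(key, 0.0) + p * self.background[b]
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        sf = np.cumsum(probs[::-1])[::-1]
        self._exact_cache = (scores, sf)
        return self._exact_cache


_EXACT_DP_MAX_LENGTH = 10


def pwm_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """P(background sequence scores >= ``score``), by DP over positions.

    For matrices up to 10 positions the DP runs on the exact attainable
    partial-sum scores, so the p-value matches exhaustive enumeration.
    Longer matrices use per-position scores rounded to ``granularity`` bits
    with the sum distribution built by convolution; the query threshold is
    then lowered by the worst-case accumulated rounding slack, so the
    returned p-value never underestimates the exact one (conservative to
    within the probability mass lying inside the slack of the threshold).
    """
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if len(pwm) <= _EXACT_DP_MAX_LENGTH:
        scores, sf = pwm._exact_survival()
        # tiny epsilon absorbs summation-order float noise in the query score
        k = int(np.searchsorted(scores, score - 1e-9, side="left"))
        return 1.0 if k == 0 else (float(sf[k]) if k < scores.size else 0.0)
    sf, qmin = pwm._survival(granularity)
    slack = (len(pwm) + 1) / 2.0
    qt = math.ceil(score / granularity - slack)
    k = qt - qmin
    if k <= 0:
        return 1.0
    if k >= sf.size:
        return 0.0
    return float(min(sf[k], 1.0))


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (N) to -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class MotifSite:
    interval: GenomicInterval
    strand: str
    score: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Exact per-offset sum of log-odds; windows touching N score -inf."""
    L = log_odds.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        c = codes[j : j + n]
        ok = c >= 0
        valid &= ok
        scores += np.where(ok, log_odds[j, np.clip(c, 0, 3)], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    strands: str = "both",
    chrom: str = ".",
    offset: int = 0,
    granularity: float = 1e-3,
) -> list[MotifSite]:
    """All motif sites with p <= ``p_threshold``, sorted by position.

    ``strands`` is "both", "+" or "-"; minus-strand matches are scored on
    the reverse complement but reported on forward coordinates.  ``offset``
    shifts reported coordinates (e.g. a region's genomic start).
    """
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    codes = _encode(sequence)
    L = len(pwm)
    if codes.size < L:
        return []
    sites: list[MotifSite] = []
    matrices = []
    if strands in ("both", "+"):
        matrices.append(("+", pwm.log_odds))
    if strands in ("both", "-"):
        matrices.append(("-", pwm.reverse_complement().log_odds))
    for strand, lo in matrices:
        scores = _window_scores(codes, lo)
        for i in np.nonzero(np.isfinite(scores))[0]:
            p = pwm_pvalue(pwm, float(scores[i]), granularity)
            if p <= p_threshold:
                iv = GenomicInterval(chrom, offset + int(i), offset + int(i) + L)
                sites.append(MotifSite(iv, strand, float(scores[i]), p))
    sites.sort(key=lambda s: (s.interval.start, s.strand))
    return sites


def call_tata(
    promoter_sequence: str,
    tss_offset: int,
    tata_pwm: PWM,
    window: tuple[int, int] = (25, 35),
    p_threshold: float = 1e-3,
) -> bool:
    """True if a forward-strand TATA site starts 25-35 bp upstream of the TSS.

    The promoter sequence must be given in transcription orientation (the
    scan is forward-only).  Offsets are inclusive at both window edges.  A
    window extending past the sequence start is truncated with a warning.
    """
    if not (0 <= tss_offset < len(promoter_sequence)):
        raise ValueError("tss_offset must lie within the sequence")
    near, far = min(window), max(window)
    lo = tss_offset - far
    hi = tss_offset - near  # last allowed site start, inclusive
    if hi < 0:
        warnings.warn("TATA window lies entirely upstream of the sequence start",
                      stacklevel=2)
        return False
    if lo < 0:
        warnings.warn("TATA window truncated at the sequence start", stacklevel=2)
        lo = 0
    sites = scan_pwm(promoter_sequence, tata_pwm, p_threshold, strands="+")
    return any(lo <= s.interval.start <= hi for s in sites)


def motif_stats(
    region: GenomicInterval, sites: Sequence[MotifSite]
) -> tuple[int, int]:
    """(site count, bp covered by the union of site intervals) in a region."""
    count = 0
    spans: list[tuple[int, int]] = []
    for s in sites:
        if s.interval.chrom != region.chrom:
            continue
        if s.interval.start >= region.start and s.interval.end <= region.end:
            count += 1
            spans.append((s.interval.start, s.interval.end))
    spans.sort()
    coverage = 0
    cur_s, cur_e = None, None
    for st, en in spans:
        if cur_e is None or st > cur_e:
            if cur_e is not None:
                coverage += cur_e - cur_s
            cur_s, cur_e = st, en
        else:
            cur_e = max(cur_e, en)
    if cur_e is not None:
        coverage += cur_e - cur_s
    return count, coverage


def motif_tss_distance_shift(
    paired_sites: Sequence[
        tuple[MotifSite, MotifSite, Sequence[int] | None, Sequence[int] | None]
    ],
    p_filter: float = 1e-5,
) -> tuple[list[int], int]:
    """Cross-species shift in motif-to-TSS distance for orthologous sites.

    Each tuple is (site_a, site_b, tss_positions_a, tss_positions_b).  Pairs
    where either site misses the p filter are dropped; pairs lacking a TSS
    annotation on either side are skipped and counted.  Returns
    (|d_a - d_b| per retained pair, n_skipped) where d is the distance from
    the site start to the nearest annotated TSS.
    """
    out: list[int] = []
    skipped = 0
    for site_a, site_b, tss_a, tss_b in paired_sites:
        if site_a.p_value >= p_filter or site_b.p_value >= p_filter:
            continue
        if not tss_a or not tss_b:
            skipped += 1
            continue
        d_a = min(abs(site_a.interval.start - t) for t in tss_a)
        d_b = min(abs(site_b.interval.start - t) for t in tss_b)
        out.append(abs(d_a - d_b))
    return out, skipped


# ---------------------------------------------------------------------------
# Motif and sequence I/O


def read_jaspar_pfm(path: str, **pwm_kw) -> PWM:
    """Read a JASPAR PFM (with or without the '>' header line)."""
    from Bio import motifs

    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "jaspar" if first == ">" else "pfm-four-columns"
        try:
            m = motifs.read(fh, "jaspar" if first == ">" else "pfm")
        except Exception:
            fh.seek(0)
            m = motifs.read(fh, fmt)
    counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
    name = getattr(m, "matrix_id", None) or m.name or ""
    return PWM.from_counts(counts, name=name, **pwm_kw)


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_motif_sites(path: str, sites: Sequence[MotifSite]) -> None:
    """BED6+2: name=., score column 0, then bits score and p-value."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ubiprom {__version__} motif sites bed6+2\n")
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{s.strand}"
                f"\t{s.score:.4f}\t{s.p_value:.3e}\n"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
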