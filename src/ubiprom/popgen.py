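"""Nucleotide diversity (pi) at sites, regions and oriented flank profiles.

Per-site diversity is ``pi = 1 - sum(p_i^2)`` over the allele frequencies
at that position; positions without a variant contribute 0.  Region
diversity is the per-position mean over the region.  Profiles average pi
in bins across +/-2 kb windows centered on regions, oriented so positive
offsets point downstream of transcription.  Group differences are tested
with a 10 000-replicate bootstrap of the Welch t-statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regions import GenomicInterval, MetaProfile, _oriented_bin_bounds


class AlleleFrequencyTable:
    """Per-site allele frequencies; indels are excluded at load."""

    def __init__(self):
        self._sites: dict[str, dict[int, tuple[float, ...]]] = {}

    def add_site(self, chrom: str, pos: int, frequencies: Sequence[float]) -> None:
        freqs = tuple(float(p) for p in frequencies)
        if abs(sum(freqs) - 1.0) > 1e-6:
            raise ValueError(
                f"allele frequencies at {chrom}:{pos} sum to {sum(freqs)}, not 1"
            )
        if any(p < 0 or p > 1 for p in freqs):
            raise ValueError("allele frequencies must lie in [0, 1]")
        chrom_sites = self._sites.setdefault(chrom, {})
        if pos in chrom_sites:
            raise ValueError(f"duplicate site {chrom}:{pos}")
        chrom_sites[pos] = freqs

    def frequencies(self, chrom: str, pos: int) -> tuple[float, ...] | None:
        return self._sites.get(chrom, {}).get(pos)

    def n_sites(self) -> int:
        return sum(len(v) for v in self._sites.values())

    def positions(self, chrom: str) -> list[int]:
        return sorted(self._sites.get(chrom, {}))

    @classmethod
    def from_vcf(cls, path: str, pass_only: bool = True) -> "AlleleFrequencyTable":
        """Load biallelic-or-multiallelic SNVs from a VCF.

        Honors FILTER=PASS (or '.'), skips indels, and takes allele
        frequencies from the AF INFO field when present, else computes them
        from genotypes.
        """
        import pysam

        table = cls()
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                    continue
                alts = rec.alts or ()
                if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                    continue  # indel
                af = rec.info.get("AF") if "AF" in rec.info else None
                if af is not None:
                    alt_freqs = [float(x) for x in (
                        af if isinstance(af, (tuple, list)) else (af,))]
                else:
                    counts = [0] * (len(alts) + 1)
                    total = 0
                    for sample in rec.samples.values():
                        for allele in sample["GT"]:
                            if allele is not None:
                                counts[allele] += 1
                                total += 1
                    if total == 0:
                        continue
                    alt_freqs = [c / total for c in counts[1:]]
                ref_freq = max(0.0, 1.0 - sum(alt_freqs))
                table.add_site(rec.chrom, rec.pos - 1, (ref_freq, *alt_freqs))
        return table


@dataclass(frozen=True)
class RegionDiversity:
    region: GenomicInterval
    pi: float
    n_positions: int


def site_pi(frequencies: Sequence[float]) -> float:
    """1 - sum(p_i^2): the chance two sampled alleles differ at the site."""
    freqs = np.asarray(frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")
    return float(1.0 - np.sum(freqs**2))


def region_pi(region: GenomicInterval, table: AlleleFrequencyTable) -> RegionDiversity:
    """Mean per-position pi across the region (0 at invariant positions)."""
    total = 0.0
    chrom_sites = table._sites.get(region.chrom, {})
    for pos in range(region.start, region.end):
        freqs = chrom_sites.get(pos)
        if freqs is not None:
            total += site_pi(freqs)
    return RegionDiversity(region, total / len(region), len(region))


def pi_profile(
    regions: Sequence[GenomicInterval],
    table: AlleleFrequencyTable,
    flank: int = 2000,
    bin_width: int = 100,
) -> MetaProfile:
    """Binned mean pi across +/-``flank`` windows centered on regions.

    Minus-strand regions are flipped so positive offsets point downstream
    of transcription.  Every position in a bin contributes (0 when
    invariant), so the profile is a per-bp average like the region metric.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    offs = np.arange(-flank, flank, bin_width, dtype=np.int64)
    acc = np.zeros(offs.size)
    # sorted position / pi arrays per chromosome for fast bin queries
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sites in table._sites.items():
        pos = np.array(sorted(sites), dtype=np.int64)
        pis = np.array([site_pi(sites[p]) for p in pos])
        per_chrom[chrom] = (pos, np.cumsum(pis))
    for region in regions:
        pos, cum = per_chrom.get(
            region.chrom, (np.empty(0, np.int64), np.empty(0))
        )
        lo, hi = _oriented_bin_bounds(region.center, region.strand, flank, bin_width)
        if pos.size == 0:
            continue
        i = np.searchsorted(pos, np.clip(lo, 0, None), side="left")
        j = np.searchsorted(pos, hi, side="left")
        tot = np.where(j > 0, cum[np.maximum(j - 1, 0)], 0.0) - np.where(
            i > 0, cum[np.maximum(i - 1, 0)], 0.0
        )
        acc += np.where(j > i, tot, 0.0) / bin_width
    acc /= len(regions)
    return MetaProfile(offs, acc, len(regions), bin_width)


@dataclass(frozen=True)
class BootstrapResult:
    t_observed: float
    empirical_p: float
    p_label: str
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    n_boot: int


def _welch_t(a_mean, a_var, n_a, b_mean, b_var, n_b):
    denom = np.sqrt(a_var / n_a + b_var / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (a_mean - b_mean) / denom, 0.0)


def bootstrap_pi_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_boot: int = 10000,
    seed: int = 0,
    two_sided: bool = False,
) -> BootstrapResult:
    """Bootstrap test for a difference in mean diversity between groups.

    The null distribution pools both groups and resamples two pseudo-groups
    of the original sizes with replacement, computing the Welch t-statistic
    per replicate; the empirical p is the fraction of replicates whose t
    meets or exceeds the observed t (one-sided in the larger-t direction by
    default; the two-sided variant compares |t|).  Zero exceedances are
    reported as "< 1/n_boot".  Group means come with within-group
    percentile 95% bootstrap CIs.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; empirical p will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    t_obs = float(
        _welch_t(a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size)
    )
    pooled = np.concatenate([a, b])
    idx_a = rng.integers(0, pooled.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, pooled.size, size=(n_boot, b.size))
    ra, rb = pooled[idx_a], pooled[idx_b]
    t_boot = _welch_t(
        ra.mean(axis=1), ra.var(axis=1, ddof=1), a.size,
        rb.mean(axis=1), rb.var(axis=1, ddof=1), b.size,
    )
    if two_sided:
        n_exceed = int(np.sum(np.abs(t_boot) >= abs(t_obs)))
    else:
        n_exceed = int(np.sum(t_boot >= t_obs))
    p = n_exceed / n_boot
    label = f"< {1 / n_boot:g}" if n_exceed == 0 else f"{p:g}"
    means_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    ci_a = tuple(np.percentile(means_a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(means_b, [2.5, 97.5]))
    return BootstrapResult(
        t_obs, p, label, float(a.mean()), float(b.mean()),
        (float(ci_a[0]), float(ci_a[1])), (float(ci_b[0]), float(ci_b[1])),
        n_boot,
    )


def write_region_pi(path: str, results: Sequence[RegionDiversity]) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ubiprom {__version__} region pi\n")
        fh.write("region_id\tpi\tn_positions\n")
        for r in results:
            fh.write(f"{r.region.id or '.'}\t{r.pi:.6g}\t{r.n_positions}\n")
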