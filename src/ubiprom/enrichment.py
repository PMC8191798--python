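"""Gene-cCRE assignment and the categorical / permutation statistics.

Genes are assigned to promoter classes by which promoter-class elements
contain their TSSs.  Enrichment questions — are ubiquitous promoters
enriched at essential genes, Mendelian-disease genes, chromatin-loop
anchors, particular motifs — reduce to 2x2 Fisher exact tests (two-sided,
minimum-likelihood) with Benjamini-Hochberg FDR control, plus a label
permutation null for the "genes with both promoter types" statistic.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .regions import GenomicInterval, resize_center
from .ubiquity import CcreRecord

EXCLUDED_BIOTYPES = frozenset({"pseudogene", "TEC"})


@dataclass
class GeneModel:
    """A gene with its TSSs, biotype, and essentiality/disease labels."""

    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    tss_list: list[int] = field(default_factory=list)
    crispr_scores: dict[str, float] = field(default_factory=dict)
    essential: bool = False
    mendelian: bool = False

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id} has no TSSs")

    @property
    def min_crispr_score(self) -> float:
        return min(self.crispr_scores.values()) if self.crispr_scores else float("nan")


def filter_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop genes with inactive/uncertain biotypes (pseudogene, TEC)."""
    return [
        g
        for g in genes
        if not any(g.biotype.startswith(b) or b in g.biotype for b in EXCLUDED_BIOTYPES)
    ]


class _PointIndex:
    """Sorted interval lists per chromosome for point-containment queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        per: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in per.items():
            pairs.sort()
            starts = [p[0] for p in pairs]
            # running max of ends makes containment queries correct even for
            # nested intervals
            ends: list[int] = []
            m = 0
            for _, e in pairs:
                m = max(m, e)
                ends.append(m)
            self._by_chrom[chrom] = (starts, ends)
            self._pairs = per

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, max_ends = self._by_chrom[chrom]
        i = bisect_right(starts, pos)
        if i == 0:
            return False
        # any interval starting at or before pos with running-max end > pos?
        return max_ends[i - 1] > pos


def assign_gene_class(
    ubi_pls: Sequence[GenomicInterval],
    nonubi_pls: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> dict[str, str]:
    """Per-gene class: ubi-only / nonubi-only / both / none.

    A gene is "ubi" when at least one of its TSS positions falls inside a
    ubiquitous promoter element, "nonubi" likewise; "both" when it has TSSs
    of both kinds.  The four classes partition the gene set.
    """
    ubi_idx = _PointIndex(ubi_pls)
    non_idx = _PointIndex(nonubi_pls)
    out: dict[str, str] = {}
    for g in genes:
        in_ubi = any(ubi_idx.contains(g.chrom, t) for t in g.tss_list)
        in_non = any(non_idx.contains(g.chrom, t) for t in g.tss_list)
        if in_ubi and in_non:
            out[g.gene_id] = "both"
        elif in_ubi:
            out[g.gene_id] = "ubi-only"
        elif in_non:
            out[g.gene_id] = "nonubi-only"
        else:
            out[g.gene_id] = "none"
    return out


def center_within(ccre: CcreRecord, tss: int, max_distance: int = 200) -> bool:
    """True when the element center is within ``max_distance`` bp (inclusive)."""
    return abs(ccre.interval.center - tss) <= max_distance


def bidirectional_pairs(
    genes: Sequence[GeneModel], max_gap: int = 1000
) -> list[tuple[str, str]]:
    """Unordered opposite-strand gene pairs with TSSs within ``max_gap`` bp.

    A gene may appear in several pairs.  Pairs are returned sorted by id.
    """
    out: set[tuple[str, str]] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, a in enumerate(chrom_genes):
            for b in chrom_genes[i + 1 :]:
                if a.strand == b.strand or a.gene_id == b.gene_id:
                    continue
                gap = min(
                    abs(ta - tb) for ta in a.tss_list for tb in b.tss_list
                )
                if gap <= max_gap:
                    out.add(tuple(sorted((a.gene_id, b.gene_id))))
    return sorted(out)


@dataclass(frozen=True)
class PermutationResult:
    expected_mean: float
    expected_sd: float
    observed: int | None
    empirical_p: float | None
    p_label: str | None
    n_perm: int


def both_class_permutation(
    genes: Sequence[GeneModel],
    n_ubi_tss: int,
    n_perm: int = 10000,
    seed: int = 0,
    observed: int | None = None,
) -> PermutationResult:
    """Permutation null for the number of genes with both promoter types.

    Each permutation labels a uniformly random subset of ``n_ubi_tss`` of
    all TSSs as ubiquitous, preserving each gene's TSS count, and counts
    genes with at least one ubiquitous and one non-ubiquitous TSS.  The
    one-sided empirical p tests whether ``observed`` is lower than the
    null; zero exceedances are reported as "< 1/n_perm".
    """
    sizes = np.array([len(g.tss_list) for g in genes], dtype=np.int64)
    total = int(sizes.sum())
    if n_ubi_tss > total:
        raise ValueError(f"n_ubi_tss ({n_ubi_tss}) exceeds total TSS count ({total})")
    gene_of_tss = np.repeat(np.arange(sizes.size), sizes)
    rng = np.random.default_rng(seed)
    stats_ = np.empty(n_perm, dtype=np.int64)
    n_genes = sizes.size
    for i in range(n_perm):
        if n_ubi_tss == 0:
            stats_[i] = 0
            continue
        chosen = rng.choice(total, size=n_ubi_tss, replace=False)
        k = np.bincount(gene_of_tss[chosen], minlength=n_genes)
        stats_[i] = int(np.sum((k > 0) & (k < sizes)))
    mean = float(stats_.mean())
    sd = float(stats_.std(ddof=1)) if n_perm > 1 else 0.0
    p = label = None
    if observed is not None:
        n_le = int(np.sum(stats_ <= observed))
        p = n_le / n_perm
        label = f"< {1 / n_perm:g}" if n_le == 0 else f"{p:g}"
    return PermutationResult(mean, sd, observed, p, label, n_perm)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (sample odds ratio, p).  p is the minimum-likelihood two-sided
    p: the sum of hypergeometric probabilities of all tables with the same
    margins that are no more likely than the observed one.  The odds ratio
    is a*d/(b*c) (inf when b*c == 0 with a*d > 0, nan for 0/0).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table must have a positive grand total")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    # relative tolerance guards against floating-point ties, as in standard
    # implementations
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_window_fraction(
    genes: Sequence[GeneModel],
    flags: dict[str, bool],
    window: int = 500,
    score_of=None,
) -> pd.DataFrame:
    """Fraction of flagged genes in consecutive rank windows.

    Genes are ranked ascending by CRISPR score (most essential first; ties
    broken by gene id) and cut into non-overlapping ``window``-gene windows;
    the trailing partial window is reported with its actual size.
    """
    if score_of is None:
        score_of = lambda g: g.min_crispr_score  # noqa: E731
    ranked = sorted(genes, key=lambda g: (score_of(g), g.gene_id))
    rows = []
    for w, i in enumerate(range(0, len(ranked), window)):
        chunk = ranked[i : i + window]
        n_flag = sum(1 for g in chunk if flags.get(g.gene_id, False))
        rows.append(
            {"window": w, "n_genes": len(chunk), "fraction": n_flag / len(chunk)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Loop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("loop read support must be >= 1")


class _OverlapIndex:
    """Sorted intervals per chromosome for any-overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in per.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs],
                                                  dtype=np.int64))
            self._by_chrom[chrom] = (starts, ends)

    def overlaps(self, iv: GenomicInterval) -> bool:
        if iv.chrom not in self._by_chrom:
            return False
        starts, max_ends = self._by_chrom[iv.chrom]
        i = int(np.searchsorted(starts, iv.end, side="left"))
        if i == 0:
            return False
        return bool(max_ends[i - 1] > iv.start)


@dataclass(frozen=True)
class AnchorEnrichment:
    percent_ubi_anchored: float
    percent_nonubi_anchored: float
    percent_anchors_on_ubi: float
    percent_anchors_on_nonubi: float
    fisher_p: float
    odds_ratio: float
    n_loops: int


def chia_anchor_enrichment(
    loops: Sequence[Loop],
    ubi: Sequence[GenomicInterval],
    nonubi: Sequence[GenomicInterval],
    min_reads: int = 4,
    resize_width: int = 345,
) -> AnchorEnrichment:
    """Enrichment of ubiquitous promoters at chromatin-loop anchors.

    Loops are filtered to >= ``min_reads`` supporting reads; both promoter
    groups are resized to ``resize_width`` bp around their centers (the
    median promoter-element length, removing the length-distribution
    difference); a promoter counts as anchored on >= 1 bp overlap with any
    anchor, and reciprocally an anchor counts when it overlaps any promoter
    of a group.  Fisher tests anchored/not x ubi/non-ubi.
    """
    kept = [l for l in loops if l.reads >= min_reads]
    if not kept:
        raise ValueError("no loops pass the read-support filter")
    anchors = [l.anchor1 for l in kept] + [l.anchor2 for l in kept]
    anchor_idx = _OverlapIndex(anchors)
    ubi_r = [resize_center(r, resize_width) for r in ubi]
    non_r = [resize_center(r, resize_width) for r in nonubi]
    ubi_hit = sum(1 for r in ubi_r if anchor_idx.overlaps(r))
    non_hit = sum(1 for r in non_r if anchor_idx.overlaps(r))
    ubi_idx = _OverlapIndex(ubi_r)
    non_idx = _OverlapIndex(non_r)
    anch_on_ubi = sum(1 for a in anchors if ubi_idx.overlaps(a))
    anch_on_non = sum(1 for a in anchors if non_idx.overlaps(a))
    odds, p = fisher_exact(
        [[ubi_hit, len(ubi_r) - ubi_hit], [non_hit, len(non_r) - non_hit]]
    )
    return AnchorEnrichment(
        100.0 * ubi_hit / len(ubi_r),
        100.0 * non_hit / len(non_r),
        100.0 * anch_on_ubi / len(anchors),
        100.0 * anch_on_non / len(anchors),
        p,
        odds,
        len(kept),
    )


def chip_bound(ccre: CcreRecord, peaks: Sequence[GenomicInterval], sites) -> bool:
    """Bound call: a ChIP peak overlaps the element by at least half the
    peak's own width AND the element contains at least one motif site."""
    iv = ccre.interval
    peak_ok = any(iv.overlap(p) * 2 >= len(p) and iv.overlap(p) > 0 for p in peaks)
    if not peak_ok:
        return False
    return any(
        s.interval.chrom == iv.chrom
        and s.interval.start >= iv.start
        and s.interval.end <= iv.end
        for s in sites
    )


@dataclass(frozen=True)
class StapseqComparison:
    medians: pd.DataFrame  # cofactor x group
    ratios: pd.Series  # median(ubi) / median(nonubi), per cofactor
    infinite_ratio: pd.Series  # flag: non-ubi median was zero
    linkage: np.ndarray  # scipy linkage matrix over cofactors
    merge_order: list[tuple[str, str]]
    leaf_order: list[str]


def stapseq_compare(
    signal: pd.DataFrame, groups: dict[str, str]
) -> StapseqComparison:
    """Cofactor-responsiveness comparison for promoter groups.

    ``signal`` is cofactors x promoters; ``groups`` maps promoter id to
    'ubi', 'nonubi' or 'none'.  Returns per-cofactor group medians, the
    ubi/nonubi median ratio, and an average-linkage clustering of cofactors
    on 1 - Pearson correlation across promoters overlapping either group.
    """
    if signal.shape[0] < 2:
        raise ValueError("need at least 2 cofactors")
    cols = {g: [p for p in signal.columns if groups.get(p) == g]
            for g in ("ubi", "nonubi", "none")}
    if not cols["ubi"] or not cols["nonubi"]:
        raise ValueError("both ubi and nonubi groups must be non-empty")
    medians = pd.DataFrame(
        {g: signal[ps].median(axis=1) for g, ps in cols.items() if ps}
    )
    inf_flag = medians["nonubi"] == 0
    with np.errstate(divide="ignore"):
        ratios = medians["ubi"] / medians["nonubi"]
    overl = cols["ubi"] + cols["nonubi"]
    corr = np.corrcoef(signal[overl].values)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    names = list(signal.index)
    clusters: dict[int, list[str]] = {i: [n] for i, n in enumerate(names)}
    merge_order = []
    for k, (i, j, _, _) in enumerate(Z):
        a, b = clusters[int(i)], clusters[int(j)]
        merge_order.append((a[0], b[0]))
        clusters[len(names) + k] = a + b
    leaf_order = [names[i] for i in hierarchy.leaves_list(Z)]
    return StapseqComparison(medians, ratios, inf_flag, Z, merge_order, leaf_order)


SYNTENY_CLASSES = (
    "ubi-in-target",
    "nonubi-PLS-in-target",
    "other-cCRE",
    "not-a-cCRE",
    "liftover-failed",
)


def synteny_class(
    lifted: Sequence[tuple[GenomicInterval, GenomicInterval | None]],
    target_ccres: Sequence[CcreRecord],
    min_overlap_fraction: float = 0.5,
) -> list[str]:
    """Classify lifted-over regions by their best-overlapping target cCRE.

    A lifted region counts as a cCRE in the target genome when at least
    ``min_overlap_fraction`` of it overlaps one; the best such overlap
    decides ubiquitous-PLS vs non-ubiquitous-PLS vs other class.  Regions
    that failed liftover pass through.  Ties in overlap break
    deterministically by coordinates, so the result is stable under target
    list reordering.
    """
    out = []
    targets = sorted(
        target_ccres,
        key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end),
    )
    for _, tgt in lifted:
        if tgt is None:
            out.append("liftover-failed")
            continue
        best = None
        best_ov = 0
        for rec in targets:
            ov = tgt.overlap(rec.interval)
            if ov > best_ov:
                best, best_ov = rec, ov
        if best is None or best_ov < min_overlap_fraction * len(tgt):
            out.append("not-a-cCRE")
        elif best.ccre_class == "PLS" and best.ubiquitous:
            out.append("ubi-in-target")
        elif best.ccre_class == "PLS":
            out.append("nonubi-PLS-in-target")
        else:
            out.append("other-cCRE")
    return out


def omim_filter(gene_phenotypes: pd.DataFrame) -> set[str]:
    """Mendelian gene set from a gene-phenotype table.

    Keeps genes with at least one phenotype string that does not start with
    '[' (non-disease) or '{' (multifactorial susceptibility).
    """
    keep: set[str] = set()
    for gene, pheno in zip(gene_phenotypes["gene"], gene_phenotypes["phenotype"]):
        s = str(pheno).strip()
        if s and not s.startswith("[") and not s.startswith("{"):
            keep.add(str(gene))
    return keep


# ---------------------------------------------------------------------------
# I/O: GTF genes, BEDPE loops, gene-phenotype TSV


def _gtf_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf_genes(path: str, apply_biotype_filter: bool = True) -> list[GeneModel]:
    """Read gene models from GTF transcript records.

    Each transcript contributes one TSS (its 5' end); transcripts sharing a
    ``gene_id`` are merged.  Pseudogene/TEC biotypes are dropped at load
    unless disabled.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "transcript":
                continue
            attrs = _gtf_attributes(f[8])
            gid = attrs.get("gene_id", "")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype",
                                                       "protein_coding"))
            strand = f[6]
            start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
            tss = start if strand == "+" else end - 1
            if gid in genes:
                if tss not in genes[gid].tss_list:
                    genes[gid].tss_list.append(tss)
            else:
                genes[gid] = GeneModel(gid, f[0], strand, biotype, [tss])
    out = list(genes.values())
    return filter_genes(out) if apply_biotype_filter else out


def read_bedpe_loops(path: str) -> list[Loop]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
            reads = int(f[7]) if len(f) > 7 and f[7] != "." else 1
            out.append(Loop(a1, a2, reads))
    return out


def write_bedpe_loops(path: str, loops: Sequence[Loop]) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# ubiprom {__version__} loops bedpe\n")
        for l in loops:
            fh.write(
                f"{l.anchor1.chrom}\t{l.anchor1.start}\t{l.anchor1.end}"
                f"\t{l.anchor2.chrom}\t{l.anchor2.start}\t{l.anchor2.end}"
                f"\t.\t{l.reads}\n"
            )
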