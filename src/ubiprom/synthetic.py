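"""Synthetic inputs with planted ground truth for every pipeline stage.

One synthetic chromosome ("chrS") carries regularly spaced accessible
elements and genes.  The generators emulate the statistical structure the
analyses assume — a bimodal ubiquity distribution of DNase Z-scores,
CpG-rich vs TATA-containing promoter sequences, narrow/broad/dispersed
5'-end read distributions, housekeeping vs tissue-specific expression,
allele-frequency tracks with elevated diversity at element centers, loops
anchored on ubiquitous elements, and cofactor-responsiveness matrices with
correlated blocks.  Every generator is a pure function of the config: the
global seed expands into independent per-generator streams, so outputs are
byte-stable and adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomicInterval, SignalTrack
from .transcription import RampageReadSet
from .ubiquity import SignalZMatrix

# fixed stream ids: appending new generators must not shift existing streams
_STREAMS = {
    "zscore": 1,
    "annotation": 2,
    "rampage": 3,
    "allele": 4,
    "expression": 5,
    "loops": 6,
    "chip": 7,
    "stapseq": 8,
    "signal": 9,
}

CHROM = "chrS"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the real study's regime at desk scale: ~1% of elements
    ubiquitously accessible, high/low Z-scores separated by >3 SD around
    the 1.64 cutoff, equal mixtures of the three TSS peak shapes at 50
    reads per peak, promoter-centered variant density five-fold above the
    flanks, and TOPMed-like rare-allele frequencies (Beta(1, 9)).
    """

    seed: int = 0
    n_elements: int = 10000
    n_biosamples: int = 100
    n_genes: int = 400
    ubiquitous_fraction: float = 0.01
    z_high_mean: float = 5.0
    z_low_mean: float = 0.0
    z_sd: float = 1.0
    shape_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # narrow, broad, dispersed
    reads_per_peak: int = 50
    pi_center_rate: float = 0.05  # variants per bp inside elements
    pi_flank_rate: float = 0.01
    af_beta_params: tuple[float, float] = (1.0, 9.0)
    essential_fraction: float = 0.285  # 5312 / 18633 in the CRISPR screens
    mendelian_fraction: float = 0.146  # 2718 / 18633
    cg_island_fraction: float = 0.5
    tata_fraction: float = 0.5  # of low-CG promoters, planted TATA at -30
    bidirectional_fraction: float = 0.1
    element_width: int = 300
    element_spacing: int = 10000
    gene_spacing: int = 10000

    def __post_init__(self) -> None:
        for name in ("ubiquitous_fraction", "essential_fraction",
                     "mendelian_fraction", "cg_island_fraction",
                     "tata_fraction", "bidirectional_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise ValueError("shape_mix must sum to 1")
        if self.pi_center_rate < 0 or self.pi_flank_rate < 0:
            raise ValueError("variant rates must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def element_intervals(config: SyntheticConfig) -> list[GenomicInterval]:
    """Deterministic element coordinates: fixed width, regular spacing."""
    out = []
    for i in range(config.n_elements):
        start = 5000 + i * config.element_spacing
        out.append(
            GenomicInterval(
                CHROM, start, start + config.element_width,
                "+" if i % 2 == 0 else "-", f"E{i:06d}",
            )
        )
    return out


def gen_zscore_matrix(config: SyntheticConfig) -> tuple[SignalZMatrix, np.ndarray]:
    """DNase Z-score matrix with a planted bimodal ubiquity structure.

    Planted ubiquitous elements score high (Normal(z_high_mean, z_sd)) in
    >= 95% of biosamples; the rest are high in a geometric-tailed handful
    of biosamples, reproducing the empirical two-population histogram of
    "number of biosamples with a high signal".  Returns the matrix and the
    boolean truth labels.
    """
    rng = config.rng("zscore")
    n, m = config.n_elements, config.n_biosamples
    ubi = np.zeros(n, dtype=bool)
    n_ubi = int(round(config.ubiquitous_fraction * n))
    if n_ubi:
        ubi[rng.choice(n, size=n_ubi, replace=False)] = True
    z = rng.normal(config.z_low_mean, config.z_sd, size=(n, m))
    floor_high = int(np.ceil(0.95 * m))
    for i in range(n):
        if ubi[i]:
            n_high = max(floor_high, m - rng.binomial(m, 0.02))
        else:
            n_high = min(int(rng.geometric(0.5)) - 1, m // 2)
        if n_high <= 0:
            continue
        cols = rng.choice(m, size=n_high, replace=False)
        z[i, cols] = rng.normal(config.z_high_mean, config.z_sd, size=n_high)
    df = pd.DataFrame(
        z,
        index=[f"E{i:06d}" for i in range(n)],
        columns=[f"B{j:03d}" for j in range(m)],
    )
    return SignalZMatrix(df), ubi


def _markov_seq(rng: np.random.Generator, length: int, base_probs: np.ndarray,
                p_g_after_c: float) -> str:
    """First-order sequence with an explicit P(G | previous C) control.

    Setting p_g_after_c above / below the marginal G frequency plants CpG
    enrichment / depletion, the axis the normalized CG statistic measures.
    """
    bases = "ACGT"
    g = 2
    rest = 1.0 - p_g_after_c
    others = np.delete(base_probs, g)
    probs_after_c = np.empty(4)
    probs_after_c[g] = p_g_after_c
    scale = rest / others.sum()
    k = 0
    for b in range(4):
        if b != g:
            probs_after_c[b] = others[k] * scale
            k += 1
    out = []
    prev = None
    draws_main = rng.choice(4, size=length, p=base_probs)
    draws_after_c = rng.choice(4, size=length, p=probs_after_c)
    for i in range(length):
        b = draws_after_c[i] if prev == 1 else draws_main[i]
        out.append(bases[b])
        prev = b
    return "".join(out)


TATA_CONSENSUS = "TATAAAAG"  # strong TBP-motif core planted at -30


@dataclass
class SyntheticAnnotation:
    chrom_sequence: str
    genes: list  # GeneModel
    cpg_islands: list[GenomicInterval]
    promoter_sequences: dict[str, str]  # gene_id -> promoter (txn orientation)
    promoter_tss_offset: dict[str, int]
    truth: dict


def gen_annotation(config: SyntheticConfig) -> SyntheticAnnotation:
    """Genes with 1-5 TSSs, strands, biotypes, and planted promoter classes.

    Ubiquitous-promoter genes get CpG-rich promoters (normalized CG >= 0.5,
    CpG-island annotated); a configured subset of the rest get AT-rich,
    CpG-depleted promoters with a TATA box planted 30 bp upstream of the
    TSS.  A configured fraction of genes form bidirectional (opposite
    strand, TSS within 1 kb) pairs.  A few pseudogene/TEC biotypes are
    planted to exercise the load-time filter.
    """
    from .enrichment import GeneModel

    rng = config.rng("annotation")
    n = config.n_genes
    prom_len = 600
    tss_off = 400  # TSS offset within the promoter (transcription orientation)
    chrom_len = 5000 + n * config.gene_spacing + 10000
    ubi_gene = np.zeros(n, dtype=bool)
    n_ubi = int(round(config.cg_island_fraction * n))
    if n_ubi:
        ubi_gene[rng.choice(n, size=n_ubi, replace=False)] = True
    cg_probs = np.array([0.2, 0.3, 0.3, 0.2])
    at_probs = np.array([0.35, 0.15, 0.15, 0.35])
    genes: list[GeneModel] = []
    promoters: dict[str, str] = {}
    tata_truth: dict[str, bool] = {}
    islands: list[GenomicInterval] = []
    # neutral background sequence
    chrom = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=chrom_len)
    essential = rng.random(n) < config.essential_fraction
    mendelian = rng.random(n) < config.mendelian_fraction
    for i in range(n):
        gid = f"G{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = 5000 + i * config.gene_spacing
        if ubi_gene[i]:
            seq = _markov_seq(rng, prom_len, cg_probs, 0.45)
            tata = False
        else:
            seq = _markov_seq(rng, prom_len, at_probs, 0.0)
            tata = rng.random() < config.tata_fraction
            if tata:
                at = tss_off - 30
                seq = seq[:at] + TATA_CONSENSUS + seq[at + len(TATA_CONSENSUS):]
        n_tss = int(rng.integers(1, 6))
        jitters = [0] + sorted(rng.integers(10, 140, size=n_tss - 1).tolist())
        # primary TSS sits at the matching element's center so gene i and
        # element i line up for overlap analyses; extra TSSs stay inside the
        # element's span
        tss0 = anchor + config.element_width // 2
        if strand == "+":
            prom_start = tss0 - tss_off
            tss_list = [tss0 + j for j in jitters]
            chrom[prom_start:prom_start + prom_len] = np.frombuffer(
                seq.encode(), dtype=np.uint8)
        else:
            tss_list = [tss0 - j for j in jitters]
            from .seqfeat import reverse_complement
            lo = tss0 + tss_off - (prom_len - 1)
            chrom[lo:lo + prom_len] = np.frombuffer(
                reverse_complement(seq).encode(), dtype=np.uint8)
        biotype = "protein_coding"
        if i % 97 == 0:
            biotype = "pseudogene"
        elif i % 89 == 0:
            biotype = "TEC"
        genes.append(
            GeneModel(gid, CHROM, strand, biotype, tss_list,
                      essential=bool(essential[i]), mendelian=bool(mendelian[i]))
        )
        promoters[gid] = seq
        tata_truth[gid] = tata
        if ubi_gene[i]:
            lo = min(tss_list) - 200
            islands.append(GenomicInterval(CHROM, max(lo, 0),
                                           max(tss_list) + 200, ".", f"CpG_{gid}"))
    # bidirectional partners: planted opposite-strand genes near a subset
    n_bidir = int(round(config.bidirectional_fraction * n))
    bidir_partners = []
    for j in range(n_bidir):
        host = genes[j * max(1, n // max(n_bidir, 1)) % n]
        gid = f"GB{j:04d}"
        strand = "-" if host.strand == "+" else "+"
        tss = host.tss_list[0] + int(rng.integers(200, 900)) * (
            1 if host.strand == "-" else -1)
        tss = max(0, min(tss, chrom_len - 1))
        partner = GeneModel(gid, CHROM, strand, "protein_coding", [tss])
        genes.append(partner)
        bidir_partners.append((host.gene_id, gid))
    # per-gene CRISPR scores: essential genes more negative
    for g in genes:
        base = -3.0 if g.essential else 0.2
        g.crispr_scores = {"study1": float(base + rng.normal(0, 0.5))}
    truth = {
        "ubi_gene": {f"G{i:05d}": bool(ubi_gene[i]) for i in range(n)},
        "tata": tata_truth,
        "bidirectional_pairs": bidir_partners,
    }
    return SyntheticAnnotation(
        chrom.tobytes().decode(), genes, islands, promoters,
        {g: tss_off for g in promoters}, truth,
    )


def gen_rampage_reads(
    config: SyntheticConfig,
) -> tuple[list[RampageReadSet], list[str]]:
    """rPeak read sets with planted narrow/broad/dispersed shapes.

    narrow: a point mass with +/-1 nt jitter inside an 8-bp rPeak;
    broad: a dominant summit (~2/3 of reads within +/-1 nt) plus a 30-bp
    unimodal spread inside a 40-bp rPeak; dispersed: uniform over a 100-bp
    rPeak, so no summit captures half the reads.
    """
    rng = config.rng("rampage")
    n = config.n_elements
    labels: list[str] = []
    readsets: list[RampageReadSet] = []
    shape_idx = rng.choice(3, size=n, p=list(config.shape_mix))
    shape_names = ("narrow", "broad", "dispersed")
    for i in range(n):
        shape = shape_names[shape_idx[i]]
        start = 5000 + i * config.element_spacing
        nr = config.reads_per_peak
        if shape == "narrow":
            width = 8
            summit = start + 4
            reads = summit + rng.integers(-1, 2, size=nr)
            reads = np.clip(reads, start, start + width - 1)
        elif shape == "broad":
            width = 40
            summit = start + 20
            at_summit = summit + rng.integers(-1, 2, size=int(np.ceil(nr * 2 / 3)))
            spread = summit + np.round(
                rng.normal(0, 8, size=nr - at_summit.size)).astype(int)
            reads = np.concatenate([at_summit, spread])
            reads = np.clip(reads, start, start + width - 1)
        else:
            width = 100
            reads = start + rng.integers(0, width, size=nr)
        rpeak = GenomicInterval(CHROM, start, start + width, "+", f"P{i:06d}")
        readsets.append(RampageReadSet(rpeak, "B000", tuple(int(r) for r in reads)))
        labels.append(shape)
    return readsets, labels


def expected_site_pi(config: SyntheticConfig) -> float:
    """Closed-form E[site pi] = 2 E[p(1-p)] for Beta(a, b) alt frequencies."""
    a, b = config.af_beta_params
    e_p = a / (a + b)
    e_p2 = a * (a + 1) / ((a + b) * (a + b + 1))
    return 2.0 * (e_p - e_p2)


def gen_allele_freqs(
    config: SyntheticConfig,
    regions: list[GenomicInterval] | None = None,
    flank: int = 2000,
):
    """Variant table with elevated density at region centers.

    Variant positions arise as Bernoulli(rate) per bp — ``pi_center_rate``
    inside each region, ``pi_flank_rate`` in the +/-``flank`` windows
    around it — and alternate-allele frequencies are Beta(a, b).  Returns
    (AlleleFrequencyTable, truth dict).
    """
    from .popgen import AlleleFrequencyTable

    rng = config.rng("allele")
    if regions is None:
        regions = element_intervals(config)
    table = AlleleFrequencyTable()
    a, b = config.af_beta_params
    taken: set[int] = set()
    for region in regions:
        lo = max(region.start - flank, 0)
        hi = region.end + flank
        for pos in range(lo, hi):
            rate = (
                config.pi_center_rate
                if region.start <= pos < region.end
                else config.pi_flank_rate
            )
            if rate > 0 and pos not in taken and rng.random() < rate:
                taken.add(pos)
                p_alt = float(np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9))
                table.add_site(CHROM, pos, (1.0 - p_alt, p_alt))
    truth = {
        "expected_site_pi": expected_site_pi(config),
        "pi_center_rate": config.pi_center_rate,
        "pi_flank_rate": config.pi_flank_rate,
    }
    return table, truth


def write_vcf(path: str, table, chrom_len: int | None = None) -> None:
    """Write an AlleleFrequencyTable as a minimal VCF with AF INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        length = chrom_len or 10**9
        fh.write(f"##contig=<ID={CHROM},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in sorted(table._sites):
            for pos in sorted(table._sites[chrom]):
                freqs = table._sites[chrom][pos]
                alts = ",".join("G" for _ in freqs[1:])
                af = ",".join(f"{p:.6g}" for p in freqs[1:])
                fh.write(
                    f"{chrom}\t{pos + 1}\t.\tA\t{alts}\t100\tPASS\tAF={af}\n"
                )


@dataclass
class SyntheticAux:
    expression: pd.DataFrame  # genes x biosamples, TPM
    tau_truth: dict[str, str]  # gene -> housekeeping | specific
    loops: list
    loop_truth: dict
    chip_peaks: list[GenomicInterval]
    stapseq: pd.DataFrame  # cofactors x promoters
    stapseq_blocks: dict[str, int]
    signal_track: SignalTrack


def gen_aux(
    config: SyntheticConfig,
    ubi_labels: np.ndarray | None = None,
    housekeeping_labels: np.ndarray | None = None,
) -> SyntheticAux:
    """Expression, loops, ChIP peaks, cofactor matrix and a signal track.

    Housekeeping genes are expressed in every biosample (tau near 0);
    tissue-specific genes in exactly one (tau = 1).  Loops preferentially
    anchor on planted-ubiquitous elements (``ubi_labels``, per element).
    The cofactor matrix has two planted blocks with high within-block
    correlation.  The signal track is elevated at ubiquitous element
    centers.
    """
    from .enrichment import Loop

    rng_e = config.rng("expression")
    n_genes, m = config.n_genes, config.n_biosamples
    if housekeeping_labels is None:
        housekeeping_labels = np.arange(n_genes) < int(round(0.5 * n_genes))
    housekeeping_labels = np.asarray(housekeeping_labels[:n_genes], dtype=bool)
    expr = np.zeros((n_genes, m))
    tau_truth: dict[str, str] = {}
    for i in range(n_genes):
        gid = f"G{i:05d}"
        if housekeeping_labels[i]:
            # near-constant across biosamples (~2% CV): tau stays near 0
            expr[i] = np.abs(rng_e.normal(100.0, 2.0, size=m))
            tau_truth[gid] = "housekeeping"
        else:
            j = int(rng_e.integers(0, m))
            expr[i, j] = float(np.abs(rng_e.normal(50.0, 5.0)))
            tau_truth[gid] = "specific"
    expression = pd.DataFrame(
        expr, index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"B{j:03d}" for j in range(m)],
    )

    rng_l = config.rng("loops")
    elements = element_intervals(config)
    n_el = len(elements)
    ubi_el = np.zeros(n_el, dtype=bool)
    if ubi_labels is None:
        ubi_el[: int(round(config.ubiquitous_fraction * n_el))] = True
    else:
        ubi_labels = np.asarray(ubi_labels, dtype=bool)
        k = min(n_el, ubi_labels.size)
        ubi_el[:k] = ubi_labels[:k]
    loops: list[Loop] = []
    for i in np.nonzero(ubi_el)[0]:
        if rng_l.random() < 0.8:  # planted: most ubi elements are anchored
            el = elements[i]
            far = GenomicInterval(
                CHROM, el.start + 5000, el.start + 5400, ".", None)
            loops.append(Loop(el, far, int(rng_l.integers(4, 30))))
    # background loops away from any element, some below the read filter
    for _ in range(max(4, len(loops) // 4)):
        s = int(rng_l.integers(0, n_el)) * config.element_spacing + 7000
        a1 = GenomicInterval(CHROM, s, s + 400)
        a2 = GenomicInterval(CHROM, s + 20000, s + 20400)
        loops.append(Loop(a1, a2, int(rng_l.integers(1, 8))))

    rng_c = config.rng("chip")
    chip_peaks = []
    for i in range(0, n_el, 3):
        el = elements[i]
        center = el.center + int(rng_c.integers(-50, 51))
        w = int(rng_c.integers(120, 240))
        chip_peaks.append(
            GenomicInterval(CHROM, max(center - w // 2, 0), center + w // 2,
                            ".", f"peak_{i}")
        )

    rng_s = config.rng("stapseq")
    n_prom = 120
    cofactors = [f"CF{i}" for i in range(6)]
    blocks = {cf: (0 if i < 3 else 1) for i, cf in enumerate(cofactors)}
    u = rng_s.normal(0, 1, size=n_prom)
    v = rng_s.normal(0, 1, size=n_prom)
    rows = []
    for cf in cofactors:
        latent = u if blocks[cf] == 0 else v
        rows.append(10 + 3 * latent + rng_s.normal(0, 0.3, size=n_prom))
    stapseq = pd.DataFrame(
        rows, index=cofactors, columns=[f"prom{i:03d}" for i in range(n_prom)]
    )

    rng_g = config.rng("signal")
    runs = []
    for i, el in enumerate(elements[: min(n_el, 500)]):
        height = 8.0 if ubi_el[i] else 2.0
        runs.append((el.start, el.end, height + float(rng_g.normal(0, 0.2))))
    track = SignalTrack({CHROM: runs})

    return SyntheticAux(
        expression, tau_truth, loops,
        {"anchored_on_ubi": True}, chip_peaks, stapseq, blocks, track,
    )


# ---------------------------------------------------------------------------
# File emission


def write_gtf(path: str, genes, source: str = "ubiprom-synth") -> None:
    """One transcript record per TSS; 1-based inclusive GTF coordinates."""
    with open(path, "w") as fh:
        fh.write("#!ubiprom synthetic annotation\n")
        for g in genes:
            for k, tss in enumerate(g.tss_list):
                if g.strand == "+":
                    start, end = tss, tss + 500
                else:
                    start, end = tss - 500, tss
                start = max(start, 0)
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.{k}"; '
                    f'gene_type "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{start + 1}\t{end + 1}\t."
                    f"\t{g.strand}\t.\t{attrs}\n"
                )


def write_dataset(config: SyntheticConfig, out_dir: str) -> dict:
    """Generate and write every input file the pipeline consumes.

    Emits FASTA, GTF, BED6, BEDPE, VCF, bedGraph and TSV matrices plus a
    JSON truth file, and returns the truth dict.
    """
    from . import __version__
    from .regions import write_bed6, write_bedgraph
    from .seqfeat import write_fasta
    from .enrichment import write_bedpe_loops
    from .transcription import write_rampage_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, ubi = gen_zscore_matrix(config)
    matrix.to_tsv(str(out / "zscores.tsv"))
    ann = gen_annotation(config)
    write_fasta(str(out / "genome.fa"), {CHROM: ann.chrom_sequence})
    write_gtf(str(out / "genes.gtf"), ann.genes)
    write_bed6(str(out / "cpg_islands.bed"), ann.cpg_islands)
    write_bed6(str(out / "elements.bed"), element_intervals(config))
    readsets, shapes = gen_rampage_reads(config)
    write_rampage_tsv(str(out / "rampage.tsv"), readsets)
    afreq_regions = element_intervals(config)[: min(config.n_elements, 200)]
    table, af_truth = gen_allele_freqs(config, afreq_regions)
    write_vcf(str(out / "variants.vcf"), table,
              chrom_len=5000 + config.n_elements * config.element_spacing + 10000)
    hk = np.array([ann.truth["ubi_gene"].get(f"G{i:05d}", False)
                   for i in range(config.n_genes)])
    aux = gen_aux(config, ubi_labels=ubi, housekeeping_labels=hk)
    aux.expression.to_csv(out / "expression.tsv", sep="\t")
    meta = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "biotype": g.biotype,
                "strand": g.strand,
                "essential": int(g.essential),
                "mendelian": int(g.mendelian),
                "crispr_score": round(g.min_crispr_score, 4)
                if g.crispr_scores else "",
            }
            for g in ann.genes
        ]
    )
    meta.to_csv(out / "gene_metadata.tsv", sep="\t", index=False)
    write_bedpe_loops(str(out / "loops.bedpe"), aux.loops)
    write_bed6(str(out / "chip_peaks.bed"), aux.chip_peaks)
    aux.stapseq.to_csv(out / "stapseq.tsv", sep="\t")
    write_bedgraph(str(out / "signal.bedGraph"), aux.signal_track)
    truth = {
        "version": __version__,
        "seed": config.seed,
        "ubiquitous_elements": [f"E{i:06d}" for i in np.nonzero(ubi)[0]],
        "rpeak_shapes": {f"P{i:06d}": s for i, s in enumerate(shapes)},
        "tau": aux.tau_truth,
        "stapseq_blocks": aux.stapseq_blocks,
        "allele_freqs": af_truth,
        "annotation": {
            "tata": ann.truth["tata"],
            "ubi_gene": ann.truth["ubi_gene"],
            "bidirectional_pairs": ann.truth["bidirectional_pairs"],
        },
        "config": asdict(config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return truth
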