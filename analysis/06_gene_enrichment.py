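#!/usr/bin/env python
"""Gene-level association statistics.

Assigns genes to promoter classes, runs the "genes with both promoter
types" permutation null, the essential/Mendelian Fisher tests (including
the published 2x2), the essentiality rank sweep, and loop-anchor
enrichment.  Writes results/gene_enrichment.tsv and prints the headline
numbers.
"""

import json
from pathlib import Path

import pandas as pd

from ubiprom.enrichment import (assign_gene_class, both_class_permutation,
                                chia_anchor_enrichment, fisher_exact,
                                rank_window_fraction, read_bedpe_loops,
                                read_gtf_genes)
from ubiprom.synthetic import SyntheticConfig, element_intervals

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    config = SyntheticConfig(seed=1)
    genes = read_gtf_genes(str(ROOT / "data" / "genes.gtf"))
    meta = pd.read_csv(ROOT / "data" / "gene_metadata.tsv", sep="\t",
                       index_col="gene_id")
    for g in genes:
        if g.gene_id in meta.index:
            row = meta.loc[g.gene_id]
            g.essential = bool(row["essential"])
            g.mendelian = bool(row["mendelian"])
            if row["crispr_score"] != "":
                g.crispr_scores = {"merged": float(row["crispr_score"])}
    truth = json.load(open(ROOT / "data" / "truth.json"))
    ubi_ids = set(truth["ubiquitous_elements"])
    elements = element_intervals(config)
    ubi_iv = [e for e in elements if e.id in ubi_ids]
    non_iv = [e for e in elements if e.id not in ubi_ids]

    classes = assign_gene_class(ubi_iv, non_iv, genes)
    counts = pd.Series(classes).value_counts()
    print("gene classes:", dict(counts))
    pd.Series(classes, name="class").to_csv(ROOT / "gene_enrichment.tsv",
                                            sep="\t")

    n_both = int(counts.get("both", 0))
    n_ubi_tss = sum(
        1 for g in genes for t in g.tss_list
        if any(iv.contains(t) for iv in ubi_iv if iv.chrom == g.chrom)
    )
    perm = both_class_permutation(genes, n_ubi_tss, n_perm=10_000, seed=1,
                                  observed=n_both)
    print(f"genes with both promoter types: observed {n_both}, "
          f"null {perm.expected_mean:.1f} +/- {perm.expected_sd:.1f}, "
          f"p {perm.p_label}")

    # the published Mendelian x essential overlap
    _, p = fisher_exact([[941, 1777], [4371, 11544]])
    print(f"Mendelian x essential overlap (941/2718 vs 5312/18633): "
          f"p = {p:.3g}")

    ess_flags = {g.gene_id: g.essential for g in genes}
    sweep = rank_window_fraction(genes, ess_flags, window=100)
    print("essential fraction by CRISPR-rank window:",
          [round(f, 2) for f in sweep['fraction']])

    loops = read_bedpe_loops(str(ROOT / "data" / "loops.bedpe"))
    res = chia_anchor_enrichment(loops, ubi_iv, non_iv)
    print(f"loop anchors: {res.percent_ubi_anchored:.1f}% of ubiquitous vs "
          f"{res.percent_nonubi_anchored:.1f}% of other promoters anchored "
          f"(Fisher p = {res.fisher_p:.3g}, {res.n_loops} loops kept)")
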