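"""End-to-end orchestration over synthetic or user-supplied inputs.

Stages run in dependency order (synth -> ubiquity -> sequence features /
transcription / diversity / enrichment) and write one TSV or JSON report
per analysis plus a machine-readable manifest of inputs, parameters and
seeds.  Identical config and inputs give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

log = logging.getLogger("ubiprom")

STAGES = ("synth", "ubiquity", "seqfeat", "transcription", "popgen", "enrichment")
_DEPS = {
    "ubiquity": ("synth",),
    "seqfeat": ("synth",),
    "transcription": ("synth",),
    "popgen": ("synth",),
    "enrichment": ("synth", "ubiquity"),
}

_KNOWN_KEYS = {
    "out_dir", "stages", "seed", "z_threshold", "min_samples", "n_boot",
    "n_perm", "flank", "bin_width", "p_motif", "p_tata", "synthetic",
}


@dataclass
class PipelineConfig:
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    z_threshold: float = 1.64
    min_samples: int | None = None
    n_boot: int = 10000
    n_perm: int = 10000
    flank: int = 2000
    bin_width: int = 100
    p_motif: float = 1e-4
    p_tata: float = 1e-3
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
            for dep in _DEPS.get(s, ()):
                if dep not in self.stages:
                    raise ValueError(
                        f"stage {s!r} requires stage {dep!r} to be enabled"
                    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write reports under ``out_dir``.

    Returns the manifest dict (also written as manifest.json).
    """
    from .synthetic import SyntheticConfig, write_dataset, element_intervals
    from . import ubiquity as ub
    from . import seqfeat as sf
    from . import transcription as tx
    from . import popgen as pg
    from . import enrichment as en

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.stages:
        warnings.warn("no stages enabled; nothing to do")
        return {}
    manifest: dict = {
        "tool": "ubiprom",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "z_threshold": config.z_threshold,
            "min_samples": config.min_samples,
            "n_boot": config.n_boot,
            "n_perm": config.n_perm,
            "flank": config.flank,
            "bin_width": config.bin_width,
            "p_motif": config.p_motif,
            "p_tata": config.p_tata,
        },
        "outputs": [],
    }

    def _emit(name: str) -> str:
        manifest["outputs"].append(name)
        return str(out / name)

    scfg = SyntheticConfig(seed=config.seed, **config.synthetic)
    data_dir = out / "data"
    truth = None
    if "synth" in config.stages:
        log.info("stage synth: generating dataset")
        truth = write_dataset(scfg, str(data_dir))

    ubi_ids: list[str] = []
    if "ubiquity" in config.stages:
        log.info("stage ubiquity")
        matrix = ub.SignalZMatrix.from_tsv(str(data_dir / "zscores.tsv"))
        counts = ub.count_high_samples(matrix, config.z_threshold)
        min_s = config.min_samples or ub.default_min_samples(matrix.n_biosamples)
        calls = ub.call_ubiquitous(counts, min_s)
        ubi_ids = list(calls.index[calls])
        pd.DataFrame({"n_high": counts, "ubiquitous": calls}).to_csv(
            _emit("ubiquity_calls.tsv"), sep="\t")

    if "seqfeat" in config.stages:
        log.info("stage seqfeat")
        seqs = sf.read_fasta(str(data_dir / "genome.fa"))
        rows = []
        for iv in element_intervals(scfg)[:500]:
            if iv.chrom not in seqs or iv.end > len(seqs[iv.chrom]):
                continue  # element beyond the synthetic chromosome
            seq = seqs[iv.chrom][iv.start:iv.end]
            comp = sf.normalized_cg_content(seq)
            rows.append({"element": iv.id, "normalized_cg": comp.normalized_cg,
                         "frac_CpG": comp.frac_CpG})
        pd.DataFrame(rows).to_csv(_emit("cg_content.tsv"), sep="\t", index=False)

    if "transcription" in config.stages:
        log.info("stage transcription")
        from .synthetic import gen_rampage_reads
        readsets, _ = gen_rampage_reads(scfg)
        rows = []
        for rs in readsets[:2000]:
            call = tx.classify_peak_shape(rs)
            rows.append({"rpeak": rs.rpeak.id, "shape": call.shape,
                         "n_reads": call.n_reads,
                         "summit_fraction": round(call.summit_fraction, 4)})
        pd.DataFrame(rows).to_csv(_emit("peak_shapes.tsv"), sep="\t", index=False)
        expr = pd.read_csv(data_dir / "expression.tsv", sep="\t", index_col=0)
        qn = tx.quantile_normalize(expr)
        taus = {g: tx.tissue_specificity_index(qn.loc[g].values)
                for g in qn.index if qn.loc[g].max() > 0}
        pd.Series(taus, name="tau").to_csv(_emit("tau.tsv"), sep="\t")

    if "popgen" in config.stages:
        log.info("stage popgen")
        table = pg.AlleleFrequencyTable.from_vcf(str(data_dir / "variants.vcf"))
        regions = element_intervals(scfg)[:200]
        results = [pg.region_pi(r, table) for r in regions]
        pg.write_region_pi(_emit("region_pi.tsv"), results)
        profile = pg.pi_profile(regions, table, config.flank, config.bin_width)
        from .regions import write_metaprofile
        write_metaprofile(_emit("pi_profile.tsv"), profile,
                          params=f"flank={config.flank}")

    if "enrichment" in config.stages:
        log.info("stage enrichment")
        genes = en.read_gtf_genes(str(data_dir / "genes.gtf"))
        elements = element_intervals(scfg)
        ubi_set = set(ubi_ids)
        ubi_iv = [e for e in elements if e.id in ubi_set]
        non_iv = [e for e in elements if e.id not in ubi_set]
        classes = en.assign_gene_class(ubi_iv, non_iv, genes)
        pd.Series(classes, name="class").to_csv(_emit("gene_classes.tsv"),
                                                sep="\t")
        ess = [g for g in genes if g.essential]
        men = [g for g in genes if g.mendelian]
        both = sum(1 for g in genes if g.essential and g.mendelian)
        odds, p = en.fisher_exact(
            [[both, len(men) - both],
             [len(ess) - both, len(genes) - len(men) - len(ess) + both]]
        )
        with open(_emit("essential_mendelian_fisher.json"), "w") as fh:
            json.dump({"odds_ratio": odds, "p": p, "n_genes": len(genes)}, fh)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
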