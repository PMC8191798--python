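#!/usr/bin/env python
"""Generate the synthetic study dataset with planted ground truth.

Writes every input the downstream stages consume (Z-score matrix, genome
FASTA, gene GTF, CpG-island/element BEDs, RAMPAGE 5'-end reads, variant
VCF, expression and cofactor matrices, loops, ChIP peaks, signal track)
under results/data/, plus truth.json recording what was planted.
"""

from pathlib import Path

from ubiprom.synthetic import SyntheticConfig, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

if __name__ == "__main__":
    config = SyntheticConfig(seed=1)
    truth = write_dataset(config, str(OUT))
    print(f"wrote dataset to {OUT}")
    print(f"  elements: {config.n_elements}  biosamples: {config.n_biosamples}"
          f"  genes: {config.n_genes}")
    print(f"  planted ubiquitous elements: {len(truth['ubiquitous_elements'])}"
          f" ({100 * config.ubiquitous_fraction:.1f}%)")
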