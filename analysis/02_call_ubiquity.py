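#!/usr/bin/env python
"""Call ubiquitously accessible elements from the DNase Z-score matrix.

An element is "high" in a biosample at Z > 1.64 (one-sided 5% of the
standard normal) and ubiquitous when high in >= 95% of biosamples.
Compares the calls against the planted truth and writes the per-element
table to results/ubiquity_calls.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from ubiprom.ubiquity import (SignalZMatrix, call_ubiquitous,
                              count_high_samples, default_min_samples)

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    matrix = SignalZMatrix.from_tsv(str(ROOT / "data" / "zscores.tsv"))
    counts = count_high_samples(matrix)
    min_s = default_min_samples(matrix.n_biosamples)
    calls = call_ubiquitous(counts, min_s)
    truth = set(json.load(open(ROOT / "data" / "truth.json"))
                ["ubiquitous_elements"])
    called = set(calls.index[calls])
    tp = len(called & truth)
    print(f"{len(called)} / {len(calls)} elements ubiquitous "
          f"(>= {min_s} of {matrix.n_biosamples} biosamples with Z > 1.64)")
    print(f"  sensitivity {tp / len(truth):.4f}  "
          f"specificity {1 - len(called - truth) / (len(calls) - len(truth)):.4f}")
    pd.DataFrame({"n_high": counts, "ubiquitous": calls}).to_csv(
        ROOT / "ubiquity_calls.tsv", sep="\t")
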