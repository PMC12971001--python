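#!/usr/bin/env python
"""Simulate the confounded biobank-style cohort and write it to disk.

Two subpopulations with allele-frequency differentiation (Fst 0.05) and a
direct subpopulation-to-risk coupling, three planted causal variants, and
genotype-derived principal components — the cohort every later stage
consumes. Writes results/cohort/ (samples.tsv, variants.tsv, dosages.tsv,
truth.json).
"""

import sys
from pathlib import Path

from ctrlgwas import io, synthdata

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 1) -> None:
    cfg = synthdata.confounded_preset(seed=seed)
    cohort = synthdata.simulate_cohort(cfg)
    io.write_cohort(cohort, OUT)
    status = cohort.samples["STATUS"].value_counts()
    print(f"cohort: {cohort.n_samples} samples, {cohort.n_variants} variants "
          f"on {cfg.n_chromosomes} chromosomes")
    print(f"cases {status.get('case', 0)}, potential controls "
          f"{status.get('control', 0)}")
    print(f"planted causal variants: {list(cohort.truth['causal']['ID'])}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
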