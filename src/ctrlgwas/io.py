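"""Plain-text cohort serialization.

A cohort is written as four files in a directory:

* ``samples.tsv``  — SAMPLE_ID, REPORTED_SEX, GENETIC_SEX, STATUS, AGE,
  CENTRE, CHIP, PC1..PC10, MISS_RATE, HET, ANEUPLOIDY
* ``variants.tsv`` — CHROM, POS, ID, ALLELE0, ALLELE1, INFO
* ``dosages.tsv``  — one row per variant: ID then per-sample integer
  dosages, missing encoded as ``NA``
* ``truth.json``   — generating config, subpopulation assignment and the
  planted-causal table (truth side-channel; not part of the exported
  study data)

The round trip is lossless: ``read_cohort(write_cohort(c)) == c`` field
for field (floats are written with shortest-exact repr).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import SyntheticCohort, MISSING

SAMPLE_COLUMNS = (
    ["SAMPLE_ID", "REPORTED_SEX", "GENETIC_SEX", "STATUS", "AGE", "CENTRE", "CHIP"]
    + [f"PC{i}" for i in range(1, 11)]
    + ["MISS_RATE", "HET", "ANEUPLOIDY"]
)
VARIANT_COLUMNS = ["CHROM", "POS", "ID", "ALLELE0", "ALLELE1", "INFO"]


class CohortFormatError(ValueError):
    """Malformed cohort file; message carries the offending file and line."""


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.samples[SAMPLE_COLUMNS].to_csv(path / "samples.tsv", sep="\t", index=False)
    cohort.variants[VARIANT_COLUMNS].to_csv(path / "variants.tsv", sep="\t", index=False)
    ids = cohort.variants["ID"].to_numpy()
    with open(path / "dosages.tsv", "w") as fh:
        fh.write("ID\t" + "\t".join(cohort.samples["SAMPLE_ID"]) + "\n")
        for i, vid in enumerate(ids):
            row = cohort.dosages[i]
            cells = np.where(row == MISSING, "NA", row.astype(str))
            fh.write(vid + "\t" + "\t".join(cells) + "\n")
    truth = {
        "config": cohort.truth["config"],
        "subpop": np.asarray(cohort.truth["subpop"]).tolist(),
        "causal": cohort.truth["causal"].to_dict(orient="list"),
    }
    with open(path / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return path


def read_cohort(path: str | Path) -> SyntheticCohort:
    path = Path(path)
    samples = pd.read_csv(path / "samples.tsv", sep="\t",
                          dtype={"REPORTED_SEX": str, "GENETIC_SEX": str})
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise CohortFormatError(f"{path / 'samples.tsv'}: missing columns {missing_cols}")
    variants = pd.read_csv(path / "variants.tsv", sep="\t")
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise CohortFormatError(f"{path / 'variants.tsv'}: missing columns {missing_cols}")

    n = len(samples)
    m = len(variants)
    dosages = np.empty((m, n), dtype=np.int8)
    with open(path / "dosages.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != n + 1:
            raise CohortFormatError(
                f"{path / 'dosages.tsv'}: line 1: expected {n + 1} columns, found {len(header)}")
        i = -1
        for i, line in enumerate(fh):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n + 1:
                raise CohortFormatError(
                    f"{path / 'dosages.tsv'}: line {i + 2}: expected {n + 1} columns, "
                    f"found {len(cells)}")
            if i >= m:
                raise CohortFormatError(
                    f"{path / 'dosages.tsv'}: line {i + 2}: more rows than variants ({m})")
            if cells[0] != variants["ID"].iloc[i]:
                raise CohortFormatError(
                    f"{path / 'dosages.tsv'}: line {i + 2}: variant id {cells[0]!r} "
                    f"does not match variants.tsv ({variants['ID'].iloc[i]!r})")
            row = np.array(cells[1:])
            row[row == "NA"] = str(MISSING)
            dosages[i] = row.astype(np.int8)
        if i + 1 != m:
            raise CohortFormatError(
                f"{path / 'dosages.tsv'}: expected {m} variant rows, found {i + 1}")

    with open(path / "truth.json") as fh:
        raw = json.load(fh)
    raw["config"]["base_maf_range"] = tuple(raw["config"]["base_maf_range"])
    raw["config"]["info_beta_params"] = tuple(raw["config"]["info_beta_params"])
    raw["config"]["causal_effects"] = [tuple(t) for t in raw["config"]["causal_effects"]]
    truth = {
        "config": raw["config"],
        "subpop": np.asarray(raw["subpop"]),
        "causal": pd.DataFrame(raw["causal"], columns=["ID", "CHROM", "POS", "BETA"]),
    }
    return SyntheticCohort(samples=samples, variants=variants, dosages=dosages, truth=truth)
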