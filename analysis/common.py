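"""Shared paths and loaders for the numbered analysis scripts.

Every script reads its inputs from, and writes its outputs under,
``results/`` at the repository root, so the stages can be run one after
another: 01 writes the dataset, later stages consume it plus earlier
stages' tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 11

# reduced-scale MCMC used throughout the analysis scripts
MCMC = dict(burn_in=1500, length=4500, thin=5, alpha_prop_sd=0.2)


def load_dataset():
    from cryptohyb.genodata import read_fasta, read_genotypes

    gm = read_genotypes(DATA / "genotypes.csv", "csv_wide")
    coi = read_fasta(DATA / "coi.fasta")
    meta = pd.read_csv(DATA / "metadata.csv", index_col="individual_id")
    truth = pd.read_csv(DATA / "truth.csv", index_col="individual_id")
    return gm, coi, meta, truth


def load_labels():
    """Cluster labels from stage 02: Series of 'A'/'B' indexed by id."""
    q = pd.read_csv(RESULTS / "consensus_q.tsv", sep="\t", index_col="id")
    return q["cluster"], q


def save_table(df: pd.DataFrame, name: str, index=False) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=index)
    return path


def announce(script: str, *lines: str) -> None:
    print(f"== {script} ==")
    for ln in lines:
        print(f"   {ln}")
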