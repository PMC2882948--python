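"""Genotype-matrix conventions and TSV I/O.

Genotypes are stored as integer codes counting copies of the B allele:
``0 = AA, 1 = AB, 2 = BB, -1 = missing``.  On disk the matrix is a
tab-separated table with samples as rows, SNPs as columns and calls coded
``AA/AB/BB/NA``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
CODE_TO_LABEL = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}
LABEL_TO_CODE = {v: k for k, v in CODE_TO_LABEL.items()}


def write_genotypes(gm: pd.DataFrame, path: str | Path) -> None:
    labels = gm.apply(lambda col: col.map(CODE_TO_LABEL))
    labels.to_csv(path, sep="\t", index_label="sample_id")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(
        path, sep="\t", index_col="sample_id", dtype=str,
        keep_default_na=False,
    )
    bad = set(np.unique(labels.values)) - set(LABEL_TO_CODE)
    if bad:
        raise ValueError(f"unrecognized genotype labels: {sorted(bad)}")
    codes = labels.apply(lambda col: col.map(LABEL_TO_CODE))
    return codes.astype(np.int8)


def allele_frequencies(gm: pd.DataFrame, samples=None) -> pd.Series:
    """Plug-in B-allele frequency per SNP, ignoring missing calls.

    ``samples`` restricts the computation (e.g. to unrelated founders so that
    family structure does not distort the estimate).
    """
    sub = gm.loc[samples] if samples is not None else gm
    vals = sub.to_numpy()
    obs = vals != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(obs, vals, 0).sum(axis=0) / (2.0 * obs.sum(axis=0)),
            np.nan,
        )
    return pd.Series(freq, index=sub.columns, name="freq")


def minor_allele_frequencies(gm: pd.DataFrame, samples=None) -> pd.Series:
    p = allele_frequencies(gm, samples)
    return np.minimum(p, 1.0 - p).rename("maf")
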