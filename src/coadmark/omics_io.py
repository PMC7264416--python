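"""Readers/writers for the pipeline's on-disk formats.

Everything is plain TSV: omics matrices as feature rows x sample columns,
survival/clinical tables with a header row, annotation maps and PPI edge
lists as two-column files. Missing values in continuous layers are imputed
feature-wise with the median at load (count logged); missing mutation
calls become 0.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, SurvivalTable, check_domain

logger = logging.getLogger(__name__)


def read_matrix(path, omics_type: str) -> OmicsMatrix:
    """Read a feature x sample TSV into an :class:`OmicsMatrix`.

    Duplicate feature/sample ids and out-of-domain values are rejected
    with the offending id / cell location in the message. Row and column
    order are preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        if omics_type == "mutation":
            df = df.fillna(0.0)
        else:
            med = df.median(axis=1)
            df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
        logger.info("imputed %d missing values in %s matrix %s", n_missing, omics_type, path)
    return OmicsMatrix(omics_type, df)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature")


def read_survival(path) -> SurvivalTable:
    """Read a survival/clinical TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample")


def read_annotation(path) -> dict:
    """Read a two-column feature -> gene-symbol TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature", "symbol"], dtype=str)
    if df["symbol"].isna().any() or (df["symbol"].str.len() == 0).any():
        raise ValueError("annotation map contains an empty gene symbol")
    return dict(zip(df["feature"], df["symbol"]))


def write_annotation(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(sorted(mapping.items())).to_csv(path, sep="\t", header=False, index=False)


def read_edge_list(path) -> list:
    """Read a two-column gene-symbol edge list TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    return list(df.itertuples(index=False, name=None))


def write_edge_list(edges: Iterable[tuple], path) -> None:
    pd.DataFrame(list(edges)).to_csv(path, sep="\t", header=False, index=False)


def align_samples(
    matrices: Sequence[OmicsMatrix], survival: SurvivalTable
) -> tuple[list, SurvivalTable, list]:
    """Restrict all layers and the survival table to their shared samples.

    The shared list keeps the order of the first matrix's columns. Raises
    if the intersection is empty. Idempotent.
    """
    if len(matrices) == 0:
        raise ValueError("align_samples needs at least one matrix")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    shared &= set(survival.sample_ids)
    order = [s for s in matrices[0].sample_ids if s in shared]
    if not order:
        raise ValueError("no samples shared across all omics layers and survival")
    aligned = [m.restrict_samples(order) for m in matrices]
    return aligned, survival.restrict_samples(order), order
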