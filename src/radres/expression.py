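"""Probe-level expression processing.

Custom oligonucleotide chips carry several probes (and probe replicates) per
gene transcript.  This module turns a long-format probe signal table into a
gene x sample expression matrix: probe signals belonging to one gene are
geometrically averaged per sample, and the resulting columns are quantile
normalized so that every sample shares the same empirical intensity
distribution.

File dialect: TSV, decimal point ".", expression values written with 6
significant digits.  The matrix file has gene_id as the first column and one
column per sample; sample annotations (cell_line, drug, week) live in a
sidecar metadata TSV.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: signals at or below zero are floored to this value before any logarithmic
#: or geometric operation (undetectable electrochemical signal, not biology)
SIGNAL_FLOOR = 1e-6

PROBE_COLUMNS = ["probe_id", "gene_id", "sample_id", "signal"]
META_COLUMNS = ["sample_id", "cell_line", "drug", "week"]


class ProbeTableError(ValueError):
    """Raised when a probe signal table violates its invariants."""


def validate_probe_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the probe-table invariants and return the validated frame.

    Each probe must map to exactly one gene and each (probe_id, sample_id)
    pair must be unique.
    """
    missing = [c for c in PROBE_COLUMNS if c not in table.columns]
    if missing:
        raise ProbeTableError(f"probe table missing columns: {missing}")
    gene_counts = table.groupby("probe_id")["gene_id"].nunique()
    multi = gene_counts[gene_counts > 1]
    if len(multi):
        raise ProbeTableError(
            "probe(s) mapped to multiple genes: "
            + ", ".join(map(str, multi.index[:5]))
        )
    if table.duplicated(["probe_id", "sample_id"]).any():
        dup = table[table.duplicated(["probe_id", "sample_id"])].iloc[0]
        raise ProbeTableError(
            f"duplicate measurement for probe {dup['probe_id']!r} "
            f"in sample {dup['sample_id']!r}"
        )
    return table


def floor_signals(signals: pd.Series, floor: float | None = SIGNAL_FLOOR) -> pd.Series:
    """Floor non-positive signals; ``floor=None`` disables flooring (reject instead)."""
    bad = signals <= 0
    if bad.any():
        if floor is None:
            raise ProbeTableError(
                f"{int(bad.sum())} non-positive signal(s) with flooring disabled"
            )
        for idx in signals.index[bad]:
            logger.info("flooring non-positive signal at row %s to %g", idx, floor)
        signals = signals.where(~bad, floor)
    return signals


def collapse_probes(
    table: pd.DataFrame, floor: float | None = SIGNAL_FLOOR
) -> pd.DataFrame:
    """Collapse probe replicate signals to one value per gene and sample.

    Returns a gene x sample DataFrame whose entry is the geometric mean of
    all probe signals of that gene in that sample.  Genes are sorted
    lexicographically; sample order follows first appearance in the table.
    """
    table = validate_probe_table(table)
    table = table.assign(signal=floor_signals(table["signal"].astype(float), floor))
    logs = np.log(table["signal"].to_numpy())
    grouped = (
        pd.DataFrame(
            {"gene_id": table["gene_id"], "sample_id": table["sample_id"], "log": logs}
        )
        .groupby(["gene_id", "sample_id"], sort=False)["log"]
        .mean()
    )
    matrix = np.exp(grouped).unstack("sample_id")
    sample_order = table["sample_id"].drop_duplicates().tolist()
    matrix = matrix.reindex(columns=sample_order).sort_index()
    if matrix.isna().any().any():
        gene = matrix.index[matrix.isna().any(axis=1)][0]
        raise ProbeTableError(f"gene {gene!r} has no probes in some sample")
    matrix.index.name = "gene_id"
    return matrix


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column of ``matrix`` onto the common mean distribution.

    The value at rank r of each column is replaced by the mean, across
    columns, of each column's rank-r value; tied values receive the average
    of the replacement values over the tied ranks.  Gene and sample order are
    preserved.  A single-column matrix is returned unchanged (copy).
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN; quantile normalization rejects NaN")
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[1] == 1:
        return matrix.copy()
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = sorted_means.copy()
        # average replacement values over runs of tied input values
        sorted_col = col[order]
        run_id = np.concatenate([[0], np.cumsum(sorted_col[1:] != sorted_col[:-1])])
        ranked = pd.Series(ranked).groupby(run_id).transform("mean").to_numpy()
        out[order, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# I/O


def read_probe_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str, "sample_id": str})
    return validate_probe_table(table)


def write_probe_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    return matrix


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str, "drug": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta["week"] = meta["week"].astype(int)
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index(drop=True)[META_COLUMNS].to_csv(path, sep="\t", index=False)


def normalize_pipeline(
    table: pd.DataFrame, meta: pd.DataFrame | None = None, per_cell_line: bool = True
) -> pd.DataFrame:
    """collapse_probes followed by quantile normalization.

    By default normalization is run within each cell line's sample block
    (chips of one line are processed as one batch); set
    ``per_cell_line=False`` to normalize across the full sample set.
    """
    matrix = collapse_probes(table)
    if meta is None or not per_cell_line:
        return quantile_normalize(matrix)
    pieces = []
    for _, block in meta.groupby("cell_line", sort=False):
        cols = [s for s in block["sample_id"] if s in matrix.columns]
        if cols:
            pieces.append(quantile_normalize(matrix[cols]))
    normalized = pd.concat(pieces, axis=1)
    return normalized.reindex(columns=[c for c in matrix.columns if c in normalized])
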