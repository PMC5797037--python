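"""Statistics for gammaH2AX and pATM double-strand-break focus counts.

A focus dataset is a long table of per-cell counts: each row is one imaged
nucleus with its gammaH2AX and pATM focus counts, grouped by condition
(cell line, drug lineage, irradiation status, washout status) and by
independent experiment.  Summaries are hierarchical — cells are averaged
within each experiment first, then the grand mean and standard error are
taken over the experiment-level means — because cells within an experiment
are not independent replicates of the experiment itself.  Group comparisons
use the two-sided equal-variance Student t-test on experiment-level means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FOCI_COLUMNS = [
    "cell_line", "lineage", "irradiated", "washout",
    "experiment", "cell_index", "h2ax_count", "patm_count",
]
CONDITION_KEYS = ["cell_line", "lineage", "irradiated", "washout"]
MARKERS = {"h2ax": "h2ax_count", "patm": "patm_count"}


def _marker_column(marker: str) -> str:
    if marker not in MARKERS:
        raise ValueError(f"marker must be one of {sorted(MARKERS)}, got {marker!r}")
    return MARKERS[marker]


def validate_foci(ds: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FOCI_COLUMNS if c not in ds.columns]
    if missing:
        raise ValueError(f"foci table missing columns: {missing}")
    for col in ("h2ax_count", "patm_count"):
        if (ds[col] < 0).any():
            raise ValueError(f"negative counts in {col}")
    return ds


def summarize(ds: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Hierarchical mean and standard error of foci per nucleus per condition.

    Per-experiment cell means are averaged into a grand mean; the SE is the
    standard deviation of the experiment means over sqrt(n_experiments).
    With a single experiment the SE is undefined and reported as NaN with a
    warning.
    """
    validate_foci(ds)
    if not len(ds):
        raise ValueError("empty foci dataset")
    col = _marker_column(marker)
    exp_means = (
        ds.groupby(CONDITION_KEYS + ["experiment"], sort=True)[col].mean().rename("mean")
    )
    rows = []
    for cond, grp in exp_means.groupby(level=CONDITION_KEYS, sort=True):
        means = grp.to_numpy(dtype=float)
        n_exp = len(means)
        if n_exp < 2:
            logger.warning("condition %s has a single experiment; SE undefined", (cond,))
            se = float("nan")
        else:
            se = float(np.std(means, ddof=1) / math.sqrt(n_exp))
        mask = np.ones(len(ds), dtype=bool)
        for key, val in zip(CONDITION_KEYS, cond):
            mask &= (ds[key] == val).to_numpy()
        rows.append(
            dict(
                zip(CONDITION_KEYS, cond),
                marker=marker,
                mean_foci=float(np.mean(means)),
                se=se,
                n_cells=int(mask.sum()),
                n_experiments=n_exp,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InducedFoci:
    """Radiation-induced focus excess: irradiated minus mock-irradiated."""

    induced: float
    se: float  # sqrt(se_irr^2 + se_mock^2)


def induced_foci(irr_mean: float, irr_se: float, mock_mean: float, mock_se: float) -> InducedFoci:
    induced = irr_mean - mock_mean
    if induced < 0:
        logger.warning(
            "mock-irradiated mean (%.3g) exceeds irradiated mean (%.3g); "
            "negative induced focus count", mock_mean, irr_mean,
        )
    return InducedFoci(float(induced), float(math.hypot(irr_se, mock_se)))


def percent_reduction(treated: float, naive: float) -> float:
    """Percent drop of the treated readout relative to the naive readout."""
    if naive <= 0:
        raise ValueError("naive readout must be positive")
    return 100.0 * (naive - treated) / naive


def experiment_means(ds: pd.DataFrame, condition: dict, marker: str) -> np.ndarray:
    """Per-experiment mean foci for the rows matching ``condition``."""
    col = _marker_column(marker)
    mask = np.ones(len(ds), dtype=bool)
    for key, val in condition.items():
        mask &= (ds[key] == val).to_numpy()
    sub = ds[mask]
    if not len(sub):
        raise ValueError(f"no cells match condition {condition}")
    return sub.groupby("experiment")[col].mean().to_numpy(dtype=float)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def compare(ds: pd.DataFrame, condition_a: dict, condition_b: dict, marker: str) -> TTestResult:
    """Equal-variance two-sided Student t-test on experiment-level means."""
    a = experiment_means(ds, condition_a, marker)
    b = experiment_means(ds, condition_b, marker)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "t-test needs >=2 experiments per group "
            f"(got {len(a)} and {len(b)})"
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), len(a) + len(b) - 2, float(res.pvalue))


def reduction_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Percent reduction of foci in each drug lineage versus naive cells.

    ``summary`` is one marker's :func:`summarize` output.  For every
    irradiated drug-lineage condition two readouts are given: the headline
    ``residual_reduction_pct`` compares total residual foci directly, and
    ``induced_reduction_pct`` first subtracts the matching non-irradiated
    (spontaneous) mean from both lineages.  Rows where the naive induced
    count is non-positive report NaN for the subtracted readout.
    """
    rows = []
    for (cell_line, washout), grp in summary.groupby(["cell_line", "washout"]):
        def _mean(lineage, irradiated):
            sel = grp[(grp["lineage"] == lineage) & (grp["irradiated"] == irradiated)]
            return float(sel["mean_foci"].iloc[0]) if len(sel) else None

        naive_irr, naive_spont = _mean("naive", True), _mean("naive", False)
        if naive_irr is None or naive_irr <= 0:
            continue
        for lineage in sorted(set(grp["lineage"]) - {"naive"}):
            irr, spont = _mean(lineage, True), _mean(lineage, False)
            if irr is None:
                continue
            residual = percent_reduction(irr, naive_irr)
            induced = float("nan")
            if (
                spont is not None and naive_spont is not None
                and naive_irr - naive_spont > 0
            ):
                induced = percent_reduction(irr - spont, naive_irr - naive_spont)
            rows.append(
                {
                    "cell_line": cell_line, "lineage": lineage, "washout": washout,
                    "marker": grp["marker"].iloc[0],
                    "residual_reduction_pct": residual,
                    "induced_reduction_pct": induced,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_foci(path) -> pd.DataFrame:
    ds = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "lineage": str})
    ds["irradiated"] = ds["irradiated"].astype(bool)
    ds["washout"] = ds["washout"].astype(bool)
    return validate_foci(ds)


def write_foci(ds: pd.DataFrame, path) -> None:
    validate_foci(ds)[FOCI_COLUMNS].to_csv(path, sep="\t", index=False)


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
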