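"""MTT viability, 4PL dose-response fitting and IC50 resistance tables.

Viability of a well is (OD_treated - OD_blank) / (OD_control - OD_blank) x
100%, where the control wells received no drug and the blank wells no cells.
Viability over a concentration series is fitted with the four-parameter
logistic (4PL)

    v(c) = floor + (ceiling - floor) / (1 + (c / IC50)^hill)

by least squares on log10 concentration; the zero-dose wells define 100%
viability and are excluded from the log-scale fit.  An IC50 is censored
(">= max dose") when the fitted midpoint lies beyond the highest tested
concentration or the curve never reaches its midpoint within the tested
range; an all-dead plate censors at the lowest dose ("<=").

Acquired resistance over a culturing time course is summarized as the
percent change of IC50 versus the untreated baseline, rounded half-up to an
integer percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: drug concentrations (uM) of the standard plate design
STANDARD_CONCENTRATIONS = (0.0, 0.8, 1.56, 3.1, 6.25, 12.5, 25.0, 50.0)

#: RMSE (viability percentage points) above which a fit is flagged low-confidence
RSS_RMSE_THRESHOLD = 15.0

NOT_SIGNIFICANT = "Not significant"
NOT_DETECTED = "Not detected"


def viability(od_treated, od_control: float, od_blank: float):
    """Percent viability of treated wells; may exceed 100% (growth stimulation)."""
    if od_control <= od_blank:
        raise ValueError(
            f"OD of control wells ({od_control}) must exceed OD blank ({od_blank})"
        )
    return (np.asarray(od_treated, dtype=float) - od_blank) / (od_control - od_blank) * 100.0


def four_pl(conc, floor: float, ceiling: float, ic50: float, hill: float):
    """Four-parameter logistic viability curve (decreasing for hill > 0)."""
    conc = np.asarray(conc, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (conc / ic50) ** hill)


@dataclass
class DoseResponsePlate:
    """One MTT plate: a concentration series in replicate for one condition."""

    cell_line: str
    drug: str
    week: int
    concentrations: list[float]  # non-zero doses, uM, strictly increasing
    od: np.ndarray  # shape (n_concentrations, n_replicates)
    od_blank: float
    od_control: list[float]  # OD of the 0 uM wells

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if (conc <= 0).any() or (np.diff(conc) <= 0).any():
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.od.shape[0] != len(conc) or self.od.shape[1] < 1:
            raise ValueError("OD matrix must be (n_concentrations x >=1 replicates)")
        if float(np.mean(self.od_control)) <= self.od_blank:
            raise ValueError("mean control OD must exceed blank OD")

    def viability_matrix(self) -> np.ndarray:
        """Per-well percent viability against the mean 0-dose control OD."""
        return viability(self.od, float(np.mean(self.od_control)), self.od_blank)


@dataclass(frozen=True)
class IC50Estimate:
    """Fitted IC50 with censoring status and 4PL curve parameters."""

    ic50: float | None  # uM; None when censored
    censored: bool
    censor_bound: float | None  # uM; the tested-range bound when censored
    censor_direction: str | None  # ">=" or "<="
    hill: float
    viability_floor: float
    viability_ceiling: float
    fit_rss: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        assert (self.ic50 is None) == self.censored

    def display(self) -> str:
        if self.censored:
            bound = f"{self.censor_bound:g}"
            return f"{self.censor_direction}{bound}"
        return f"{self.ic50:g}"


def fit_ic50(plate: DoseResponsePlate) -> IC50Estimate:
    """Fit the 4PL model to a plate and estimate IC50 with censoring.

    Needs at least 4 distinct non-zero concentrations.  A noisy, non-monotone
    plate is not rejected: it is flagged ``low_confidence`` when the fit RMSE
    exceeds 15 viability points.
    """
    conc = np.asarray(plate.concentrations, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need >=4 distinct non-zero concentrations for a 4PL fit")
    viab = plate.viability_matrix()
    mean_v = viab.mean(axis=1)
    cmin, cmax = conc[0], conc[-1]

    # all-alive / all-dead plates carry no midpoint information
    if mean_v.min() >= 90.0:
        logger.info("%s/%s week %s: all-alive plate, censoring at >=%g uM",
                    plate.cell_line, plate.drug, plate.week, cmax)
        return IC50Estimate(None, True, cmax, ">=", np.nan, mean_v.min(), 100.0, 0.0)
    if mean_v.max() <= 10.0:
        logger.info("%s/%s week %s: all-dead plate, censoring at <=%g uM",
                    plate.cell_line, plate.drug, plate.week, cmin)
        return IC50Estimate(None, True, cmin, "<=", np.nan, 0.0, mean_v.max(), 0.0)

    x = np.repeat(conc, viab.shape[1])
    y = viab.ravel()

    def model(log_c, floor, ceiling, log_ic50, hill):
        return four_pl(10.0 ** log_c, floor, ceiling, 10.0 ** log_ic50, hill)

    ceiling0 = float(mean_v.max())
    floor0 = float(mean_v.min())
    mid = (ceiling0 + floor0) / 2.0
    ic50_0 = float(conc[np.argmin(np.abs(mean_v - mid))])
    p0 = [floor0, ceiling0, np.log10(ic50_0), 1.0]
    # viability is normalized to the 0-dose controls, so the ceiling sits
    # near 100% and the floor cannot be negative; bounding both keeps
    # shallow-hill fits identifiable
    bounds = (
        [0.0, 60.0, np.log10(cmin / 10.0), 0.2],
        [60.0, 150.0, np.log10(cmax * 10.0), 8.0],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, _ = curve_fit(
            model, np.log10(x), y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:  # no convergence: fall back to the initial guess
        popt = np.asarray(p0, dtype=float)
    floor_f, ceiling_f, log_ic50_f, hill_f = map(float, popt)
    ic50_f = 10.0 ** log_ic50_f
    resid = y - model(np.log10(x), *popt)
    rss = float(resid @ resid)
    rmse = float(np.sqrt(rss / len(y)))
    low_conf = rmse > RSS_RMSE_THRESHOLD
    if low_conf:
        logger.info("%s/%s week %s: fit RMSE %.1f above threshold, low confidence",
                    plate.cell_line, plate.drug, plate.week, rmse)

    midpoint = (floor_f + ceiling_f) / 2.0
    crosses = four_pl(cmax, floor_f, ceiling_f, ic50_f, hill_f) <= midpoint
    if ic50_f > cmax or not crosses:
        logger.info("%s/%s week %s: IC50 beyond tested range, censoring at >=%g uM",
                    plate.cell_line, plate.drug, plate.week, cmax)
        return IC50Estimate(
            None, True, cmax, ">=", hill_f, floor_f, ceiling_f, rss, low_conf
        )
    return IC50Estimate(
        ic50_f, False, None, None, hill_f, floor_f, ceiling_f, rss, low_conf
    )


# ---------------------------------------------------------------------------
# Percent-change arithmetic


def percent_change_raw(ic50_t: float, ic50_0: float) -> float:
    """Unrounded percent change of IC50 versus the baseline."""
    if ic50_t <= 0 or ic50_0 <= 0:
        raise ValueError("IC50 values must be positive")
    return 100.0 * (ic50_t - ic50_0) / ic50_0


def percent_change(ic50_t, ic50_0) -> int | str:
    """Integer percent change (half-up rounding); censored input is not comparable.

    Accepts floats or IC50Estimate objects; a censored estimate on either
    side yields the "Not significant" marker.
    """
    for v in (ic50_t, ic50_0):
        if isinstance(v, IC50Estimate) and v.censored:
            return NOT_SIGNIFICANT
    t = ic50_t.ic50 if isinstance(ic50_t, IC50Estimate) else float(ic50_t)
    z = ic50_0.ic50 if isinstance(ic50_0, IC50Estimate) else float(ic50_0)
    raw = percent_change_raw(t, z)
    return int(Decimal(repr(raw)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Plate I/O and the resistance table


PLATE_COLUMNS = ["cell_line", "drug", "week", "concentration_uM", "replicate", "od"]


def read_plates(path, od_blank: float = 0.05) -> list[DoseResponsePlate]:
    """Read a long-format plate TSV into DoseResponsePlate objects.

    Rows with concentration 0 are the untreated control wells.  An optional
    ``od_blank`` column overrides the blank OD per plate.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    plates = []
    for (cell_line, drug, week), grp in frame.groupby(
        ["cell_line", "drug", "week"], sort=False
    ):
        blank = float(grp["od_blank"].iloc[0]) if "od_blank" in grp else od_blank
        controls = grp[grp["concentration_uM"] == 0]["od"].tolist()
        dosed = grp[grp["concentration_uM"] > 0]
        pivot = dosed.pivot_table(
            index="concentration_uM", columns="replicate", values="od"
        ).sort_index()
        plates.append(
            DoseResponsePlate(
                cell_line=str(cell_line),
                drug=str(drug),
                week=int(week),
                concentrations=pivot.index.tolist(),
                od=pivot.to_numpy(),
                od_blank=blank,
                od_control=controls,
            )
        )
    return plates


def write_plates(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def resistance_table(
    estimates: dict[tuple[str, str, int], IC50Estimate | None],
    baseline_week: int = 0,
) -> pd.DataFrame:
    """Render fitted IC50s in the time-course layout of the study's table.

    ``estimates`` maps (cell_line, drug, week) to an IC50Estimate, or None
    for a missing measurement ("Not detected").  Each cell shows the IC50
    with the percent change versus the baseline week in parentheses; a
    censored baseline makes every later entry "Not significant".
    """
    cell_lines = sorted({k[0] for k in estimates})
    drugs = sorted({k[1] for k in estimates})
    weeks = sorted({k[2] for k in estimates})
    rows = []
    for cell_line in cell_lines:
        for week in weeks:
            row: dict[str, object] = {"cell_line": cell_line, "week": week}
            for drug in drugs:
                est = estimates.get((cell_line, drug, week), None)
                base = estimates.get((cell_line, drug, baseline_week), None)
                if est is None:
                    row[drug] = NOT_DETECTED
                elif week == baseline_week:
                    row[drug] = est.display()
                elif base is None:
                    row[drug] = NOT_DETECTED
                else:
                    change = percent_change(est, base)
                    if change == NOT_SIGNIFICANT:
                        row[drug] = NOT_SIGNIFICANT
                    else:
                        row[drug] = f"{est.display()} ({change}%)"
            rows.append(row)
    return pd.DataFrame(rows, columns=["cell_line", "week", *drugs])
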