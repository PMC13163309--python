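"""CCK-8 viability percentages and four-parameter-logistic IC50 fitting.

Viability of a treated well is the blank-corrected absorbance relative to the
untreated control:  100 * (A_sample - A_blank) / (A_control - A_blank), left
unclipped (values below 0 or above 100 carry fit-relevant information).
Technical replicates are averaged within each biological replicate; the
biological replicates enter the regression as separate points.

The dose–response model is the four-parameter logistic

    y(x) = bottom + (top - bottom) / (1 + (x / ic50) ** hill)

fitted by least squares with log10(ic50) as the free parameter for
conditioning, multi-start initialization (top/bottom from the data extremes,
ic50 seeded near the concentration closest to half-maximal response, hill
from {+1, -1} at several magnitudes), and r^2 = 1 - SSres/SStot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters for one compound."""

    bottom: float
    top: float
    hill: float
    ic50: float
    r_squared: float


def viability_percent(a_sample, a_control, a_blank):
    """Blank-corrected viability percentage (not clipped)."""
    a_sample = np.asarray(a_sample, dtype=float)
    span = a_control - a_blank
    if span == 0:
        raise ValidationError("control and blank absorbances coincide; "
                              "viability undefined")
    out = 100.0 * (a_sample - a_blank) / span
    return float(out) if out.ndim == 0 else out


def plate_viabilities(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well viability from a plate table, using each biological
    replicate's own mean control and mean blank absorbance."""
    required = {"compound", "conc_uM", "bio_rep", "absorbance", "well_type"}
    missing = required - set(plate.columns)
    if missing:
        raise ValidationError(f"plate table missing columns {sorted(missing)}")
    rows = []
    for bio, sub in plate.groupby("bio_rep"):
        ctrl = sub.loc[sub["well_type"] == "control", "absorbance"].mean()
        blank = sub.loc[sub["well_type"] == "blank", "absorbance"].mean()
        if np.isnan(ctrl) or np.isnan(blank):
            raise ValidationError(f"bio replicate {bio}: missing control or blank wells")
        samples = sub[sub["well_type"] == "sample"].copy()
        samples["viability"] = viability_percent(samples["absorbance"].to_numpy(),
                                                 ctrl, blank)
        rows.append(samples)
    return pd.concat(rows, ignore_index=True)


def aggregate_replicates(wells: pd.DataFrame) -> pd.DataFrame:
    """Mean viability per (compound, concentration, biological replicate).

    Technical replicates are averaged; biological replicates stay separate
    so each contributes its own point to the regression.
    """
    required = {"compound", "conc_uM", "bio_rep", "viability"}
    missing = required - set(wells.columns)
    if missing:
        raise ValidationError(f"wells table missing columns {sorted(missing)}")
    if len(wells) == 0:
        raise ValidationError("no wells to aggregate")
    out = (wells.groupby(["compound", "conc_uM", "bio_rep"], sort=True)["viability"]
           .mean().reset_index())
    return out


def _4pl(log_conc: np.ndarray, bottom: float, top: float, hill: float,
         log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_conc - log_ic50)))


def fit_4pl(concentrations, viabilities, max_starts: int = 8) -> DoseResponseFit:
    """Least-squares 4PL fit; raises FitError when no start converges."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("concentrations and viabilities must be equal-length 1-D")
    if np.any(x <= 0):
        raise ValidationError("concentrations must be positive")
    if len(np.unique(x)) < 4:
        raise ValidationError("at least 4 distinct concentrations are required")
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise FitError("constant viability input; hill slope and IC50 undetermined",
                       {"constant_value": float(y[0])})

    lx = np.log10(x)
    top0, bottom0 = float(y.max()), float(y.min())
    half = bottom0 + 0.5 * (top0 - bottom0)
    lic0 = float(lx[np.argmin(np.abs(y - half))])
    lic_grid = [lic0, float(np.median(lx))]
    starts = []
    for hill0 in (1.0, -1.0, 2.0, -2.0):
        for lic in lic_grid:
            starts.append((bottom0, top0, hill0, lic))
    starts = starts[:max_starts]

    def residuals(theta):
        return _4pl(lx, *theta) - y

    best = None
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("4PL fit failed to converge from any start",
                       {"n_starts": len(starts), "n_points": len(x)})
    bottom, top, hill, lic50 = best.x
    ssres = float(2.0 * best.cost)
    r2 = 1.0 - ssres / sstot
    # the logistic is symmetric under (hill, bottom<->top) sign flips; report
    # the orientation with top >= bottom
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(bottom=float(bottom), top=float(top), hill=float(hill),
                           ic50=float(10.0 ** lic50), r_squared=r2)


def fit_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Fit a 4PL curve per compound from a raw plate table.

    Returns a frame (compound, bottom, top, hill, ic50_uM, r2, n_points).
    Compounds whose fit fails are reported with NaN parameters.
    """
    wells = plate_viabilities(plate)
    agg = aggregate_replicates(wells)
    rows = []
    for compound, sub in agg.groupby("compound", sort=True):
        try:
            fit = fit_4pl(sub["conc_uM"].to_numpy(), sub["viability"].to_numpy())
            rows.append({"compound": compound, "bottom": fit.bottom, "top": fit.top,
                         "hill": fit.hill, "ic50_uM": fit.ic50, "r2": fit.r_squared,
                         "n_points": len(sub)})
        except FitError:
            rows.append({"compound": compound, "bottom": np.nan, "top": np.nan,
                         "hill": np.nan, "ic50_uM": np.nan, "r2": np.nan,
                         "n_points": len(sub)})
    return pd.DataFrame(rows)
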