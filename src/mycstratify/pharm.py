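"""Dose-response analysis and geometric volume models.

Chemogram viabilities are fit with the four-parameter logistic (4PL)

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

by bounded least squares over log10-dose with multi-start initialization.  The
reported IC50 is the inflection-dose parameter of the fit (relative IC50).
Vehicle wells (dose 0) are excluded from the log-domain residuals but anchor
the initial top-asymptote estimate.  Volume helpers cover spheroids
(V = 4/3 pi r^3) and caliper-measured xenograft tumors (V = length * width^2 / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .containers import DoseResponseSeries
from .outcomes import group_compare
from .simulate import four_param_logistic

__all__ = [
    "FourPLFit",
    "normalize_viability",
    "fit_dose_response_4pl",
    "ic50_group_summary",
    "spheroid_volume",
    "tumor_volume",
]


@dataclass
class FourPLFit:
    bottom: float | None
    top: float | None
    hill: float | None
    ic50: float | None
    rss: float | None
    converged: bool
    no_inhibition: bool = False

    def predict(self, doses):
        if not self.converged:
            raise RuntimeError("fit did not converge")
        return four_param_logistic(doses, self.bottom, self.top, self.hill, self.ic50)


def normalize_viability(raw, vehicle) -> np.ndarray:
    """Percent-of-control viability: 100 * raw / mean(vehicle wells)."""
    raw = np.asarray(raw, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    vmean = vehicle.mean()
    if not np.isfinite(vmean) or vmean <= 0:
        raise ValueError("vehicle mean signal must be positive")
    return 100.0 * raw / vmean


def _residuals(params, log10_d, v, fix_bottom, fix_top):
    i = 0
    if fix_bottom is None:
        bottom = params[i]; i += 1
    else:
        bottom = fix_bottom
    if fix_top is None:
        top = params[i]; i += 1
    else:
        top = fix_top
    hill, log10_ic50 = params[i], params[i + 1]
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_d - log10_ic50)))
    return pred - v


def fit_dose_response_4pl(
    series: DoseResponseSeries,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> FourPLFit:
    """Fit the 4PL model to one chemogram.

    Requires at least 4 distinct positive doses.  Parameters are constrained
    to 0 <= bottom <= top <= 120, hill in [0.1, 10] and ic50 in
    [1e-3, 1e3] uM; several log10-IC50/hill starting points are tried and the
    lowest-RSS converged solution is kept.  A series whose viability never
    drops (flat or rising with dose) is flagged ``no_inhibition`` and gets no
    IC50.
    """
    df = series.data
    pos = df[df["dose_uM"] > 0]
    doses = pos["dose_uM"].to_numpy(dtype=float)
    viab = pos["viability_pct"].to_numpy(dtype=float)
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct positive doses")

    vehicle = df[df["dose_uM"] == 0]["viability_pct"]
    top0 = float(vehicle.mean()) if len(vehicle) else float(viab.max())

    # no-inhibition screen: compare means at the lowest vs highest dose tiers
    per_dose = pos.groupby("dose_uM")["viability_pct"].mean().sort_index()
    k = max(1, len(per_dose) // 3)
    drop = per_dose.iloc[:k].mean() - per_dose.iloc[-k:].mean()
    if drop < 5.0:
        return FourPLFit(bottom=None, top=None, hill=None, ic50=None, rss=None,
                         converged=False, no_inhibition=True)

    log10_d = np.log10(doses)
    lower, upper, x0_base = [], [], []
    if fix_bottom is None:
        lower.append(0.0); upper.append(120.0); x0_base.append(max(float(viab.min()), 0.0))
    if fix_top is None:
        lower.append(0.0); upper.append(120.0); x0_base.append(min(max(top0, 1.0), 120.0))
    lower += [0.1, -3.0]
    upper += [10.0, 3.0]

    best = None
    for hill0 in (0.5, 1.0, 2.0):
        for lic0 in (-1.0, 0.0, 0.5, 1.0, 1.6, 2.3):
            x0 = np.array(x0_base + [hill0, lic0])
            try:
                res = least_squares(
                    _residuals, x0, bounds=(lower, upper),
                    args=(log10_d, viab, fix_bottom, fix_top),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except ValueError:
                continue
            rss = float(np.sum(res.fun ** 2))
            if res.success and (best is None or rss < best[0]):
                best = (rss, res.x)

    if best is None:
        return FourPLFit(bottom=None, top=None, hill=None, ic50=None, rss=None,
                         converged=False)
    rss, x = best
    i = 0
    if fix_bottom is None:
        bottom = float(x[i]); i += 1
    else:
        bottom = float(fix_bottom)
    if fix_top is None:
        top = float(x[i]); i += 1
    else:
        top = float(fix_top)
    hill = float(x[i])
    ic50 = float(10.0 ** x[i + 1])
    if bottom > top:  # boundary solutions can invert the asymptotes
        return FourPLFit(bottom=bottom, top=top, hill=hill, ic50=None, rss=rss,
                         converged=False)
    return FourPLFit(bottom=bottom, top=top, hill=hill, ic50=ic50, rss=rss,
                     converged=True)


def ic50_group_summary(fits: dict, labels: dict) -> pd.DataFrame:
    """Per-group IC50 mean +/- SEM with a Welch comparison between groups.

    ``fits`` maps cell_id -> FourPLFit; ``labels`` maps cell_id -> group.
    Returns a DataFrame indexed by group with columns mean, sem, n; the Welch
    p-value (two groups only) is stored in ``.attrs['welch_pvalue']``.
    """
    rows = []
    for cell_id, fit in fits.items():
        if fit.converged and fit.ic50 is not None:
            rows.append({"cell_id": cell_id, "group": labels[cell_id], "ic50": fit.ic50})
    df = pd.DataFrame(rows)
    present_groups = set(labels.values())
    fitted_groups = set(df["group"]) if len(df) else set()
    missing = present_groups - fitted_groups
    if missing:
        raise ValueError(f"no converged fits in group(s): {sorted(missing)}")

    grouped = df.groupby("group")["ic50"]
    out = grouped.agg(mean="mean", n="count")
    out["sem"] = grouped.agg(
        lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else np.nan
    )
    out = out.sort_index()
    if len(out) == 2:
        g1, g2 = out.index
        a = df[df["group"] == g1]["ic50"]
        b = df[df["group"] == g2]["ic50"]
        if len(a) >= 2 and len(b) >= 2:
            _, p = group_compare(a, b, method="welch")
            out.attrs["welch_pvalue"] = p
    return out


def spheroid_volume(radius_um) -> np.ndarray | float:
    """Spheroid volume V = 4/3 pi r^3 (um^3)."""
    r = np.asarray(radius_um, dtype=float)
    if (r < 0).any():
        raise ValueError("radius must be nonnegative")
    v = 4.0 / 3.0 * np.pi * r ** 3
    return float(v) if v.ndim == 0 else v


def tumor_volume(length_mm, width_mm, formula: str = "standard") -> np.ndarray | float:
    """Caliper tumor volume (mm^3).

    ``standard``: V = length * width^2 / 2, the usual ellipsoid approximation.
    ``as-printed``: V = (length / width^2) / 2, a dimensionally inconsistent
    variant kept only as an escape hatch for byte-level reproduction of
    legacy spreadsheets.
    """
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if (length < 0).any() or (width < 0).any():
        raise ValueError("dimensions must be nonnegative")
    if formula == "standard":
        v = length * width ** 2 / 2.0
    elif formula == "as-printed":
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (length / width ** 2) / 2.0
    else:
        raise ValueError("formula must be 'standard' or 'as-printed'")
    return float(v) if np.ndim(v) == 0 else v
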