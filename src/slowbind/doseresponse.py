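"""Dose–response analysis: apparent IC50 fits, in vivo conversion from
band intensities with knockout background correction, and activity-based
probe (ABP) competition quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoseResponseTable",
    "DoseResponseFit",
    "BandTable",
    "fit_ic50",
    "conversion_from_bands",
    "correct_background",
    "abp_percent_inhibition",
    "abp_inhibition_table",
]


@dataclass
class DoseResponseTable:
    """(concentration, response) rows; the concentration unit is recorded."""

    concentration: np.ndarray
    response: np.ndarray
    unit: str = "nM"
    response_kind: str = "relative_activity"  # or conversion_percent, band_intensity
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must match")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(self.response < 0):
            raise ValueError("responses must be >= 0")


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit; ``flag`` marks out-of-range results.

    flag is None for a converged in-range fit, "above_range" when the
    transition is not reached by the highest tested concentration (report
    as "IC50 > max tested"), "below_range" for the converse.
    """

    ic50: Optional[float]
    hill: Optional[float]
    top: float
    bottom: float
    se_ic50: float = np.nan
    se_hill: float = np.nan
    se_top: float = np.nan
    se_bottom: float = np.nan
    rss: float = np.nan
    converged: bool = True
    flag: Optional[str] = None
    unit: str = "nM"


def _logistic4(x, bottom, top, ic50, hill):
    # at x = 0 the response is exactly `top` (no pseudo-log substitution)
    with np.errstate(divide="ignore"):
        r = np.where(x > 0, (x / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + r)


def fit_ic50(table: DoseResponseTable, fix_bottom: Optional[float] = None,
             fix_top: Optional[float] = None, fix_hill: Optional[float] = None,
             range_margin: float = 0.15) -> DoseResponseFit:
    """Fit the four-parameter logistic y = bottom + (top−bottom)/(1+(x/IC50)^h).

    Before fitting, the transition is checked to be bracketed: if all
    responses sit within ``range_margin`` of the top (resp. bottom) plateau
    the result is flagged "above_range" ("below_range") instead of
    extrapolating a number.
    """
    x = table.concentration
    y = table.response
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 concentrations for an IC50 fit")
    # plateau anchors: response at the lowest tested concentrations is the top
    order = np.argsort(x)
    top0 = float(np.mean(y[order[:2]])) if fix_top is None else fix_top
    bottom0 = float(y.min()) if fix_bottom is None else fix_bottom
    # a transition smaller than the margin cannot be fitted: decide which
    # plateau the data sit on relative to the (known or presumed) top
    if np.ptp(y) <= range_margin * max(top0, 1e-30):
        flag = "above_range" if float(np.mean(y)) >= 0.5 * top0 else "below_range"
        return DoseResponseFit(ic50=None, hill=None, top=top0, bottom=bottom0,
                               converged=False, flag=flag, unit=table.unit)
    if np.all(y >= (1.0 - range_margin) * top0):
        return DoseResponseFit(ic50=None, hill=None, top=top0, bottom=bottom0,
                               converged=False, flag="above_range", unit=table.unit)
    if np.all(y <= bottom0 + range_margin * top0) and float(np.max(y)) < 0.5 * top0:
        return DoseResponseFit(ic50=None, hill=None, top=top0, bottom=bottom0,
                               converged=False, flag="below_range", unit=table.unit)

    half = bottom0 + 0.5 * (top0 - bottom0)
    pos = x > 0
    ic50_0 = float(x[pos][np.argmin(np.abs(y[pos] - half))])

    free, p0, lb, ub = [], [], [], []
    fixed = {}
    for name, val, start, lo, hi in (
        ("bottom", fix_bottom, bottom0, -np.inf, np.inf),
        ("top", fix_top, top0, -np.inf, np.inf),
        ("ic50", None, ic50_0, 1e-12, np.inf),
        ("hill", fix_hill, 1.0, 1e-3, 20.0),
    ):
        if val is None:
            free.append(name)
            p0.append(start)
            lb.append(lo)
            ub.append(hi)
        else:
            fixed[name] = val

    def model(xx, *params):
        kw = dict(zip(free, params))
        kw.update(fixed)
        return _logistic4(xx, kw["bottom"], kw["top"], kw["ic50"], kw["hill"])

    converged = True
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=(lb, ub),
                                        maxfev=50000, xtol=1e-14, ftol=1e-14)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    except RuntimeError:
        converged = False
        popt = np.asarray(p0)
        se = np.full(len(p0), np.nan)
    resid = y - model(x, *popt)
    params = dict(zip(free, popt))
    params.update(fixed)
    ses = dict(zip(free, se))
    return DoseResponseFit(
        ic50=float(params["ic50"]), hill=float(params["hill"]),
        top=float(params["top"]), bottom=float(params["bottom"]),
        se_ic50=float(ses.get("ic50", 0.0)), se_hill=float(ses.get("hill", 0.0)),
        se_top=float(ses.get("top", 0.0)), se_bottom=float(ses.get("bottom", 0.0)),
        rss=float(resid @ resid), converged=converged, flag=None, unit=table.unit,
    )


@dataclass
class BandTable:
    """Gel/blot band intensities, one row per lane.

    Columns: condition (label; the vehicle lane is 'DMSO' or inhibitor 0),
    inhibitor concentration, substrate and product band intensities (AU).
    """

    lanes: pd.DataFrame
    unit: str = "nM"
    log: list = field(default_factory=list)

    REQUIRED = ("condition", "inhibitor", "substrate_au", "product_au")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.lanes.columns]
        if missing:
            raise ValueError(f"band table missing columns: {missing}")
        for c in ("substrate_au", "product_au"):
            if (self.lanes[c] < 0).any():
                raise ValueError(f"negative intensities in {c}")


def conversion_from_bands(bands: BandTable) -> DoseResponseTable:
    """Substrate conversion per lane, in percent of the vehicle control.

    conversion = product/(product + substrate); lanes with zero total
    intensity are excluded with a warning. The vehicle lane (condition
    'DMSO' or inhibitor = 0) defines 100%.
    """
    df = bands.lanes.copy()
    total = df["product_au"] + df["substrate_au"]
    bad = total <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} zero-intensity lane(s)", stacklevel=2)
        df = df[~bad]
        total = total[~bad]
    conv = df["product_au"] / total
    vehicle = (df["condition"].astype(str).str.upper() == "DMSO") | (df["inhibitor"] == 0)
    if not vehicle.any():
        raise ValueError("no vehicle (DMSO / zero-inhibitor) lane present")
    conv0 = float(conv[vehicle].mean())
    if conv0 <= 0:
        raise ValueError("vehicle conversion is zero; cannot normalize")
    rel = 100.0 * conv / conv0
    return DoseResponseTable(
        concentration=df["inhibitor"].to_numpy(dtype=float),
        response=rel.to_numpy(dtype=float),
        unit=bands.unit, response_kind="conversion_percent",
        provenance={"vehicle_conversion": conv0,
                    "lanes": df["condition"].tolist()},
    )


def correct_background(bands: BandTable, knockout: BandTable) -> BandTable:
    """Subtract knockout-background product intensity, matched by concentration.

    corrected product = max(0, observed − matched knockout product). The
    correction applied to each lane is recorded in the returned table's log.
    """
    ko = knockout.lanes.set_index("inhibitor")["product_au"]
    df = bands.lanes.copy()
    unmatched = sorted(set(df["inhibitor"]) - set(ko.index))
    if unmatched:
        raise ValueError(f"no knockout lane matching inhibitor concentration(s): {unmatched}")
    log = []
    corrected = []
    for _, row in df.iterrows():
        bg = float(np.atleast_1d(ko.loc[row["inhibitor"]]).mean())
        new = max(0.0, row["product_au"] - bg)
        if bg >= row["product_au"] and row["product_au"] > 0:
            warnings.warn(
                f"knockout background ({bg:g}) >= observed product "
                f"({row['product_au']:g}) in lane {row['condition']}; clamped to 0",
                stacklevel=2,
            )
        log.append({"condition": row["condition"], "background": bg,
                    "before": float(row["product_au"]), "after": new})
        corrected.append(new)
    df["product_au"] = corrected
    return BandTable(lanes=df, unit=bands.unit, log=log)


def abp_percent_inhibition(band, dmso_band):
    """Percent inhibition from ABP competition: 100·(1 − band/DMSO band).

    Accepts scalars or arrays; results are clamped to [0, 100].
    """
    band = np.asarray(band, dtype=float)
    dmso = np.asarray(dmso_band, dtype=float)
    if np.any(dmso <= 0):
        raise ValueError("DMSO control band intensity must be > 0")
    out = np.clip(100.0 * (1.0 - band / dmso), 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def abp_inhibition_table(df: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-style percent-inhibition matrix from long-format ABP data.

    Expects columns compound, concentration, enzyme, band_au, dmso_au;
    returns a pivoted (compound, concentration) × enzyme table.
    """
    required = {"compound", "concentration", "enzyme", "band_au", "dmso_au"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ABP table missing columns: {sorted(missing)}")
    out = df.copy()
    out["percent_inhibition"] = abp_percent_inhibition(
        out["band_au"].to_numpy(), out["dmso_au"].to_numpy())
    return out.pivot_table(index=["compound", "concentration"], columns="enzyme",
                           values="percent_inhibition")
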