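"""Nonlinear fitting of biphasic progress curves.

Extracts the initial rate vi, steady-state rate vs and the onset rate kobs
from signal(t) = offset + vs·t + (vi − vs)/kobs·(1 − e^(−kobs·t)).
A nested extra-sum-of-squares F-test against the straight line guards
against reporting spurious kobs from curves with no detectable curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .schemes import ProgressCurve
from .simulate import product_progress

__all__ = ["ProgressFit", "fit_progress_curve", "fit_linear_rate", "batch_fit"]

KOBS_BOUNDS = (1e-5, 1e2)  # min⁻¹; outside this window Eq-1 curvature is unidentifiable


@dataclass
class ProgressFit:
    """Result of fitting the biphasic law to one progress curve."""

    vi: float  # AU/min
    vs: float  # AU/min
    kobs: Optional[float]  # min⁻¹; None when the curve is statistically linear
    offset: float  # AU
    se_vi: float = np.nan
    se_vs: float = np.nan
    se_kobs: float = np.nan
    se_offset: float = np.nan
    rss: float = np.nan
    n_points: int = 0
    converged: bool = True
    linear: bool = False
    p_linearity: float = np.nan
    curve_id: str = ""
    inhibitor_nM: float = np.nan


def fit_linear_rate(curve: ProgressCurve) -> tuple[float, float]:
    """OLS slope of signal vs time (AU·min⁻¹) with its standard error."""
    if curve.n_points < 3:
        raise ValueError("need at least 3 points for a linear rate")
    res = stats.linregress(curve.time_min, curve.signal_au)
    return float(res.slope), float(res.stderr)


def _initial_guess(t, y):
    """Curvature-aware starting values (vi, vs, kobs, offset).

    vi from the slope of the first 15% of points, vs from the last 25%,
    kobs ≈ 3/t_mid with t_mid the time at half the transient amplitude.
    """
    n = t.size
    n_head = max(3, int(math.ceil(0.15 * n)))
    n_tail = max(3, int(math.ceil(0.25 * n)))
    vi0 = np.polyfit(t[:n_head], y[:n_head], 1)[0]
    vs0 = np.polyfit(t[-n_tail:], y[-n_tail:], 1)[0]
    off0 = float(y[0])
    transient = y - off0 - vs0 * t
    amp = transient[-1]
    kobs0 = 3.0 / t[-1]
    if abs(amp) > 0:
        above = np.nonzero(np.abs(transient) >= 0.5 * abs(amp))[0]
        if above.size and t[above[0]] > 0:
            kobs0 = 3.0 / t[above[0]]
    kobs0 = float(np.clip(kobs0, *KOBS_BOUNDS))
    return float(vi0), float(vs0), kobs0, off0


def _fit_line(t, y):
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_progress_curve(curve: ProgressCurve, fix_offset: Optional[float] = None,
                       alpha_linearity: float = 0.05,
                       weighting: Optional[str] = None) -> ProgressFit:
    """Fit the biphasic progress law to one curve.

    Parameters
    ----------
    curve
        The time course to fit (≥ 6 points recommended).
    fix_offset
        Fix the additive baseline to this value instead of fitting it.
    alpha_linearity
        Significance level of the extra-sum-of-squares F-test against the
        straight-line nested model; if the biphasic model is not
        significantly better, the result is flagged ``linear`` and kobs is
        withheld.
    weighting
        ``None`` (default) for unweighted least squares; ``"relative"``
        weights residuals by 1/signal, appropriate when measurement noise
        is proportional to the signal (fluorescence plate readers).
    """
    t = curve.time_min
    y = curve.signal_au
    n = t.size
    sigma = None
    if weighting == "relative":
        sigma = np.maximum(np.abs(y), 0.05 * np.max(np.abs(y)) + 1e-300)
    elif weighting is not None:
        raise ValueError(f"unknown weighting {weighting!r}")
    vi0, vs0, kobs0, off0 = _initial_guess(t, y)
    free_offset = fix_offset is None
    if not free_offset:
        off0 = fix_offset

    if free_offset:
        def model(tt, vi, vs, kobs, off):
            return off + product_progress(tt, vi, vs, kobs)
        p0 = [max(vi0, 0.0), max(vs0, 0.0), kobs0, off0]
        lb = [0.0, 0.0, KOBS_BOUNDS[0], -np.inf]
        ub = [np.inf, np.inf, KOBS_BOUNDS[1], np.inf]
    else:
        def model(tt, vi, vs, kobs):
            return fix_offset + product_progress(tt, vi, vs, kobs)
        p0 = [max(vi0, 0.0), max(vs0, 0.0), kobs0]
        lb = [0.0, 0.0, KOBS_BOUNDS[0]]
        ub = [np.inf, np.inf, KOBS_BOUNDS[1]]
    n_par = len(p0)

    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=(lb, ub), maxfev=20000, sigma=sigma,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    except (RuntimeError, optimize.OptimizeWarning):
        converged = False
        popt = np.asarray(p0, dtype=float)
        se = np.full(n_par, np.nan)

    resid = y - model(t, *popt)
    rss = float(resid @ resid)

    # linearity guard: nested F-test vs straight line
    (b0, b1), rss_lin = _fit_line(t, y)
    linear = False
    p_lin = np.nan
    scale = max(float(np.ptp(y)), 1.0)
    tiny = n * (1e-10 * scale) ** 2
    if converged:
        if rss_lin <= tiny:
            # the data are a line to numerical precision
            linear = True
            p_lin = 1.0
        else:
            df1 = n_par - 2
            df2 = n - n_par
            if df2 > 0 and rss > 0:
                F = ((rss_lin - rss) / df1) / (rss / df2)
                p_lin = float(stats.f.sf(max(F, 0.0), df1, df2))
                linear = p_lin >= alpha_linearity
            elif rss <= tiny:
                linear = False  # exact biphasic data: curvature is real
                p_lin = 0.0

    if linear:
        se_line = math.sqrt(rss_lin / (n - 2) / float(np.sum((t - t.mean()) ** 2))) if n > 2 else np.nan
        return ProgressFit(vi=float(b1), vs=float(b1), kobs=None,
                           offset=float(b0), se_vi=se_line, se_vs=se_line,
                           rss=rss_lin, n_points=n, converged=converged,
                           linear=True, p_linearity=p_lin,
                           curve_id=curve.curve_id, inhibitor_nM=curve.inhibitor_nM)

    vi, vs, kobs = popt[0], popt[1], popt[2]
    offset = popt[3] if free_offset else fix_offset
    return ProgressFit(
        vi=float(vi), vs=float(vs), kobs=float(kobs), offset=float(offset),
        se_vi=float(se[0]), se_vs=float(se[1]), se_kobs=float(se[2]),
        se_offset=float(se[3]) if free_offset else 0.0,
        rss=rss, n_points=n, converged=converged, linear=False,
        p_linearity=p_lin, curve_id=curve.curve_id,
        inhibitor_nM=curve.inhibitor_nM,
    )


def batch_fit(curves: Sequence[ProgressCurve], fix_offset: Optional[float] = None,
              alpha_linearity: float = 0.05, weighting: Optional[str] = None):
    """Fit every curve of a shared-design family; assemble the kobs profile.

    Returns ``(KobsProfile, fits)`` where the profile contains one
    (inhibitor, kobs, se) entry per converged, detectably-curved fit,
    sorted by inhibitor concentration, and ``fits`` is the full per-curve
    ledger including flagged/excluded entries.
    """
    from .rates import KobsProfile  # local import to avoid a cycle

    if not curves:
        raise ValueError("no curves given")
    S_ref, E_ref = curves[0].substrate_uM, curves[0].enzyme_nM
    for c in curves[1:]:
        if not (math.isclose(c.substrate_uM, S_ref, rel_tol=1e-9)
                and math.isclose(c.enzyme_nM, E_ref, rel_tol=1e-9)):
            raise ValueError(
                "curves must share the assay design (substrate, enzyme) and vary only [I]"
            )
    fits = [fit_progress_curve(c, fix_offset=fix_offset,
                               alpha_linearity=alpha_linearity,
                               weighting=weighting) for c in curves]
    usable, excluded = [], []
    for f in fits:
        if not f.converged:
            excluded.append((f.curve_id, "non-convergent fit"))
        elif f.linear or f.kobs is None:
            excluded.append((f.curve_id, "no detectable curvature"))
        else:
            usable.append(f)
    usable.sort(key=lambda f: f.inhibitor_nM)
    profile = KobsProfile(
        inhibitor_nM=np.array([f.inhibitor_nM for f in usable]),
        kobs=np.array([f.kobs for f in usable]),
        se=np.array([f.se_kobs for f in usable]),
        provenance={"excluded": excluded, "n_curves": len(curves),
                    "substrate_uM": S_ref, "enzyme_nM": E_ref},
    )
    return profile, fits
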