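"""Mechanism-level constants from the kobs–[I] dependence.

A linear dependence kobs = koff + kon·[I] is the signature of one-step
slow binding (E + I ↔ EI); its slope and intercept give kon and koff and
hence the apparent inhibitory constant Kiapp = koff/kon. A hyperbolic
(saturating) dependence kobs = k6 + k5·[I]/(Ki1 + [I]) indicates the
two-step mechanism with an EI ↔ EI* isomerization. Model choice is by
corrected AIC with the linear model as the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .progress import ProgressFit

__all__ = [
    "KobsProfile",
    "SlowBindingFit",
    "KobsModelComparison",
    "ViIndependenceResult",
    "aicc",
    "fit_kobs_linear",
    "fit_kobs_hyperbolic",
    "compare_kobs_models",
    "test_vi_independence",
]


def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected Akaike information criterion for LSQ fits.

    k counts the fitted parameters plus the residual variance.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class KobsProfile:
    """kobs as a function of inhibitor concentration, with provenance."""

    inhibitor_nM: np.ndarray
    kobs: np.ndarray
    se: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inhibitor_nM = np.asarray(self.inhibitor_nM, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if self.inhibitor_nM.shape != self.kobs.shape:
            raise ValueError("inhibitor and kobs vectors must match")
        if np.any(self.inhibitor_nM < 0):
            raise ValueError("inhibitor concentrations must be >= 0")

    @property
    def n(self) -> int:
        return self.inhibitor_nM.size


@dataclass
class SlowBindingFit:
    """Rate constants extracted from a kobs profile.

    ``Kiapp = koff/kon`` exactly as computed; a negative or zero slope, or
    an intercept negative beyond 2 SE, leaves Kiapp unset with a flag.
    """

    model: str  # "one_step_linear" | "two_step_hyperbolic"
    n: int
    rss: float
    aicc: float
    kon: Optional[float] = None  # nM⁻¹·min⁻¹
    koff: Optional[float] = None  # min⁻¹
    Kiapp: Optional[float] = None  # nM
    se_kon: float = np.nan
    se_koff: float = np.nan
    se_Kiapp: float = np.nan
    k5: Optional[float] = None
    k6: Optional[float] = None
    Ki1: Optional[float] = None
    se_k5: float = np.nan
    se_k6: float = np.nan
    se_Ki1: float = np.nan
    converged: bool = True
    flags: tuple = ()
    data_key: Optional[tuple] = None


def _data_key(profile: KobsProfile) -> tuple:
    return (tuple(np.round(profile.inhibitor_nM, 12)),
            tuple(np.round(profile.kobs, 15)))


def fit_kobs_linear(profile: KobsProfile, weighted: bool = False) -> SlowBindingFit:
    """OLS (or 1/SE²-weighted WLS) line through the kobs profile.

    kon = slope, koff = intercept, Kiapp = koff/kon with its SE from the
    delta method using the full slope–intercept covariance.
    """
    if profile.n < 3 or np.unique(profile.inhibitor_nM).size < 3:
        raise ValueError("need at least 3 distinct inhibitor concentrations")
    if np.ptp(profile.inhibitor_nM) == 0:
        raise ValueError("singular design: all inhibitor concentrations equal")
    X = sm.add_constant(profile.inhibitor_nM)
    if weighted:
        if profile.se is None or np.any(~np.isfinite(profile.se)) or np.any(profile.se <= 0):
            raise ValueError("weighted fit requires finite positive kobs standard errors")
        res = sm.WLS(profile.kobs, X, weights=1.0 / profile.se**2).fit()
    else:
        res = sm.OLS(profile.kobs, X).fit()
    koff, kon = res.params
    se_koff, se_kon = res.bse
    cov = res.cov_params()
    rss = float(res.ssr)
    flags = []
    Kiapp = se_Kiapp = None
    if kon <= 0 or kon * np.ptp(profile.inhibitor_nM) <= 1e-9 * np.max(np.abs(profile.kobs)):
        flags.append("non-positive or negligible slope: Kiapp undefined")
    elif koff < -2 * se_koff:
        flags.append("negative intercept beyond 2 SE: Kiapp withheld")
    else:
        Kiapp = koff / kon
        grad = np.array([1.0 / kon, -koff / kon**2])
        var = float(grad @ np.asarray(cov) @ grad)
        se_Kiapp = float(np.sqrt(max(var, 0.0)))
    return SlowBindingFit(
        model="one_step_linear", n=profile.n, rss=rss,
        aicc=aicc(rss, profile.n, 2),
        kon=float(kon), koff=float(koff),
        Kiapp=None if Kiapp is None else float(Kiapp),
        se_kon=float(se_kon), se_koff=float(se_koff),
        se_Kiapp=np.nan if se_Kiapp is None else se_Kiapp,
        flags=tuple(flags), data_key=_data_key(profile),
    )


def fit_kobs_hyperbolic(profile: KobsProfile) -> SlowBindingFit:
    """Fit the two-step diagnostic kobs = k6 + k5·I/(Ki1 + I)."""
    if profile.n < 5:
        raise ValueError("need at least 5 concentrations for the hyperbolic model")
    I, k = profile.inhibitor_nM, profile.kobs

    def model(x, k6, k5, Ki1):
        return k6 + k5 * x / (Ki1 + x)

    k6_0 = max(float(k.min()), 1e-9)
    k5_0 = max(float(k.max() - k.min()), 1e-9)
    Ki1_0 = float(np.median(I[I > 0])) if np.any(I > 0) else 1.0
    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            model, I, k, p0=[k6_0, k5_0, Ki1_0],
            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
            x_scale=[max(k6_0, 1e-6), max(k5_0, 1e-6), max(Ki1_0, 1e-3)],
            maxfev=50000, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    except RuntimeError:
        converged = False
        popt = np.array([k6_0, k5_0, Ki1_0])
        se = np.full(3, np.nan)
    resid = k - model(I, *popt)
    rss = float(resid @ resid)
    return SlowBindingFit(
        model="two_step_hyperbolic", n=profile.n, rss=rss,
        aicc=aicc(rss, profile.n, 3),
        k6=float(popt[0]), k5=float(popt[1]), Ki1=float(popt[2]),
        se_k6=float(se[0]), se_k5=float(se[1]), se_Ki1=float(se[2]),
        converged=converged,
        flags=() if converged else ("non-convergent hyperbolic fit",),
        data_key=_data_key(profile),
    )


@dataclass
class KobsModelComparison:
    """Verdict of the one-step vs two-step comparison on one profile."""

    selected: str
    delta_aicc: float  # AICc(linear) − AICc(hyperbolic); positive favors hyperbolic
    aicc_linear: float
    aicc_hyperbolic: float
    rule: str = "hyperbolic requires ΔAICc ≥ 2; ties → linear"


def compare_kobs_models(linear: SlowBindingFit, hyperbolic: SlowBindingFit) -> KobsModelComparison:
    """Select one- vs two-step by AICc; the simpler linear model wins ties.

    The hyperbolic (two-step) model is preferred only when its AICc beats
    the linear model's by at least 2.
    """
    if linear.data_key != hyperbolic.data_key:
        raise ValueError("model comparison requires fits of the identical profile")
    delta = linear.aicc - hyperbolic.aicc
    kmax = max(abs(k) for k in linear.data_key[1]) if linear.data_key[1] else 1.0
    rss_floor = linear.n * (1e-7 * kmax + 1e-300) ** 2
    selected = "two_step_hyperbolic" if (
        hyperbolic.converged and linear.rss > rss_floor and delta >= 2.0
    ) else "one_step_linear"
    return KobsModelComparison(selected=selected, delta_aicc=float(delta),
                               aicc_linear=linear.aicc, aicc_hyperbolic=hyperbolic.aicc)


@dataclass
class ViIndependenceResult:
    slope: float
    se_slope: float
    p_value: float
    independent: bool
    n: int


def test_vi_independence(fits: Sequence[ProgressFit], alpha: float = 0.05) -> ViIndependenceResult:
    """Test whether the initial rate vi depends on inhibitor concentration.

    For one-step slow binding vi is independent of [I]; a significant OLS
    slope of vi against [I] indicates an instantaneous binding component.
    """
    pts = [(f.inhibitor_nM, f.vi) for f in fits
           if f.converged and np.isfinite(f.vi) and np.isfinite(f.inhibitor_nM)]
    if len(pts) < 3:
        raise ValueError("need at least 3 (inhibitor, vi) pairs")
    I = np.array([p[0] for p in pts])
    vi = np.array([p[1] for p in pts])
    if np.unique(I).size < 3:
        raise ValueError("need at least 3 distinct inhibitor concentrations")
    res = stats.linregress(I, vi)
    slope, se = float(res.slope), float(res.stderr)
    if np.allclose(vi, vi[0], rtol=1e-12, atol=1e-12 * max(abs(vi[0]), 1.0)):
        # exactly constant vi: trivially independent (t statistic is 0/0)
        return ViIndependenceResult(0.0, 0.0, 1.0, True, len(pts))
    p = float(res.pvalue)
    return ViIndependenceResult(slope, se, p, p >= alpha, len(pts))
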