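"""Inhibition-modality inference from steady-state rate grids.

Steady-state rates vs measured over a substrate × inhibitor grid are
globally fitted to the four classical reversible-inhibition models
(shared Vmax, Km, Ki and, for mixed, α across all curves):

* competitive:     v = Vmax·S / (Km·(1 + I/Ki) + S)
* noncompetitive:  v = Vmax·S / ((Km + S)·(1 + I/Ki))
* uncompetitive:   v = Vmax·S / (Km + S·(1 + I/Ki))
* mixed:           v = Vmax·S / (Km·(1 + I/Ki) + S·(1 + I/(α·Ki)))

Selection is by corrected AIC (the extra-parameter mixed model must beat
the best three-parameter model by ΔAICc ≥ 2), with nested extra-sum-of-
squares F-tests reported as secondary evidence. The module also converts
apparent constants to the true, substrate-independent Ki and predicts
steady-state IC50 values from a mechanistic scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .rates import aicc
from .schemes import KineticScheme, Modality
from .simulate import steady_rate

__all__ = [
    "MichaelisGrid",
    "ModelFit",
    "ModalityResult",
    "global_fit_modality",
    "ki_from_kiapp",
    "ic50_from_scheme",
]

MODEL_NAMES = ("competitive", "noncompetitive", "uncompetitive", "mixed")


@dataclass
class MichaelisGrid:
    """Steady-state rates over substrate × inhibitor concentrations."""

    substrate_uM: np.ndarray
    inhibitor_nM: np.ndarray
    rate: np.ndarray  # same units throughout (e.g. nM/min or AU/min)
    sd: Optional[np.ndarray] = None
    enzyme_nM: float = np.nan

    def __post_init__(self):
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.inhibitor_nM = np.asarray(self.inhibitor_nM, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if not (self.substrate_uM.shape == self.inhibitor_nM.shape == self.rate.shape):
            raise ValueError("substrate, inhibitor and rate vectors must match")
        if np.unique(self.substrate_uM).size < 4:
            raise ValueError("need at least 4 substrate levels")
        ilev = np.unique(self.inhibitor_nM)
        if ilev.size < 3 or 0.0 not in ilev:
            raise ValueError("need at least 3 inhibitor levels including 0")
        if np.any(self.rate < 0):
            raise ValueError("rates must be >= 0")


def _model_fn(name: str):
    if name == "competitive":
        def f(X, Vmax, Km, Ki):
            S, I = X
            return Vmax * S / (Km * (1 + I / Ki) + S)
    elif name == "noncompetitive":
        def f(X, Vmax, Km, Ki):
            S, I = X
            return Vmax * S / ((Km + S) * (1 + I / Ki))
    elif name == "uncompetitive":
        def f(X, Vmax, Km, Ki):
            S, I = X
            return Vmax * S / (Km + S * (1 + I / Ki))
    else:  # mixed, α on log10 scale to avoid boundary pathologies
        def f(X, Vmax, Km, Ki, log10_alpha):
            S, I = X
            a = 10.0 ** log10_alpha
            return Vmax * S / (Km * (1 + I / Ki) + S * (1 + I / (a * Ki)))
    return f


@dataclass
class ModelFit:
    name: str
    params: dict
    se: dict
    rss: float
    aicc: float
    converged: bool


@dataclass
class ModalityResult:
    """Per-model fits, the selected modality and its true Ki."""

    fits: dict
    selected: str
    Ki_true: float  # nM; the selected model's Ki
    selection: dict = field(default_factory=dict)
    notes: tuple = ()


def _fit_one(name: str, S, I, v, weights=None) -> ModelFit:
    f = _model_fn(name)
    Vmax0 = 1.2 * float(v.max())
    Km0 = float(np.median(np.unique(S)))
    Inz = I[I > 0]
    Ki0 = float(np.median(Inz)) if Inz.size else 100.0
    p0 = [Vmax0, Km0, Ki0]
    lb = [1e-12, 1e-9, 1e-9]
    ub = [np.inf, np.inf, np.inf]
    names = ["Vmax", "Km", "Ki"]
    if name == "mixed":
        p0.append(0.0)
        lb.append(-2.0)
        ub.append(2.0)
        names.append("log10_alpha")
    sigma = None
    if weights is not None:
        sigma = 1.0 / np.sqrt(weights)
    try:
        popt, pcov = optimize.curve_fit(
            f, (S, I), v, p0=p0, sigma=sigma, bounds=(lb, ub),
            maxfev=50000, xtol=1e-14, ftol=1e-14,
        )
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        converged = True
    except RuntimeError:
        popt = np.asarray(p0)
        se = np.full(len(p0), np.nan)
        converged = False
    resid = v - f((S, I), *popt)
    rss = float(resid @ resid)
    params = dict(zip(names, (float(x) for x in popt)))
    ses = dict(zip(names, (float(x) for x in se)))
    if name == "mixed":
        params["alpha"] = 10.0 ** params.pop("log10_alpha")
        ses["alpha"] = np.log(10) * params["alpha"] * ses.pop("log10_alpha")
    return ModelFit(name=name, params=params, se=ses, rss=rss,
                    aicc=aicc(rss, v.size, len(popt)), converged=converged)


def global_fit_modality(grid: MichaelisGrid, weighted: bool = False) -> ModalityResult:
    """Fit all four inhibition models globally and select the modality.

    The three 3-parameter models compete by minimum AICc; the 4-parameter
    mixed model supersedes the winner only if its AICc is lower by ≥ 2.
    Nested F-tests (each simpler model vs mixed) are reported as secondary
    statistics, and a mixed fit whose α CI covers 1 is noted as consistent
    with noncompetitive.
    """
    S, I, v = grid.substrate_uM, grid.inhibitor_nM, grid.rate
    weights = None
    if weighted:
        if grid.sd is None or np.any(~np.isfinite(grid.sd)) or np.any(grid.sd <= 0):
            raise ValueError("weighted fit requires finite positive replicate SDs")
        weights = 1.0 / grid.sd**2
    fits = {}
    notes = []
    for name in MODEL_NAMES:
        mf = _fit_one(name, S, I, v, weights)
        if mf.converged:
            fits[name] = mf
        else:
            notes.append(f"{name} model excluded: fit did not converge")
    if not fits:
        raise RuntimeError("all four modality fits failed to converge")

    simple = {k: f for k, f in fits.items() if k != "mixed"}
    best_simple = min(simple.values(), key=lambda f: f.aicc) if simple else None
    # below this floor residuals are numerical noise and AICc differences
    # are meaningless; the simpler model then wins by parsimony
    rss_floor = v.size * (1e-7 * float(np.max(np.abs(v))) + 1e-300) ** 2
    selected = None
    if "mixed" in fits and best_simple is not None:
        if best_simple.rss > rss_floor and fits["mixed"].aicc <= best_simple.aicc - 2.0:
            selected = "mixed"
    if selected is None:
        selected = best_simple.name if best_simple is not None else "mixed"

    # nested F-tests: each 3-parameter model against mixed
    f_tests = {}
    if "mixed" in fits:
        mixed = fits["mixed"]
        n = v.size
        for name, mf in simple.items():
            df1, df2 = 1, n - 4
            if df2 > 0 and mixed.rss > 0:
                F = ((mf.rss - mixed.rss) / df1) / (mixed.rss / df2)
                f_tests[name] = {"F": float(F),
                                 "p": float(stats.f.sf(max(F, 0.0), df1, df2))}
        a = mixed.params.get("alpha", np.nan)
        se_a = mixed.se.get("alpha", np.nan)
        if np.isfinite(a) and np.isfinite(se_a) and abs(a - 1.0) <= 1.96 * se_a:
            notes.append("mixed-model alpha consistent with 1 (noncompetitive)")

    aicc_table = {k: f.aicc for k, f in fits.items()}
    return ModalityResult(
        fits=fits, selected=selected, Ki_true=fits[selected].params["Ki"],
        selection={"aicc": aicc_table, "f_vs_mixed": f_tests,
                   "rule": "min AICc among 3-parameter models; mixed needs ΔAICc ≥ 2"},
        notes=tuple(notes),
    )


def ki_from_kiapp(Kiapp: float, modality: Modality | str, S: Optional[float] = None,
                  Km: Optional[float] = None, alpha: Optional[float] = None) -> float:
    """Convert an apparent inhibitory constant to the true Ki (nM).

    noncompetitive: Ki = Kiapp (α = 1, substrate-independent);
    competitive: Ki = Kiapp/(1 + S/Km); uncompetitive: Ki = Kiapp/(1 + Km/S);
    mixed: the free-enzyme binding constant Ki = Kiapp·(Km + S/α)/(Km + S).
    """
    modality = Modality(modality)
    if Kiapp <= 0:
        raise ValueError("Kiapp must be > 0")
    if modality is Modality.noncompetitive:
        return Kiapp
    if S is None or Km is None or S <= 0 or Km <= 0:
        raise ValueError("substrate-dependent conversion requires S > 0 and Km > 0")
    if modality is Modality.competitive:
        return Kiapp / (1 + S / Km)
    if modality is Modality.uncompetitive:
        return Kiapp / (1 + Km / S)
    if alpha is None:
        raise ValueError("mixed-modality conversion requires alpha")
    return Kiapp * (Km + S / alpha) / (Km + S)


def ic50_from_scheme(scheme: KineticScheme, S: float, method: str = "closed_form") -> float:
    """Steady-state IC50 (nM) at substrate S (μM).

    Closed forms: noncompetitive IC50 = Ki (independent of S); competitive
    Ki·(1 + S/Km); uncompetitive Ki·(1 + Km/S); mixed the apparent constant
    Ki·(Km + S)/(Km + S/α). ``method='numeric'`` instead root-finds the
    half-maximum of :func:`slowbind.simulate.steady_rate`.
    """
    if method == "numeric":
        v0 = steady_rate(scheme, S, 0.0, 1.0)

        def g(I):
            return steady_rate(scheme, S, I, 1.0) - 0.5 * v0

        hi = scheme.Ki
        while g(hi) > 0:
            hi *= 10
            if hi > 1e15:
                raise RuntimeError("failed to bracket the IC50")
        return float(optimize.brentq(g, 1e-12, hi, xtol=1e-12, rtol=1e-14))
    Ki, Km = scheme.Ki, scheme.Km
    m = scheme.modality
    if m is Modality.noncompetitive:
        return Ki
    if m is Modality.competitive:
        return Ki * (1 + S / Km)
    if m is Modality.uncompetitive:
        return Ki * (1 + Km / S)
    return Ki * (Km + S) / (Km + S / scheme.alpha)
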