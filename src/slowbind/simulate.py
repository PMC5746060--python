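"""Synthetic-data generation for slow-binding inhibition assays.

Two simulators are provided:

* :func:`closed_form_curve` — the standard biphasic progress-curve law
  [P](t) = vs·t + (vi − vs)/kobs·(1 − e^(−kobs·t)), valid at low substrate
  conversion with the inhibitor in large excess over enzyme;
* :func:`ode_curve` — brute-force numerical integration of the binding
  scheme with rapid-equilibrium substrate binding, explicit substrate and
  free-inhibitor depletion and optional EI ↔ EI* isomerization.  It serves
  as the independent oracle for the closed form and as the engine for
  jump-dilution simulations where depletion matters.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .schemes import NM_PER_UM, AssayDesign, KineticScheme, Modality, NoiseModel, ProgressCurve

__all__ = [
    "steady_rate",
    "kobs_predict",
    "apparent_kiapp",
    "product_progress",
    "closed_form_curve",
    "ode_curve",
    "add_noise",
    "subseed",
    "simulate_experiment",
    "simulate_dilution",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries diagnostic state."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _check_conc(**kw):
    for name, v in kw.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def steady_rate(scheme: KineticScheme, S: float, I: float, E0: float) -> float:
    """Steady-state rate (nM product · min⁻¹) at substrate S (μM), inhibitor I (nM).

    v = kcat·E0·S / denom with the modality-specific denominator:

    * competitive:     Km·(1 + I/Ki) + S
    * noncompetitive:  (Km + S)·(1 + I/Ki)
    * uncompetitive:   Km + S·(1 + I/Ki)
    * mixed:           Km·(1 + I/Ki) + S·(1 + I/(α·Ki))
    """
    _check_conc(S=S, I=I, E0=E0)
    Km, Ki, a = scheme.Km, scheme.Ki, scheme.alpha
    m = scheme.modality
    if m is Modality.competitive:
        denom = Km * (1 + I / Ki) + S
    elif m is Modality.noncompetitive:
        denom = (Km + S) * (1 + I / Ki)
    elif m is Modality.uncompetitive:
        denom = Km + S * (1 + I / Ki)
    else:
        denom = Km * (1 + I / Ki) + S * (1 + I / (a * Ki))
    return scheme.kcat * E0 * S / denom


def _kon_eff(scheme: KineticScheme, S: float) -> float:
    """Apparent association rate at substrate S, per modality.

    For mixed inhibition kon_eff = kon·(Km + S/α)/(Km + S), which recovers
    the competitive form as α → ∞ and the noncompetitive one at α = 1.
    """
    Km = scheme.Km
    m = scheme.modality
    if m is Modality.competitive:
        return scheme.kon / (1 + S / Km)
    if m is Modality.noncompetitive:
        return scheme.kon
    if m is Modality.uncompetitive:
        if S == 0:
            return 0.0
        return scheme.kon / (1 + Km / S)
    return scheme.kon * (Km + S / scheme.alpha) / (Km + S)


def apparent_kiapp(scheme: KineticScheme, S: float) -> float:
    """Substrate-dependent apparent inhibitory constant koff/kon_eff (nM)."""
    ke = _kon_eff(scheme, S)
    if ke == 0:
        return np.inf
    return scheme.koff / ke


def kobs_predict(scheme: KineticScheme, S: float, I: float) -> float:
    """Observed rate of onset of inhibition (min⁻¹).

    One-step: kobs = koff + kon_eff·I (affine in I).
    Two-step: kobs = k6 + k5·I/(Ki1_eff + I), where Ki1_eff carries the same
    substrate correction as the one-step apparent constant.
    """
    _check_conc(S=S, I=I)
    if scheme.two_step:
        if scheme.k5 is None or scheme.k6 is None or scheme.Ki1 is None:
            raise ValueError("two-step kobs requested without two-step constants")
        ke = _kon_eff(scheme, S)
        if ke == 0:
            return scheme.k6
        ki1_eff = scheme.Ki1 * scheme.kon / ke
        return scheme.k6 + scheme.k5 * I / (ki1_eff + I)
    return scheme.koff + _kon_eff(scheme, S) * I


def product_progress(t: np.ndarray, vi: float, vs: float, kobs: float) -> np.ndarray:
    """Biphasic progress law [P](t) = vs·t + (vi − vs)/kobs·(1 − e^(−kobs·t)).

    Degenerates gracefully to the straight line vi·t as kobs → 0 or vi = vs.
    """
    t = np.asarray(t, dtype=float)
    if kobs <= 1e-12 or vi == vs:
        return vi * t
    return vs * t + (vi - vs) / kobs * (-np.expm1(-kobs * t))


def _preincubated_bound_fraction(scheme: KineticScheme, I: float, minutes: float) -> float:
    """Fraction of enzyme in inhibited complexes after incubating at S = 0."""
    if minutes <= 0 or I <= 0:
        return 0.0
    if scheme.modality is Modality.uncompetitive:
        return 0.0  # no ES present, no binding
    if scheme.two_step:
        # two-state relaxation has no simple closed form; integrate at S = 0
        return float(_ode_bind_only(scheme, I, 1.0, minutes))
    k = scheme.koff + scheme.kon * I
    f_eq = I / (scheme.Ki + I)
    return f_eq * (1.0 - np.exp(-k * minutes))


def _bind_rhs_factory(scheme: KineticScheme, E0: float, I_total: float, S_const=None):
    """RHS of the binding/catalysis ODE. State: [S_uM, EI_nM, EIs_nM, P_uM]."""
    Km, kcat = scheme.Km, scheme.kcat
    kon, koff = scheme.kon, scheme.koff
    k5 = scheme.k5 or 0.0
    k6 = scheme.k6 or 0.0
    m = scheme.modality
    alpha = scheme.alpha

    def phi(S):
        # fraction of inhibitor-free enzyme accessible to the inhibitor
        if m is Modality.competitive:
            return Km / (Km + S)
        if m is Modality.noncompetitive:
            return 1.0
        if m is Modality.uncompetitive:
            return S / (Km + S)
        return (Km + S / alpha) / (Km + S)

    def rhs(t, y):
        S, EI, EIs, _P = y
        S = max(S, 0.0)
        Ef = max(E0 - EI - EIs, 0.0)
        If = max(I_total - EI - EIs, 0.0)
        ES = Ef * S / (Km + S)
        bind = kon * If * Ef * phi(S)
        dEI = bind - koff * EI - k5 * EI + k6 * EIs
        dEIs = k5 * EI - k6 * EIs
        dP = kcat * ES / NM_PER_UM  # μM/min
        return [-dP, dEI, dEIs, dP]

    return rhs


def _ode_bind_only(scheme: KineticScheme, I: float, E0: float, minutes: float):
    """Bound fraction (EI + EI*)/E0 after incubating enzyme + inhibitor at S = 0."""
    rhs = _bind_rhs_factory(scheme, E0, I)
    sol = solve_ivp(rhs, (0.0, minutes), [0.0, 0.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError("preincubation integration failed",
                              {"message": sol.message})
    return (sol.y[1, -1] + sol.y[2, -1]) / E0


def closed_form_curve(scheme: KineticScheme, design: AssayDesign, I: float) -> ProgressCurve:
    """Generate a noise-free progress curve from the biphasic closed form.

    vi is the uninhibited steady-state rate (the inhibitor is slow, so the
    initial rate is independent of [I]); vs is the inhibited steady-state
    rate; kobs comes from :func:`kobs_predict`. With preincubation, vi is
    lowered by the enzyme fraction already bound at substrate addition.
    A ``depletion_warning`` is set if predicted conversion exceeds 10%.
    """
    _check_conc(I=I)
    t = design.times
    vs = steady_rate(scheme, design.S0, I, design.E0)
    vi = steady_rate(scheme, design.S0, 0.0, design.E0)
    fb0 = _preincubated_bound_fraction(scheme, I, design.preincubation_min)
    if fb0 > 0:
        vi = (1.0 - fb0) * vi
    kobs = kobs_predict(scheme, design.S0, I)
    P_nM = product_progress(t, vi, vs, kobs)
    meta = {"simulator": "closed_form", "vi_nM_min": vi, "vs_nM_min": vs,
            "kobs_min": kobs, "preincubated_bound_fraction": fb0}
    conv = P_nM[-1] / NM_PER_UM / design.S0
    if conv > 0.10:
        meta["depletion_warning"] = True
        warnings.warn(
            f"predicted conversion {conv:.1%} exceeds 10%; closed form unreliable",
            stacklevel=2,
        )
    signal = design.baseline + design.gain * P_nM / NM_PER_UM
    return ProgressCurve(
        curve_id=f"I={I:g}nM",
        time_min=t,
        signal_au=signal,
        inhibitor_nM=I,
        substrate_uM=design.S0,
        enzyme_nM=design.E0,
        meta=meta,
    )


def ode_curve(scheme: KineticScheme, design: AssayDesign, I: float,
              rtol: float = 1e-9, atol: float = 1e-12) -> ProgressCurve:
    """Progress curve by numerical integration of the full binding scheme.

    Substrate binding is treated as rapid equilibrium (ES = Ef·S/(Km+S));
    inhibitor association/dissociation and the optional EI ↔ EI* step are
    integrated explicitly, with substrate and free-inhibitor depletion.
    """
    _check_conc(I=I)
    t = design.times
    EI0 = EIs0 = 0.0
    if design.preincubation_min > 0 and I > 0:
        rhs_pre = _bind_rhs_factory(scheme, design.E0, I)
        sol = solve_ivp(rhs_pre, (0.0, design.preincubation_min),
                        [0.0, 0.0, 0.0, 0.0], method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError("preincubation integration failed",
                                  {"message": sol.message})
        EI0, EIs0 = sol.y[1, -1], sol.y[2, -1]
    rhs = _bind_rhs_factory(scheme, design.E0, I)
    sol = solve_ivp(rhs, (t[0], t[-1]), [design.S0, EI0, EIs0, 0.0],
                    method="LSODA", t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError("progress-curve integration failed",
                              {"message": sol.message, "t_reached": sol.t[-1] if sol.t.size else None})
    S, EI, EIs, P = sol.y
    balance = np.max(np.abs(S + P - design.S0))
    if balance > 1e-6 * design.S0:
        raise SimulationError("substrate mass balance violated",
                              {"max_violation_uM": float(balance)})
    signal = design.baseline + design.gain * P
    return ProgressCurve(
        curve_id=f"I={I:g}nM",
        time_min=t,
        signal_au=signal,
        inhibitor_nM=I,
        substrate_uM=design.S0,
        enzyme_nM=design.E0,
        meta={"simulator": "ode", "final_conversion": float(P[-1] / design.S0),
              "bound_fraction_final": float((EI[-1] + EIs[-1]) / design.E0)},
    )


# --- noise -----------------------------------------------------------------

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def _fnv1a64(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for b in data:
        h = ((h ^ b) * 0x100000001B3) & _MASK64
    return h


def subseed(master_seed: int, curve_id: str) -> int:
    """Per-curve sub-seed: splitmix64(master_seed XOR fnv1a64(curve_id)).

    The scheme is deterministic and documented so independent
    implementations can reproduce the fixture suite exactly.
    """
    return _splitmix64((int(master_seed) & _MASK64) ^ _fnv1a64(curve_id.encode("utf-8")))


def add_noise(curve: ProgressCurve, noise: NoiseModel) -> ProgressCurve:
    """Apply Gaussian noise signal·(1+ε_rel)+ε_abs; mean-preserving, seeded per curve."""
    if noise.sigma_rel == 0 and noise.sigma_abs == 0:
        return curve
    rng = np.random.default_rng(subseed(noise.seed, curve.curve_id))
    n = curve.n_points
    noisy = curve.signal_au * (1.0 + noise.sigma_rel * rng.standard_normal(n)) \
        + noise.sigma_abs * rng.standard_normal(n)
    meta = dict(curve.meta)
    meta["noise"] = {"sigma_rel": noise.sigma_rel, "sigma_abs": noise.sigma_abs,
                     "seed": noise.seed}
    return ProgressCurve(curve.curve_id, curve.time_min.copy(), noisy,
                         curve.inhibitor_nM, curve.substrate_uM, curve.enzyme_nM, meta)


def simulate_experiment(scheme: KineticScheme, design: AssayDesign,
                        noise: Optional[NoiseModel] = None,
                        simulator: str = "closed_form") -> list[ProgressCurve]:
    """Simulate one progress curve per inhibitor concentration in the design."""
    if simulator == "closed_form":
        sim = closed_form_curve
    elif simulator == "ode":
        sim = ode_curve
    else:
        raise ValueError(f"unknown simulator {simulator!r}")
    curves = []
    for I in design.I_grid:
        c = sim(scheme, design, I)
        if noise is not None:
            c = add_noise(c, noise)
        curves.append(c)
    return curves


def simulate_dilution(scheme: KineticScheme, pre_E0: float, pre_I: float,
                      pre_minutes: float, dilution_factor: float,
                      post_design: AssayDesign,
                      noise: Optional[NoiseModel] = None) -> ProgressCurve:
    """Jump-dilution experiment: preincubate E + I, dilute, follow recovery.

    Pre-equilibration is integrated at S = 0; the bound enzyme fraction is
    carried across the dilution. ``post_design.I_grid[0]`` is inhibitor
    *added to the dilution buffer* (0 for a plain jump dilution; set it to
    the pre-dilution concentration for a topped-up no-recovery control),
    so the post-dilution inhibitor is pre_I/dilution_factor + that amount.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    _check_conc(pre_E0=pre_E0, pre_I=pre_I)
    rhs_pre = _bind_rhs_factory(scheme, pre_E0, pre_I)
    sol = solve_ivp(rhs_pre, (0.0, pre_minutes), [0.0, 0.0, 0.0, 0.0],
                    method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError("pre-equilibration failed", {"message": sol.message})
    EI0 = sol.y[1, -1] / dilution_factor
    EIs0 = sol.y[2, -1] / dilution_factor
    E0_post = pre_E0 / dilution_factor
    I_post = pre_I / dilution_factor + post_design.I_grid[0]
    t = post_design.times
    rhs = _bind_rhs_factory(scheme, E0_post, I_post)
    sol = solve_ivp(rhs, (t[0], t[-1]), [post_design.S0, EI0, EIs0, 0.0],
                    method="LSODA", t_eval=t, rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise SimulationError("post-dilution integration failed",
                              {"message": sol.message})
    P = sol.y[3]
    signal = post_design.baseline + post_design.gain * P
    bound0 = (EI0 + EIs0) / E0_post
    curve = ProgressCurve(
        curve_id=f"dilution_I={I_post:g}nM",
        time_min=t,
        signal_au=signal,
        inhibitor_nM=I_post,
        substrate_uM=post_design.S0,
        enzyme_nM=E0_post,
        meta={"simulator": "ode_dilution", "bound_fraction_at_dilution": float(bound0),
              "I_post_nM": float(I_post), "dilution_factor": dilution_factor},
    )
    if noise is not None:
        curve = add_noise(curve, noise)
    return curve
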