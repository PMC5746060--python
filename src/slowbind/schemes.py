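"""Domain types for slow-binding inhibition kinetics.

Unit conventions, fixed throughout the package:

* time            minutes
* inhibitor, enzyme   nM
* substrate       μM
* first-order rates   min⁻¹
* second-order rates  nM⁻¹·min⁻¹
* signal          arbitrary fluorescence units (AU)

All unit conversions are explicit at module boundaries (``NM_PER_UM``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: nanomolar per micromolar — the only unit conversion used internally.
NM_PER_UM = 1000.0


class Modality(str, enum.Enum):
    """Inhibition modality of a reversible inhibitor.

    ``noncompetitive`` here means the classical pure noncompetitive case:
    the inhibitor binds free enzyme and the enzyme–substrate complex with
    equal affinity (α = 1), so Vmax drops while Km is unchanged.
    """

    competitive = "competitive"
    noncompetitive = "noncompetitive"
    uncompetitive = "uncompetitive"
    mixed = "mixed"


class KineticScheme(BaseModel):
    """Mechanistic ground truth for a reversible (slow-binding) inhibitor.

    The scheme is parameterized by the true inhibitory constant ``Ki`` and
    the dissociation rate ``koff``; the association rate is derived as
    ``kon = koff / Ki`` unless explicitly overridden.

    Parameters
    ----------
    modality
        Inhibition modality; determines how the inhibitor partitions
        between free enzyme E and the ES complex.
    Ki
        True inhibitory constant (nM). For competitive/noncompetitive/mixed
        this is the E·I dissociation constant; for uncompetitive it is the
        ES·I constant.
    koff
        Inhibitor dissociation rate (min⁻¹).
    kon
        Inhibitor association rate (nM⁻¹·min⁻¹); derived from Ki and koff
        when not given.
    alpha
        Modality factor of the mixed model: the ES·I constant is α·Ki.
        Forced to 1 for noncompetitive.
    Km, kcat
        Michaelis constant (μM) and turnover number (min⁻¹) of the
        substrate used in the assay.
    two_step
        If set, binding proceeds E + I ↔ EI ↔ EI*: (kon, koff) describe the
        fast encounter step (so Ki1 = koff/kon) and (k5, k6) the slow
        isomerization to the tightened EI* complex.
    """

    model_config = ConfigDict(validate_assignment=True)

    modality: Modality = Modality.noncompetitive
    Ki: float
    koff: float
    kon: Optional[float] = None
    alpha: float = 1.0
    Km: float = 10.0
    kcat: float = 0.1
    two_step: bool = False
    k5: Optional[float] = None
    k6: Optional[float] = None
    Ki1: Optional[float] = None

    @field_validator("Ki", "Km", "kcat")
    @classmethod
    def _positive(cls, v: float, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("koff", "alpha")
    @classmethod
    def _nonnegative(cls, v: float, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _finalize(self):
        if self.modality is Modality.noncompetitive and self.alpha != 1.0:
            raise ValueError("noncompetitive inhibition requires alpha = 1")
        if self.kon is None:
            object.__setattr__(self, "kon", self.koff / self.Ki)
        elif self.kon < 0:
            raise ValueError("kon must be >= 0")
        if self.two_step:
            if self.k5 is None or self.k6 is None:
                raise ValueError("two_step scheme requires k5 and k6")
            if self.Ki1 is None:
                if self.kon == 0:
                    raise ValueError("two_step scheme with kon = 0 needs Ki1")
                object.__setattr__(self, "Ki1", self.koff / self.kon)
        else:
            if any(v is not None for v in (self.k5, self.k6, self.Ki1)):
                raise ValueError("k5/k6/Ki1 are only meaningful when two_step is set")
        return self


class AssayDesign(BaseModel):
    """Layout of a progress-curve experiment.

    ``preincubation_min`` is the time enzyme and inhibitor are incubated
    together before substrate addition; during it binding proceeds at
    S = 0 and the curve then starts from the pre-equilibrated enzyme.
    """

    E0: float  # nM
    S0: float  # μM
    I_grid: Sequence[float] = (0.0,)  # nM
    t_grid: Sequence[float]  # min
    preincubation_min: float = 0.0
    gain: float = 1000.0  # AU per μM product
    baseline: float = 0.0  # AU

    @field_validator("E0", "S0", "gain")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("preincubation_min")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("preincubation_min must be >= 0")
        return v

    @field_validator("I_grid", "t_grid", mode="before")
    @classmethod
    def _coerce_seq(cls, v):
        if isinstance(v, np.ndarray):
            return tuple(float(x) for x in v)
        return v

    @field_validator("I_grid")
    @classmethod
    def _igrid(cls, v):
        v = tuple(float(x) for x in v)
        if len(v) == 0:
            raise ValueError("I_grid must be non-empty")
        if any(x < 0 for x in v):
            raise ValueError("inhibitor concentrations must be >= 0")
        return v

    @field_validator("t_grid")
    @classmethod
    def _tgrid(cls, v):
        v = tuple(float(x) for x in v)
        if len(v) < 2:
            raise ValueError("t_grid needs at least 2 points")
        if v[0] != 0.0:
            raise ValueError("t_grid must start at 0")
        if np.any(np.diff(v) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        return v

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.t_grid, dtype=float)


class NoiseModel(BaseModel):
    """Gaussian measurement noise: signal·(1 + ε_rel) + ε_abs.

    Identical (scheme, design, noise, seed) inputs reproduce bit-identical
    datasets; per-curve sub-seeds are derived from (seed, curve_id) by the
    splitmix-style mix in :func:`slowbind.simulate.subseed`.
    """

    sigma_rel: float = 0.0
    sigma_abs: float = 0.0
    seed: int = 0

    @field_validator("sigma_rel", "sigma_abs")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v


@dataclass
class ProgressCurve:
    """A single product-formation time course.

    ``signal_au`` is baseline + gain·[P](t) in fluorescence units; the
    concentrations it was recorded at travel with the curve.
    """

    curve_id: str
    time_min: np.ndarray
    signal_au: np.ndarray
    inhibitor_nM: float
    substrate_uM: float
    enzyme_nM: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal_au = np.asarray(self.signal_au, dtype=float)
        if self.time_min.shape != self.signal_au.shape:
            raise ValueError("time and signal vectors must have equal length")
        if self.time_min.size < 4:
            raise ValueError("a progress curve needs at least 4 points")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.inhibitor_nM < 0:
            raise ValueError("inhibitor_nM must be >= 0")

    @property
    def n_points(self) -> int:
        return self.time_min.size
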