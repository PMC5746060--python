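"""Tabular I/O, experiment configuration and the end-to-end pipeline.

Curves travel as tidy long-format CSV (one row per time point) with the
required header ``curve_id, time_min, signal_au, inhibitor_nM,
substrate_uM, enzyme_nM``. Configurations are YAML documents validated by
pydantic; unknown keys are rejected by name. ``run_pipeline`` chains
simulation (or loaded curves) → per-curve biphasic fits → kobs regression
→ optional modality analysis into a deterministic, seed-reproducible
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .modality import MichaelisGrid, global_fit_modality
from .progress import batch_fit
from .rates import compare_kobs_models, fit_kobs_hyperbolic, fit_kobs_linear, test_vi_independence
from .schemes import AssayDesign, KineticScheme, NoiseModel, ProgressCurve
from .simulate import add_noise, simulate_experiment, steady_rate

__all__ = ["read_curves", "write_curves", "ExperimentConfig", "PipelineReport",
           "run_pipeline"]

CURVE_COLUMNS = ["curve_id", "time_min", "signal_au", "inhibitor_nM",
                 "substrate_uM", "enzyme_nM"]


def write_curves(curves, path) -> None:
    """Write a curve family as tidy long-format CSV (12 significant digits)."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "curve_id": c.curve_id,
            "time_min": c.time_min,
            "signal_au": c.signal_au,
            "inhibitor_nM": c.inhibitor_nM,
            "substrate_uM": c.substrate_uM,
            "enzyme_nM": c.enzyme_nM,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_curves(path) -> list[ProgressCurve]:
    """Read progress curves from CSV; rows are reassembled sorted by time.

    Raises ``ValueError`` naming any missing column, and reports duplicate
    time points within a curve with their row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve file missing required column(s): {missing}")
    curves = []
    for cid, g in df.groupby("curve_id", sort=True):
        g = g.sort_values("time_min")
        t = g["time_min"].to_numpy(dtype=float)
        dup = np.nonzero(np.diff(t) <= 0)[0]
        if dup.size:
            rows = (g.index[dup] + 2).tolist()  # +2: header + 0-based
            raise ValueError(
                f"curve {cid!r}: non-increasing time at file line(s) {rows}")
        for col in ("inhibitor_nM", "substrate_uM", "enzyme_nM"):
            if g[col].nunique() > 1:
                raise ValueError(f"curve {cid!r}: column {col} is not constant")
        curves.append(ProgressCurve(
            curve_id=str(cid), time_min=t,
            signal_au=g["signal_au"].to_numpy(dtype=float),
            inhibitor_nM=float(g["inhibitor_nM"].iloc[0]),
            substrate_uM=float(g["substrate_uM"].iloc[0]),
            enzyme_nM=float(g["enzyme_nM"].iloc[0]),
        ))
    return curves


class AnalysisOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    weighted_kobs: bool = False
    alpha_linearity: float = 0.05
    alpha_vi: float = 0.05
    fix_offset: Optional[float] = None
    fit_modality: bool = False
    compare_two_step: bool = True


class MichaelisBlock(BaseModel):
    """Design of the steady-state substrate × inhibitor grid."""

    model_config = ConfigDict(extra="forbid")

    S_levels_uM: list[float]
    I_levels_nM: list[float]
    E0_nM: float = 1.0
    sigma_rel: float = 0.0


class ExperimentConfig(BaseModel):
    """Complete, serializable description of an experiment + analysis."""

    model_config = ConfigDict(extra="forbid")

    scheme: KineticScheme
    design: AssayDesign
    noise: Optional[NoiseModel] = None
    options: AnalysisOptions = AnalysisOptions()
    michaelis: Optional[MichaelisBlock] = None

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(json.loads(self.model_dump_json()), sort_keys=True).encode()
        ).hexdigest()[:16]


def _fit_to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        d = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif dataclasses.is_dataclass(v):
                v = _fit_to_dict(v)
            elif isinstance(v, dict):
                v = {k: (_fit_to_dict(x) if dataclasses.is_dataclass(x) else x)
                     for k, x in v.items()}
            d[f.name] = v
        return d
    return obj


@dataclass
class PipelineReport:
    """Machine-readable analysis report with full provenance."""

    config_hash: str
    seed: Optional[int]
    stages: list = field(default_factory=list)
    progress_fits: list = field(default_factory=list)
    kobs_profile: Optional[dict] = None
    slow_binding: Optional[dict] = None
    two_step: Optional[dict] = None
    model_comparison: Optional[dict] = None
    vi_independence: Optional[dict] = None
    modality: Optional[dict] = None
    notices: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return _fit_to_dict(o)
            return str(o)
        return json.dumps(dataclasses.asdict(self), default=default, sort_keys=True,
                          indent=1, allow_nan=True)

    def to_text(self) -> str:
        lines = [f"slowbind pipeline report (config {self.config_hash}, seed {self.seed})"]
        lines.append(f"stages: {', '.join(self.stages)}")
        if self.slow_binding:
            sb = self.slow_binding
            lines.append("kobs-[I] linear regression:")
            lines.append(f"  kon  = {sb['kon']:.4g} +/- {sb['se_kon']:.2g} nM^-1 min^-1")
            lines.append(f"  koff = {sb['koff']:.4g} +/- {sb['se_koff']:.2g} min^-1")
            if sb.get("Kiapp") is not None:
                lines.append(f"  Kiapp = koff/kon = {sb['Kiapp']:.4g} +/- {sb['se_Kiapp']:.2g} nM")
        if self.model_comparison:
            lines.append(f"binding-model selection: {self.model_comparison['selected']}"
                         f" (dAICc = {self.model_comparison['delta_aicc']:.3g})")
        if self.vi_independence:
            v = self.vi_independence
            lines.append(f"vi vs [I]: slope {v['slope']:.3g}, p = {v['p_value']:.3g}"
                         f" -> {'independent' if v['independent'] else 'dependent'}")
        if self.modality:
            lines.append(f"modality: {self.modality['selected']}"
                         f" (Ki = {self.modality['Ki_true']:.4g} nM)")
        for n in self.notices:
            lines.append(f"note: {n}")
        return "\n".join(lines)


def run_pipeline(config: ExperimentConfig, curves=None) -> PipelineReport:
    """Run simulate → fit-progress → fit-kobs → (optional) modality.

    If ``curves`` is None the experiment is simulated from the config's
    scheme/design/noise block. Every stage's numeric output lands in the
    report; a stage that cannot run (e.g. modality without a Michaelis
    block) is skipped with an explicit notice.
    """
    report = PipelineReport(config_hash=config.config_hash(),
                            seed=None if config.noise is None else config.noise.seed)
    if curves is None:
        curves = simulate_experiment(config.scheme, config.design, config.noise)
        report.stages.append("simulate")

    opts = config.options
    try:
        profile, fits = batch_fit(curves, fix_offset=opts.fix_offset,
                                  alpha_linearity=opts.alpha_linearity)
    except Exception as exc:  # noqa: BLE001 - structured stage failure
        raise RuntimeError(f"stage progress_fit failed: {exc}") from exc
    report.stages.append("progress_fit")
    report.progress_fits = [_fit_to_dict(f) for f in fits]
    report.kobs_profile = {"inhibitor_nM": profile.inhibitor_nM.tolist(),
                           "kobs": profile.kobs.tolist(),
                           "se": profile.se.tolist(),
                           "excluded": profile.provenance.get("excluded", [])}

    if profile.n >= 3:
        linear = fit_kobs_linear(profile, weighted=opts.weighted_kobs)
        report.slow_binding = _fit_to_dict(linear)
        report.stages.append("rate_analysis")
        if opts.compare_two_step and profile.n >= 5:
            hyp = fit_kobs_hyperbolic(profile)
            report.two_step = _fit_to_dict(hyp)
            report.model_comparison = _fit_to_dict(compare_kobs_models(linear, hyp))
        try:
            report.vi_independence = _fit_to_dict(
                test_vi_independence(fits, alpha=opts.alpha_vi))
        except ValueError as exc:
            report.notices.append(f"vi-independence test skipped: {exc}")
    else:
        report.notices.append(
            f"kobs regression skipped: only {profile.n} usable kobs value(s)")

    if opts.fit_modality:
        if config.michaelis is None:
            report.notices.append("modality stage skipped: no Michaelis grid configured")
        else:
            mb = config.michaelis
            S = np.repeat(mb.S_levels_uM, len(mb.I_levels_nM))
            I = np.tile(mb.I_levels_nM, len(mb.S_levels_uM))
            v = np.array([steady_rate(config.scheme, s, i, mb.E0_nM)
                          for s, i in zip(S, I)])
            if mb.sigma_rel > 0:
                seed = config.noise.seed if config.noise else 0
                rng = np.random.default_rng(seed)
                v = v * (1 + mb.sigma_rel * rng.standard_normal(v.size))
            grid = MichaelisGrid(substrate_uM=S, inhibitor_nM=I, rate=v,
                                 enzyme_nM=mb.E0_nM)
            res = global_fit_modality(grid)
            report.modality = {
                "selected": res.selected, "Ki_true": res.Ki_true,
                "aicc": res.selection["aicc"],
                "params": {k: f.params for k, f in res.fits.items()},
                "notes": list(res.notes),
            }
            report.stages.append("modality")
    return report
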