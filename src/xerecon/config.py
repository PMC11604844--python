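"""Run configuration: one YAML file driving every pipeline stage.

The canonical keys mirror the dataclasses of the library modules; every
protocol constant (TR, echo times, flips, bandwidth, spoke count, matrix,
FOV) is a default here and overridable from file.  Resonance offsets may be
given in Hz (canonical) or in ppm together with ``reference_frequency_hz``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cs import CSConfig
from .decomposition import COMPARTMENTS, GAMMA_XE_HZ, ResonanceModel, default_resonance_model
from .gridding import GriddingConfig
from .phantom import SequenceParams, SimulationParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class PhantomSpec:
    matrix: int = 32
    rbc_to_m: float = 0.41
    m_to_gas: float = 0.0098
    dissolved_gain: float = 1.0
    texture_amplitude: float = 0.10
    defects: list = field(default_factory=list)


@dataclass
class AcquisitionSpec:
    n_spokes: int = 934
    samples_per_spoke: int = 32
    spoke_style: str = "center_out"
    fov_cm: float = 40.0


@dataclass
class UndersamplingSpec:
    af: float = 1.0
    mode: str = "first_n"


@dataclass
class MaskSpec:
    k_sigma: float = 3.0
    n_edge_slices: int = 3
    slice_axis: int = 2
    t2star_mode: str = "none"
    denominator_eps: float = 0.01


@dataclass
class RunConfig:
    sequence: SequenceParams = field(default_factory=SequenceParams)
    resonances: ResonanceModel = field(default_factory=default_resonance_model)
    gridding: GriddingConfig = field(default_factory=GriddingConfig)
    cs: CSConfig = field(default_factory=CSConfig)
    undersampling: UndersamplingSpec = field(default_factory=UndersamplingSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    mask: MaskSpec = field(default_factory=MaskSpec)
    seed: int = 0
    output_dir: str = "runs"

    @property
    def voxel_mm(self) -> tuple[float, float, float]:
        v = self.acquisition.fov_cm * 10.0 / self.gridding.matrix
        return (v, v, v)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sequence"]["te_ms"] = list(self.sequence.te_ms)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _resonances_from_dict(d: dict) -> ResonanceModel:
    ref = float(d.get("reference_frequency_hz", GAMMA_XE_HZ))
    df, t2 = {}, {}
    base = default_resonance_model()
    for c in COMPARTMENTS:
        entry = d.get(c, {})
        if "delta_f_hz" in entry:
            df[c] = float(entry["delta_f_hz"])
        elif "delta_f_ppm" in entry:
            df[c] = float(entry["delta_f_ppm"]) * 1e-6 * ref
        else:
            df[c] = base.delta_f_hz[c]
        t2[c] = float(entry.get("t2star_ms", base.t2star_ms[c]))
    return ResonanceModel(delta_f_hz=df, t2star_ms=t2)


def _build(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    cfg = RunConfig()
    if "sequence" in raw:
        seq = dict(raw.pop("sequence"))
        if "te_ms" in seq:
            seq["te_ms"] = tuple(float(t) for t in seq["te_ms"])
        cfg.sequence = _build(SequenceParams, seq)
    if "resonances" in raw:
        cfg.resonances = _resonances_from_dict(raw.pop("resonances"))
    for key, cls, attr in (
        ("gridding", GriddingConfig, "gridding"),
        ("cs", CSConfig, "cs"),
        ("undersampling", UndersamplingSpec, "undersampling"),
        ("phantom", PhantomSpec, "phantom"),
        ("acquisition", AcquisitionSpec, "acquisition"),
        ("simulation", SimulationParams, "simulation"),
        ("mask", MaskSpec, "mask"),
    ):
        if key in raw:
            setattr(cfg, attr, _build(cls, dict(raw.pop(key))))
    if "seed" in raw:
        cfg.seed = int(raw.pop("seed"))
    if "output_dir" in raw:
        cfg.output_dir = str(raw.pop("output_dir"))
    if raw:
        raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    d = cfg.to_dict()
    # ResonanceModel serializes per-compartment for the canonical layout
    d["resonances"] = {
        c: {
            "delta_f_hz": cfg.resonances.delta_f_hz[c],
            "t2star_ms": cfg.resonances.t2star_ms[c],
        }
        for c in COMPARTMENTS
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
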