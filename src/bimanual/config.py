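"""Run configuration: a serializable description of one full pipeline run.

A run config bundles the experiment design (participants, factors,
repetitions, sampling), the load-condition dynamics mapping, the analysis
window and transition-screen parameters, and the statistics options.  It
round-trips through YAML and is echoed verbatim into every output
directory so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synth import ALL_LOAD_PAIRS, DesignSpec, DynamicsMapping, LoadType, Mode

__all__ = ["AnalysisConfig", "StatsConfig", "RunConfig"]


@dataclass
class AnalysisConfig:
    window_start_s: float = 12.0
    window_end_s: float = 42.0
    transition_window_s: float = 3.0
    transition_step_s: float = 0.5
    transition_threshold_deg: float = 90.0


@dataclass
class StatsConfig:
    reference_level: str = "none/none"
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    participants: int = 2
    modes: list = field(default_factory=lambda: ["in_phase", "anti_phase"])
    cycles_ms: list = field(default_factory=lambda: [750.0, 1200.0])
    load_pairs: list = field(
        default_factory=lambda: [[l.value, r.value] for l, r in ALL_LOAD_PAIRS]
    )
    repetitions: int = 5
    duration_s: float = 45.0
    fs: float = 1000.0
    amplitude_cm: float = 10.0
    measurement_noise_m: float = 5e-4
    hkb_a: float = 1.0
    hkb_b: float = 1.0
    omega_pull: dict = field(
        default_factory=lambda: {"none": 0.0, "viscous": -0.35, "elastic": -0.15}
    )
    q_base: float = 0.02
    q_increment: dict = field(
        default_factory=lambda: {"none": 0.0, "viscous": 0.01, "elastic": 0.02}
    )
    antiphase_q_factor: float = 2.0
    offset_sd_deg: float = 2.0
    noise_mult_sd: float = 0.2
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def design(self) -> DesignSpec:
        mapping = DynamicsMapping(
            omega_pull={LoadType(k): float(v) for k, v in self.omega_pull.items()},
            q_base=float(self.q_base),
            q_increment={LoadType(k): float(v) for k, v in self.q_increment.items()},
            antiphase_q_factor=float(self.antiphase_q_factor),
        )
        return DesignSpec(
            modes=tuple(Mode(m) for m in self.modes),
            cycles_ms=tuple(float(c) for c in self.cycles_ms),
            load_pairs=tuple((LoadType(l), LoadType(r)) for l, r in self.load_pairs),
            repetitions=int(self.repetitions),
            duration_s=float(self.duration_s),
            fs=float(self.fs),
            amplitude_cm=float(self.amplitude_cm),
            measurement_noise_m=float(self.measurement_noise_m),
            hkb_a=float(self.hkb_a),
            hkb_b=float(self.hkb_b),
            mapping=mapping,
            offset_sd_deg=float(self.offset_sd_deg),
            noise_mult_sd=float(self.noise_mult_sd),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        analysis = AnalysisConfig(**raw.pop("analysis", {}))
        stats = StatsConfig(**raw.pop("stats", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("analysis", "stats")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(analysis=analysis, stats=stats, **raw)
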