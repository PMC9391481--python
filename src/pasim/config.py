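"""Experiment configuration: YAML/JSON loading, validation, defaults.

Every stochastic component (pattern generation, lesion realization,
probe noise) has an explicit seed in the config, and runners write a
resolved-config snapshot beside their outputs, so any experiment is
reproducible from its config alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .pathology import LesionConfig, SineSpec, ThresholdSchedule, parse_projection
from .patterns import ModuleLayout


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayoutSection(_Model):
    n_visual: int = 900
    n_memory: int = 1200
    n_perceiving: int = 900
    visual_grid: tuple[int, int] = (30, 30)
    memory_grid: tuple[int, int] = (30, 40)
    perceiving_grid: tuple[int, int] = (30, 30)

    def build(self) -> ModuleLayout:
        return ModuleLayout(
            n_visual=self.n_visual,
            n_memory=self.n_memory,
            n_perceiving=self.n_perceiving,
            visual_grid=self.visual_grid,
            memory_grid=self.memory_grid,
            perceiving_grid=self.perceiving_grid,
        )


class SeedsSection(_Model):
    patterns: int = 1
    lesion: int = 2
    noise: int = 3


class LesionSection(_Model):
    dead_counts: dict[str, int] = Field(default_factory=dict)
    fan_in: dict[str, int] = Field(default_factory=dict)

    def build(self, seed: int) -> LesionConfig:
        return LesionConfig(
            dead_counts=dict(self.dead_counts),
            fan_in=dict(self.fan_in),
            seed=seed,
        )

    @property
    def is_trivial(self) -> bool:
        return not self.dead_counts and not self.fan_in


class ThresholdEntry(_Model):
    amplitude: float
    period: int
    phase: float = 0.0


class InputSection(_Model):
    mode: Literal["init", "persistent"] = "init"
    noise_fraction: float = 0.05
    strength: float = 1.0
    duration: int = 0


class RunSection(_Model):
    steps: Optional[int] = None  # default: 10 * L
    match_threshold: float = 0.95
    sustain: Optional[int] = None  # default: L
    probe_cycle: int = 0


class GridCell(_Model):
    name: str
    lesion: LesionSection


class SweepSection(_Model):
    kind: Literal["bottom_up", "threshold", "necrosis"] = "bottom_up"
    budgets: list[int] = Field(default_factory=lambda: [1050])
    n_config: int = 20
    n_probe: Optional[int] = None
    phases: Optional[list[int]] = None
    grid: list[GridCell] = Field(default_factory=list)
    typical_fraction: float = 0.5


class ExperimentConfig(_Model):
    """Fully defaulted description of one experiment."""

    layout: LayoutSection = Field(default_factory=LayoutSection)
    K: int = 11
    L: int = 10
    seeds: SeedsSection = Field(default_factory=SeedsSection)
    lesion: LesionSection = Field(default_factory=LesionSection)
    thresholds: dict[str, ThresholdEntry] = Field(default_factory=dict)
    input: InputSection = Field(default_factory=InputSection)
    run: RunSection = Field(default_factory=RunSection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    output: str = "out"

    def module_layout(self) -> ModuleLayout:
        return self.layout.build()

    def lesion_config(self) -> LesionConfig:
        return self.lesion.build(seed=self.seeds.lesion)

    def threshold_schedule(self) -> ThresholdSchedule | None:
        if not self.thresholds:
            return None
        return ThresholdSchedule(
            {
                module: SineSpec(e.amplitude, e.period, e.phase)
                for module, e in self.thresholds.items()
            }
        )

    @property
    def steps(self) -> int:
        return self.run.steps if self.run.steps is not None else 10 * self.L


def load_config(path: "str | Path | None") -> ExperimentConfig:
    """Load and validate a YAML (or JSON) config; None -> all defaults.

    An empty file also yields the all-defaults config: full
    connectivity, no thresholds, standard layout.
    """
    if path is None:
        cfg = ExperimentConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        try:
            cfg = ExperimentConfig.model_validate(raw)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc
    report = validate_config(cfg)
    if report["errors"]:
        raise ConfigurationError("; ".join(report["errors"]))
    return cfg


def validate_config(cfg: ExperimentConfig) -> dict:
    """Feasibility checks beyond schema validation.

    Returns {"ok": bool, "errors": [messages naming the field]}.
    """
    errors: list[str] = []
    try:
        layout = cfg.module_layout()
    except ConfigurationError as exc:
        return {"ok": False, "errors": [f"layout: {exc}"]}
    if cfg.K < 1 or cfg.L < 1:
        errors.append(f"K/L: must be >= 1, got K={cfg.K}, L={cfg.L}")
    elif cfg.K * cfg.L > layout.N // 4:
        errors.append(
            f"K/L: K*L={cfg.K * cfg.L} exceeds capacity N/4={layout.N // 4}"
        )
    for module, count in cfg.lesion.dead_counts.items():
        try:
            n_mod = layout.count(module)
        except KeyError:
            errors.append(f"lesion.dead_counts: unknown module {module!r}")
            continue
        if not 0 <= count <= n_mod:
            errors.append(
                f"lesion.dead_counts.{module}: {count} exceeds module "
                f"size {n_mod}"
            )
    for key, budget in cfg.lesion.fan_in.items():
        try:
            target, sources = parse_projection(key)
        except ConfigurationError as exc:
            errors.append(f"lesion.fan_in: {exc}")
            continue
        pool = sum(layout.count(s) for s in sources)
        pool -= sum(cfg.lesion.dead_counts.get(s, 0) for s in sources)
        if not 0 <= budget <= pool:
            errors.append(
                f"lesion.fan_in.{key}: budget {budget} infeasible "
                f"(living pool {pool})"
            )
    for budget in cfg.sweep.budgets:
        pool = layout.n_visual + layout.n_memory
        if not 0 <= budget <= pool:
            errors.append(
                f"sweep.budgets: {budget} infeasible (pool {pool})"
            )
    if not 0.0 <= cfg.input.noise_fraction <= 1.0:
        errors.append("input.noise_fraction: must lie in [0, 1]")
    if not 0 <= cfg.run.probe_cycle < cfg.K:
        errors.append(
            f"run.probe_cycle: {cfg.run.probe_cycle} out of range 0..{cfg.K - 1}"
        )
    return {"ok": not errors, "errors": errors}


def dump_config(cfg: ExperimentConfig, path: "str | Path") -> None:
    """Write the fully resolved config as YAML (audit snapshot)."""
    data = cfg.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
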