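"""Run configuration: YAML-backed settings for the whole pipeline.

A single YAML file describes the umbrella schedule, the synthetic surface
landmarks, integrator settings, WHAM/bootstrap settings and the transition-state
search range; CLI flags override file values.  Every command echoes the exact
configuration it ran with next to its outputs, so runs are reproducible from the
output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import ScheduleSegment, DEFAULT_SEGMENTS, build_window_schedule, WindowSpec
from .langevin import LangevinParams
from .surfaces import ModelSurface, surface_from_landmarks
from .wham import WHAMConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SurfaceLandmarks:
    reactant_rc: float
    ts_rc: float
    barrier: float
    product_rc: float
    overall_dg: float

    def build(self) -> ModelSurface:
        return surface_from_landmarks(
            self.reactant_rc, self.ts_rc, self.barrier, self.product_rc, self.overall_dg
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, resolvable before any work starts."""

    segments: tuple[ScheduleSegment, ...] = DEFAULT_SEGMENTS
    force_constant: float = 500.0
    n_equil_samples: int = 2000
    n_prod_samples: int = 4000
    sample_interval: float = 5.0
    surface: SurfaceLandmarks | None = None
    langevin: LangevinParams = field(default_factory=LangevinParams)
    wham: WHAMConfig = field(default_factory=WHAMConfig)
    n_boot: int = 20
    block_length: int | None = None
    ts_search: tuple[float, float] = (-2.0, 1.0)
    half_prefactor: bool = True
    seed: int = 0

    def windows(self) -> list[WindowSpec]:
        return build_window_schedule(
            self.segments,
            force_constant=self.force_constant,
            n_equil_samples=self.n_equil_samples,
            n_prod_samples=self.n_prod_samples,
            sample_interval=self.sample_interval,
        )


def _segment_from_mapping(m: Mapping[str, Any]) -> ScheduleSegment:
    try:
        return ScheduleSegment(
            start=float(m["start"]),
            stop=float(m["stop"]),
            step=float(m["step"]),
            include_start=bool(m.get("include_start", True)),
            include_stop=bool(m.get("include_stop", True)),
        )
    except KeyError as exc:
        raise ConfigError(f"schedule segment missing field {exc}") from None


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus flat overrides.

    Missing file (``path=None``) means all defaults.  Unknown top-level keys are
    an error so typos fail loudly.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {
        "segments", "force_constant", "n_equil_samples", "n_prod_samples",
        "sample_interval", "surface", "langevin", "wham", "n_boot",
        "block_length", "ts_search", "half_prefactor", "seed", "temperature",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    temperature = float(data.get("temperature", 300.0))

    segments = DEFAULT_SEGMENTS
    if "segments" in data:
        raw = data["segments"]
        if not isinstance(raw, list) or not raw:
            raise ConfigError("segments must be a non-empty list of mappings")
        segments = tuple(_segment_from_mapping(m) for m in raw)

    surface = None
    if "surface" in data and data["surface"] is not None:
        s = data["surface"]
        for key in ("reactant_rc", "ts_rc", "barrier", "product_rc", "overall_dg"):
            if key not in s:
                raise ConfigError(f"surface config missing field {key!r}")
        surface = SurfaceLandmarks(
            reactant_rc=float(s["reactant_rc"]), ts_rc=float(s["ts_rc"]),
            barrier=float(s["barrier"]), product_rc=float(s["product_rc"]),
            overall_dg=float(s["overall_dg"]),
        )

    lv = data.get("langevin", {}) or {}
    langevin = LangevinParams(
        dt=float(lv.get("dt", 0.05)),
        friction=float(lv.get("friction", 1000.0)),
        temperature=float(lv.get("temperature", temperature)),
        seed=int(data.get("seed", 0)),
    )

    wh = data.get("wham", {}) or {}
    wham = WHAMConfig(
        bin_width=float(wh.get("bin_width", 0.02)),
        rc_range=tuple(wh["rc_range"]) if wh.get("rc_range") else None,
        tolerance=float(wh.get("tolerance", 1e-7)),
        max_iterations=int(wh.get("max_iterations", 100_000)),
        temperature=float(wh.get("temperature", temperature)),
        half_prefactor=bool(data.get("half_prefactor", True)),
        anchor_rc_max=float(wh.get("anchor_rc_max", -2.0)),
    )

    ts_search = tuple(float(v) for v in data.get("ts_search", (-2.0, 1.0)))
    if len(ts_search) != 2:
        raise ConfigError("ts_search must be [lo, hi]")

    return RunConfig(
        segments=segments,
        force_constant=float(data.get("force_constant", 500.0)),
        n_equil_samples=int(data.get("n_equil_samples", 2000)),
        n_prod_samples=int(data.get("n_prod_samples", 4000)),
        sample_interval=float(data.get("sample_interval", 5.0)),
        surface=surface,
        langevin=langevin,
        wham=wham,
        n_boot=int(data.get("n_boot", 20)),
        block_length=None if data.get("block_length") in (None, "null") else int(data["block_length"]),
        ts_search=ts_search,  # type: ignore[arg-type]
        half_prefactor=bool(data.get("half_prefactor", True)),
        seed=int(data.get("seed", 0)),
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration as YAML next to outputs."""
    payload = {
        "segments": [asdict(s) for s in cfg.segments],
        "force_constant": cfg.force_constant,
        "n_equil_samples": cfg.n_equil_samples,
        "n_prod_samples": cfg.n_prod_samples,
        "sample_interval": cfg.sample_interval,
        "surface": asdict(cfg.surface) if cfg.surface else None,
        "langevin": {
            "dt": cfg.langevin.dt,
            "friction": cfg.langevin.friction,
            "temperature": cfg.langevin.temperature,
        },
        "wham": {
            "bin_width": cfg.wham.bin_width,
            "rc_range": list(cfg.wham.rc_range) if cfg.wham.rc_range else None,
            "tolerance": cfg.wham.tolerance,
            "max_iterations": cfg.wham.max_iterations,
            "temperature": cfg.wham.temperature,
            "anchor_rc_max": cfg.wham.anchor_rc_max,
        },
        "n_boot": cfg.n_boot,
        "block_length": cfg.block_length,
        "ts_search": list(cfg.ts_search),
        "half_prefactor": cfg.half_prefactor,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
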