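"""Pipeline configuration: YAML schema, validation and echo."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .registration import RegistrationParams
from .resp_signal import BandConfig
from .roi_tracking import TrackingConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    ``population`` selects the breathing band defaults (adults breathe
    at 0.1-0.85 Hz, neonates at 0.5-1.5 Hz); explicit ``low_hz`` /
    ``high_hz`` override them.  Every value is echoed into the run log.
    """

    seed: int
    population: str = "neonate"
    window_s: float = 30.0
    step_s: float = 20.0
    low_hz: float | None = None
    high_hz: float | None = None
    fps: float | None = None          # fallback when frames carry no rate
    rig_corners: tuple[int, int] = (5, 6)
    rgb_path: str | None = None
    thermal_path: str | None = None
    rig_rgb_path: str | None = None
    rig_thermal_path: str | None = None
    affine_path: str | None = None    # precomputed map instead of rig frames
    reference_path: str | None = None  # belt-signal CSV (10 Hz force series)
    reference_fs: float = 10.0
    out_dir: str = "out"
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    def band(self) -> BandConfig:
        base = BandConfig.for_population(self.population)
        if self.low_hz is not None or self.high_hz is not None:
            return BandConfig(low_hz=self.low_hz or base.low_hz,
                              high_hz=self.high_hz or base.high_hz,
                              order=base.order, population="custom")
        return base

    def validate(self) -> None:
        problems = []
        if self.population not in ("adult", "neonate"):
            problems.append(f"unknown population {self.population!r}")
        if self.window_s <= 0 or self.step_s <= 0:
            problems.append("window_s and step_s must be positive")
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.rgb_path is None or self.thermal_path is None:
            problems.append("rgb_path and thermal_path are required")
        has_rig = self.rig_rgb_path is not None and self.rig_thermal_path is not None
        if not has_rig and self.affine_path is None:
            problems.append("either rig frame paths or a precomputed "
                            "affine_path is required")
        try:
            band = self.band()
        except ValueError as exc:
            problems.append(str(exc))
        else:
            if self.fps is not None and band.high_hz >= self.fps / 2:
                problems.append("band exceeds the frame-rate Nyquist limit")
        if problems:
            raise ConfigError("; ".join(problems))

    def echo(self) -> dict:
        """Full parameter dump for the run log."""
        d = asdict(self)
        d["resolved_band"] = asdict(self.band())
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "registration" in raw and isinstance(raw["registration"], dict):
        raw["registration"] = RegistrationParams(**raw["registration"])
    if "tracking" in raw and isinstance(raw["tracking"], dict):
        raw["tracking"] = TrackingConfig(**raw["tracking"])
    if "rig_corners" in raw:
        raw["rig_corners"] = tuple(raw["rig_corners"])
    if "seed" not in raw:
        raise ConfigError("seed is mandatory")
    try:
        config = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    config.validate()
    return config
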