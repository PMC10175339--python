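"""Exception hierarchy shared across the pipeline stages."""

from __future__ import annotations

__all__ = [
    "ThermorespError",
    "ConfigError",
    "RegistrationError",
    "RigNotFoundError",
    "DegenerateLandmarksError",
    "FlatSignalError",
    "SignalTooShortError",
]


class ThermorespError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ThermorespError):
    """Invalid or incomplete pipeline configuration."""


class RegistrationError(ThermorespError):
    """Visible/thermal registration failed.

    ``stage`` names the failing step (``"rig"``, ``"keypoints"``,
    ``"matching"``, ``"consensus"``).
    """

    def __init__(self, message: str, stage: str = "registration"):
        super().__init__(message)
        self.stage = stage


class RigNotFoundError(RegistrationError):
    """Calibration-rig corner grid not found in one modality."""

    def __init__(self, message: str, modality: str):
        super().__init__(message, stage="rig")
        self.modality = modality


class DegenerateLandmarksError(ThermorespError):
    """Facial landmarks give a zero-width or zero-height ROI."""


class FlatSignalError(ThermorespError):
    """Signal has zero variance; no rate can be estimated."""


class SignalTooShortError(ThermorespError):
    """Record shorter than one analysis window."""
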