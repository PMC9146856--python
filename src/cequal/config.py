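"""Declarative run configuration for the pipeline and CLI.

A single JSON-serialisable object bundles everything a run depends on: the
master seed, the simulation profile, the GLCM settings, the contrast
threshold (or the instruction to calibrate it), and the two clinical
criteria — bubbles on >= 10% of the surface, R/G > 1.6.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .frame_scoring import GlcmParams
from .synthetic import ArmProfile, paper_study_profiles

KNOWN_PROFILES = ("paper-study",)


@dataclass
class RunConfig:
    seed: int = 1
    profile: str = "paper-study"
    frames_per_video: int = 200
    n_videos: int | None = None  # per-arm override, mainly for smoke runs
    tau: float | str = "calibrate"
    calibration_n: int = 500
    bubble_coverage_criterion: float = 0.10
    rg_criterion: float = 1.6
    glcm: GlcmParams = field(default_factory=GlcmParams)
    sphericity_correction: str = "none"

    def __post_init__(self) -> None:
        if self.bubble_coverage_criterion <= 0 or self.rg_criterion <= 0:
            raise ValueError("thresholds must be positive")
        if self.profile not in KNOWN_PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; known: {KNOWN_PROFILES}")
        if isinstance(self.tau, str) and self.tau != "calibrate":
            raise ValueError("tau must be a number or 'calibrate'")
        if self.sphericity_correction not in ("none", "gg"):
            raise ValueError("sphericity_correction must be 'none' or 'gg'")

    @property
    def tau_value(self) -> float | None:
        """Numeric threshold, or None when it is to be calibrated."""
        return None if self.tau == "calibrate" else float(self.tau)

    def arm_profiles(self) -> dict[str, ArmProfile]:
        profiles = paper_study_profiles(frames_per_video=self.frames_per_video)
        if self.n_videos is not None:
            profiles = {
                label: ArmProfile(**{**asdict(p), "n_videos": self.n_videos})
                for label, p in profiles.items()
            }
        return profiles

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["glcm"] = asdict(self.glcm)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        glcm = payload.pop("glcm", None)
        config = cls(**payload)
        if glcm is not None:
            glcm["orientations"] = tuple(glcm.get("orientations", (0, 45, 90, 135)))
            config.glcm = GlcmParams(**glcm)
        return config
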