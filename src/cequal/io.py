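"""Disk plumbing: PNG frame directories, JSON sidecars, CSV tables."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .synthetic import ArmProfile, VideoRecord, render_frame


def write_video(video: VideoRecord, out_dir: str | Path) -> Path:
    """Render a simulated video to ``out_dir/<video_id>/`` as PNG frames plus
    ``sidecar.json``; frame filenames carry the zero-padded frame index."""
    video_dir = Path(out_dir) / video.video_id
    video_dir.mkdir(parents=True, exist_ok=True)
    for k, spec in enumerate(video.frame_specs):
        render_frame(spec).save_png(video_dir / f"frame_{k:05d}.png")
    (video_dir / "sidecar.json").write_text(json.dumps(video.sidecar(), indent=1))
    return video_dir


def read_sidecar(video_dir: str | Path) -> dict:
    path = Path(video_dir) / "sidecar.json"
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar: {path}")
    return json.loads(path.read_text())


def profile_hash(profiles: dict[str, ArmProfile]) -> str:
    """Stable short hash of the simulation profiles, recorded in manifests."""
    payload = json.dumps(
        {k: asdict(v) for k, v in sorted(profiles.items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int, profiles: dict[str, ArmProfile]) -> Path:
    manifest = {
        "seed": int(seed),
        "profile_hash": profile_hash(profiles),
        "arms": {k: asdict(v) for k, v in sorted(profiles.items())},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.to_csv(path, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
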