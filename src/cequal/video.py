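"""Per-video aggregation of frame scores.

The small-bowel (SB) segment of a recording — everything between the first
and last SB frame — is split into four consecutive quartiles of the frame
sequence (Q1..Q4). Within each quartile we report the proportion of frames
classified abundant in bubbles and the proportion classified adequately
cleansed, the repeated measures carried into the cohort statistics.
Reader-level outcomes (transit times, completion, diagnostic yield) are
derived from the video sidecar metadata.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_SIDECAR_FIELDS = (
    "video_id",
    "timestamps",
    "sb_first_frame",
    "sb_last_frame",
    "colonic_frame_present",
    "findings",
)


def quartile_bounds(n_sb_frames: int) -> list[tuple[int, int]]:
    """Half-open index ranges of the four SB quartiles.

    Boundaries sit at ``floor(k * N / 4)`` for k = 0..4 over 0-based SB frame
    indices, so the four ranges always partition ``[0, N)``; remainder frames
    fall into Q2 and Q4.
    """
    n = int(n_sb_frames)
    if n < 4:
        raise ValueError(f"too few SB frames: {n} < 4")
    edges = [(k * n) // 4 for k in range(5)]
    return [(edges[k], edges[k + 1]) for k in range(4)]


@dataclass(frozen=True)
class QuartileSummary:
    """Per-quartile fractions of abundant and adequately-cleansed SB frames."""

    video_id: str
    abundant_fraction: tuple[float, float, float, float]
    adequate_fraction: tuple[float, float, float, float]
    n_frames: tuple[int, int, int, int]


@dataclass(frozen=True)
class VideoOutcome:
    """Reader-level outcomes of one recording.

    ``dy_positive`` — at least one finding of intermediate (P1) or high (P2)
    pertinence; ``complete`` — at least one colonic (or stoma/anal) frame was
    captured, i.e. the capsule reached the caecum.
    """

    video_id: str
    gastric_transit_min: float
    sb_transit_min: float
    n_images: int
    complete: bool
    dy_positive: bool
    has_p1: bool
    has_p2: bool


def summarize_video(
    scores: pd.DataFrame, sidecar: dict
) -> tuple[QuartileSummary, VideoOutcome]:
    """Aggregate per-frame scores of one video into quartile fractions and outcomes.

    Parameters
    ----------
    scores
        Per-frame table with columns ``frame_index``, ``bubble_class``
        (``scarce``/``abundant``) and ``cleanliness_class``
        (``adequate``/``inadequate``); only rows in the SB segment are used.
    sidecar
        Video metadata dict; must contain :data:`REQUIRED_SIDECAR_FIELDS`.
        Timestamps are seconds from capsule ingestion.
    """
    missing = [f for f in REQUIRED_SIDECAR_FIELDS if f not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing required fields: {missing}")

    sb_first = int(sidecar["sb_first_frame"])
    sb_last = int(sidecar["sb_last_frame"])
    sb = scores[
        (scores["frame_index"] >= sb_first) & (scores["frame_index"] <= sb_last)
    ].sort_values("frame_index")
    n_sb = len(sb)
    bounds = quartile_bounds(n_sb)

    abundant = (sb["bubble_class"].to_numpy() == "abundant")
    adequate = (sb["cleanliness_class"].to_numpy() == "adequate")
    ab_frac, ad_frac, counts = [], [], []
    for lo, hi in bounds:
        counts.append(hi - lo)
        ab_frac.append(float(abundant[lo:hi].mean()))
        ad_frac.append(float(adequate[lo:hi].mean()))

    ts = np.asarray(sidecar["timestamps"], dtype=float)
    findings = list(sidecar["findings"])
    has_p1 = "P1" in findings
    has_p2 = "P2" in findings
    summary = QuartileSummary(
        video_id=str(sidecar["video_id"]),
        abundant_fraction=tuple(ab_frac),
        adequate_fraction=tuple(ad_frac),
        n_frames=tuple(counts),
    )
    outcome = VideoOutcome(
        video_id=str(sidecar["video_id"]),
        gastric_transit_min=float(ts[sb_first] - sidecar.get("ingestion_time", 0.0)) / 60.0,
        sb_transit_min=float(ts[sb_last] - ts[sb_first]) / 60.0,
        n_images=len(ts),
        complete=bool(sidecar["colonic_frame_present"]),
        dy_positive=has_p1 or has_p2,
        has_p1=has_p1,
        has_p2=has_p2,
    )
    return summary, outcome


def summary_row(summary: QuartileSummary, outcome: VideoOutcome, arm: str) -> dict:
    """Flatten one video's summary into a row for the cohort table."""
    row = {"video_id": summary.video_id, "arm": arm}
    for q in range(4):
        row[f"abundant_q{q + 1}"] = summary.abundant_fraction[q]
        row[f"adequate_q{q + 1}"] = summary.adequate_fraction[q]
        row[f"n_q{q + 1}"] = summary.n_frames[q]
    row.update(
        gastric_transit_min=outcome.gastric_transit_min,
        sb_transit_min=outcome.sb_transit_min,
        n_images=outcome.n_images,
        complete=outcome.complete,
        dy_positive=outcome.dy_positive,
        has_p1=outcome.has_p1,
        has_p2=outcome.has_p2,
    )
    return row
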