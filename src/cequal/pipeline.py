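"""End-to-end study pipeline: calibrate, simulate, score, aggregate, report.

The in-memory path used by the acceptance workflow and the CLI: frames are
rendered from their seeded recipes, scored, and discarded, so a full
two-arm cohort never has to sit on disk.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .frame_scoring import (
    CalibrationResult,
    GlcmParams,
    calibrate_threshold,
    score_frames,
)
from .stats import StudyReport, build_report
from .synthetic import ArmProfile, FrameSpec, VideoRecord, render_frame
from .video import quartile_bounds, summarize_video, summary_row

#: seed-stream tags (kept distinct from per-video streams)
_CALIBRATION_TAG = 777_777


def calibration_set(
    seed: int,
    n: int = 500,
    coverage_max: float = 0.3,
    frame_size: int = 128,
) -> tuple[list[FrameSpec], np.ndarray]:
    """Labelled calibration recipes: coverage ~ Uniform[0, coverage_max].

    The label is the ground truth of the bubble criterion: coverage >= 10%
    of the field of view. The stream is disjoint from every cohort stream.
    """
    rng = np.random.default_rng([seed, _CALIBRATION_TAG])
    coverage = rng.uniform(0.0, coverage_max, size=n)
    rg = rng.uniform(1.0, 2.2, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    specs = [
        FrameSpec(frame_size, frame_size, float(c), float(g), seed=int(s))
        for c, g, s in zip(coverage, rg, seeds)
    ]
    labels = coverage >= synthetic.ABUNDANT_COVERAGE
    return specs, labels


def calibrate(
    seed: int,
    n: int = 500,
    params: GlcmParams = GlcmParams(),
    frame_size: int = 128,
) -> CalibrationResult:
    """Calibrate the contrast threshold tau on a synthetic labelled set."""
    specs, labels = calibration_set(seed, n=n, frame_size=frame_size)
    return calibrate_threshold((render_frame(s) for s in specs), labels, params)


def score_video_record(
    video: VideoRecord, params: GlcmParams, tau: float
) -> pd.DataFrame:
    """Render and score every frame of one simulated recording."""
    frames = (render_frame(s) for s in video.frame_specs)
    return score_frames(frames, params, tau)


@dataclass
class StudyRun:
    """Everything one pipeline run produces."""

    seed: int
    tau: float
    calibration: CalibrationResult | None
    summaries: pd.DataFrame
    report: StudyReport
    #: measured frame-pooled per-arm, per-quartile fractions
    pooled_abundant: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_adequate: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_n: dict[str, np.ndarray] = field(default_factory=dict)


def run_study(
    seed: int,
    profiles: dict[str, ArmProfile] | None = None,
    params: GlcmParams = GlcmParams(),
    tau: float | None = None,
    calibration_n: int = 500,
    progress: bool = False,
) -> StudyRun:
    """Simulate the two-arm cohort, score every SB frame, and build the report.

    When ``tau`` is None it is first calibrated on a disjoint synthetic set.
    Pooled per-quartile fractions aggregate classified frames over all
    videos of an arm (frame-level pooling).
    """
    if profiles is None:
        profiles = synthetic.paper_study_profiles()
    frame_size = next(iter(profiles.values())).frame_size
    calibration = None
    if tau is None:
        calibration = calibrate(seed, n=calibration_n, params=params, frame_size=frame_size)
        tau = calibration.tau

    videos, roster = synthetic.generate_cohort(profiles, seed)
    rows = []
    abundant_counts = {a: np.zeros(4) for a in profiles}
    adequate_counts = {a: np.zeros(4) for a in profiles}
    frame_counts = {a: np.zeros(4) for a in profiles}
    for k, video in enumerate(videos):
        scores = score_video_record(video, params, tau)
        summary, outcome = summarize_video(scores, video.sidecar())
        rows.append(summary_row(summary, outcome, video.arm_label))
        for q in range(4):
            n_q = summary.n_frames[q]
            frame_counts[video.arm_label][q] += n_q
            abundant_counts[video.arm_label][q] += summary.abundant_fraction[q] * n_q
            adequate_counts[video.arm_label][q] += summary.adequate_fraction[q] * n_q
        if progress and (k + 1) % 10 == 0:
            print(f"scored {k + 1}/{len(videos)} videos", flush=True)

    summaries = pd.DataFrame(rows)
    report = build_report(summaries, roster)
    return StudyRun(
        seed=seed,
        tau=float(tau),
        calibration=calibration,
        summaries=summaries,
        report=report,
        pooled_abundant={a: abundant_counts[a] / frame_counts[a] for a in profiles},
        pooled_adequate={a: adequate_counts[a] / frame_counts[a] for a in profiles},
        pooled_n={a: frame_counts[a].astype(int) for a in profiles},
    )


def planted_quartile_fractions(
    videos: list[VideoRecord],
) -> dict[str, np.ndarray]:
    """Frame-pooled *planted* abundant fractions per arm and quartile.

    Ground truth only (no rendering); used for generator convergence checks
    and fast statistical simulations.
    """
    hits: dict[str, np.ndarray] = {}
    totals: dict[str, np.ndarray] = {}
    for video in videos:
        flags = video.planted_abundant_flags()
        arm = video.arm_label
        hits.setdefault(arm, np.zeros(4))
        totals.setdefault(arm, np.zeros(4))
        for q, (lo, hi) in enumerate(quartile_bounds(len(flags))):
            hits[arm][q] += flags[lo:hi].sum()
            totals[arm][q] += hi - lo
    return {arm: hits[arm] / totals[arm] for arm in hits}


def planted_scores(video: VideoRecord) -> pd.DataFrame:
    """Per-frame score table built from the planted ground truth (no rendering)."""
    ab = video.planted_abundant_flags()
    ad = video.planted_adequate_flags()
    return pd.DataFrame(
        {
            "frame_index": np.arange(video.sb_first_frame, video.sb_last_frame + 1),
            "contrast": np.nan,
            "bubble_class": np.where(ab, "abundant", "scarce"),
            "rg_ratio": np.nan,
            "cleanliness_class": np.where(ad, "adequate", "inadequate"),
        }
    )


def planted_summaries(videos: list[VideoRecord]) -> pd.DataFrame:
    """Cohort summary table from planted ground truth instead of scored pixels.

    Useful for generator checks and statistical simulations where rendering
    every frame would only add classifier noise.
    """
    rows = []
    for video in videos:
        summary, outcome = summarize_video(planted_scores(video), video.sidecar())
        rows.append(summary_row(summary, outcome, video.arm_label))
    return pd.DataFrame(rows)


def planted_video_fractions(videos: list[VideoRecord], endpoint: str = "abundant"):
    """Per-video planted quartile fractions and arm labels (for ANOVA runs)."""
    values = []
    arms = []
    for video in videos:
        flags = (
            video.planted_abundant_flags()
            if endpoint == "abundant"
            else video.planted_adequate_flags()
        )
        values.append(
            [flags[lo:hi].mean() for lo, hi in quartile_bounds(len(flags))]
        )
        arms.append(video.arm_label)
    return np.array(values), np.array(arms)
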