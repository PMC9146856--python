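"""Synthetic capsule-endoscopy frames, videos and cohorts with planted ground truth.

No public repository of small-bowel capsule recordings with per-frame bubble
annotations exists, so every downstream stage is exercised on synthetic
material that plants the quantities the analysis is supposed to recover:

* frames — a reddish, softly textured mucosa inside a circular field of view,
  with non-overlapping bright circular annuli standing in for bubbles at a
  controlled surface coverage, and a controlled red/green channel balance
  standing in for debris and bile;
* videos — ordered frames with timestamps, gastric/SB/colonic segment
  markers, per-quartile abundant-bubble and adequate-cleanliness rates,
  completion and findings metadata;
* cohorts — two preparation arms (``SMT-`` without and ``SMT+`` with the
  anti-foaming agent simethicone) plus a screening roster reproducing a
  two-period observational flow chart.

Everything is deterministic under a single master seed; per-video random
streams are derived from ``(master_seed, arm, video_index)`` so each arm can
be regenerated independently.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._util import round_half_up
from .frame import Frame, circular_fov
from .video import quartile_bounds

ARM_LABELS = ("SMT-", "SMT+")

#: bubble-coverage criterion separating scarce from abundant frames
ABUNDANT_COVERAGE = 0.10
#: R/G criterion separating adequately from inadequately cleansed frames
RG_ADEQUATE = 1.6

# mucosa base colour (R, G, B) before channel balancing
_MUCOSA = np.array([152.0, 96.0, 72.0])
_DEBRIS = np.array([95.0, 135.0, 75.0])
# single bubble radius in pixels; a fixed size keeps total rim length
# proportional to covered area, the signal the texture detector keys on
_NOMINAL_BUBBLE_RADIUS = 5


@dataclass(frozen=True)
class FrameSpec:
    """Recipe for one synthetic frame.

    ``true_bubble_coverage`` is the planted fraction of the field-of-view
    area occupied by bubbles; ``rg_balance`` the planted ratio of mean red to
    mean green intensity inside the FOV; ``noise_sd`` per-pixel Gaussian
    grain in grey-level units.
    """

    width: int = 128
    height: int = 128
    true_bubble_coverage: float = 0.0
    rg_balance: float = 1.8
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_bubble_coverage <= 1.0:
            raise ValueError("true_bubble_coverage must lie in [0, 1]")
        if self.rg_balance <= 0:
            raise ValueError("rg_balance must be positive")
        if self.width < 16 or self.height < 16:
            raise ValueError("frame too small")


@dataclass(frozen=True)
class ArmProfile:
    """Statistical profile of one preparation arm.

    Per-quartile rates are the probabilities with which an SB frame is
    planted abundant in bubbles (coverage >= 0.10) or adequately cleansed
    (R/G > 1.6); completion and findings rates are planted as exact per-arm
    quotas so small-cohort percentages land on their targets.
    """

    arm_label: str
    n_videos: int
    frames_per_video: int = 200
    per_quartile_abundant_rate: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    per_quartile_adequate_rate: tuple[float, float, float, float] = (0.7, 0.7, 0.7, 0.7)
    completion_prob: float = 0.9
    transit_time_means: tuple[float, float] = (40.0, 200.0)  # gastric, SB (minutes)
    findings_rates: tuple[float, float] = (0.15, 0.27)  # P1, P2
    frame_size: int = 128
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.arm_label not in ARM_LABELS:
            raise ValueError(f"arm_label must be one of {ARM_LABELS}")
        if self.n_videos < 1:
            raise ValueError("n_videos must be >= 1")
        if self.frames_per_video < 8:
            raise ValueError("frames_per_video must be >= 8 (non-empty quartiles)")
        for rates in (
            self.per_quartile_abundant_rate,
            self.per_quartile_adequate_rate,
            (self.completion_prob,),
            self.findings_rates,
        ):
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class RosterRecord:
    """One screened patient in the cohort roster."""

    patient_id: str
    setting: str  # outpatient / inpatient
    indication: str  # OGIB / other
    age: float
    washout_period_flag: bool
    technical_defect_flag: bool
    endoscopic_delivery_flag: bool
    recent_CE_flag: bool
    gastric_retention_flag: bool
    active_bleeding_flag: bool
    contraindication_flag: bool
    arm_label: str


ROSTER_COLUMNS = [f.name for f in RosterRecord.__dataclass_fields__.values()]


@dataclass
class VideoRecord:
    """One simulated recording: frame recipes plus sidecar metadata.

    Frames are stored as :class:`FrameSpec` recipes and rendered on demand
    (``render_frame``), which keeps a 100-video cohort in memory and lets the
    scorer re-render identical pixels from the same seeds.
    """

    video_id: str
    arm_label: str
    frame_specs: list[FrameSpec]
    timestamps: list[float]  # seconds from ingestion
    sb_first_frame: int
    sb_last_frame: int
    colonic_frame_present: bool
    findings: list[str]

    @property
    def n_sb_frames(self) -> int:
        return self.sb_last_frame - self.sb_first_frame + 1

    @property
    def sb_specs(self) -> list[FrameSpec]:
        return self.frame_specs[self.sb_first_frame : self.sb_last_frame + 1]

    def planted_abundant_flags(self) -> np.ndarray:
        """Ground-truth abundant labels of the SB frames (coverage >= 0.10)."""
        return np.array(
            [s.true_bubble_coverage >= ABUNDANT_COVERAGE for s in self.sb_specs]
        )

    def planted_adequate_flags(self) -> np.ndarray:
        """Ground-truth adequate-cleanliness labels of the SB frames."""
        return np.array([s.rg_balance > RG_ADEQUATE for s in self.sb_specs])

    def sidecar(self) -> dict:
        return {
            "video_id": self.video_id,
            "arm_label": self.arm_label,
            "timestamps": list(map(float, self.timestamps)),
            "sb_first_frame": int(self.sb_first_frame),
            "sb_last_frame": int(self.sb_last_frame),
            "colonic_frame_present": bool(self.colonic_frame_present),
            "findings": list(self.findings),
        }


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _disk_offsets(radius: int):
    """Pixel offsets of a rasterised disk and of its ~1.5 px outer rim."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy * yy + xx * xx
    inside = d2 <= r * r
    rim = inside & (d2 >= (r - 1.5) ** 2)
    return (
        yy[inside].copy(),
        xx[inside].copy(),
        yy[rim].copy(),
        xx[rim].copy(),
    )


def _place_bubbles(
    fov: np.ndarray, target: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Place non-overlapping disks inside the FOV until the covered fraction
    of the FOV area is within +-0.005 of ``target`` (contract is +-0.01).

    Returns (interior mask, rim mask, achieved fraction).
    """
    h, w = fov.shape
    interior = np.zeros_like(fov)
    rim = np.zeros_like(fov)
    fov_area = int(fov.sum())
    if target <= 0:
        return interior, rim, 0.0
    if target > 0.95:
        raise ValueError(f"bubble coverage {target} unreachable (> 0.95)")

    radius_fov = 0.48 * min(w, h)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    target_px = target * fov_area
    tol_px = 0.005 * fov_area
    r_max = max(3, min(w, h) // 14)
    covered = 0
    consecutive_failures = 0
    while target_px - covered > tol_px:
        remaining = target_px - covered
        r_cap = int(math.sqrt(remaining / math.pi))
        if r_cap < 2:
            break
        if consecutive_failures >= 5:
            r = 2
        else:
            # nominal bubble radius; shrinks only when little area remains,
            # so rim length stays proportional to covered area across frames
            r = min(_NOMINAL_BUBBLE_RADIUS, min(r_max, r_cap))
        dy, dx, ry, rx = _disk_offsets(r)
        placed = False
        for _ in range(40):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = (radius_fov - r - 1.0) * math.sqrt(rng.uniform())
            y = int(round(cy + rad * math.sin(ang)))
            x = int(round(cx + rad * math.cos(ang)))
            ys, xs = y + dy, x + dx
            if interior[ys, xs].any():
                continue
            interior[ys, xs] = True
            rim[y + ry, x + rx] = True
            covered += dy.size
            placed = True
            break
        if placed:
            consecutive_failures = 0
        else:
            consecutive_failures += 1
            if consecutive_failures > 120:
                break
    achieved = covered / fov_area
    if abs(achieved - target) > 0.01:
        raise RuntimeError(
            f"bubble placement reached {achieved:.3f}, target {target:.3f}"
        )
    return interior, rim, achieved


def render_frame(spec: FrameSpec) -> Frame:
    """Render one synthetic frame from its recipe.

    Composition order: textured mucosa background, greenish debris blotches,
    bubbles (bright rim, translucent interior), pixel grain, then a global
    green-channel rescale inside the FOV that drives the achieved
    mean-R/mean-G to within 2% of ``spec.rg_balance``. Deterministic under
    ``spec.seed``.
    """
    w, h = spec.width, spec.height
    rng = np.random.default_rng(spec.seed)
    fov = circular_fov(w, h)

    # textured mucosa: coarse noise field smoothed into soft blotches
    coarse = rng.normal(0.0, 1.0, (h // 16 + 2, w // 16 + 2))
    tex = np.repeat(np.repeat(coarse, 16, axis=0), 16, axis=1)[:h, :w]
    tex = gaussian_filter(tex, sigma=5.0)
    tex /= max(tex.std(), 1e-9)
    img = np.empty((h, w, 3), dtype=float)
    for c, amp in zip(range(3), (22.0, 15.0, 10.0)):
        img[..., c] = _MUCOSA[c] + amp * tex

    # greenish debris blotches
    for _ in range(int(rng.integers(2, 5))):
        br = int(rng.integers(7, 15))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = (0.48 * min(w, h) - br - 1.0) * math.sqrt(rng.uniform())
        y = int(round((h - 1) / 2.0 + rad * math.sin(ang)))
        x = int(round((w - 1) / 2.0 + rad * math.cos(ang)))
        dy, dx, _, _ = _disk_offsets(br)
        img[y + dy, x + dx] = 0.55 * img[y + dy, x + dx] + 0.45 * _DEBRIS

    interior, rim, achieved = _place_bubbles(fov, spec.true_bubble_coverage, rng)
    img[interior] = 0.62 * img[interior] + 0.38 * 222.0
    img[rim] = 240.0

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    # drive mean-R / mean-G over the FOV to the planted balance by tinting
    # the mucosa/debris pixels only (specular bubble highlights keep their
    # colour, as bile staining affects the mucosa, not reflections), with
    # channel scales chosen to leave mean luminance 0.299 R + 0.587 G
    # unchanged so the bubble-to-mucosa level gap the texture detector sees
    # is independent of the planted cleanliness
    target = spec.rg_balance
    tissue = fov & ~interior
    if not tissue.any():
        raise RuntimeError("no tissue pixels left to balance")
    for iteration in range(25):
        clipped = np.clip(img, 0.0, 255.0)
        r_mean = clipped[..., 0][fov].mean()
        g_mean = clipped[..., 1][fov].mean()
        if g_mean <= 0 or r_mean <= 0:
            raise RuntimeError("channel collapsed during balancing")
        ratio = r_mean / g_mean
        if abs(ratio / target - 1.0) < 0.004:
            break
        if iteration >= 12:
            # tissue tinting alone cannot reach the target (heavy bubble
            # load and extreme balance): fall back to a whole-FOV rescale
            img[..., 1][fov] *= ratio / target
            continue
        rt_mean = clipped[..., 0][tissue].mean()
        gt_mean = clipped[..., 1][tissue].mean()
        n_fov, n_t = fov.sum(), tissue.sum()
        bubble_r = r_mean * n_fov - rt_mean * n_t  # bubble-pixel channel sums
        bubble_g = g_mean * n_fov - gt_mean * n_t
        # tissue-channel means that put the FOV ratio on target while keeping
        # the tissue's mean luminance fixed (exact linear solve, iterated
        # only because clipping at 0/255 perturbs it)
        luma = 0.299 * rt_mean + 0.587 * gt_mean
        want_r = (target * bubble_g + target * n_t * luma / 0.587 - bubble_r) / (
            n_t * (1.0 + 0.299 * target / 0.587)
        )
        want_r = min(max(want_r, 1.0), luma / 0.299 - 1.0)
        want_g = (luma - 0.299 * want_r) / 0.587
        img[..., 0][tissue] *= want_r / rt_mean
        img[..., 1][tissue] *= want_g / gt_mean
    else:
        clipped = np.clip(img, 0.0, 255.0)
        ratio = clipped[..., 0][fov].mean() / clipped[..., 1][fov].mean()
        if abs(ratio / target - 1.0) > 0.02:
            raise RuntimeError(
                f"could not balance R/G to {target} (achieved {ratio:.3f})"
            )

    rgb = np.clip(img, 0.0, 255.0).astype(np.uint8)
    rgb[~fov] = 0
    return Frame(
        rgb=rgb,
        fov=fov,
        planted_bubble_fraction=achieved,
        planted_rg=target,
    )


def measured_bubble_fraction(spec: FrameSpec) -> float:
    """Achieved bubble-pixel fraction of the FOV for a recipe (renders it)."""
    return float(render_frame(spec).planted_bubble_fraction)


# ---------------------------------------------------------------------------
# videos and cohorts
# ---------------------------------------------------------------------------

_N_GASTRIC_FRAMES = 4
_N_COLONIC_FRAMES = 2
_MIN_TRANSIT_MIN = 2.0
_TRANSIT_CV = 0.35  # sd as a fraction of the mean, clipped at _MIN_TRANSIT_MIN

# coverage / balance draws for planted classes; kept clear of the class
# boundaries by roughly the generator's own rendering tolerance
_SCARCE_COVERAGE = (0.0, 0.095)
_ABUNDANT_COVERAGE_RANGE = (0.105, 0.40)
_INADEQUATE_RG = (0.95, 1.55)
_ADEQUATE_RG = (1.65, 2.30)


def _arm_index(arm_label: str) -> int:
    return ARM_LABELS.index(arm_label)


def _quota(rate: float, n: int) -> int:
    return int(round_half_up(rate * n))


def _arm_assignments(profile: ArmProfile, master_seed: int):
    """Exact per-arm quota assignment of findings and completion.

    A seeded permutation of video indices maps the first ``n_P1`` slots to a
    P1 finding, the next ``n_P2`` slots to a P2 finding; an independent
    permutation marks the first ``n_complete`` slots complete.
    """
    n = profile.n_videos
    arm = _arm_index(profile.arm_label)
    finding_order = np.random.default_rng([master_seed, arm, 999_983]).permutation(n)
    complete_order = np.random.default_rng([master_seed, arm, 999_979]).permutation(n)
    n_p1 = _quota(profile.findings_rates[0], n)
    n_p2 = _quota(profile.findings_rates[1], n)
    if n_p1 + n_p2 > n:
        raise ValueError("findings rates exceed cohort size")
    n_complete = _quota(profile.completion_prob, n)
    pos_f = np.empty(n, dtype=int)
    pos_f[finding_order] = np.arange(n)
    pos_c = np.empty(n, dtype=int)
    pos_c[complete_order] = np.arange(n)
    return pos_f, n_p1, n_p2, pos_c, n_complete


def generate_video(
    profile: ArmProfile, video_index: int, master_seed: int
) -> VideoRecord:
    """Simulate one recording of the given arm.

    Each SB frame draws its abundant indicator from the quartile's planted
    rate (coverage then uniform over the class's range) and its adequacy
    indicator from the quartile's adequate rate (R/G balance likewise).
    Deterministic under ``(master_seed, arm, video_index)``.
    """
    if not 0 <= video_index < profile.n_videos:
        raise ValueError("video_index out of range")
    arm = _arm_index(profile.arm_label)
    rng = np.random.default_rng([master_seed, arm, video_index])
    n_sb = profile.frames_per_video

    pos_f, n_p1, n_p2, pos_c, n_complete = _arm_assignments(profile, master_seed)
    has_p1 = pos_f[video_index] < n_p1
    has_p2 = n_p1 <= pos_f[video_index] < n_p1 + n_p2
    complete = pos_c[video_index] < n_complete

    findings: list[str] = []
    if has_p1:
        findings.append("P1")
    if has_p2:
        findings.append("P2")
    if not findings and rng.uniform() < 0.3:
        findings.append("P0")

    # planted per-frame classes
    abundant = np.zeros(n_sb, dtype=bool)
    adequate = np.zeros(n_sb, dtype=bool)
    for q, (lo, hi) in enumerate(quartile_bounds(n_sb)):
        abundant[lo:hi] = rng.uniform(size=hi - lo) < profile.per_quartile_abundant_rate[q]
        adequate[lo:hi] = rng.uniform(size=hi - lo) < profile.per_quartile_adequate_rate[q]
    coverage = np.where(
        abundant,
        rng.uniform(*_ABUNDANT_COVERAGE_RANGE, size=n_sb),
        rng.uniform(*_SCARCE_COVERAGE, size=n_sb),
    )
    rg = np.where(
        adequate,
        rng.uniform(*_ADEQUATE_RG, size=n_sb),
        rng.uniform(*_INADEQUATE_RG, size=n_sb),
    )

    # transit times (minutes), truncated-normal around the arm means
    gtt = max(_MIN_TRANSIT_MIN, rng.normal(profile.transit_time_means[0],
                                           _TRANSIT_CV * profile.transit_time_means[0]))
    sbtt = max(_MIN_TRANSIT_MIN, rng.normal(profile.transit_time_means[1],
                                            _TRANSIT_CV * profile.transit_time_means[1]))

    frame_seeds = rng.integers(0, 2**31 - 1, size=n_sb + _N_GASTRIC_FRAMES + _N_COLONIC_FRAMES)
    size = profile.frame_size
    specs: list[FrameSpec] = []
    k = 0
    for _ in range(_N_GASTRIC_FRAMES):
        specs.append(FrameSpec(size, size, 0.0, float(rng.uniform(1.2, 1.6)),
                               profile.noise_sd, int(frame_seeds[k])))
        k += 1
    for i in range(n_sb):
        specs.append(FrameSpec(size, size, float(coverage[i]), float(rg[i]),
                               profile.noise_sd, int(frame_seeds[k])))
        k += 1
    n_colonic = _N_COLONIC_FRAMES if complete else 0
    for _ in range(n_colonic):
        specs.append(FrameSpec(size, size, 0.0, float(rng.uniform(1.0, 1.4)),
                               profile.noise_sd, int(frame_seeds[k])))
        k += 1

    gtt_s, sbtt_s = gtt * 60.0, sbtt * 60.0
    timestamps = list(np.linspace(0.0, gtt_s, _N_GASTRIC_FRAMES, endpoint=False))
    timestamps += list(gtt_s + np.linspace(0.0, sbtt_s, n_sb))
    timestamps += [gtt_s + sbtt_s + 300.0 * (i + 1) for i in range(n_colonic)]

    return VideoRecord(
        video_id=f"{profile.arm_label}_{video_index:03d}",
        arm_label=profile.arm_label,
        frame_specs=specs,
        timestamps=timestamps,
        sb_first_frame=_N_GASTRIC_FRAMES,
        sb_last_frame=_N_GASTRIC_FRAMES + n_sb - 1,
        colonic_frame_present=complete,
        findings=findings,
    )


def generate_cohort(
    profiles: dict[str, ArmProfile], master_seed: int
) -> tuple[list[VideoRecord], pd.DataFrame]:
    """Simulate both arms and build the all-pass cohort roster.

    Roster rows carry clinical attributes (age, sex, overt-OGIB indicator)
    drawn per arm, all screening flags clear; patient_id equals the video_id.
    """
    for label, profile in profiles.items():
        if label != profile.arm_label:
            raise ValueError(f"profile key {label!r} != arm_label {profile.arm_label!r}")
    videos: list[VideoRecord] = []
    rows: list[dict] = []
    # per-arm clinical attribute targets (mean age, sd, male and overt rates)
    clinical = {
        "SMT-": dict(age_mean=63.2, age_sd=13.3, male=19 / 48, overt=11 / 48),
        "SMT+": dict(age_mean=61.7, age_sd=16.8, male=32 / 57, overt=20 / 57),
    }
    for label in sorted(profiles, key=_arm_index):
        profile = profiles[label]
        arm = _arm_index(label)
        arng = np.random.default_rng([master_seed, arm, 555_557])
        n = profile.n_videos
        attrs = clinical.get(label, dict(age_mean=62.0, age_sd=15.0, male=0.5, overt=0.3))
        male_order = arng.permutation(n)
        overt_order = arng.permutation(n)
        n_male = _quota(attrs["male"], n)
        n_overt = _quota(attrs["overt"], n)
        ages = np.clip(arng.normal(attrs["age_mean"], attrs["age_sd"], size=n), 18.0, 95.0)
        for i in range(n):
            video = generate_video(profile, i, master_seed)
            videos.append(video)
            rows.append(
                {
                    "patient_id": video.video_id,
                    "setting": "outpatient",
                    "indication": "OGIB",
                    "age": float(round(ages[i], 1)),
                    "sex": "M" if int(np.where(male_order == i)[0][0]) < n_male else "F",
                    "overt_ogib": bool(int(np.where(overt_order == i)[0][0]) < n_overt),
                    "washout_period_flag": False,
                    "technical_defect_flag": False,
                    "endoscopic_delivery_flag": False,
                    "recent_CE_flag": False,
                    "gastric_retention_flag": False,
                    "active_bleeding_flag": False,
                    "contraindication_flag": False,
                    "arm_label": label,
                }
            )
    roster = pd.DataFrame(rows)
    if roster["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in roster")
    return videos, roster


def paper_study_profiles(frames_per_video: int = 200, frame_size: int = 128) -> dict[str, ArmProfile]:
    """The packaged two-arm study profile (48 vs 57 recordings).

    Q3/Q4 abundant rates and the completion/findings/transit parameters are
    the published arm-level values; Q1/Q2 abundant rates and the
    cleanliness-by-quartile curves are fixed package choices consistent with
    the published narrative (between-arm difference growing along the SB;
    cleanliness declining over quartiles similarly in both arms). See
    docs/methods.md.
    """
    return {
        "SMT-": ArmProfile(
            arm_label="SMT-",
            n_videos=48,
            frames_per_video=frames_per_video,
            per_quartile_abundant_rate=(0.190, 0.225, 0.277, 0.305),
            per_quartile_adequate_rate=(0.82, 0.75, 0.68, 0.60),
            completion_prob=0.875,
            transit_time_means=(40.0, 199.0),
            findings_rates=(0.146, 0.271),
            frame_size=frame_size,
        ),
        "SMT+": ArmProfile(
            arm_label="SMT+",
            n_videos=57,
            frames_per_video=frames_per_video,
            per_quartile_abundant_rate=(0.185, 0.205, 0.221, 0.206),
            per_quartile_adequate_rate=(0.83, 0.77, 0.70, 0.63),
            completion_prob=0.929,
            transit_time_means=(39.0, 232.0),
            findings_rates=(0.158, 0.263),
            frame_size=frame_size,
        ),
    }


# ---------------------------------------------------------------------------
# screening roster fixture
# ---------------------------------------------------------------------------

_EXCLUSION_FLAGS = (
    "technical_defect_flag",
    "endoscopic_delivery_flag",
    "recent_CE_flag",
    "gastric_retention_flag",
    "active_bleeding_flag",
    "contraindication_flag",
)


def generate_screening_roster(seed: int = 0) -> pd.DataFrame:
    """The 345-patient screening roster reproducing the study flow chart.

    Strata: 18 capsules during the washout month; 61 non-OGIB indications;
    122 OGIB inpatients; 66 eligible outpatients in the SMT- period (18 of
    whom carry one exclusion criterion) and 78 in the SMT+ period (21 with
    one exclusion criterion), leaving 48 and 57 included. Row order is a
    seeded shuffle; counts are exact by construction.
    """
    rng = np.random.default_rng([seed, 424_243])
    rows: list[dict] = []

    def base_row(setting: str, indication: str, arm: str) -> dict:
        row = {
            "setting": setting,
            "indication": indication,
            "age": float(round(np.clip(rng.normal(62.0, 15.0), 18.0, 95.0), 1)),
            "washout_period_flag": False,
            "arm_label": arm,
        }
        for flag in _EXCLUSION_FLAGS:
            row[flag] = False
        return row

    for i in range(18):  # washout month
        row = base_row("outpatient", "OGIB", ARM_LABELS[i % 2])
        row["washout_period_flag"] = True
        rows.append(row)
    for i in range(61):  # non-OGIB indications
        rows.append(base_row("outpatient" if i % 2 else "inpatient", "other",
                             ARM_LABELS[i % 2]))
    for i in range(122):  # OGIB inpatients
        rows.append(base_row("inpatient", "OGIB", ARM_LABELS[i % 2]))
    for arm, n_eligible, n_excluded in (("SMT-", 66, 18), ("SMT+", 78, 21)):
        for i in range(n_eligible):
            row = base_row("outpatient", "OGIB", arm)
            if i < n_excluded:
                criterion = i % (len(_EXCLUSION_FLAGS) + 1)
                if criterion == len(_EXCLUSION_FLAGS):
                    row["age"] = float(rng.integers(12, 18))  # below 18 years
                else:
                    row[_EXCLUSION_FLAGS[criterion]] = True
            rows.append(row)

    order = rng.permutation(len(rows))
    roster = pd.DataFrame([rows[i] for i in order])
    roster.insert(0, "patient_id", [f"S{i:04d}" for i in range(len(roster))])
    return roster[ROSTER_COLUMNS]
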