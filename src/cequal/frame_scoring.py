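"""Per-frame quality scorers: GLCM bubble detection and R/G cleanliness.

Two measurements are made on every still frame, restricted to the circular
field of view:

* a grey-level co-occurrence matrix (GLCM) is accumulated by counting pairs
  of pixels at a fixed offset, and its Haralick contrast
  ``sum (i - j)^2 p(i, j)`` summarises local intensity variation. Bubbles —
  bright specular annuli on darker mucosa — inflate the contrast, so a frame
  is called *abundant in bubbles* (>= 10% of the visible surface) when its
  contrast exceeds a calibrated threshold tau;
* the ratio of mean red to mean green intensity (R/G). Visible mucosa is
  red, faecal debris and bile are green, so a frame is *adequately cleansed*
  when R/G > 1.6 (strict).

tau is calibrated on labelled synthetic frames by maximising the Youden
index, since the published detector's cut-off is not public.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frame import Frame

RG_THRESHOLD = 1.6

# offsets (drow, dcol) per orientation at unit distance
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GlcmParams:
    """Co-occurrence accumulation settings (standard Haralick conventions)."""

    n_levels: int = 32
    distance: int = 1
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.orientations:
            raise ValueError("orientations must be non-empty")
        bad = [a for a in self.orientations if a % 360 not in _ANGLE_OFFSETS]
        if bad:
            raise ValueError(f"unsupported orientations {bad}; use multiples of 45 in {{0,45,90,135}}")


@dataclass(frozen=True)
class GlcmMatrix:
    """Normalised co-occurrence probabilities ``p[i, j]`` (sums to 1)."""

    p: np.ndarray
    params: GlcmParams
    n_pairs: int


@dataclass(frozen=True)
class FrameScore:
    contrast: float
    bubble_class: str  # scarce / abundant
    rg_ratio: float
    cleanliness_class: str  # adequate / inadequate


@dataclass(frozen=True)
class CalibrationResult:
    """Contrast threshold tau with its training-set operating point."""

    tau: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def quantize_grey(rgb: np.ndarray, n_levels: int) -> np.ndarray:
    """Luminance (0.299 R + 0.587 G + 0.114 B) binned into equal-width levels
    over [0, 255]."""
    grey = rgb.astype(float) @ _LUMA
    levels = (grey * n_levels / 256.0).astype(np.intp)
    return np.minimum(levels, n_levels - 1)


def compute_glcm(frame: Frame, params: GlcmParams = GlcmParams()) -> GlcmMatrix:
    """Accumulate the masked GLCM of a frame.

    Pairs are counted only when both pixels lie inside the FOV mask; counts
    are pooled over the requested orientations, symmetrised (transpose
    added) when ``params.symmetric``, and normalised to sum 1.
    """
    levels = quantize_grey(frame.rgb, params.n_levels)
    mask = frame.fov
    h, w = levels.shape
    L = params.n_levels
    counts = np.zeros(L * L, dtype=np.int64)
    n_pairs = 0
    for angle in params.orientations:
        dr0, dc0 = _ANGLE_OFFSETS[angle % 360]
        dr, dc = dr0 * params.distance, dc0 * params.distance
        rs = slice(max(0, -dr), h - max(0, dr))
        cs = slice(max(0, -dc), w - max(0, dc))
        rt = slice(max(0, dr), h + min(0, dr))
        ct = slice(max(0, dc), w + min(0, dc))
        both = mask[rs, cs] & mask[rt, ct]
        i = levels[rs, cs][both]
        j = levels[rt, ct][both]
        if i.size:
            counts += np.bincount(i * L + j, minlength=L * L)
            n_pairs += i.size
    if n_pairs < 2:
        raise ValueError("degenerate field of view: fewer than 2 interior pixel pairs")
    counts = counts.reshape(L, L).astype(float)
    if params.symmetric:
        counts = counts + counts.T
    return GlcmMatrix(p=counts / counts.sum(), params=params, n_pairs=n_pairs)


def glcm_contrast(m: GlcmMatrix | np.ndarray) -> float:
    """Haralick contrast ``sum (i - j)^2 p(i, j)`` of a normalised GLCM."""
    p = m.p if isinstance(m, GlcmMatrix) else np.asarray(m, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"GLCM not normalised (sum = {p.sum():.6g})")
    idx = np.arange(p.shape[0])
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((diff2 * p).sum())


def rg_ratio(frame: Frame) -> float:
    """Mean red over mean green intensity inside the FOV.

    The ratio-of-means form is robust to individual zero-green pixels; it is
    undefined only when the whole FOV has zero mean green (all-black disc).
    """
    if not frame.fov.any():
        raise ValueError("undefined ratio: empty field of view")
    rgb = frame.rgb.astype(float)
    g = rgb[..., 1][frame.fov].mean()
    if g == 0:
        raise ValueError("undefined ratio: zero mean green in field of view")
    return float(rgb[..., 0][frame.fov].mean() / g)


def classify_cleanliness(frame: Frame, threshold: float = RG_THRESHOLD) -> str:
    """``adequate`` iff R/G strictly exceeds the threshold (default 1.6)."""
    return "adequate" if rg_ratio(frame) > threshold else "inadequate"


def classify_bubbles(
    frame: Frame, params: GlcmParams = GlcmParams(), tau: float = 0.0
) -> str:
    """``abundant`` iff the frame's GLCM contrast reaches the threshold tau."""
    return "abundant" if glcm_contrast(compute_glcm(frame, params)) >= tau else "scarce"


def calibrate_from_contrasts(
    contrasts: Sequence[float], labels: Sequence[bool]
) -> CalibrationResult:
    """Choose the contrast cut-off maximising the Youden index.

    Candidate thresholds are midpoints between consecutive distinct contrast
    values (plus open ends); a frame is predicted abundant when its contrast
    is >= tau. Ties in the Youden index break toward the higher threshold,
    i.e. toward higher specificity.
    """
    c = np.asarray(contrasts, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("contrasts and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("calibration set must contain both classes")
    values = np.unique(c)
    candidates = np.concatenate(
        ([values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0])
    )
    best = None
    for tau in candidates:
        pred = c >= tau
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / (y.size - n_pos))
        j = sens + spec - 1.0
        # strict > on J plus ascending candidates -> ties resolve to higher tau
        if best is None or j >= best[0] - 1e-12:
            best = (j, tau, sens, spec)
    return CalibrationResult(tau=best[1], sensitivity=best[2], specificity=best[3])


def calibrate_threshold(
    frames: Iterable[Frame],
    labels: Sequence[bool],
    params: GlcmParams = GlcmParams(),
) -> CalibrationResult:
    """Calibrate tau on labelled frames (True = truly abundant, coverage >= 10%)."""
    contrasts = [glcm_contrast(compute_glcm(f, params)) for f in frames]
    return calibrate_from_contrasts(contrasts, labels)


def score_frame(
    frame: Frame,
    params: GlcmParams = GlcmParams(),
    tau: float = 0.0,
    rg_threshold: float = RG_THRESHOLD,
) -> FrameScore:
    """Both scorers on one frame."""
    contrast = glcm_contrast(compute_glcm(frame, params))
    ratio = rg_ratio(frame)
    return FrameScore(
        contrast=contrast,
        bubble_class="abundant" if contrast >= tau else "scarce",
        rg_ratio=ratio,
        cleanliness_class="adequate" if ratio > rg_threshold else "inadequate",
    )


def score_frames(
    frames: Iterable[Frame],
    params: GlcmParams = GlcmParams(),
    tau: float = 0.0,
    rg_threshold: float = RG_THRESHOLD,
    frame_indices: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Score an iterable of frames into the per-frame table."""
    rows = []
    for k, frame in enumerate(frames):
        s = score_frame(frame, params, tau, rg_threshold)
        rows.append(
            {
                "frame_index": k if frame_indices is None else int(frame_indices[k]),
                "contrast": s.contrast,
                "bubble_class": s.bubble_class,
                "rg_ratio": s.rg_ratio,
                "cleanliness_class": s.cleanliness_class,
            }
        )
    return pd.DataFrame(rows)


def score_video_dir(
    video_dir: str | Path,
    params: GlcmParams = GlcmParams(),
    tau: float = 0.0,
    rg_threshold: float = RG_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Batch-score a video directory of PNG frames with its JSON sidecar.

    Expects ``frame_*.png`` files (zero-padded index order) and
    ``sidecar.json``; returns the per-frame table and the sidecar dict.
    """
    video_dir = Path(video_dir)
    sidecar_path = video_dir / "sidecar.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    paths = sorted(video_dir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {video_dir}")
    frames = (Frame.load_png(p) for p in paths)
    scores = score_frames(frames, params, tau, rg_threshold)
    return scores, sidecar
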