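"""Gaze preprocessing: I-VT fixation detection, ROI sequences, binning.

The raw input is a 60 Hz stream of gaze samples (time in ms, screen
position in pixels, validity flag).  Fixations are detected with the
velocity-threshold method (I-VT): consecutive samples whose angular
velocity stays below a threshold (default 20 deg/s) are merged into one
fixation; fixations shorter than a minimum dwell (default 100 ms) are
discarded.  Angular velocity is derived from pixel displacement through
the screen geometry (physical size, resolution, viewing distance) with
the arctangent small-angle formula.

Each fixation is then assigned to one ROI (see :mod:`gazemine.rois`),
giving a fixation-ROI sequence ``S = s_1 ... s_n``.  To preserve dwell
time in symbolic form each fixation is expanded into
``ceil(dwell / bin_window)`` repeated tokens (default window 150 ms; a
445 ms fixation on ROI ``s`` becomes ``s s s``).  Finally all contiguous
windows of the binned sequence with length in ``[min_len, max_len]`` are
pooled for pattern mining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rois import RoiSet, assign_roi

__all__ = [
    "ScreenGeometry",
    "Fixation",
    "CaseMeta",
    "FixationRoiSequence",
    "BinnedSequence",
    "PreprocessParams",
    "detect_fixations",
    "build_roi_sequence",
    "bin_sequence",
    "enumerate_subsequences",
]

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display setup used to convert pixels to visual angle.

    Defaults describe a 27-inch 1920x1080 monitor viewed from 60 cm.
    """

    diagonal_inches: float = 27.0
    resolution: tuple[int, int] = (1920, 1080)
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        if (
            self.diagonal_inches <= 0
            or self.viewing_distance_cm <= 0
            or min(self.resolution) <= 0
        ):
            raise ValueError("screen geometry values must be strictly positive")

    @property
    def pixel_pitch_cm(self) -> float:
        """Physical size of one (square) pixel in cm."""
        diag_px = math.hypot(*self.resolution)
        return self.diagonal_inches * 2.54 / diag_px

    def pixels_to_degrees(self, pixels: float) -> float:
        """Visual angle in degrees subtended by a pixel displacement."""
        return math.degrees(
            math.atan(pixels * self.pixel_pitch_cm / self.viewing_distance_cm)
        )


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: onset and dwell in ms, centroid in pixels."""

    onset: float
    dwell: float
    centroid: tuple[float, float]
    roi_label: Optional[str] = None


@dataclass(frozen=True)
class CaseMeta:
    case_id: str
    viewer_id: str = ""
    group_id: str = ""
    task_id: str = ""


@dataclass(frozen=True)
class FixationRoiSequence:
    """One viewing case: ordered ROI-labelled fixations."""

    meta: CaseMeta
    fixations: tuple[Fixation, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        """The fixation-ROI sequence ``S = s_1 ... s_n``."""
        return tuple(f.roi_label for f in self.fixations)  # type: ignore[misc]

    @property
    def dwells(self) -> tuple[float, ...]:
        return tuple(f.dwell for f in self.fixations)

    def __len__(self) -> int:
        return len(self.fixations)


@dataclass(frozen=True)
class BinnedSequence:
    """Dwell-preserving token expansion of a fixation-ROI sequence."""

    tokens: tuple[str, ...]
    bin_window: float = 150.0


@dataclass(frozen=True)
class PreprocessParams:
    """Bundle of the preprocessing defaults used across the pipeline."""

    velocity_threshold: float = 20.0  # deg/s
    min_dwell: float = 100.0  # ms
    velocity_window: int = 1  # samples between velocity endpoints
    bin_window: float = 150.0  # ms
    min_len: int = 4  # tokens (= 400 ms at the default window)
    max_len: int = 16


def _as_sample_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples
    else:
        df = pd.DataFrame(list(samples), columns=list(GAZE_COLUMNS))
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze samples missing columns: {missing}")
    return df


def detect_fixations(
    samples,
    geom: ScreenGeometry,
    velocity_threshold: float = 20.0,
    min_dwell: float = 100.0,
    velocity_window: int = 1,
) -> list[Fixation]:
    """I-VT fixation detection.

    Parameters
    ----------
    samples
        DataFrame (or iterable of rows) with columns ``t_ms, x_px, y_px,
        valid``, strictly increasing in time.
    geom
        Screen geometry for the pixel-to-degree conversion.
    velocity_threshold
        Angular velocity cutoff in deg/s; sample gaps at or above it are
        saccadic and split fixation runs.
    min_dwell
        Minimum fixation duration in ms; shorter runs are discarded.
    velocity_window
        Number of samples between the two endpoints of each velocity
        estimate (1 = consecutive samples).

    Returns
    -------
    list of :class:`Fixation`, ordered by onset.  Invalid samples break
    runs; an empty or all-invalid stream yields an empty list.
    """
    df = _as_sample_frame(samples)
    if len(df) == 0:
        return []
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("gaze sample timestamps must be strictly increasing")
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be > 0")
    if velocity_window < 1:
        raise ValueError("velocity_window must be >= 1")
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool)

    n = len(t)
    w = velocity_window
    # fixational[i] is True when the gap from sample i to sample i+w is slow
    # and every sample it spans is valid.
    fixational = np.zeros(max(n - w, 0), dtype=bool)
    if n > w:
        dist_px = np.hypot(x[w:] - x[:-w], y[w:] - y[:-w])
        dt_s = (t[w:] - t[:-w]) / 1000.0
        deg = np.degrees(np.arctan(dist_px * geom.pixel_pitch_cm / geom.viewing_distance_cm))
        vel = deg / dt_s
        span_valid = np.ones(n - w, dtype=bool)
        for k in range(w + 1):
            span_valid &= valid[k : n - w + k]
        fixational = (vel < velocity_threshold) & span_valid

    # A fixation is a maximal run of consecutive fixational gaps i..j-1,
    # covering samples i..(j-1)+w.
    fixations: list[Fixation] = []
    i = 0
    while i < len(fixational):
        if not fixational[i]:
            i += 1
            continue
        j = i
        while j < len(fixational) and fixational[j]:
            j += 1
        end = j - 1 + w
        dwell = t[end] - t[i]
        if dwell >= min_dwell:
            members = slice(i, end + 1)
            fixations.append(
                Fixation(
                    onset=float(t[i]),
                    dwell=float(dwell),
                    centroid=(float(x[members].mean()), float(y[members].mean())),
                )
            )
        i = j + 1
    return fixations


def build_roi_sequence(
    fixations: Sequence[Fixation], rois: RoiSet, meta: CaseMeta
) -> FixationRoiSequence:
    """Assign each fixation to an ROI and return the labelled sequence."""
    assigned = tuple(
        replace(f, roi_label=assign_roi(f.centroid, rois)) for f in fixations
    )
    return FixationRoiSequence(meta=meta, fixations=assigned)


def bin_sequence(seq: FixationRoiSequence, bin_window: float = 150.0) -> BinnedSequence:
    """Expand each fixation into ``ceil(dwell / bin_window)`` repeated tokens."""
    if bin_window <= 0:
        raise ValueError("bin_window must be > 0")
    tokens: list[str] = []
    for f in seq.fixations:
        k = max(1, math.ceil(f.dwell / bin_window))
        tokens.extend([f.roi_label] * k)  # type: ignore[list-item]
    return BinnedSequence(tokens=tuple(tokens), bin_window=bin_window)


def enumerate_subsequences(
    binned: BinnedSequence, min_len: int = 4, max_len: int = 16
) -> frozenset[tuple[str, ...]]:
    """All distinct contiguous token windows with length in [min_len, max_len].

    Duplicate windows within one case are collapsed (set semantics); a
    sequence shorter than ``min_len`` yields the empty pool.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    toks = binned.tokens
    pool: set[tuple[str, ...]] = set()
    for length in range(min_len, min(max_len, len(toks)) + 1):
        for start in range(len(toks) - length + 1):
            pool.add(toks[start : start + length])
    return frozenset(pool)
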