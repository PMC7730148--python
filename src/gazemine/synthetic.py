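"""Synthetic ROI layouts, gaze sessions and multi-group case libraries.

The generator emulates the study conditions the rest of the package is
designed for: 15-second viewing sessions sampled at 60 Hz on a 27-inch
display at 60 cm, over an expert-annotated polygon layout.  Each group's
behaviour is a :class:`StrategyProfile`: a categorical distribution of
ROI visits, lognormal per-ROI dwells, occasional stray fixations, and
*planted* token subsequences inserted with a per-case inclusion
probability.  Planted runs are the ground truth for pattern-recovery
experiments: their dwells are chosen to bin deterministically to the
planted token counts ((k - 0.5) x bin_window for k >= 2 tokens, the
midpoint of the one-token bin otherwise), and saccades are realized as
fast linear sweeps so that I-VT detection segments fixations cleanly.
When two planned fixation targets are too close for a detectable
saccade, a single invalid (blink-like) sample is emitted between them,
which splits the fixation runs conservatively.

Determinism: every case derives its own RNG stream from
``SeedSequence(entropy=(master_seed, group_index, case_index))``, so a
case regenerates identically regardless of library size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocessing import CaseMeta, ScreenGeometry
from .rois import Roi, RoiSet

__all__ = [
    "StrategyProfile",
    "LibraryCase",
    "CaseLibrary",
    "generate_roi_layout",
    "generate_session",
    "generate_library",
    "planted_contrast_profiles",
    "distinct_strategy_profiles",
    "identical_strategy_profiles",
]


@dataclass(frozen=True)
class StrategyProfile:
    """Generative description of one viewer group's strategy."""

    group_id: str
    roi_visit_distribution: dict[str, float]
    planted_subsequences: tuple[tuple[tuple[str, ...], float], ...] = ()
    dwell_mean_ms: float = 420.0
    dwell_cv: float = 0.45
    stray_fixation_rate: float = 0.05
    saccade_speed: float = 250.0  # deg/s

    def __post_init__(self) -> None:
        probs = np.array(list(self.roi_visit_distribution.values()), dtype=float)
        if len(probs) == 0 or probs.min() < 0 or probs.sum() <= 0:
            raise ValueError("roi_visit_distribution must be a non-trivial categorical")
        for _, p in self.planted_subsequences:
            if not 0 <= p <= 1:
                raise ValueError("planted inclusion probabilities must be in [0, 1]")


def generate_roi_layout(
    n_rois: int,
    image_size: tuple[int, int] = (1920, 1080),
    overlap_fraction: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> RoiSet:
    """Random rectangular ROI layout, deterministic given the seed.

    ROIs are placed in separate grid cells with margins, so distinct
    cells never intersect.  Overlaps are created by nesting: a fraction
    ``overlap_fraction`` of the ``n_rois // 2`` disjoint ROI pairs is
    realized as a small rectangle strictly inside a larger one, which
    exercises the minimal-area assignment rule.  The number of
    intersecting pairs is exactly ``round(overlap_fraction * (n_rois // 2))``.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    w, h = image_size
    ncols = math.ceil(math.sqrt(n_rois))
    nrows = math.ceil(n_rois / ncols)
    cell_w, cell_h = w / ncols, h / nrows
    if min(cell_w, cell_h) < 40:
        raise ValueError("image too small to pack the requested number of ROIs")

    n_pairs = round(overlap_fraction * (n_rois // 2))
    nested_children = {2 * k + 1: 2 * k for k in range(n_pairs)}

    def rect(x0: float, y0: float, x1: float, y1: float) -> tuple:
        return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))

    boxes: list[tuple[float, float, float, float]] = []
    rois = []
    for i in range(n_rois):
        label = f"R{i + 1:02d}"
        if i in nested_children:
            px0, py0, px1, py1 = boxes[nested_children[i]]
            pw, ph = px1 - px0, py1 - py0
            bw = rng.uniform(0.25, 0.4) * pw
            bh = rng.uniform(0.25, 0.4) * ph
            x0 = rng.uniform(px0 + 0.1 * pw, px1 - 0.1 * pw - bw)
            y0 = rng.uniform(py0 + 0.1 * ph, py1 - 0.1 * ph - bh)
        else:
            col, row = i % ncols, i // ncols
            cx0, cy0 = col * cell_w, row * cell_h
            bw = rng.uniform(0.45, 0.7) * cell_w
            bh = rng.uniform(0.45, 0.7) * cell_h
            x0 = rng.uniform(cx0 + 0.08 * cell_w, cx0 + 0.92 * cell_w - bw)
            y0 = rng.uniform(cy0 + 0.08 * cell_h, cy0 + 0.92 * cell_h - bh)
        boxes.append((x0, y0, x0 + bw, y0 + bh))
        rois.append(Roi(label=label, vertices=rect(x0, y0, x0 + bw, y0 + bh)))
    return RoiSet(rois)


@dataclass
class _PlannedFix:
    point: tuple[float, float]
    dwell_ms: float
    planted_id: int = -1  # index into the planted block list, -1 = filler/stray


def _planted_dwell(k_tokens: int, bin_window: float, min_dwell: float) -> float:
    """Dwell that robustly bins to exactly ``k_tokens`` and passes min_dwell."""
    if k_tokens == 1:
        return (min_dwell + bin_window) / 2.0
    return (k_tokens - 0.5) * bin_window


def _runs(tokens: Sequence[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for tok in tokens:
        if runs and runs[-1][0] == tok:
            runs[-1] = (tok, runs[-1][1] + 1)
        else:
            runs.append((tok, 1))
    return runs


def _generate_session(
    profile: StrategyProfile,
    layout: RoiSet,
    duration_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    geom: ScreenGeometry,
    min_dwell: float,
    bin_window: float,
    velocity_threshold: float,
    image_size: tuple[int, int],
) -> tuple[pd.DataFrame, list[tuple[str, ...]]]:
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be > 0")
    dt = 1000.0 / rate_hz
    n_samples = round(duration_s * rate_hz)
    total_ms = duration_s * 1000.0
    saccade_overhead_ms = 3 * dt  # planning estimate per fixation

    anchor = {
        roi.label: (roi.polygon.representative_point().x, roi.polygon.representative_point().y)
        for roi in layout
    }
    labels = list(profile.roi_visit_distribution)
    probs = np.array([profile.roi_visit_distribution[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    # lognormal dwell parameters from mean and coefficient of variation
    sigma2 = math.log(1.0 + profile.dwell_cv**2)
    mu = math.log(profile.dwell_mean_ms) - sigma2 / 2.0

    def filler() -> _PlannedFix:
        if rng.random() < profile.stray_fixation_rate:
            pt = (rng.uniform(0, image_size[0]), rng.uniform(0, image_size[1]))
            return _PlannedFix(pt, rng.uniform(min_dwell + 10, min_dwell + 60))
        lab = labels[rng.choice(len(labels), p=probs)]
        dwell = float(np.clip(rng.lognormal(mu, math.sqrt(sigma2)), min_dwell + 25, 2500))
        return _PlannedFix(anchor[lab], dwell)

    fillers: list[_PlannedFix] = []
    budget = 0.0
    while budget < total_ms * 1.4:
        f = filler()
        fillers.append(f)
        budget += f.dwell_ms + saccade_overhead_ms

    # plant token blocks at filler positions guaranteed to be fully realized;
    # blocks are spliced between fillers so each stays contiguous
    block_tokens: list[tuple[str, ...]] = []
    inserts: dict[int, list[list[_PlannedFix]]] = {}
    cum = np.cumsum([f.dwell_ms + saccade_overhead_ms for f in fillers])
    for tokens, incl_prob in profile.planted_subsequences:
        if rng.random() >= incl_prob:
            continue
        block_id = len(block_tokens)
        block = [
            _PlannedFix(anchor[lab], _planted_dwell(k, bin_window, min_dwell), block_id)
            for lab, k in _runs(tokens)
        ]
        block_tokens.append(tuple(tokens))
        block_ms = sum(f.dwell_ms + saccade_overhead_ms for f in block)
        eligible = int(np.searchsorted(cum, total_ms - block_ms - 1500.0))
        idx = int(rng.integers(0, max(eligible, 1)))
        inserts.setdefault(idx, []).append(block)
    plan: list[_PlannedFix] = []
    for i, f in enumerate(fillers):
        for block in inserts.get(i, []):
            plan.extend(block)
        plan.append(f)

    min_saccade_px = (
        math.tan(math.radians(1.6 * velocity_threshold * dt / 1000.0))
        * geom.viewing_distance_cm
        / geom.pixel_pitch_cm
    )

    t: list[float] = []
    x: list[float] = []
    y: list[float] = []
    valid: list[bool] = []
    realized: dict[int, bool] = {}

    def emit(px: float, py: float, ok: bool = True) -> None:
        t.append(len(t) * dt)
        x.append(px)
        y.append(py)
        valid.append(ok)

    prev: Optional[tuple[float, float]] = None
    for fix in plan:
        if len(t) >= n_samples:
            break
        px, py = fix.point
        if prev is not None:
            dist = math.hypot(px - prev[0], py - prev[1])
            if dist < min_saccade_px:
                emit(prev[0], prev[1], ok=False)  # blink-like break
            else:
                deg = math.degrees(
                    math.atan(dist * geom.pixel_pitch_cm / geom.viewing_distance_cm)
                )
                steps = round(deg / (profile.saccade_speed * dt / 1000.0))
                # keep per-sample spacing above the saccadic minimum:
                # spacing = dist/(steps+1) >= min_saccade_px
                steps = max(0, min(steps, int(dist / min_saccade_px) - 1))
                for s in range(1, steps + 1):
                    frac = s / (steps + 1)
                    emit(prev[0] + frac * (px - prev[0]), prev[1] + frac * (py - prev[1]))
        n_fix = int(round(fix.dwell_ms / dt)) + 1
        complete = len(t) + n_fix <= n_samples
        for _ in range(n_fix):
            if len(t) >= n_samples:
                break
            emit(px + rng.normal(0, 1.2), py + rng.normal(0, 1.2))
        if fix.planted_id >= 0:
            realized[fix.planted_id] = realized.get(fix.planted_id, True) and complete
        prev = (px, py)

    while len(t) < n_samples:  # pad at the final position (plan exhausted)
        emit(x[-1] + rng.normal(0, 1.2), y[-1] + rng.normal(0, 1.2))

    df = pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "valid": valid})
    planted_tokens = [
        tokens for bid, tokens in enumerate(block_tokens) if realized.get(bid, False)
    ]
    return df, planted_tokens


def generate_session(
    profile: StrategyProfile,
    layout: RoiSet,
    duration_s: float = 15.0,
    rate_hz: float = 60.0,
    seed: int | np.random.SeedSequence = 0,
    geom: ScreenGeometry = ScreenGeometry(),
    min_dwell: float = 100.0,
    bin_window: float = 150.0,
    velocity_threshold: float = 20.0,
    image_size: tuple[int, int] = (1920, 1080),
) -> pd.DataFrame:
    """Generate one raw gaze session (``duration_s * rate_hz`` samples)."""
    rng = np.random.default_rng(seed)
    df, _ = _generate_session(
        profile, layout, duration_s, rate_hz, rng, geom, min_dwell, bin_window,
        velocity_threshold, image_size,
    )
    return df


@dataclass(frozen=True)
class LibraryCase:
    meta: CaseMeta
    samples: pd.DataFrame
    planted: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class CaseLibrary:
    layout: RoiSet
    cases: tuple[LibraryCase, ...]
    geom: ScreenGeometry

    def group_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.meta.group_id for c in self.cases))


def generate_library(
    profiles: Sequence[StrategyProfile],
    layout: RoiSet,
    cases_per_group: int = 12,
    seed: int = 0,
    duration_s: float = 15.0,
    rate_hz: float = 60.0,
    geom: ScreenGeometry = ScreenGeometry(),
    min_dwell: float = 100.0,
    bin_window: float = 150.0,
    velocity_threshold: float = 20.0,
    image_size: tuple[int, int] = (1920, 1080),
    task_id: str = "T1",
    out_dir: Optional[str | Path] = None,
) -> CaseLibrary:
    """Generate a multi-group case library; optionally write it to disk.

    When ``out_dir`` is given the library is written as one gaze CSV per
    case, an ROI JSON, a case manifest, and a ``ground_truth.json``
    sidecar listing the planted token sequences realized in each case.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one strategy profile")
    cases: list[LibraryCase] = []
    for gi, profile in enumerate(profiles):
        for ci in range(cases_per_group):
            ss = np.random.SeedSequence(entropy=(int(seed), gi, ci))
            rng = np.random.default_rng(ss)
            df, planted = _generate_session(
                profile, layout, duration_s, rate_hz, rng, geom, min_dwell,
                bin_window, velocity_threshold, image_size,
            )
            meta = CaseMeta(
                case_id=f"{profile.group_id}_{ci:03d}",
                viewer_id=f"{profile.group_id}_v{ci:03d}",
                group_id=profile.group_id,
                task_id=task_id,
            )
            cases.append(LibraryCase(meta=meta, samples=df, planted=tuple(planted)))
    library = CaseLibrary(layout=layout, cases=tuple(cases), geom=geom)
    if out_dir is not None:
        _write_library(library, Path(out_dir))
    return library


def _write_library(library: CaseLibrary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    library.layout.to_json(out_dir / "rois.json")
    manifest: dict[str, dict] = {}
    truth: dict[str, list[list[str]]] = {}
    for case in library.cases:
        fname = f"{case.meta.case_id}.csv"
        case.samples.to_csv(out_dir / fname, index=False, float_format="%.4f")
        manifest[case.meta.case_id] = {
            "gaze_file": fname,
            "roi_file": "rois.json",
            "viewer_id": case.meta.viewer_id,
            "group": case.meta.group_id,
            "task": case.meta.task_id,
        }
        truth[case.meta.case_id] = [list(p) for p in case.planted]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# Canned study conditions


def planted_contrast_profiles(
    layout: RoiSet,
    planted: tuple[str, ...] = ("R07", "R07", "R07", "R08", "R08", "R08"),
    inclusion: float = 0.8,
) -> tuple[StrategyProfile, StrategyProfile]:
    """Two groups with identical filler behaviour; group 1 additionally
    carries a planted contrast pattern over ROIs the second group never
    deliberately visits (so the pattern has no similar match there)."""
    planted_labels = set(planted)
    filler = [l for l in layout.labels if l not in planted_labels]
    dist = {l: 1.0 / len(filler) for l in filler}
    return (
        StrategyProfile(
            group_id="expert",
            roi_visit_distribution=dist,
            planted_subsequences=((planted, inclusion),),
        ),
        StrategyProfile(group_id="novice", roi_visit_distribution=dist),
    )


def distinct_strategy_profiles(layout: RoiSet) -> tuple[StrategyProfile, StrategyProfile]:
    """Two clearly different strategies: disjoint ROI focus and dwell scale."""
    labels = layout.labels
    half = max(1, len(labels) // 2)
    focus1, focus2 = labels[:half], labels[half:] or labels[:half]
    d1 = {l: (0.9 / len(focus1) if l in focus1 else 0.1 / max(len(labels) - len(focus1), 1)) for l in labels}
    d2 = {l: (0.9 / len(focus2) if l in focus2 else 0.1 / max(len(labels) - len(focus2), 1)) for l in labels}
    return (
        StrategyProfile(group_id="expert", roi_visit_distribution=d1, dwell_mean_ms=550.0),
        StrategyProfile(group_id="novice", roi_visit_distribution=d2, dwell_mean_ms=320.0),
    )


def identical_strategy_profiles(layout: RoiSet) -> tuple[StrategyProfile, StrategyProfile]:
    """Two groups drawn from one strategy (the null condition)."""
    dist = {l: 1.0 / len(layout.labels) for l in layout.labels}
    return (
        StrategyProfile(group_id="expert", roi_visit_distribution=dist),
        StrategyProfile(group_id="novice", roi_visit_distribution=dist),
    )
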