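"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import math

import pandas as pd
import pytest

from gazemine import CaseMeta, Fixation, FixationRoiSequence, Roi, RoiSet, ScreenGeometry

DT_MS = 1000.0 / 60.0  # 60 Hz sample period


@pytest.fixture
def geom() -> ScreenGeometry:
    return ScreenGeometry()


def square_roi(label: str, x0: float, y0: float, size: float, **kw) -> Roi:
    return Roi(
        label=label,
        vertices=((x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)),
        **kw,
    )


@pytest.fixture
def simple_rois() -> RoiSet:
    """Three disjoint squares plus a small square nested in the first."""
    return RoiSet(
        [
            square_roi("A", 0, 0, 400),
            square_roi("B", 600, 0, 300),
            square_roi("C", 0, 600, 300),
            square_roi("N", 100, 100, 80),  # nested inside A
        ]
    )


def samples_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["t_ms", "x_px", "y_px", "valid"])


def trace(points, start_t: float = 0.0, dt: float = DT_MS) -> pd.DataFrame:
    """Build a gaze trace from (x, y, n_samples) stationary clusters,
    joined by direct jumps (one fast gap between clusters)."""
    rows = []
    t = start_t
    for x, y, n in points:
        for _ in range(n):
            rows.append((t, x, y, True))
            t += dt
    return samples_frame(rows)


def roi_sequence(spec, case_id: str = "case", group: str = "g") -> FixationRoiSequence:
    """Build a FixationRoiSequence from (label, dwell_ms) pairs directly."""
    fixations = []
    t = 0.0
    for label, dwell in spec:
        fixations.append(
            Fixation(onset=t, dwell=float(dwell), centroid=(0.0, 0.0), roi_label=label)
        )
        t += dwell + 30.0
    return FixationRoiSequence(
        meta=CaseMeta(case_id=case_id, group_id=group, task_id="T1"),
        fixations=tuple(fixations),
    )


def angular_velocity_oracle(
    x0: float, y0: float, x1: float, y1: float, dt_ms: float, geom: ScreenGeometry
) -> float:
    """Brute-force trigonometric per-sample angular velocity in deg/s."""
    diag_px = math.sqrt(geom.resolution[0] ** 2 + geom.resolution[1] ** 2)
    cm_per_px = geom.diagonal_inches * 2.54 / diag_px
    dist_cm = math.hypot(x1 - x0, y1 - y0) * cm_per_px
    angle_deg = math.degrees(math.atan(dist_cm / geom.viewing_distance_cm))
    return angle_deg / (dt_ms / 1000.0)
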