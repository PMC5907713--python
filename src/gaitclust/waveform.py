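"""Step segmentation, time normalization and the standardized feature matrix.

Each step cycle (foot strike to next foot strike) is split into stance and
flight, linearly resampled to 80 + 20 points, averaged over steps, and the
three axes (VT, AP, ML) concatenated into a 300-dimensional vector per
subject.  The subject-by-300 matrix is z-scored per column across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AXES, RunConfig
from .io_formats import EventTable
from .kinematics import AccelerationSeries

logger = logging.getLogger(__name__)


@dataclass
class StepWaveform:
    """Per-subject step-averaged local acceleration, 3 x 100 (VT, AP, ML rows)."""

    subject_id: str
    axes: np.ndarray
    n_steps_averaged: int
    stance_points: int = 80
    flight_points: int = 20

    def __post_init__(self) -> None:
        n = self.stance_points + self.flight_points
        if self.axes.shape != (3, n):
            raise ValueError(f"axes must be 3 x {n}, got {self.axes.shape}")
        if self.n_steps_averaged < 1:
            raise ValueError("n_steps_averaged must be >= 1")
        if not np.isfinite(self.axes).all():
            raise ValueError("waveform contains non-finite values")

    @property
    def phase_grid(self) -> np.ndarray:
        """Cycle fractions of the 100 columns (stance = 0..79, flight = 80..99)."""
        n = self.stance_points + self.flight_points
        return np.arange(n) / n


@dataclass
class FeatureMatrix:
    """n-subjects x 300 waveform matrix with its standardization and index map."""

    subjects: list[str]
    X_raw: np.ndarray
    X_std: np.ndarray
    column_map: list[tuple[str, int]]
    column_means: np.ndarray
    column_sds: np.ndarray
    zero_variance: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def axis_columns(self, axis: str) -> np.ndarray:
        return np.array([i for i, (a, _) in enumerate(self.column_map) if a == axis])

    def subset(self, subject_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Rows of (X_raw, X_std) for the given ids, in the given order."""
        index = {s: i for i, s in enumerate(self.subjects)}
        rows = np.array([index[s] for s in subject_ids])
        return self.X_raw[rows], self.X_std[rows]

    def to_csv(self, path) -> None:
        cols = [f"{a}_{p:03d}" for a, p in self.column_map]
        df = pd.DataFrame(self.X_raw, columns=cols)
        df.insert(0, "subject_id", self.subjects)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        subjects = [str(s) for s in df.pop("subject_id")]
        column_map = []
        for c in df.columns:
            axis, point = c.rsplit("_", 1)
            column_map.append((axis, int(point)))
        return _assemble(subjects, df.to_numpy(float), column_map)


def segment_steps(
    acc_local: AccelerationSeries, events: EventTable
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split the local acceleration into per-step (stance, flight) segments.

    Stance = [strike, toe_off), flight = [toe_off, next_strike).  Steps
    overlapping the invalid edge regions are dropped (and counted in the
    log).  Raises if no usable step remains.
    """
    sl = acc_local.valid_slice
    lo, hi = sl.start, sl.stop
    out = []
    dropped = 0
    for _, row in events.data.iterrows():
        s = int(row["foot_strike_frame"])
        t = int(row["toe_off_frame"])
        nxt = int(row["next_strike_frame"])
        if s < lo or nxt > hi:
            dropped += 1
            continue
        out.append((acc_local.data[s:t], acc_local.data[t:nxt]))
    if dropped:
        logger.info("segment_steps: dropped %d step(s) in invalid edge regions", dropped)
    if not out:
        raise ValueError("zero usable steps after edge trimming")
    return out


def time_normalize(
    step: tuple[np.ndarray, np.ndarray], stance_points: int = 80, flight_points: int = 20
) -> np.ndarray:
    """Resample one step to (stance_points + flight_points) samples per axis.

    Each phase is linearly interpolated on its own closed-endpoint grid and
    the two phases concatenated; returns (n_points, n_axes).
    """
    stance, flight = step
    stance = np.atleast_2d(np.asarray(stance, float))
    flight = np.atleast_2d(np.asarray(flight, float))
    if stance.shape[0] < 2 or flight.shape[0] < 2:
        raise ValueError(
            f"degenerate phase: stance has {stance.shape[0]} and flight "
            f"{flight.shape[0]} samples (need >= 2 each)"
        )

    def resample(seg: np.ndarray, n_out: int) -> np.ndarray:
        src = np.arange(seg.shape[0], dtype=float)
        dst = np.linspace(0.0, seg.shape[0] - 1.0, n_out)
        return np.stack(
            [np.interp(dst, src, seg[:, j]) for j in range(seg.shape[1])], axis=-1
        )

    return np.vstack([resample(stance, stance_points), resample(flight, flight_points)])


def average_steps(
    normalized_steps: list[np.ndarray],
    subject_id: str = "",
    stance_points: int = 80,
    flight_points: int = 20,
) -> StepWaveform:
    """Element-wise mean over steps; input segments are (n_points, 3) in lab
    axis order (AP, ML, VT), output rows are ordered (VT, AP, ML)."""
    if not normalized_steps:
        raise ValueError("need at least one step")
    mean = np.mean(np.stack(normalized_steps), axis=0)  # (n_points, 3) lab order
    axes = mean[:, [2, 0, 1]].T  # rows VT, AP, ML
    return StepWaveform(
        subject_id=subject_id,
        axes=axes,
        n_steps_averaged=len(normalized_steps),
        stance_points=stance_points,
        flight_points=flight_points,
    )


def build_feature_matrix(waveforms: list[StepWaveform]) -> FeatureMatrix:
    """Stack per-subject waveforms into the standardized feature matrix.

    Row order follows input order; columns are VT[0..n), AP[0..n), ML[0..n).
    Zero-variance columns are flagged and left unscaled (centred only).
    """
    if len(waveforms) < 2:
        raise ValueError("need at least 2 subjects")
    ids = [w.subject_id for w in waveforms]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dup}")
    n_pts = waveforms[0].axes.shape[1]
    if any(w.axes.shape[1] != n_pts for w in waveforms):
        raise ValueError("inconsistent waveform grids")
    X_raw = np.stack([w.axes.reshape(-1) for w in waveforms])
    column_map = [(axis, p) for axis in AXES for p in range(n_pts)]
    return _assemble(ids, X_raw, column_map)


def _assemble(
    subjects: list[str], X_raw: np.ndarray, column_map: list[tuple[str, int]]
) -> FeatureMatrix:
    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0, ddof=1)
    zero_var = sds < 1e-12
    if zero_var.any():
        logger.info("feature matrix: %d zero-variance column(s)", int(zero_var.sum()))
    safe = np.where(zero_var, 1.0, sds)
    X_std = (X_raw - means) / safe
    return FeatureMatrix(
        subjects=list(subjects),
        X_raw=X_raw,
        X_std=X_std,
        column_map=column_map,
        column_means=means,
        column_sds=sds,
        zero_variance=zero_var,
    )
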