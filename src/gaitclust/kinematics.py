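"""Pelvic kinematics from marker-cluster trajectories.

Derives local-frame pelvic acceleration by double Savitzky-Golay
differentiation of the cluster centroid, expressed in the segment frame via
per-frame rigid-body (Kabsch) pose estimation against the static trial.
Positions are millimetres, accelerations m/s^2, lab axes (x=AP, y=ML, z=VT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .config import RunConfig
from .io_formats import EventTable, TrajectoryTable

logger = logging.getLogger(__name__)


@dataclass
class RigidPose:
    """Least-squares rigid transform (rotation local->global, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")


@dataclass
class AccelerationSeries:
    """Acceleration samples (m/s^2) with an edge-validity mask.

    ``data`` columns follow lab order (x=AP, y=ML, z=VT); ``frame_label``
    records whether values are expressed in the global or pelvic-local frame.
    Samples within one differentiation window of either end are invalid
    (NaN) and excluded downstream rather than padded.
    """

    time: np.ndarray
    data: np.ndarray
    frame_label: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_label not in ("global", "local"):
            raise ValueError("frame_label must be 'global' or 'local'")
        if not np.isfinite(self.data[self.valid]).all():
            raise ValueError("non-finite values inside the valid region")

    @property
    def valid_slice(self) -> slice:
        idx = np.flatnonzero(self.valid)
        if len(idx) == 0:
            raise ValueError("no valid samples")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def pelvic_centroid(dynamic: TrajectoryTable) -> np.ndarray:
    """Per-frame unweighted mean of the cluster markers, (n_frames, 3) mm."""
    pos = dynamic.positions()
    if not np.isfinite(pos).all():
        bad = int(np.argwhere(~np.isfinite(pos).all(axis=(1, 2)))[0])
        raise ValueError(f"missing/non-finite marker data at frame index {bad}")
    return pos.mean(axis=1)


def sg_derivative(
    signal: np.ndarray, dt: float, window: int = 11, order: int = 4
) -> np.ndarray:
    """Savitzky-Golay first derivative: a sliding local polynomial fit whose
    analytic derivative is evaluated at the window centre.

    Odd windows evaluate at the centre sample; even windows at the mid-point
    between the two central samples (half-sample timing shift, reported at
    the lower index).  A half-window at each edge is returned as NaN.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    if n < window:
        raise ValueError(f"signal length {n} shorter than window {window}")
    pos = (window - 1) / 2.0
    coeffs = savgol_coeffs(window, order, deriv=1, delta=dt, pos=pos, use="conv")

    def one(x: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        valid = np.convolve(x, coeffs, mode="valid")
        off = (window - 1) // 2
        out[off : off + len(valid)] = valid
        return out

    if signal.ndim == 1:
        return one(signal)
    return np.stack([one(signal[:, j]) for j in range(signal.shape[1])], axis=-1)


def double_differentiate(
    position_mm: np.ndarray, dt: float, cfg: RunConfig | None = None
) -> AccelerationSeries:
    """Two sequential SG derivative passes: mm positions -> m/s^2 acceleration."""
    cfg = cfg or RunConfig()
    pos_m = np.asarray(position_mm, dtype=float) * 1e-3
    vel = sg_derivative(pos_m, dt, cfg.sg_window, cfg.sg_order)
    acc = np.where(np.isfinite(vel), vel, 0.0)
    acc = sg_derivative(acc, dt, cfg.sg_window, cfg.sg_order)
    n = acc.shape[0]
    # one full window invalid per pass
    edge = 2 * ((cfg.sg_window - 1) // 2 + 1)
    valid = np.zeros(n, dtype=bool)
    if n > 2 * edge:
        valid[edge : n - edge] = True
    acc[~valid] = np.nan
    time = np.arange(n) * dt
    return AccelerationSeries(time=time, data=acc, frame_label="global", valid=valid)


def estimate_pose(frame_markers: np.ndarray, static_markers: np.ndarray) -> RigidPose:
    """Orthogonal-Procrustes rigid fit of the static (local) marker shape onto
    one frame's markers, with reflection correction."""
    X = np.asarray(static_markers, float)
    Y = np.asarray(frame_markers, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 markers")
    R, t, res = _kabsch(X, Y)
    return RigidPose(rotation=R, translation=t, residual=res)


def _kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    sv = np.linalg.svd(X0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) marker configuration")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    res = float(np.sqrt(np.mean(np.sum((Y - (X @ R.T + t)) ** 2, axis=1))))
    return R, t, res


def pose_series(dynamic_positions: np.ndarray, static_markers: np.ndarray) -> np.ndarray:
    """Vectorized per-frame rotations (n_frames, 3, 3), local -> global."""
    X = np.asarray(static_markers, float)
    X0 = X - X.mean(axis=0)
    sv = np.linalg.svd(X0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) marker configuration")
    Y = np.asarray(dynamic_positions, float)
    Y0 = Y - Y.mean(axis=1, keepdims=True)
    H = np.einsum("mi,nmj->nij", X0, Y0)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("nij,nkj->nik", Vt, U)))  # det(V U^T)
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)  # V D U^T per frame
    return R


def global_to_local(
    acc: AccelerationSeries,
    dynamic: TrajectoryTable | np.ndarray,
    static: TrajectoryTable | np.ndarray,
) -> AccelerationSeries:
    """Rotate global-frame acceleration into the pelvic segment frame.

    The local frame coincides with the lab frame during the static trial,
    so each sample is premultiplied by the transpose of that frame's
    estimated rotation.
    """
    if acc.frame_label != "global":
        raise ValueError("input series must be in the global frame")
    dyn_pos = dynamic.positions() if isinstance(dynamic, TrajectoryTable) else dynamic
    stat_pos = static.positions() if isinstance(static, TrajectoryTable) else static
    if stat_pos.ndim == 3:
        stat_pos = stat_pos.mean(axis=0)
    if dyn_pos.shape[0] != acc.data.shape[0]:
        raise ValueError("acceleration and trajectory frame counts differ")
    R = pose_series(dyn_pos, stat_pos)
    data = np.einsum("nji,nj->ni", R, np.nan_to_num(acc.data))
    data[~acc.valid] = np.nan
    return AccelerationSeries(
        time=acc.time, data=data, frame_label="local", valid=acc.valid.copy()
    )


def detect_events(
    acc_local: AccelerationSeries,
    cfg: RunConfig | None = None,
    stance_fraction: float = 0.65,
    events: EventTable | None = None,
) -> EventTable:
    """Surrogate foot-strike detector on the vertical local acceleration.

    If ``events`` is given it is returned unchanged (external events take
    precedence).  Otherwise strikes are placed at the steepest VT-acceleration
    rise preceding each prominent VT peak; peaks must be separated by at
    least 0.4x the cadence period estimated from the VT power spectrum.
    Toe-offs are placed at ``stance_fraction`` of each strike-to-strike
    interval.  Each event gets a prominence-based confidence score.
    """
    if events is not None:
        return events
    cfg = cfg or RunConfig()
    sl = acc_local.valid_slice
    vt = acc_local.data[sl, 2]
    dt = float(acc_local.time[1] - acc_local.time[0])
    if len(vt) * dt < 3.0:
        raise ValueError("need at least 3 s of valid signal for event detection")

    x = vt - vt.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    freqs = np.fft.rfftfreq(len(x), dt)
    band = (freqs >= 1.0) & (freqs <= 5.0)
    if not band.any() or spec[band].max() < 10.0 * np.median(spec[freqs > 0.5]):
        raise ValueError("no periodic structure found in vertical acceleration")
    f0 = float(freqs[band][np.argmax(spec[band])])
    period_frames = 1.0 / f0 / dt

    vs = savgol_filter(vt, 9, 2)
    slope = savgol_filter(vt, 9, 2, deriv=1)
    prominence = 0.5 * float(np.std(vs))
    peaks, props = find_peaks(
        vs, distance=max(1, int(0.4 * period_frames)), prominence=prominence
    )
    if len(peaks) < 4:
        raise ValueError("too few acceleration peaks: no periodic gait detected")

    # initial contact ~ the first strong acceleration rise after the flight
    # trough preceding each peak (the impact transient precedes the active
    # peak, so the earliest steep rise marks touchdown)
    back = max(2, int(0.6 * period_frames))
    strikes = []
    for i, p in enumerate(peaks):
        lo = max(0, p - back)
        if i > 0:
            lo = max(lo, int(peaks[i - 1]))
        if p - lo < 3:
            continue
        trough = lo + int(np.argmin(vs[lo:p]))
        if p - trough < 3:
            continue
        win = slope[trough:p]
        cand, _ = find_peaks(win, height=0.5 * float(win.max()))
        idx = int(cand[0]) if len(cand) else int(np.argmax(win))
        strikes.append(trough + idx)
    strikes = np.asarray(sorted(set(strikes)), dtype=int)
    if len(strikes) < 2:
        raise ValueError("could not localize enough foot strikes")
    strikes = _refine_by_template(vt, strikes)

    s0, s1 = strikes[:-1], strikes[1:]
    toe = np.round(s0 + stance_fraction * (s1 - s0)).astype(int)
    offset = sl.start
    table = EventTable.from_arrays(s0 + offset, toe + offset, s1 + offset)
    prom = props["prominences"]
    table.confidence = np.clip(prom[: len(s0)] / (2 * prominence), 0.0, 1.0)
    return table


def _refine_by_template(
    vt: np.ndarray, strikes: np.ndarray, max_shift: int = 4, n_iter: int = 2
) -> np.ndarray:
    """Align each strike to the subject's average step cycle.

    Averaging the strike-anchored cycles gives a near-noise-free template;
    shifting each strike (within +-max_shift samples) to the best
    template match suppresses per-cycle noise jitter.
    """
    for _ in range(n_iter):
        if len(strikes) < 4:
            return strikes
        L = int(np.median(np.diff(strikes)))
        segs = [vt[s : s + L] for s in strikes if s + L <= len(vt)]
        if len(segs) < 3:
            return strikes
        template = np.mean(segs, axis=0)
        refined = []
        for s in strikes:
            best, best_sse = s, np.inf
            for d in range(-max_shift, max_shift + 1):
                a = s + d
                if a < 0 or a + L > len(vt):
                    continue
                sse = float(np.sum((vt[a : a + L] - template) ** 2))
                if sse < best_sse:
                    best_sse, best = sse, a
            refined.append(best)
        strikes = np.asarray(sorted(set(refined)), dtype=int)
    return strikes


def vertical_excursion(centroid_mm: np.ndarray, events: EventTable) -> float:
    """Mean per-step peak-to-peak vertical centroid displacement, mm."""
    z = np.asarray(centroid_mm)[:, 2] if np.asarray(centroid_mm).ndim == 2 else np.asarray(
        centroid_mm, float
    )
    spans = []
    for _, row in events.data.iterrows():
        seg = z[int(row["foot_strike_frame"]) : int(row["next_strike_frame"])]
        if len(seg) >= 2:
            spans.append(seg.max() - seg.min())
    if not spans:
        raise ValueError("no complete steps within the signal")
    return float(np.mean(spans))
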