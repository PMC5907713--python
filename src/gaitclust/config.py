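"""Run configuration shared by every pipeline stage.

Internal unit conventions, fixed package-wide: marker coordinates in
millimetres, accelerations in m/s^2, angles in degrees, time in seconds.
Lab frame: X antero-posterior (anterior positive), Y medio-lateral,
Z vertical (up positive), right-handed. Frame indices are 0-based and step
intervals are half-open, ``[strike, next_strike)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable parameters of the acceleration sub-grouping pipeline.

    Parameters
    ----------
    sampling_rate : float
        Motion-capture sampling rate in Hz.
    sg_window : int
        Savitzky-Golay differentiation window, in samples.  An odd window
        is evaluated at its centre sample; an even window is evaluated at
        the mid-point between the two central samples (half-sample shift).
    sg_order : int
        Polynomial order of the local fit; must be < effective window length.
    stance_points, flight_points : int
        Number of resampled points assigned to stance and flight when each
        step cycle is time-normalized.  The per-axis waveform has
        ``stance_points + flight_points`` samples (100 by default).
    k_min, k_max : int
        Range of cluster counts scanned by the variance-ratio criterion.
    effect_size_threshold : float
        eta-squared above which a principal component is flagged as showing
        a large group effect (0.14 by default).
    alpha : float
        Significance level for every hypothesis test.
    cluster_on : str
        ``"features"`` clusters the standardized 300-dim vectors,
        ``"scores"`` clusters the retained PCA scores.
    seed : int
        Master seed; every stochastic stage derives its stream from it.
    """

    sampling_rate: float = 200.0
    sg_window: int = 11
    sg_order: int = 4
    stance_points: int = 80
    flight_points: int = 20
    k_min: int = 2
    k_max: int = 10
    effect_size_threshold: float = 0.14
    alpha: float = 0.05
    cluster_on: str = "features"
    n_null: int = 99
    null_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_order >= self.sg_window:
            raise ValueError(
                f"sg_order ({self.sg_order}) must be < sg_window ({self.sg_window})"
            )
        if self.stance_points < 2 or self.flight_points < 2:
            raise ValueError("stance_points and flight_points must each be >= 2")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.cluster_on not in ("features", "scores"):
            raise ValueError("cluster_on must be 'features' or 'scores'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def n_cycle_points(self) -> int:
        return self.stance_points + self.flight_points

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat YAML key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


#: Axis labels of the local pelvic frame, in feature-vector order.
AXES = ("VT", "AP", "ML")

#: Column index of each axis in lab-frame (x, y, z) arrays.
LAB_COLUMN = {"AP": 0, "ML": 1, "VT": 2}
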