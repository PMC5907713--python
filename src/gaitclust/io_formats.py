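"""Readers, writers and validated containers for every external table.

Canonical on-disk dialect is CSV; C3D input is optional and requires the
``ezc3d`` extra.  All units are converted at this boundary: coordinates to
millimetres, time to seconds, angles to degrees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig

PEAK_ANGLE_NAMES = (
    "ankle_eversion",
    "knee_flexion",
    "knee_abduction",
    "knee_external_rotation",
    "hip_adduction",
    "hip_internal_rotation",
)

TRAJECTORY_COLUMNS = ("frame", "time", "marker_id", "x", "y", "z")
EVENT_COLUMNS = ("step_index", "foot_strike_frame", "toe_off_frame", "next_strike_frame")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class TrajectoryTable:
    """Long-format 3D marker trajectories in a lab frame.

    ``data`` holds one row per (frame, marker) with columns
    ``frame, time, marker_id, x, y, z``; coordinates in millimetres.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"trajectory table missing columns: {missing}")
        df = self.data
        if not np.isfinite(df[["x", "y", "z"]].to_numpy(float)).all():
            raise ParseError("trajectory coordinates contain non-finite values")
        self._validate_frames()

    def _validate_frames(self) -> None:
        frames_by_marker = {
            m: g["frame"].to_numpy() for m, g in self.data.groupby("marker_id", sort=True)
        }
        ref_marker, ref = next(iter(frames_by_marker.items()))
        for m, fr in frames_by_marker.items():
            d = np.diff(fr)
            if (d <= 0).any():
                raise ParseError(f"marker {m!r}: frame numbers not strictly increasing")
            if len(d) and not (d == d[0]).all():
                bad = fr[1:][d != d[0]][0]
                raise ParseError(f"marker {m!r}: irregular frame step near frame {bad}")
            if len(fr) != len(ref) or (fr != ref).any():
                raise ParseError(
                    f"marker {m!r} frame set differs from marker {ref_marker!r}"
                )
        times = self.data.groupby("frame", sort=True)["time"].first().to_numpy()
        if len(times) > 1:
            dts = np.diff(times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ParseError("irregular sampling interval in 'time' column")

    @property
    def marker_ids(self) -> list[str]:
        return sorted(self.data["marker_id"].unique())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    @property
    def dt(self) -> float:
        t = self.data.groupby("frame", sort=True)["time"].first().to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two frames to infer dt")
        return float(t[1] - t[0])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        """Return an (n_frames, n_markers, 3) array in marker_ids order, mm."""
        df = self.data.sort_values(["marker_id", "frame"])
        n_m = len(self.marker_ids)
        n_f = self.n_frames
        xyz = df[["x", "y", "z"]].to_numpy(float).reshape(n_m, n_f, 3)
        return np.moveaxis(xyz, 0, 1)

    def times(self) -> np.ndarray:
        return self.data.groupby("frame", sort=True)["time"].first().to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        marker_ids: Sequence[str],
        dt: float,
        first_frame: int = 0,
    ) -> "TrajectoryTable":
        """Build from an (n_frames, n_markers, 3) array in mm."""
        n_f, n_m, _ = positions.shape
        frames = np.arange(first_frame, first_frame + n_f)
        rows = []
        for j, mid in enumerate(marker_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time": frames * dt,
                        "marker_id": mid,
                        "x": positions[:, j, 0],
                        "y": positions[:, j, 1],
                        "z": positions[:, j, 2],
                    }
                )
            )
        return cls(pd.concat(rows, ignore_index=True))


@dataclass
class EventTable:
    """Foot-strike / toe-off frame indices, one row per step.

    Intervals are half-open: stance = [foot_strike, toe_off),
    flight = [toe_off, next_strike).
    """

    data: pd.DataFrame
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"event table missing columns: {missing}")
        df = self.data
        bad = df[
            ~(
                (df["foot_strike_frame"] < df["toe_off_frame"])
                & (df["toe_off_frame"] < df["next_strike_frame"])
            )
        ]
        if len(bad):
            raise ParseError(
                f"step {int(bad['step_index'].iloc[0])}: events not ordered "
                "foot_strike < toe_off < next_strike"
            )
        strikes = df["foot_strike_frame"].to_numpy()
        nxt = df["next_strike_frame"].to_numpy()
        if len(df) > 1 and (strikes[1:] < nxt[:-1]).any():
            raise ParseError("steps overlap or are out of order")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_arrays(
        cls, strikes: np.ndarray, toe_offs: np.ndarray, next_strikes: np.ndarray
    ) -> "EventTable":
        return cls(
            pd.DataFrame(
                {
                    "step_index": np.arange(len(strikes)),
                    "foot_strike_frame": np.asarray(strikes, int),
                    "toe_off_frame": np.asarray(toe_offs, int),
                    "next_strike_frame": np.asarray(next_strikes, int),
                }
            )
        )


@dataclass
class SubjectMeta:
    """Per-subject demographics, injury characteristics and peak joint angles."""

    subject_id: str
    sex: str
    age: float
    height: float
    mass: float
    running_speed: float
    years_running: float
    involvement: str
    injury_site: str
    peak_angles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.involvement not in ("unilateral", "bilateral"):
            raise ValueError(f"bad involvement {self.involvement!r}")
        if self.injury_site not in ("single", "multiple"):
            raise ValueError(f"bad injury_site {self.injury_site!r}")
        for name in ("age", "height", "mass", "running_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def require_peak_angles(self) -> None:
        missing = [a for a in PEAK_ANGLE_NAMES if a not in self.peak_angles]
        if missing:
            raise ValueError(
                f"subject {self.subject_id}: missing peak angles {missing}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_trajectories(
    path: str | Path, dialect: str = "csv", cfg: RunConfig | None = None
) -> TrajectoryTable:
    """Read marker trajectories from CSV (canonical) or C3D (optional).

    C3D point units are converted to millimetres using POINT:UNITS; the file
    frame rate is checked against ``cfg.sampling_rate`` when a config is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        table = TrajectoryTable(df)
    elif dialect == "c3d":
        table = _read_c3d(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if cfg is not None:
        dt = table.dt
        if abs(dt - cfg.dt) > 1e-6:
            raise ParseError(
                f"{path.name}: sampling interval {dt:.6f}s does not match "
                f"configured rate {cfg.sampling_rate:g} Hz"
            )
    return table


def _read_c3d(path: Path) -> TrajectoryTable:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D support requires the optional 'ezc3d' package "
            "(pip install gaitclust[c3d])"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    units = c3d["parameters"]["POINT"]["UNITS"]["value"][0].strip().lower()
    scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if scale is None:
        raise ParseError(f"unsupported POINT:UNITS {units!r}")
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    xyz = np.moveaxis(pts[:3], -1, 0) * scale  # (n_frames, n_markers, 3)
    return TrajectoryTable.from_arrays(xyz, labels, dt=1.0 / rate)


def write_trajectories(table: TrajectoryTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, columns=list(TRAJECTORY_COLUMNS))


def read_events(path: str | Path) -> EventTable:
    return EventTable(pd.read_csv(path))


def write_events(events: EventTable, path: str | Path) -> None:
    events.data.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_subjects(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    subjects = []
    for _, row in df.iterrows():
        angles = {a: float(row[a]) for a in PEAK_ANGLE_NAMES if a in row}
        subjects.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                sex=row["sex"],
                age=float(row["age"]),
                height=float(row["height"]),
                mass=float(row["mass"]),
                running_speed=float(row["running_speed"]),
                years_running=float(row["years_running"]),
                involvement=row["involvement"],
                injury_site=row["injury_site"],
                peak_angles=angles,
            )
        )
    return subjects


def write_subjects(subjects: Sequence[SubjectMeta], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row = dataclasses.asdict(s)
        angles = row.pop("peak_angles")
        row.update({a: angles.get(a, np.nan) for a in PEAK_ANGLE_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


REPORT_FILES = (
    "cluster_assignments.csv",
    "linkage.csv",
    "variance_ratio_by_k.csv",
    "pc_summary.csv",
    "group_comparisons.csv",
    "run_summary.json",
)


def write_report(results, out_dir: str | Path) -> list[Path]:
    """Write the full analysis report; returns the file manifest.

    ``results`` is a :class:`gaitclust.model.StudyResults`.  Refuses to write
    a partial report when the clustering stage produced nothing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not results.cluster_solutions:
        raise ValueError("empty cluster solution: refusing to write a partial report")

    manifest: list[Path] = []

    assign = results.assignments_frame()
    p = out_dir / "cluster_assignments.csv"
    assign.to_csv(p, index=False)
    manifest.append(p)

    rows = []
    for stratum, sol in results.cluster_solutions.items():
        for i, (a, b, h, size) in enumerate(sol.tree.merges):
            rows.append(
                {"stratum": stratum, "merge_index": i, "node_a": a, "node_b": b,
                 "height": h, "new_size": size}
            )
    p = out_dir / "linkage.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    manifest.append(p)

    rows = []
    for stratum, sol in results.cluster_solutions.items():
        for k, v in sorted(sol.vrc_by_k.items()):
            rows.append({"stratum": stratum, "k": k, "variance_ratio": v,
                         "selected": k == sol.k_selected})
    p = out_dir / "variance_ratio_by_k.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    manifest.append(p)

    p = out_dir / "pc_summary.csv"
    results.pc_summary_frame().to_csv(p, index=False)
    manifest.append(p)

    p = out_dir / "group_comparisons.csv"
    results.comparisons_frame().to_csv(p, index=False)
    manifest.append(p)

    summary = {
        "config": results.config.to_dict(),
        "seed": results.config.seed,
        "n_subjects": len(results.subject_ids),
        "groups": {g: int(n) for g, n in results.group_sizes().items()},
        "strata": {
            stratum: {
                "k_selected": int(sol.k_selected),
                "no_substructure": bool(sol.no_substructure),
                "vrc_max": float(max(sol.vrc_by_k.values())),
            }
            for stratum, sol in results.cluster_solutions.items()
        },
        "flagged_pcs": [int(i) for i in results.flagged_pcs],
        "warnings": list(results.warnings),
    }
    p = out_dir / "run_summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.append(p)
    return manifest
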