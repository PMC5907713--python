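"""Synthetic running cohort generator.

Emulates a treadmill motion-capture study: each synthetic subject carries a
rigid 4-marker pelvic cluster whose centroid follows a periodic running
trajectory.  The local pelvic acceleration is a smooth archetype waveform
(sums of circular Gaussian bumps per axis plus a fundamental cosine on the
vertical axis that is calibrated so the double-integrated trajectory attains
a prescribed peak-to-peak vertical excursion).  Ground truth — events, local
acceleration, excursion — is recorded for every subject, so the marker-side
pipeline can be tested end to end.

Because a treadmill runner is stationary on average, the global acceleration
must integrate to zero over a cycle; the constant cycle-mean of R(t)·w(t) is
therefore subtracted during construction, and the stored truth is the
realized local acceleration (within ~1% of the archetype waveform for the
default small pelvic rotations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .io_formats import EventTable, SubjectMeta, TrajectoryTable

G = 9.81

#: phase-domain widths (cycle fractions) of the per-axis Gaussian bumps
VT_IMPACT_WIDTH = 0.055
VT_PEAK_WIDTH = 0.080
AP_BRAKE_WIDTH = 0.065
AP_PUSH_WIDTH = 0.085
ML_PEAK_WIDTH = 0.075
ML_REBOUND_WIDTH = 0.100

#: rigid local marker offsets (mm) of the 4-marker pelvic cluster; zero mean
#: so the cluster centroid coincides with the pelvis origin exactly.
MARKER_OFFSETS = np.array(
    [
        [75.0, 60.0, -5.0],
        [75.0, -60.0, -5.0],
        [-75.0, 85.0, 15.0],
        [-75.0, -85.0, -5.0],
    ]
)
MARKER_IDS = ("PEL1", "PEL2", "PEL3", "PEL4")

_PHASE_GRID = np.linspace(0.0, 1.0, 2048, endpoint=False)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One acceleration archetype (a synthetic sub-group of runners)."""

    name: str
    sex: str
    n_subjects: int
    cadence_spm: float
    cadence_sd_spm: float
    stance_fraction: float
    vertical_excursion_mm: float
    vertical_excursion_sd_mm: float
    vt_peak_g: float
    vt_peak_phase: float
    vt_impact_g: float
    vt_impact_phase: float
    ap_peak_g: float
    ap_peak_phase: float  # fraction of stance
    ml_peak_g: float
    ml_peak_phase: float  # fraction of stance
    amp_cv: float = 0.06
    phase_jitter: float = 0.012
    marker_noise_mm: float = 0.5
    demographic_means: dict = field(default_factory=dict)
    demographic_sds: dict = field(default_factory=dict)
    p_unilateral: float = 0.5
    p_single_site: float = 0.75
    peak_angle_means: dict = field(default_factory=dict)
    peak_angle_sds: dict = field(default_factory=dict)
    vt_cos_amp: float | None = None  # set after excursion calibration

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for nm in ("vt_peak_g", "vt_impact_g", "ap_peak_g", "ml_peak_g"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for nm in ("vt_peak_phase", "vt_impact_phase", "ap_peak_phase", "ml_peak_phase"):
            if not 0 < getattr(self, nm) < 1:
                raise ValueError(f"{nm} must lie in (0, 1)")

    @property
    def step_period(self) -> float:
        return 60.0 / self.cadence_spm


@dataclass
class MarkerTrial:
    """One synthetic subject: trials, ground truth and metadata."""

    dynamic: TrajectoryTable
    static: TrajectoryTable
    events: EventTable
    truth_local_acc: np.ndarray  # (n_frames, 3) lab-axis order (AP, ML, VT), m/s^2
    truth_excursion_mm: float
    meta: SubjectMeta
    archetype_name: str
    effective_archetype: ArchetypeSpec


def default_archetypes() -> list[ArchetypeSpec]:
    """The three shipped archetypes: males, female C1, female C2 (44/26/40)."""
    text = resources.files("gaitclust").joinpath("data/archetypes.yaml").read_text()
    raw = yaml.safe_load(text)
    return [ArchetypeSpec(name=name, **params) for name, params in raw.items()]


# ---------------------------------------------------------------------------
# waveform model


def _bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Circular (period-1) Gaussian bump."""
    out = np.zeros_like(phase, dtype=float)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-0.5 * ((phase - center + k) / width) ** 2)
    return out


def _raw_axes(phase: np.ndarray, arch: ArchetypeSpec, alpha: float) -> np.ndarray:
    """Un-normalized axis shapes, columns ordered (VT, AP, ML), m/s^2."""
    c_ap = arch.ap_peak_phase * arch.stance_fraction
    c_ml = arch.ml_peak_phase * arch.stance_fraction
    vt = (
        arch.vt_impact_g * G * _bump(phase, arch.vt_impact_phase, VT_IMPACT_WIDTH)
        + arch.vt_peak_g * G * _bump(phase, arch.vt_peak_phase, VT_PEAK_WIDTH)
        + alpha * np.cos(2 * np.pi * (phase - arch.vt_peak_phase))
    )
    ap = arch.ap_peak_g * G * (
        _bump(phase, c_ap, AP_PUSH_WIDTH)
        - 0.85 * _bump(phase, 0.4 * c_ap, AP_BRAKE_WIDTH)
    )
    ml = arch.ml_peak_g * G * (
        _bump(phase, c_ml, ML_PEAK_WIDTH)
        - 0.6 * _bump(phase, min(c_ml + 0.18, 0.95), ML_REBOUND_WIDTH)
    )
    return np.stack([vt, ap, ml], axis=-1)


@lru_cache(maxsize=256)
def _axis_constants(key: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis (mean, scale) making each axis zero-mean with an exact peak."""
    arch, alpha = _arch_from_key(key)
    raw = _raw_axes(_PHASE_GRID, arch, alpha)
    means = raw.mean(axis=0)
    peak_phases = np.array(
        [
            arch.vt_peak_phase,
            arch.ap_peak_phase * arch.stance_fraction,
            arch.ml_peak_phase * arch.stance_fraction,
        ]
    )
    at_peak = _raw_axes(peak_phases, arch, alpha)
    peak_vals = np.diagonal(at_peak) - means
    targets = np.array([arch.vt_peak_g, arch.ap_peak_g, arch.ml_peak_g]) * G
    scales = targets / peak_vals
    return means, scales


_KEY_FIELDS = (
    "stance_fraction",
    "vt_peak_g",
    "vt_peak_phase",
    "vt_impact_g",
    "vt_impact_phase",
    "ap_peak_g",
    "ap_peak_phase",
    "ml_peak_g",
    "ml_peak_phase",
)


def _arch_key(arch: ArchetypeSpec, alpha: float) -> tuple:
    return tuple(float(getattr(arch, f)) for f in _KEY_FIELDS) + (float(alpha),)


def _arch_from_key(key: tuple) -> tuple[ArchetypeSpec, float]:
    vals = dict(zip(_KEY_FIELDS, key[:-1]))
    arch = ArchetypeSpec(
        name="_key",
        sex="male",
        n_subjects=1,
        cadence_spm=170.0,
        cadence_sd_spm=0.0,
        vertical_excursion_mm=100.0,
        vertical_excursion_sd_mm=0.0,
        **vals,
    )
    return arch, key[-1]


def _local_waveform(phase: np.ndarray, arch: ArchetypeSpec, alpha: float) -> np.ndarray:
    """Zero-mean, peak-exact local acceleration; columns (VT, AP, ML), m/s^2."""
    means, scales = _axis_constants(_arch_key(arch, alpha))
    return (_raw_axes(phase, arch, alpha) - means) * scales


def waveform_model(phase, archetype: ArchetypeSpec) -> np.ndarray:
    """Evaluate the archetype's local pelvic acceleration at ``phase``.

    Parameters
    ----------
    phase : float or array, step-cycle fraction in [0, 1).
    archetype : ArchetypeSpec.

    Returns
    -------
    ndarray with trailing dimension 3, ordered (VT, AP, ML), in m/s^2.
    Each axis is zero-mean over the cycle and attains exactly
    ``peak_g * 9.81`` at its nominal peak phase.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any((phase < 0) | (phase >= 1)):
        raise ValueError("phase must lie in [0, 1)")
    alpha = archetype.vt_cos_amp
    if alpha is None:
        alpha = calibrate_vt_cos(archetype)
    return _local_waveform(phase, archetype, alpha)


# ---------------------------------------------------------------------------
# trajectory construction


def _periodic_position(acc: np.ndarray, period: float) -> np.ndarray:
    """Double-integrate a zero-mean periodic acceleration sampled on one period.

    ``acc`` is (n_grid, 3) in m/s^2; returns position in metres (zero-mean).
    """
    n = acc.shape[0]
    coef = np.fft.rfft(acc, axis=0)
    k = np.arange(coef.shape[0])
    omega = 2 * np.pi * k / period
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_coef = -coef / omega[:, None] ** 2
    pos_coef[0] = 0.0
    return np.fft.irfft(pos_coef, n=n, axis=0)


def _rotation_angles(phase: np.ndarray, amps_deg, phases) -> np.ndarray:
    """(n, 2) yaw/roll angles in degrees."""
    yaw = amps_deg[0] * np.sin(2 * np.pi * phase + phases[0])
    roll = amps_deg[1] * np.sin(2 * np.pi * phase + phases[1])
    return np.stack([yaw, roll], axis=-1)


def _rotation_matrices(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices (local -> global) from yaw (Z) and roll (X) angles."""
    return Rotation.from_euler("zx", angles_deg, degrees=True).as_matrix()


def _vt_ap_ml_to_lab(w: np.ndarray) -> np.ndarray:
    """Reorder columns (VT, AP, ML) -> lab (x=AP, y=ML, z=VT)."""
    return w[..., [1, 2, 0]]


def _lab_to_vt_ap_ml(a: np.ndarray) -> np.ndarray:
    return a[..., [2, 0, 1]]


def _excursion_mm(
    arch: ArchetypeSpec, alpha: float, period: float, rot_grid: np.ndarray | None
) -> float:
    w = _vt_ap_ml_to_lab(_local_waveform(_PHASE_GRID, arch, alpha))
    if rot_grid is not None:
        w = np.einsum("nij,nj->ni", rot_grid, w)
    w = w - w.mean(axis=0)
    pos = _periodic_position(w, period)
    z = pos[:, 2]
    return float((z.max() - z.min()) * 1000.0)


def calibrate_vt_cos(
    arch: ArchetypeSpec,
    period: float | None = None,
    rot_grid: np.ndarray | None = None,
) -> float:
    """Solve for the VT fundamental-cosine amplitude (m/s^2) that makes the
    double-integrated trajectory's peak-to-peak height equal the archetype's
    vertical excursion."""
    period = arch.step_period if period is None else period
    target = arch.vertical_excursion_mm

    def f(alpha: float) -> float:
        return _excursion_mm(arch, alpha, period, rot_grid) - target

    # A negative amplitude may be needed when the VT bumps alone overshoot
    # the target.  Excursion vs alpha is U-shaped on (-p0, inf) where -p0 is
    # the peak-rescaling pole: locate the minimum by coarse scan and solve
    # on the increasing branch.
    raw = _raw_axes(_PHASE_GRID, arch, 0.0)
    p0 = float(
        _raw_axes(np.array([arch.vt_peak_phase]), arch, 0.0)[0, 0] - raw[:, 0].mean()
    )
    scan = np.linspace(-0.6 * p0, 0.0, 13)
    lo = float(scan[np.argmin([f(a) for a in scan])])
    hi = 1e4
    if f(lo) > 0:
        raise ValueError(
            f"archetype {arch.name!r}: excursion {target} mm unattainably small"
        )
    if f(hi) < 0:
        raise ValueError(
            f"archetype {arch.name!r}: excursion {target} mm unattainably large"
        )
    return float(brentq(f, lo, hi, xtol=1e-4))


def make_subject(
    archetype: ArchetypeSpec,
    seed: int,
    subject_id: str | None = None,
    duration_s: float = 24.0,
    sampling_rate: float = 200.0,
    noise_sd_mm: float | None = None,
) -> MarkerTrial:
    """Generate one subject's dynamic + static trials with ground truth.

    Deterministic in ``seed``.  ``noise_sd_mm`` overrides the archetype's
    white positional marker noise (set 0 for the noise-free oracle path).
    """
    rng = np.random.default_rng(seed)
    noise_sd = archetype.marker_noise_mm if noise_sd_mm is None else noise_sd_mm

    # per-subject biological variation of the archetype
    def jitter_amp(x: float) -> float:
        return float(x * max(0.2, 1.0 + archetype.amp_cv * rng.standard_normal()))

    def draw_effective() -> "ArchetypeSpec":
        cadence = float(
            np.clip(
                rng.normal(archetype.cadence_spm, archetype.cadence_sd_spm),
                140.0,
                220.0,
            )
        )
        excursion = float(
            rng.normal(
                archetype.vertical_excursion_mm, archetype.vertical_excursion_sd_mm
            )
        )
        return dataclasses.replace(
            archetype,
            cadence_spm=cadence,
            cadence_sd_spm=0.0,
            vertical_excursion_mm=excursion,
            vertical_excursion_sd_mm=0.0,
            vt_peak_g=jitter_amp(archetype.vt_peak_g),
            vt_impact_g=jitter_amp(archetype.vt_impact_g),
            ap_peak_g=jitter_amp(archetype.ap_peak_g),
            ml_peak_g=jitter_amp(archetype.ml_peak_g),
            vt_peak_phase=float(
                np.clip(
                    archetype.vt_peak_phase
                    + 0.5 * archetype.phase_jitter * rng.standard_normal(),
                    0.05,
                    0.95,
                )
            ),
            ap_peak_phase=float(
                np.clip(
                    archetype.ap_peak_phase
                    + archetype.phase_jitter * rng.standard_normal(),
                    0.05,
                    0.95,
                )
            ),
            ml_peak_phase=float(
                np.clip(
                    archetype.ml_peak_phase
                    + archetype.phase_jitter * rng.standard_normal(),
                    0.05,
                    0.95,
                )
            ),
        )

    # rare joint draws (very low cadence + low excursion target) fall outside
    # the waveform family's attainable excursion range; reject and redraw
    eff = alpha = rot_amps = rot_phases = rot_grid = None
    for _ in range(20):
        cand = draw_effective()
        amps = (rng.uniform(2.0, 4.0), rng.uniform(1.5, 3.0))
        phs = (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
        grid = _rotation_matrices(_rotation_angles(_PHASE_GRID, amps, phs))
        try:
            alpha = calibrate_vt_cos(cand, period=cand.step_period, rot_grid=grid)
        except ValueError:
            continue
        eff, rot_amps, rot_phases, rot_grid = cand, amps, phs, grid
        break
    if eff is None:
        raise ValueError(
            f"archetype {archetype.name!r}: could not draw a feasible subject"
        )
    period = eff.step_period
    eff = dataclasses.replace(eff, vt_cos_amp=alpha)

    # one-period construction on the fine grid
    w_grid = _vt_ap_ml_to_lab(_local_waveform(_PHASE_GRID, eff, alpha))
    a_global_grid = np.einsum("nij,nj->ni", rot_grid, w_grid)
    delta = a_global_grid.mean(axis=0)  # treadmill-stationarity correction
    pos_grid = _periodic_position(a_global_grid - delta, period)  # metres
    truth_excursion = float((pos_grid[:, 2].max() - pos_grid[:, 2].min()) * 1000.0)

    # sample the trial
    dt = 1.0 / sampling_rate
    n_frames = int(round(duration_s * sampling_rate))
    t = np.arange(n_frames) * dt
    phase = (t / period) % 1.0
    rot = _rotation_matrices(_rotation_angles(phase, rot_amps, rot_phases))
    w_t = _vt_ap_ml_to_lab(_local_waveform(phase, eff, alpha))
    a_global = np.einsum("nij,nj->ni", rot, w_t) - delta
    truth_local = np.einsum("nji,nj->ni", rot, a_global)  # R^T a_global

    # positions via periodic interpolation of the grid trajectory
    grid_ext = np.concatenate([_PHASE_GRID, [1.0]])
    pos_ext = np.vstack([pos_grid, pos_grid[:1]])
    centroid_mm = np.stack(
        [np.interp(phase, grid_ext, pos_ext[:, i]) for i in range(3)], axis=-1
    ) * 1000.0
    centroid_mm[:, 2] += 950.0  # standing pelvis height

    markers = centroid_mm[:, None, :] + np.einsum("nij,mj->nmi", rot, MARKER_OFFSETS)
    if noise_sd > 0:
        markers = markers + rng.normal(0.0, noise_sd, size=markers.shape)
    dynamic = TrajectoryTable.from_arrays(markers, MARKER_IDS, dt)

    n_static = int(round(1.0 * sampling_rate))
    static_centroid = np.array([0.0, 0.0, 950.0])
    static_markers = np.broadcast_to(
        static_centroid + MARKER_OFFSETS, (n_static, len(MARKER_IDS), 3)
    ).copy()
    if noise_sd > 0:
        static_markers += rng.normal(0.0, noise_sd, size=static_markers.shape)
    static = TrajectoryTable.from_arrays(static_markers, MARKER_IDS, dt)

    # ground-truth events at construction phases
    n_steps = int(np.floor((n_frames - 1) * dt / period))
    ks = np.arange(n_steps)
    strikes = np.round(ks * period * sampling_rate).astype(int)
    toe_offs = np.round((ks + eff.stance_fraction) * period * sampling_rate).astype(int)
    nxt = np.round((ks + 1) * period * sampling_rate).astype(int)
    keep = nxt <= n_frames - 1
    events = EventTable.from_arrays(strikes[keep], toe_offs[keep], nxt[keep])

    sid = subject_id if subject_id is not None else f"{archetype.name}_{seed}"
    meta = _draw_meta(archetype, rng, sid)
    return MarkerTrial(
        dynamic=dynamic,
        static=static,
        events=events,
        truth_local_acc=truth_local,
        truth_excursion_mm=truth_excursion,
        meta=meta,
        archetype_name=archetype.name,
        effective_archetype=eff,
    )


def _draw_meta(arch: ArchetypeSpec, rng: np.random.Generator, sid: str) -> SubjectMeta:
    dm, ds = arch.demographic_means, arch.demographic_sds
    def pos_draw(name, default_mean, default_sd):
        return float(
            max(0.1, rng.normal(dm.get(name, default_mean), ds.get(name, default_sd)))
        )
    angles = {
        a: float(rng.normal(arch.peak_angle_means.get(a, 10.0),
                            arch.peak_angle_sds.get(a, 1.0)))
        for a in sorted(set(arch.peak_angle_means) | {
            "ankle_eversion", "knee_flexion", "knee_abduction",
            "knee_external_rotation", "hip_adduction", "hip_internal_rotation"})
    }
    return SubjectMeta(
        subject_id=sid,
        sex=arch.sex,
        age=pos_draw("age", 33.0, 2.0),
        height=pos_draw("height", 1.70, 0.01),
        mass=pos_draw("mass", 65.0, 2.0),
        running_speed=pos_draw("running_speed", 2.61, 0.03),
        years_running=max(0.5, pos_draw("years_running", 8.0, 5.0)),
        involvement="unilateral" if rng.random() < arch.p_unilateral else "bilateral",
        injury_site="single" if rng.random() < arch.p_single_site else "multiple",
        peak_angles=angles,
    )


def make_cohort(
    specs: list[ArchetypeSpec] | None = None,
    seed: int = 0,
    duration_s: float = 24.0,
    sampling_rate: float = 200.0,
    noise_sd_mm: float | None = None,
) -> list[MarkerTrial]:
    """Generate a full cohort (default: 44 males, 26 C1, 40 C2 females).

    Per-subject seeds derive from the master seed; subject order is shuffled
    deterministically and ids reassigned S001.. in shuffled order.
    """
    if specs is None:
        specs = default_archetypes()
    if not specs:
        raise ValueError("need at least one archetype spec")
    rng = np.random.default_rng(seed)
    trials: list[MarkerTrial] = []
    for spec in specs:
        sub_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)
        for s in sub_seeds:
            trials.append(
                make_subject(
                    spec,
                    int(s),
                    duration_s=duration_s,
                    sampling_rate=sampling_rate,
                    noise_sd_mm=noise_sd_mm,
                )
            )
    order = rng.permutation(len(trials))
    shuffled = [trials[i] for i in order]
    width = max(3, len(str(len(shuffled))))
    for i, trial in enumerate(shuffled):
        trial.meta.subject_id = f"S{i + 1:0{width}d}"
    return shuffled
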