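"""The study-level model object: end-to-end sub-grouping analysis.

:class:`PelvicAccelStudy` is built from a cohort of marker trials (or a
precomputed feature matrix) and a :class:`~gaitclust.config.RunConfig`;
``fit()`` runs marker kinematics, waveform extraction, pooled PCA, per-sex
Ward clustering with variance-ratio k selection, and the statistics layer,
returning a :class:`StudyResults` carrying every stage output with
``summary()`` and plotting helpers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import decomposition as _decomp
from . import stats as _stats
from .config import AXES, RunConfig
from .io_formats import PEAK_ANGLE_NAMES, SubjectMeta, write_report
from .kinematics import (
    detect_events,
    double_differentiate,
    global_to_local,
    pelvic_centroid,
    vertical_excursion,
)
from .waveform import (
    FeatureMatrix,
    StepWaveform,
    average_steps,
    build_feature_matrix,
    segment_steps,
    time_normalize,
)


@dataclass
class StageError(RuntimeError):
    stage: str
    subject_id: str | None
    cause: Exception

    def __str__(self) -> str:
        who = f" (subject {self.subject_id})" if self.subject_id else ""
        return f"pipeline stage {self.stage!r} failed{who}: {self.cause}"


def process_trial(trial, cfg: RunConfig) -> tuple[StepWaveform, float]:
    """One subject: centroid -> double differentiation -> local frame ->
    events -> segmented, time-normalized, step-averaged waveform; plus the
    mean per-step vertical centroid excursion (mm)."""
    centroid = pelvic_centroid(trial.dynamic)
    acc = double_differentiate(centroid, trial.dynamic.dt, cfg)
    acc_local = global_to_local(acc, trial.dynamic, trial.static)
    events = detect_events(acc_local, cfg, events=getattr(trial, "events", None))
    steps = segment_steps(acc_local, events)
    normalized = [
        time_normalize(s, cfg.stance_points, cfg.flight_points) for s in steps
    ]
    wf = average_steps(
        normalized,
        subject_id=trial.meta.subject_id,
        stance_points=cfg.stance_points,
        flight_points=cfg.flight_points,
    )
    exc = vertical_excursion(centroid, events)
    return wf, exc


@dataclass
class StudyResults:
    """Fitted study: cluster solutions, PCA interpretation and statistics."""

    config: RunConfig
    subject_ids: list[str]
    metas: dict
    waveforms: dict
    feature_matrix: FeatureMatrix
    excursions: dict
    cluster_solutions: dict
    group_labels: dict
    pca: _decomp.PCAModel
    pc_etas: np.ndarray
    flagged_pcs: list[int]
    pc_interpretations: list
    comparisons: list
    correlations: list
    warnings: list[str]
    timings: dict = field(default_factory=dict)

    # -- tabular views -----------------------------------------------------

    def group_sizes(self) -> dict:
        out: dict = {}
        for g in self.group_labels.values():
            out[g] = out.get(g, 0) + 1
        return dict(sorted(out.items()))

    def assignments_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.subject_ids:
            stratum = self.metas[sid].sex
            sol = self.cluster_solutions.get(stratum)
            rows.append(
                {
                    "subject_id": sid,
                    "sex": stratum,
                    "cluster": sol.labels.get(sid) if sol else None,
                    "group": self.group_labels[sid],
                }
            )
        return pd.DataFrame(rows)

    def pc_summary_frame(self) -> pd.DataFrame:
        rows = []
        for interp in self.pc_interpretations:
            row = {
                "pc_index": interp.pc_index,
                "explained_pct": float(self.pca.explained_pct[interp.pc_index - 1]),
                "eta_squared": interp.eta_squared,
                "flagged": interp.flagged,
            }
            for a in AXES:
                row[f"relative_loading_{a}_pct"] = interp.relative_loading_pct[a]
            rows.append(row)
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "variable": c.variable,
                    "test_used": c.test_used,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "effect_size": c.effect_size,
                    "effect_size_name": c.effect_size_name,
                    "posthoc": "; ".join(
                        f"{a}-{b}: p={p:.4g}{'*' if sig else ''}"
                        for (a, b), p, sig in c.posthoc
                    ),
                }
            )
        return pd.DataFrame(rows)

    def save_report(self, out_dir) -> list:
        return write_report(self, out_dir)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = []
        w = 72
        lines.append("Pelvic acceleration sub-grouping study".center(w))
        lines.append("=" * w)
        lines.append(f"Subjects: {len(self.subject_ids)}   Groups: "
                     + ", ".join(f"{g} (n={n})" for g, n in self.group_sizes().items()))
        for stratum, sol in self.cluster_solutions.items():
            flag = "  [no sub-structure]" if sol.no_substructure else ""
            vrc = max(sol.vrc_by_k.values())
            lines.append(
                f"Stratum {stratum}: k = {sol.k_selected} "
                f"(variance ratio {vrc:.2f}){flag}"
            )
        lines.append("-" * w)
        lines.append("Principal components with large group effects "
                     f"(eta^2 > {self.config.effect_size_threshold}):")
        header = f"{'PC':>4} {'expl%':>7} {'eta^2':>7} " + " ".join(
            f"{a + '%':>7}" for a in AXES
        )
        lines.append(header)
        for interp in self.pc_interpretations:
            if not interp.flagged:
                continue
            rl = interp.relative_loading_pct
            lines.append(
                f"{interp.pc_index:>4} "
                f"{self.pca.explained_pct[interp.pc_index - 1]:>7.1f} "
                f"{interp.eta_squared:>7.2f} "
                + " ".join(f"{rl[a]:>7.1f}" for a in AXES)
            )
        if not self.flagged_pcs:
            lines.append("  (none)")
        lines.append("-" * w)
        lines.append("Group comparisons:")
        lines.append(f"{'variable':<24}{'test':<16}{'stat':>8}{'p':>10}{'effect':>8}")
        for c in self.comparisons:
            lines.append(
                f"{c.variable:<24}{c.test_used:<16}{c.statistic:>8.2f}"
                f"{c.p_value:>10.4f}{c.effect_size:>8.2f}"
            )
        if self.warnings:
            lines.append("-" * w)
            lines.append("Warnings:")
            lines.extend(f"  - {wmsg}" for wmsg in self.warnings)
        return "\n".join(lines)

    def plot_group_waveforms(self, ax=None):
        """Mean time-normalized waveform per group, one panel per axis."""
        import matplotlib.pyplot as plt

        fig, axs = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
        n = self.config.n_cycle_points
        x = 100.0 * np.arange(n) / n
        groups = sorted(set(self.group_labels.values()))
        for ai, axis_name in enumerate(AXES):
            for g in groups:
                ids = [s for s in self.subject_ids if self.group_labels[s] == g]
                mean = np.mean([self.waveforms[s].axes[ai] for s in ids], axis=0)
                axs[ai].plot(x, mean, label=g)
            axs[ai].axvspan(
                100.0 * self.config.stance_points / n, 100.0, alpha=0.15, color="gray"
            )
            axs[ai].set_title(axis_name)
            axs[ai].set_xlabel("% step cycle")
        axs[0].set_ylabel("acceleration (m/s$^2$)")
        axs[0].legend(fontsize=8)
        fig.tight_layout()
        return fig

    def plot_dendrogram(self, stratum: str):
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        sol = self.cluster_solutions[stratum]
        fig, ax = plt.subplots(figsize=(8, 4))
        dendrogram(sol.tree.scipy_linkage, labels=sol.tree.leaf_ids, ax=ax,
                   color_threshold=None)
        ax.set_title(f"Ward dendrogram - {stratum}")
        ax.set_ylabel("linkage distance")
        fig.tight_layout()
        return fig


class PelvicAccelStudy:
    """Sub-grouping analysis of a running cohort's pelvic accelerations.

    Parameters
    ----------
    cohort : sequence
        Objects with ``dynamic``, ``static``, ``events`` (optional) and
        ``meta`` attributes — e.g. :class:`gaitclust.synth.MarkerTrial` or
        trials loaded from CSV.
    config : RunConfig
    cluster_sexes : iterable of {"male", "female"}, optional
        Strata to cluster (default: every sex present with >= 4 subjects).
    pool_pca : bool
        Run PCA on all processed subjects (default) rather than only on the
        clustered strata.
    """

    def __init__(self, cohort, config: RunConfig | None = None,
                 cluster_sexes=None, pool_pca: bool = True):
        self.cohort = list(cohort)
        self.config = config or RunConfig()
        self.cluster_sexes = set(cluster_sexes) if cluster_sexes else None
        self.pool_pca = pool_pca
        if not self.cohort:
            raise ValueError("empty cohort")

    @classmethod
    def from_cohort(cls, cohort, config: RunConfig | None = None, **kw):
        return cls(cohort, config, **kw)

    def fit(self) -> StudyResults:
        cfg = self.config
        timings: dict = {}
        warnings_log: list[str] = []

        # ---- per-subject kinematics + waveforms
        t0 = time.perf_counter()
        waveforms: dict = {}
        excursions: dict = {}
        metas: dict = {}
        order: list[str] = []
        for trial in self.cohort:
            sid = trial.meta.subject_id
            try:
                wf, exc = process_trial(trial, cfg)
            except Exception as e:
                raise StageError("kinematics/waveform", sid, e) from e
            waveforms[sid] = wf
            excursions[sid] = exc
            metas[sid] = trial.meta
            order.append(sid)
        timings["waveforms_s"] = time.perf_counter() - t0

        # sex strata, restricted if requested
        strata: dict = {}
        for sid in order:
            strata.setdefault(metas[sid].sex, []).append(sid)
        cluster_strata = {
            s: ids
            for s, ids in strata.items()
            if (self.cluster_sexes is None or s in self.cluster_sexes)
        }
        for s, ids in list(cluster_strata.items()):
            if len(ids) < 4:
                warnings_log.append(
                    f"stratum {s!r} has {len(ids)} subjects (< 4): not clustered"
                )
                del cluster_strata[s]
        if not cluster_strata:
            raise StageError("clustering", None, ValueError("no stratum with >= 4 subjects"))

        pca_ids = (
            order
            if self.pool_pca
            else [sid for s in cluster_strata for sid in cluster_strata[s]]
        )

        # ---- pooled feature matrix + PCA
        t0 = time.perf_counter()
        try:
            fm = build_feature_matrix([waveforms[s] for s in pca_ids])
            pca = _decomp.fit_pca(fm.X_std, fm.column_means, fm.column_sds)
        except Exception as e:
            raise StageError("pca", None, e) from e
        timings["pca_s"] = time.perf_counter() - t0

        # ---- per-stratum clustering
        t0 = time.perf_counter()
        solutions: dict = {}
        for si, (stratum, ids) in enumerate(sorted(cluster_strata.items())):
            _, X_std_rows = fm.subset(ids)
            if cfg.cluster_on == "scores":
                idx = {s: i for i, s in enumerate(fm.subjects)}
                X = pca.scores[[idx[s] for s in ids]]
            else:
                X = X_std_rows
            try:
                tree = _cluster.ward_linkage(X, leaf_ids=ids)
                rng = np.random.default_rng([cfg.seed, si])
                sol = _cluster.select_k(
                    X,
                    tree,
                    range(cfg.k_min, min(cfg.k_max, len(ids) - 1) + 1),
                    n_null=cfg.n_null,
                    null_quantile=cfg.null_quantile,
                    rng=rng,
                )
            except Exception as e:
                raise StageError("clustering", stratum, e) from e
            solutions[stratum] = sol
        timings["clustering_s"] = time.perf_counter() - t0

        # ---- canonical group labels (clusters ordered by mean excursion)
        group_labels: dict = {}
        for stratum, ids in strata.items():
            sol = solutions.get(stratum)
            if sol is None or sol.no_substructure:
                for sid in ids:
                    group_labels[sid] = stratum
                continue
            means = {}
            for c in sorted(set(sol.labels.values())):
                members = [s for s in ids if sol.labels[s] == c]
                means[c] = float(np.mean([excursions[s] for s in members]))
            rank = {c: r + 1 for r, c in enumerate(sorted(means, key=means.get))}
            for sid in ids:
                group_labels[sid] = f"{stratum}_C{rank[sol.labels[sid]]}"

        # ---- PC effect sizes over the final groups + interpretation
        t0 = time.perf_counter()
        labels_arr = np.array([group_labels[s] for s in fm.subjects])
        try:
            etas, flags = _decomp.pc_effect_sizes(
                pca.scores, labels_arr, cfg.effect_size_threshold
            )
        except ValueError as e:
            warnings_log.append(f"PC effect sizes unavailable: {e}")
            etas = np.zeros(pca.n_components)
            flags = np.zeros(pca.n_components, bool)
        flagged = [int(i) + 1 for i in np.flatnonzero(flags)]
        interps = []
        for j in range(pca.n_components):
            rl = _decomp.relative_loading(pca, fm.X_raw, fm.column_map, j + 1)
            interp = _decomp.PCInterpretation(
                pc_index=j + 1,
                eta_squared=float(etas[j]),
                flagged=bool(flags[j]),
                relative_loading_pct=rl,
            )
            if flags[j]:
                for g in sorted(set(labels_arr)):
                    mean_score = float(pca.scores[labels_arr == g, j].mean())
                    interp.reconstructions[g] = _decomp.reconstruct(
                        pca, j + 1, mean_score, fm.column_map
                    )
            interps.append(interp)
        timings["interpretation_s"] = time.perf_counter() - t0

        # ---- statistics layer
        t0 = time.perf_counter()
        comparisons = []
        glabels = np.array([group_labels[s] for s in order])
        def numeric(getter, name):
            vals = np.array([getter(metas[s], s) for s in order], float)
            try:
                comparisons.append(
                    _stats.compare_groups(vals, glabels, cfg.alpha, variable=name)
                )
            except Exception as e:
                warnings_log.append(f"comparison {name!r} skipped: {e}")

        numeric(lambda m, s: m.age, "age")
        numeric(lambda m, s: m.height, "height")
        numeric(lambda m, s: m.mass, "mass")
        numeric(lambda m, s: m.running_speed, "running_speed")
        numeric(lambda m, s: m.years_running, "years_running")
        numeric(lambda m, s: excursions[s], "vertical_displacement")
        for angle in PEAK_ANGLE_NAMES:
            missing = [s for s in order if angle not in metas[s].peak_angles]
            if missing:
                warnings_log.append(f"peak angle {angle!r} missing for "
                                    f"{len(missing)} subject(s): skipped")
                continue
            numeric(lambda m, s, a=angle: m.peak_angles[a], angle)
        idx = {s: i for i, s in enumerate(fm.subjects)}
        for j in flagged:
            vals = np.array([pca.scores[idx[s], j - 1] for s in order])
            try:
                comparisons.append(
                    _stats.compare_groups(vals, glabels, cfg.alpha, variable=f"PC{j}")
                )
            except Exception as e:
                warnings_log.append(f"comparison PC{j} skipped: {e}")

        for name, getter, cats in (
            ("involvement", lambda m: m.involvement, ("unilateral", "bilateral")),
            ("injury_site", lambda m: m.injury_site, ("single", "multiple")),
        ):
            groups_sorted = sorted(set(glabels))
            table = np.array(
                [
                    [
                        sum(
                            1
                            for s in order
                            if group_labels[s] == g and getter(metas[s]) == c
                        )
                        for c in cats
                    ]
                    for g in groups_sorted
                ]
            )
            try:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    comparisons.append(_stats.cramers_v(table, variable=name))
            except Exception as e:
                warnings_log.append(f"comparison {name!r} skipped: {e}")

        # correlations of flagged PCs with variables that differed
        correlations = []
        differed = [
            c.variable
            for c in comparisons
            if c.p_value < cfg.alpha and c.test_used != "chi_squared"
            and not c.variable.startswith("PC")
        ]
        var_getters = {
            "age": lambda m, s: m.age,
            "height": lambda m, s: m.height,
            "mass": lambda m, s: m.mass,
            "running_speed": lambda m, s: m.running_speed,
            "years_running": lambda m, s: m.years_running,
            "vertical_displacement": lambda m, s: excursions[s],
        }
        for a in PEAK_ANGLE_NAMES:
            var_getters[a] = lambda m, s, a=a: m.peak_angles.get(a, np.nan)
        for j in flagged:
            pc_vals = np.array([pca.scores[idx[s], j - 1] for s in order])
            for var in differed:
                vals = np.array([var_getters[var](metas[s], s) for s in order])
                try:
                    r, p = _stats.pearson_r(pc_vals, vals)
                except ValueError as e:
                    warnings_log.append(f"correlation PC{j} ~ {var}: {e}")
                    continue
                correlations.append(
                    {"pc_index": j, "variable": var, "r": r, "p_value": p}
                )
        timings["stats_s"] = time.perf_counter() - t0

        return StudyResults(
            config=cfg,
            subject_ids=order,
            metas=metas,
            waveforms=waveforms,
            feature_matrix=fm,
            excursions=excursions,
            cluster_solutions=solutions,
            group_labels=group_labels,
            pca=pca,
            pc_etas=etas,
            flagged_pcs=flagged,
            pc_interpretations=interps,
            comparisons=comparisons,
            correlations=correlations,
            warnings=warnings_log,
            timings=timings,
        )


def run_pipeline(cohort, cfg: RunConfig | None = None, **kw) -> StudyResults:
    """Functional entry point: fit a :class:`PelvicAccelStudy` on a cohort."""
    return PelvicAccelStudy(cohort, cfg, **kw).fit()
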