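"""Recovery and calibration experiments on synthetic cohorts.

These are the package's standard numerical experiments: sub-group-count and
label recovery on seeded female cohorts at the default archetype
separation, the male no-sub-structure rate, and type-I calibration of the
dispatched comparison pipeline under null simulations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import cluster as _cluster
from .config import RunConfig
from .model import process_trial
from .stats import compare_groups
from .synth import default_archetypes, make_cohort
from .waveform import build_feature_matrix


def female_specs() -> list:
    """The two female archetypes at their default sizes (26 C1 : 40 C2)."""
    return [a for a in default_archetypes() if a.sex == "female"]


def male_specs() -> list:
    return [a for a in default_archetypes() if a.sex == "male"]


def cohort_features(specs, seed: int, cfg: RunConfig | None = None,
                    duration_s: float = 24.0):
    """Generate a cohort and push it through the marker pipeline.

    Returns (feature_matrix, archetype_names_in_row_order).
    """
    cfg = cfg or RunConfig()
    cohort = make_cohort(specs, seed=seed, duration_s=duration_s)
    wfs = [process_trial(t, cfg)[0] for t in cohort]
    fm = build_feature_matrix(wfs)
    return fm, [t.archetype_name for t in cohort]


def recover_female_subgroups(seed: int, cfg: RunConfig | None = None,
                             n_null: int = 0) -> dict:
    """One female-cohort recovery run: selected k and adjusted-Rand index
    of the k = 2 cut against the generator archetypes."""
    cfg = cfg or RunConfig()
    fm, truth = cohort_features(female_specs(), seed, cfg)
    tree = _cluster.ward_linkage(fm.X_std, leaf_ids=fm.subjects)
    sol = _cluster.select_k(
        fm.X_std, tree, range(cfg.k_min, cfg.k_max + 1),
        n_null=n_null, rng=np.random.default_rng([seed, 1]),
    )
    ari = adjusted_rand_score(truth, tree.cut(2))
    return {
        "seed": seed,
        "k_selected": sol.k_selected,
        "ari_k2": float(ari),
        "vrc_max": float(max(sol.vrc_by_k.values())),
        "no_substructure": sol.no_substructure,
    }


def male_substructure_flag(seed: int, cfg: RunConfig | None = None,
                           n_null: int = 99) -> bool:
    """Whether the reference-null check flags the (single-archetype) male
    cohort as having no sub-structure."""
    cfg = cfg or RunConfig()
    fm, _ = cohort_features(male_specs(), seed, cfg)
    tree = _cluster.ward_linkage(fm.X_std, leaf_ids=fm.subjects)
    sol = _cluster.select_k(
        fm.X_std, tree, range(cfg.k_min, cfg.k_max + 1),
        n_null=n_null, rng=np.random.default_rng([seed, 2]),
    )
    return sol.no_substructure


def dispatch_type_i_error(
    n_sims: int = 2000,
    n_per_group: int = 20,
    n_groups: int = 3,
    alpha: float = 0.05,
    distribution: str = "normal",
    seed: int = 0,
) -> float:
    """Rejection rate of the assumption-dispatched omnibus comparison when
    every group is drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    hits = 0
    for _ in range(n_sims):
        if distribution == "normal":
            values = rng.normal(size=n_groups * n_per_group)
        elif distribution == "skewed":
            values = rng.exponential(size=n_groups * n_per_group)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        res = compare_groups(values, labels, alpha)
        hits += res.p_value < alpha
    return hits / n_sims
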