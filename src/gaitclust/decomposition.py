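"""PCA of the standardized waveform matrix and its interpretation layer.

Components are extracted by SVD of the column-centred standardized matrix,
with a deterministic sign convention.  Interpretation attaches, per
component: a group eta-squared of the scores, the per-axis relative loading
(squared score-column correlations summed within each axis, as percentages),
and waveform reconstructions at chosen score values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AXES

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Principal components of a standardized waveform matrix."""

    loadings: np.ndarray        # (n_cols, p), unit-norm columns
    scores: np.ndarray          # (n_subjects, p)
    explained_pct: np.ndarray   # (p,), percentages of total variance
    singular_values: np.ndarray
    center: np.ndarray          # column means of the standardized matrix
    column_means: np.ndarray    # of the raw matrix (for un-standardizing)
    column_sds: np.ndarray
    sign_convention_applied: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PCInterpretation:
    pc_index: int               # 1-based
    eta_squared: float
    flagged: bool
    relative_loading_pct: dict
    reconstructions: dict = field(default_factory=dict)


def fit_pca(
    X_std: np.ndarray,
    column_means: np.ndarray | None = None,
    column_sds: np.ndarray | None = None,
) -> PCAModel:
    """SVD principal components; retains p = min(n - 1, n_cols) components.

    Sign indeterminacy is fixed by making each loading column's
    largest-magnitude element positive.  ``column_means/sds`` of the raw
    matrix enable reconstruction in raw units (default: standardized units).
    """
    X = np.asarray(X_std, float)
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for PCA")
    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= 0:
        raise ValueError("rank-0 matrix: nothing to decompose")
    p = min(n - 1, d)
    loadings = Vt[:p].T
    scores = Xc @ loadings
    total_var = float(np.sum(S**2))
    explained = 100.0 * S[:p] ** 2 / total_var
    # deterministic sign fix
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    if column_means is None:
        column_means = np.zeros(d)
    if column_sds is None:
        column_sds = np.ones(d)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_pct=explained,
        singular_values=S[:p],
        center=center,
        column_means=np.asarray(column_means, float),
        column_sds=np.asarray(column_sds, float),
    )


def eta_squared_1d(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group over total sum of squares of one variable."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for g in np.unique(labels):
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
    return float(ss_between / ss_total)


def pc_effect_sizes(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.14
) -> tuple[np.ndarray, np.ndarray]:
    """Per-PC eta-squared of the scores across groups, plus a large-effect flag."""
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    etas = np.array(
        [eta_squared_1d(scores[:, j], labels) for j in range(scores.shape[1])]
    )
    return etas, etas > threshold


def relative_loading(
    model: PCAModel,
    X_raw: np.ndarray,
    column_map: list[tuple[str, int]],
    pc_index: int,
) -> dict:
    """Per-axis relative loading (%) of one component (1-based ``pc_index``).

    Squared Pearson correlations between the PC's scores and each raw data
    column are summed within each axis and expressed as percentages of the
    grand sum; zero-variance columns contribute 0.
    """
    s = model.scores[:, pc_index - 1]
    X = np.asarray(X_raw, float)
    s_c = s - s.mean()
    denom_s = np.sqrt(np.sum(s_c**2))
    Xc = X - X.mean(axis=0)
    col_norm = np.sqrt(np.sum(Xc**2, axis=0))
    zero = (col_norm < 1e-12) | (denom_s < 1e-12)
    if zero.any():
        logger.info("relative_loading: %d zero-variance column(s) -> r=0", int(zero.sum()))
    safe = np.where(zero, 1.0, col_norm)
    r = (Xc.T @ s_c) / (safe * max(denom_s, 1e-300))
    r[zero] = 0.0
    r2 = r**2
    axes_cols = {a: [i for i, (ax, _) in enumerate(column_map) if ax == a] for a in AXES}
    sums = {a: float(np.sum(r2[cols])) for a, cols in axes_cols.items()}
    grand = sum(sums.values())
    if grand == 0:
        return {a: 0.0 for a in AXES}
    return {a: 100.0 * v / grand for a, v in sums.items()}


def reconstruct(
    model: PCAModel,
    pc_index: int,
    score_value: float,
    column_map: list[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Waveform at a given score on one component (1-based), in raw units.

    Returns a 3 x n array (VT, AP, ML rows) when ``column_map`` is given,
    otherwise the flat 300-vector.
    """
    if not 1 <= pc_index <= model.n_components:
        raise ValueError(f"pc_index {pc_index} out of range")
    flat_std = model.center + score_value * model.loadings[:, pc_index - 1]
    flat = model.column_means + model.column_sds * flat_std
    if column_map is None:
        return flat
    out = []
    for a in AXES:
        cols = [i for i, (ax, _) in enumerate(column_map) if ax == a]
        out.append(flat[cols])
    return np.stack(out)


def reconstruct_full(model: PCAModel, row_index: int) -> np.ndarray:
    """Reconstruct one subject's standardized row from all retained components."""
    return model.center + model.scores[row_index] @ model.loadings.T
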