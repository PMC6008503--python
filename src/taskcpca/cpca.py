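"""Constrained principal component analysis (CPCA) of task-related BOLD
variance.

The stacked, nuisance-cleaned data ``Z`` (scans x voxels) are regressed onto
the stacked FIR design ``G``; the predicted portion ``G @ C`` contains only
variance time-locked to the task.  Its singular value decomposition
``G C = U D V'`` yields functional networks: component loadings ``V D``
(per-voxel network weights, singular-value scaled) and component scores
``U``.  An orthogonal varimax rotation simplifies the loading structure;
scores are counter-rotated so the reconstruction ``scores @ loadings'`` is
invariant.  Regressing each rotated score column back onto the
block-diagonal design gives predictor weights per (subject, condition,
poststimulus bin) — subject- and condition-specific estimated HDR shapes.

The rank of ``G C`` never exceeds the design column count, so the SVD is
taken of ``R C`` after a thin QR of ``G``, which keeps desk-scale cohorts
cheap without changing the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .design import StackedDesign

__all__ = [
    "CPCAModel",
    "ScreeResult",
    "fit_cpca",
    "varimax_rotate",
    "varimax_criterion",
    "predictor_weights",
    "scree",
    "subject_expression_maps",
]


@dataclass
class CPCAModel:
    """Fitted CPCA decomposition.

    ``loadings`` are rotated and singular-value scaled (V D R); ``scores``
    are the counter-rotated left singular vectors, so
    ``scores @ loadings.T`` reconstructs the rank-``n_components``
    approximation of the task-predicted matrix ``G C``.
    """

    C: np.ndarray                       # design columns x voxels
    singular_values: np.ndarray         # all, descending
    loadings: np.ndarray                # voxels x k, rotated, scaled
    scores: np.ndarray                  # rows x k, rotated
    rotation: np.ndarray                # k x k orthogonal
    unrotated_loadings: np.ndarray
    unrotated_scores: np.ndarray
    task_variance_fraction: np.ndarray  # per retained component, rotated
    variance_fractions: np.ndarray      # all rank components, unrotated
    n_components: int
    columns: pd.DataFrame | None = None  # design column labels, if known

    def predicted(self, G: np.ndarray) -> np.ndarray:
        """Task-predicted matrix G @ C."""
        return G @ self.C


def _sign_fix(loadings: np.ndarray, scores: np.ndarray,
              rotation: np.ndarray | None = None):
    """Orient each component so its maximum-absolute loading is positive."""
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
            if rotation is not None:
                rotation[:, k] *= -1
    return loadings, scores, rotation


def fit_cpca(
    Z: np.ndarray,
    G: np.ndarray,
    n_components: int,
    columns: pd.DataFrame | None = None,
    rotate: bool = True,
    kaiser_normalize: bool = False,
) -> CPCAModel:
    """Fit the constrained PCA of ``Z`` on the design ``G``.

    Parameters
    ----------
    Z : (n_rows, n_voxels) stacked data matrix.
    G : (n_rows, n_design) stacked design matrix.
    n_components : number of components to retain (<= rank of G C).
    columns : optional design column labels carried through to predictor
        weights.
    rotate : apply varimax to the retained loadings (skipped automatically
        for a single component).
    """
    Z = np.asarray(Z, dtype=float)
    G = np.asarray(G, dtype=float)
    if Z.shape[0] != G.shape[0]:
        raise ValueError("Z and G must have the same number of rows")

    Q, R = scipy.linalg.qr(G, mode="economic")
    rank_R = np.linalg.matrix_rank(R)
    if rank_R < R.shape[0]:
        cond = np.linalg.cond(G.T @ G)
        warnings.warn(
            f"singular design (G'G condition number {cond:.3g}); "
            "using pseudo-inverse least squares", stacklevel=2)
        C = np.linalg.pinv(G) @ Z
        M = R @ C                       # Q' G C
    else:
        C = scipy.linalg.solve_triangular(R, Q.T @ Z)
        M = R @ C
    # SVD of G C through its thin factor: G C = Q M = (Q Us) D Vt
    Us, D, Vt = np.linalg.svd(M, full_matrices=False)

    total = np.sum(D ** 2)
    if total == 0:
        raise ValueError("task-predicted matrix is identically zero")
    rank = int(np.sum(D > D[0] * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")

    U = Q @ Us[:, :n_components]
    L = Vt[:n_components].T * D[:n_components]
    L, U, _ = _sign_fix(L.copy(), U.copy())

    if rotate and n_components >= 2:
        L_rot, Rm = varimax_rotate(L, kaiser_normalize=kaiser_normalize)
        S_rot = U @ Rm
        L_rot, S_rot, Rm = _sign_fix(L_rot, S_rot, Rm)
        # order rotated components by explained task variance
        ss = np.sum(L_rot ** 2, axis=0)
        order = np.argsort(-ss)
        L_rot, S_rot, Rm = L_rot[:, order], S_rot[:, order], Rm[:, order]
    else:
        L_rot, S_rot, Rm = L, U, np.eye(n_components)

    return CPCAModel(
        C=C,
        singular_values=D[:rank],
        loadings=L_rot,
        scores=S_rot,
        rotation=Rm,
        unrotated_loadings=L,
        unrotated_scores=U,
        task_variance_fraction=np.sum(L_rot ** 2, axis=0) / total,
        variance_fractions=D[:rank] ** 2 / total,
        n_components=n_components,
        columns=columns,
    )


def varimax_criterion(L: np.ndarray, kaiser_normalize: bool = False) -> float:
    """Varimax objective: sum over components of the variance of squared
    (optionally row-normalized) loadings."""
    L = np.asarray(L, dtype=float)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L ** 2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    sq = L ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    L: np.ndarray,
    kaiser_normalize: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation of a loading matrix.

    Iterates the standard SVD update until the criterion gain falls below
    ``tol``; with Kaiser normalization rows are scaled to unit communality
    during rotation and rescaled afterwards.  Returns ``(L @ R, R)`` with
    ``R`` orthogonal; total sum of squared loadings is preserved.  On
    hitting ``max_iter`` the best rotation found is returned with a
    warning.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        raise ValueError("varimax needs at least 2 components")
    h = np.ones(p)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L ** 2, axis=1))
        h[h == 0] = 1.0
    X = L / h[:, None]

    R = np.eye(k)
    d_old = 0.0
    converged = False
    for _ in range(max_iter):
        B = X @ R
        u, s, vt = np.linalg.svd(
            X.T @ (B ** 3 - B * (np.sum(B ** 2, axis=0) / p)))
        R = u @ vt
        d = float(np.sum(s))
        if d_old != 0 and (d - d_old) < tol * d_old:
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn("varimax did not converge; returning best rotation",
                      stacklevel=2)
    return L @ R, R


def predictor_weights(
    model: CPCAModel,
    G: np.ndarray,
    columns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress rotated component scores onto the design columns.

    For the block-diagonal stacked design each coefficient belongs to one
    (subject, condition, poststimulus bin) triple; per component the six
    bin coefficients trace that subject's estimated HDR for that condition.
    Returns a tidy frame with one row per (design column, component).
    """
    G = np.asarray(G, dtype=float)
    if columns is None:
        columns = model.columns
    P, *_ = np.linalg.lstsq(G, model.scores, rcond=None)

    frames = []
    for k in range(model.n_components):
        if columns is not None:
            f = columns.copy()
        else:
            f = pd.DataFrame({"column": np.arange(G.shape[1])})
        f["component"] = k + 1
        f["weight"] = P[:, k]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class ScreeResult:
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    suggested: int
    selected: int
    rule: str = "largest-gap"


def scree(singular_values: np.ndarray, default: int = 1,
          rel_tol: float = 1e-8) -> ScreeResult:
    """Suggest a component count from the scree of singular values.

    The elbow is located by the standard chord heuristic: the point of the
    scree curve farthest below the straight line joining its first and last
    values; components before the elbow are retained.  Flat spectra (no
    value more than ``rel_tol * d[0]`` below the chord) fall back to the
    configured default.  The suggestion is advisory; the final count is a
    config choice.
    """
    d = np.asarray(singular_values, dtype=float)
    if d.size == 0:
        raise ValueError("no singular values")
    fractions = d ** 2 / np.sum(d ** 2)
    if d.size == 1:
        return ScreeResult(d, fractions, 1, 1)
    x = np.arange(d.size, dtype=float)
    chord = d[0] + (d[-1] - d[0]) * x / (d.size - 1)
    below = chord - d
    if below.max() <= rel_tol * max(d[0], 1.0):
        return ScreeResult(d, fractions, default, default, rule="flat-fallback")
    elbow = int(np.argmax(below))  # 0-based index of the elbow point
    suggested = max(1, elbow)      # components strictly before the elbow
    return ScreeResult(d, fractions, suggested, suggested, rule="chord-elbow")


def subject_expression_maps(
    model: CPCAModel, stacked: StackedDesign
) -> dict[object, np.ndarray]:
    """Per-subject component-expression maps.

    For each component a common reference time course is built per subject
    by applying the grand-mean predictor weights (the cohort-average
    estimated HDR per condition and bin) to that subject's FIR design; the
    expression map is the per-voxel regression slope of the subject's
    residualized data on this reference.  Because the reference shape is
    shared across subjects, a subject engaging the network more strongly
    gets proportionally larger map values — group amplitude differences
    survive (regressing on the subject's *own* score segment would cancel
    them).  Returns ``{subject_id: (k, n_voxels) array}``; these maps feed
    within-network group inference.
    """
    if model.columns is None:
        raise ValueError("model needs design column labels (fit with columns=)")
    P, *_ = np.linalg.lstsq(stacked.G, model.scores, rcond=None)
    cols = model.columns.reset_index(drop=True)
    # cohort-average weight per (condition, bin) and component
    pbar = (
        pd.concat([cols, pd.DataFrame(P, columns=range(model.n_components))],
                  axis=1)
        .groupby(["condition", "bin"], sort=False)[list(range(model.n_components))]
        .mean()
    )
    out: dict[object, np.ndarray] = {}
    for sid in stacked.subjects:
        rows = stacked.row_subject == sid
        block = (cols["subject"] == sid).to_numpy()
        Gs = stacked.G[np.ix_(rows, block)]
        key = list(zip(cols.loc[block, "condition"], cols.loc[block, "bin"]))
        ref = Gs @ pbar.loc[key].to_numpy()          # (n_scans_s, k)
        denom = np.sum(ref ** 2, axis=0)
        denom[denom == 0] = 1.0
        out[sid] = (ref.T @ stacked.Z[rows]) / denom[:, None]
    return out
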