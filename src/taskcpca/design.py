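"""Finite impulse response (FIR) design construction and nuisance regression.

The task model is a FIR basis: one free amplitude per poststimulus scan and
condition, so the hemodynamic response (HDR) shape is estimated without
assuming its form.  A trial with onset ``t`` is assigned to the first full
scan acquired at or after ``t``; indicator 1 is then placed at that scan and
the following ``n_bins - 1`` scans in the column for (condition, bin).
Overlapping trials sum.  With TR = 3.25 s and 6 bins the modeled
poststimulus window spans 19.5 s.

Nuisance variance (rigid-body motion, low-order drift, intercept) is removed
by least-squares projection before the multivariate analysis, motion first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "bin_times",
    "build_fir_design",
    "build_nuisance",
    "residualize",
    "stack_subjects",
]


@dataclass
class DesignMatrix:
    """FIR task design for one subject.

    Attributes
    ----------
    G : (n_scans, n_conditions * n_bins) ndarray
        Binary FIR indicator matrix.
    columns : pandas.DataFrame
        One row per column of ``G`` with fields ``condition`` and ``bin``
        (1-based poststimulus scan index) and, after stacking, ``subject``.
    tr : float
        Repetition time in seconds.
    n_bins : int
        Number of poststimulus scans modeled per trial.
    """

    G: np.ndarray
    columns: pd.DataFrame
    tr: float
    n_bins: int
    bin_time_convention: str = "midpoint"

    @property
    def bin_times_s(self) -> np.ndarray:
        return bin_times(self.n_bins, self.tr, self.bin_time_convention)

    @property
    def window_s(self) -> float:
        """Duration of the modeled poststimulus window (n_bins * TR)."""
        return self.n_bins * self.tr

    def to_frame(self) -> pd.DataFrame:
        labels = [
            "_".join(str(v) for v in row if v is not None)
            for row in self.columns.itertuples(index=False)
        ]
        return pd.DataFrame(self.G, columns=labels)


def bin_times(n_bins: int, tr: float, convention: str = "midpoint") -> np.ndarray:
    """Times (s) attached to poststimulus bins 1..n_bins.

    ``"midpoint"`` labels bin k with (k - 0.5) * TR (scan midpoints, e.g.
    1.6, 4.9, 8.1 ... s for TR = 3.25); ``"onset"`` labels bin k with
    (k - 1) * TR so the first bin sits at time 0.
    """
    k = np.arange(1, n_bins + 1, dtype=float)
    if convention == "midpoint":
        return (k - 0.5) * tr
    if convention == "onset":
        return (k - 1.0) * tr
    raise ValueError(f"unknown bin-time convention: {convention!r}")


def build_fir_design(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    n_bins: int = 6,
    conditions: list[str] | None = None,
    bin_time_convention: str = "midpoint",
) -> DesignMatrix:
    """Build the FIR indicator matrix for one subject.

    Parameters
    ----------
    events : DataFrame with columns ``onset`` (s), ``duration`` (s),
        ``condition``.  Onsets must be non-negative.
    n_scans : number of volumes on the time axis.
    tr : repetition time (s).
    n_bins : poststimulus scans per trial.
    conditions : explicit condition order; defaults to sorted unique labels.

    A trial whose FIR window runs off the end of the scan axis is truncated
    with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if conditions is None:
        conditions = sorted(events["condition"].unique()) if len(events) else []
    cond_index = {c: j for j, c in enumerate(conditions)}

    G = np.zeros((n_scans, len(conditions) * n_bins))
    truncated = 0
    for onset, cond in zip(events["onset"], events["condition"]):
        if onset < 0:
            raise ValueError("negative onset")
        if cond not in cond_index:
            raise ValueError(f"condition {cond!r} not in {conditions}")
        s = math.ceil(onset / tr)  # first full scan at or after onset
        if s >= n_scans:
            truncated += 1
            continue
        for b in range(n_bins):
            row = s + b
            if row >= n_scans:
                truncated += 1
                break
            G[row, cond_index[cond] * n_bins + b] += 1.0
    if truncated:
        warnings.warn(
            f"{truncated} trial window(s) truncated at the end of the scan axis",
            stacklevel=2,
        )

    columns = pd.DataFrame(
        {
            "condition": [c for c in conditions for _ in range(n_bins)],
            "bin": [b + 1 for _ in conditions for b in range(n_bins)],
        }
    )
    return DesignMatrix(G=G, columns=columns, tr=tr, n_bins=n_bins,
                        bin_time_convention=bin_time_convention)


def build_nuisance(
    motion: np.ndarray | None,
    n_scans: int,
    drift_order: int = 2,
    intercept: bool = True,
) -> np.ndarray:
    """Assemble the nuisance matrix: motion columns first, then Legendre
    drift polynomials, then the intercept (the stated removal order)."""
    cols: list[np.ndarray] = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise ValueError("motion rows must equal n_scans")
        cols.append(motion)
    t = np.linspace(-1.0, 1.0, n_scans)
    for d in range(1, drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(d)(t)[:, None])
    if intercept:
        cols.append(np.ones((n_scans, 1)))
    if not cols:
        return np.zeros((n_scans, 0))
    return np.column_stack(cols)


def residualize(Y: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Remove the column space of ``N`` from ``Y`` by least squares.

    Returns ``Y - N @ pinv(N) @ Y``; residuals are orthogonal to every
    nuisance column.  A rank-deficient ``N`` is handled by the
    pseudo-inverse with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    N = np.asarray(N, dtype=float)
    if Y.shape[0] != N.shape[0]:
        raise ValueError("row mismatch between data and nuisance matrix")
    if N.shape[1] == 0:
        return Y.copy()
    rank = np.linalg.matrix_rank(N)
    if rank < N.shape[1]:
        warnings.warn("rank-deficient nuisance matrix; using pseudo-inverse",
                      stacklevel=2)
    beta, *_ = np.linalg.lstsq(N, Y, rcond=None)
    return Y - N @ beta


@dataclass
class StackedDesign:
    """Subject-stacked data and block-diagonal FIR design.

    ``Z`` holds the vertically stacked (per-subject standardized) residual
    time series; ``G`` is block-diagonal so every subject keeps its own FIR
    columns and predictor weights come out subject- and condition-specific.
    """

    Z: np.ndarray
    G: np.ndarray
    columns: pd.DataFrame
    row_subject: np.ndarray
    tr: float
    n_bins: int
    subjects: list = field(default_factory=list)


def stack_subjects(
    per_subject: list[tuple[np.ndarray, DesignMatrix]],
    subject_ids: list | None = None,
    standardize: str | bool = "scalar",
    center_design: bool = True,
) -> StackedDesign:
    """Stack residualized subject data and make the design block-diagonal.

    Each subject's data is standardized before stacking so no subject
    dominates the SVD.  ``standardize="scalar"`` (default) demeans every
    voxel and divides the whole subject by the median voxel SD — a noise-
    scale estimate insensitive to evoked signal in the (few) active
    voxels — equalizing subject scale while leaving the within-subject
    spatial pattern untouched; ``"voxel"`` z-scores each voxel time series
    individually (unit variance everywhere, at the cost of compressing
    high-amplitude voxels); ``False`` stacks raw data.

    With ``center_design`` (default) each subject's FIR columns are
    demeaned over that subject's rows, matching the demeaned data — the
    regression then carries an implicit per-subject intercept, so FIR
    coefficients are unbiased by the baseline.  Block-diagonality is
    preserved (off-block entries stay zero).  All subjects must share the
    voxel count.
    """
    if not per_subject:
        raise ValueError("no subjects to stack")
    if standardize is True:
        standardize = "scalar"
    if standardize not in ("scalar", "voxel", False):
        raise ValueError("standardize must be 'scalar', 'voxel' or False")
    n_vox = per_subject[0][0].shape[1]
    if subject_ids is None:
        subject_ids = list(range(len(per_subject)))

    Z_blocks, G_blocks, col_frames, row_subj = [], [], [], []
    for sid, (Y, dm) in zip(subject_ids, per_subject):
        if Y.shape[1] != n_vox:
            raise ValueError("voxel-count mismatch across subjects")
        Yz = np.asarray(Y, dtype=float)
        if standardize:
            mu = Yz.mean(axis=0)
            sd = Yz.std(axis=0)
            sd[sd == 0] = 1.0
            if standardize == "voxel":
                Yz = (Yz - mu) / sd
            else:
                Yz = (Yz - mu) / np.median(sd)
        Z_blocks.append(Yz)
        Gb = dm.G
        if center_design:
            Gb = Gb - Gb.mean(axis=0)
        G_blocks.append(Gb)
        cf = dm.columns.copy()
        cf.insert(0, "subject", sid)
        col_frames.append(cf)
        row_subj.append(np.full(Y.shape[0], sid, dtype=object))

    n_rows = sum(b.shape[0] for b in G_blocks)
    n_cols = sum(b.shape[1] for b in G_blocks)
    G = np.zeros((n_rows, n_cols))
    r = c = 0
    for b in G_blocks:
        G[r:r + b.shape[0], c:c + b.shape[1]] = b
        r += b.shape[0]
        c += b.shape[1]

    first = per_subject[0][1]
    return StackedDesign(
        Z=np.vstack(Z_blocks),
        G=G,
        columns=pd.concat(col_frames, ignore_index=True),
        row_subject=np.concatenate(row_subj),
        tr=first.tr,
        n_bins=first.n_bins,
        subjects=list(subject_ids),
    )
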