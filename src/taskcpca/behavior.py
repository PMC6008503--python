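"""Behavioral composite scoring and brain-behavior correlation.

Three motor measures — grip strength, finger dexterity (Nine-Hole Peg
Test) and gross manual dexterity (Box and Block Test), each expressed as a
percentage of the unaffected hand — are collapsed into a single impairment
composite: the first principal component of the standardized measures.
The composite is oriented so that higher scores mean better motor
performance (the measures are performance percentages, so PC1 is aligned
with their mean); the orientation is reported alongside the scores.

Regional activity in a within-network cluster is then related to the
composite by a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["CompositeResult", "composite_score", "brain_behavior_correlation"]

MEASURES = ["grip_strength", "nhpt", "bbt"]
ORIENTATION = "higher composite = better motor performance"


@dataclass
class CompositeResult:
    scores: np.ndarray
    variance_explained: float
    loadings: np.ndarray
    orientation: str = ORIENTATION


def composite_score(measures: pd.DataFrame | np.ndarray) -> CompositeResult:
    """First-principal-component impairment composite.

    ``measures`` holds one row per patient and one column per motor measure
    (each as % of the unaffected hand).  Measures are z-scored, so the PCA
    is on the correlation matrix; PC1 scores are returned with the fraction
    of variance it explains.
    """
    if isinstance(measures, pd.DataFrame):
        cols = [c for c in MEASURES if c in measures.columns] or list(measures.columns)
        X = measures[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(measures, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 patients")
    if m < 2:
        raise ValueError("need at least 2 measures")
    if (X < 0).any():
        raise ValueError("performance percentages must be non-negative")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance measure")
    Xz = (X - X.mean(axis=0)) / sd

    U, D, Vt = np.linalg.svd(Xz, full_matrices=False)
    pc1 = Vt[0]
    scores = Xz @ pc1
    # orient: higher composite tracks higher (= better) performance
    if np.corrcoef(scores, Xz.mean(axis=1))[0, 1] < 0:
        pc1, scores = -pc1, -scores
    var_explained = float(D[0] ** 2 / np.sum(D ** 2))
    return CompositeResult(scores=scores, variance_explained=var_explained,
                           loadings=pc1)


def brain_behavior_correlation(
    regional_activity: np.ndarray, composite: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of cluster activity with the motor composite.

    Returns (r, two-sided p).  With the documented orientation a positive r
    means more cluster activity goes with better motor performance.
    """
    x = np.asarray(regional_activity, dtype=float)
    y = np.asarray(composite, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 patients")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
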