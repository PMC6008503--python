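"""Mixed-design ANOVA for predictor weights.

The design has two within-subject factors — Poststimulus Time (the FIR
bins, 6 levels) and Force (10%, 30%) — and one between-subject factor,
Group.  Every subject contributes all within cells; group sizes may differ.
The sums-of-squares decomposition is the classical univariate mixed-model
one with subjects treated as a random factor nested in group; each
within-subject effect is tested against its own subject-interaction error
term.  Greenhouse-Geisser epsilon is computed for every within effect and
both uncorrected and GG-adjusted p values are reported, so sphericity
checks are explicit output rather than a silent choice.

Simple main effects (per-bin Force or Group contrasts) are follow-ups to a
significant interaction; the false-discovery-rate family is the set of
poststimulus bins of one follow-up, adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatReport",
    "mixed_anova",
    "anova_from_frame",
    "gg_epsilon",
    "simple_effects",
    "bh_fdr",
]


@dataclass
class StatReport:
    """ANOVA effect table plus formatting helpers."""

    table: pd.DataFrame  # effect, SS, df1, df2, F, p, eta_p2, gg_eps, df1_gg, df2_gg, p_gg

    def summary(self) -> str:
        lines = []
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['effect']}: F({r['df1']:g}, {r['df2']:g}) = {r['F']:.2f}, "
                f"p = {r['p']:.4g}, eta_p2 = {r['eta_p2']:.3f}"
                + (f" [GG eps = {r['gg_eps']:.3f}, p_GG = {r['p_gg']:.4g}]"
                   if np.isfinite(r["gg_eps"]) else ""))
        return "\n".join(lines)

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def gg_epsilon(covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a k x k within-factor covariance.

    Computed from the double-centered covariance; bounded in
    [1/(k-1), 1], with 1 meaning sphericity holds exactly.
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need k >= 2 levels")
    J = np.eye(k) - np.ones((k, k)) / k
    Sc = J @ S @ J
    denom = (k - 1) * np.sum(Sc ** 2)
    if denom == 0:
        return 1.0
    eps = np.trace(Sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _contrast_epsilon(cell_scores: np.ndarray, C: np.ndarray) -> float:
    """Epsilon for a within effect given subject cell scores (n x m) and an
    orthonormal contrast matrix C (q x m) spanning the effect."""
    scores = cell_scores @ C.T
    if scores.shape[1] < 2:
        return 1.0
    S = np.cov(scores, rowvar=False)
    q = C.shape[0]
    denom = q * np.sum(S ** 2)
    if denom == 0:
        return 1.0
    eps = np.trace(S) ** 2 / denom
    return float(np.clip(eps, 1.0 / q, 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts orthogonal to the unit vector."""
    full, _ = np.linalg.qr(np.column_stack(
        [np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]]))
    return full[:, 1:].T


def mixed_anova(y: np.ndarray, groups: np.ndarray) -> StatReport:
    """Two-within one-between mixed ANOVA.

    Parameters
    ----------
    y : (n_subjects, n_time, n_force) array of per-subject cell means.
    groups : length-n_subjects labels of the between factor.

    Raises if any cell is missing (NaN): the design must be complete.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (subjects, time, force)")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    a = len(levels)
    n, T, F = y.shape
    if len(groups) != n:
        raise ValueError("groups length mismatch")
    gi = np.array([np.flatnonzero(levels == g)[0] for g in groups])
    ng = np.bincount(gi, minlength=a).astype(float)
    if (ng < 2).any():
        raise ValueError("need >= 2 subjects per group")

    grand = y.mean()
    m_subj = y.mean(axis=(1, 2))                         # (n,)
    m_g = np.array([y[gi == g].mean() for g in range(a)])
    m_t = y.mean(axis=(0, 2))                            # (T,)
    m_f = y.mean(axis=(0, 1))                            # (F,)
    m_gt = np.stack([y[gi == g].mean(axis=(0, 2)) for g in range(a)])
    m_gf = np.stack([y[gi == g].mean(axis=(0, 1)) for g in range(a)])
    m_tf = y.mean(axis=0)                                # (T, F)
    m_gtf = np.stack([y[gi == g].mean(axis=0) for g in range(a)])
    m_it = y.mean(axis=2)                                # (n, T)
    m_if = y.mean(axis=1)                                # (n, F)

    TF = T * F
    ss_group = TF * np.sum(ng * (m_g - grand) ** 2)
    ss_sw = TF * np.sum((m_subj - m_g[gi]) ** 2)          # subjects within groups
    ss_t = n * F * np.sum((m_t - grand) ** 2)
    ss_tg = F * np.sum(ng[:, None] * (m_gt - m_g[:, None] - m_t + grand) ** 2)
    ss_ts = F * np.sum((m_it - m_subj[:, None] - m_gt[gi] + m_g[gi, None]) ** 2)
    ss_f = n * T * np.sum((m_f - grand) ** 2)
    ss_fg = T * np.sum(ng[:, None] * (m_gf - m_g[:, None] - m_f + grand) ** 2)
    ss_fs = T * np.sum((m_if - m_subj[:, None] - m_gf[gi] + m_g[gi, None]) ** 2)
    ss_tf = n * np.sum((m_tf - m_t[:, None] - m_f + grand) ** 2)
    ss_tfg = np.sum(ng[:, None, None] * (
        m_gtf - m_gt[:, :, None] - m_gf[:, None, :] - m_tf
        + m_g[:, None, None] + m_t[:, None] + m_f - grand) ** 2)
    ss_tfs = np.sum((
        y - m_it[:, :, None] - m_if[:, None, :] - m_gtf[gi]
        + m_subj[:, None, None] + m_gt[gi][:, :, None] + m_gf[gi][:, None, :]
        - m_g[gi][:, None, None]) ** 2)

    df_sw = n - a
    df_ts = (T - 1) * df_sw
    df_fs = (F - 1) * df_sw
    df_tfs = (T - 1) * (F - 1) * df_sw

    # pooled within-group cell scores for epsilon estimation
    cells = y.reshape(n, TF) - m_gtf[gi].reshape(n, TF)
    Ct = np.kron(_orthonormal_contrasts(T), np.ones((1, F)) / np.sqrt(F))
    Cf = np.kron(np.ones((1, T)) / np.sqrt(T), _orthonormal_contrasts(F))
    Ctf = np.kron(_orthonormal_contrasts(T), _orthonormal_contrasts(F))
    eps_t = _contrast_epsilon(cells, Ct)
    eps_f = _contrast_epsilon(cells, Cf)
    eps_tf = _contrast_epsilon(cells, Ctf)

    def row(name, ss_eff, df1, ss_err, df2, eps=np.nan):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        Fval = ms_eff / ms_err if ms_err > 0 else np.inf
        p = scipy.stats.f.sf(Fval, df1, df2)
        out = {
            "effect": name, "SS": ss_eff, "df1": df1, "df2": df2,
            "F": Fval, "p": p,
            "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            "gg_eps": eps,
        }
        if np.isfinite(eps):
            out["df1_gg"] = df1 * eps
            out["df2_gg"] = df2 * eps
            out["p_gg"] = scipy.stats.f.sf(Fval, df1 * eps, df2 * eps)
        else:
            out["df1_gg"] = out["df2_gg"] = out["p_gg"] = np.nan
        return out

    rows = [
        row("group", ss_group, a - 1, ss_sw, df_sw),
        row("time", ss_t, T - 1, ss_ts, df_ts, eps_t),
        row("time:group", ss_tg, (T - 1) * (a - 1), ss_ts, df_ts, eps_t),
        row("force", ss_f, F - 1, ss_fs, df_fs, eps_f),
        row("force:group", ss_fg, (F - 1) * (a - 1), ss_fs, df_fs, eps_f),
        row("time:force", ss_tf, (T - 1) * (F - 1), ss_tfs, df_tfs, eps_tf),
        row("time:force:group", ss_tfg, (T - 1) * (F - 1) * (a - 1),
            ss_tfs, df_tfs, eps_tf),
    ]
    return StatReport(pd.DataFrame(rows))


def anova_from_frame(
    df: pd.DataFrame,
    dv: str = "weight",
    subject: str = "subject",
    time: str = "bin",
    force: str = "condition",
    group: str = "group",
) -> StatReport:
    """Run the mixed ANOVA from a tidy predictor-weight frame."""
    wide = df.pivot_table(index=subject, columns=[time, force], values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells are not allowed")
    t_levels = sorted(df[time].unique())
    f_levels = sorted(df[force].unique())
    y = (wide[[(t, f) for t in t_levels for f in f_levels]]
         .to_numpy().reshape(-1, len(t_levels), len(f_levels)))
    grp = df.drop_duplicates(subject).set_index(subject)[group]
    groups = grp.loc[wide.index].to_numpy()
    return mixed_anova(y, groups)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_effects(
    y: np.ndarray,
    groups: np.ndarray,
    contrast: str = "force",
    paired_method: str = "ttest",
) -> pd.DataFrame:
    """Per-bin follow-up contrasts with FDR adjustment.

    ``contrast="force"`` runs a paired t test (30% vs 10%, averaged over
    groups) at each poststimulus bin; ``contrast="group"`` a pooled-variance
    two-sample t (group 1 vs group 2, averaged over force).  Both raw and
    BH-adjusted p values are reported.
    """
    y = np.asarray(y, dtype=float)
    n, T, F = y.shape
    rows = []
    if contrast == "force":
        if F != 2:
            raise ValueError("force contrast needs exactly 2 levels")
        for t in range(T):
            d = y[:, t, 1] - y[:, t, 0]
            stat, p = scipy.stats.ttest_rel(y[:, t, 1], y[:, t, 0])
            rows.append({"bin": t + 1, "estimate": d.mean(),
                         "t": stat, "df": n - 1, "p": p})
    elif contrast == "group":
        levels = pd.unique(np.asarray(groups))
        if len(levels) != 2:
            raise ValueError("group contrast needs exactly 2 levels")
        g0 = np.asarray(groups) == levels[0]
        for t in range(T):
            v = y[:, t, :].mean(axis=1)
            stat, p = scipy.stats.ttest_ind(v[g0], v[~g0])
            rows.append({"bin": t + 1, "estimate": v[g0].mean() - v[~g0].mean(),
                         "t": stat, "df": n - 2, "p": p})
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out
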