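"""End-to-end orchestration: simulate -> design -> CPCA -> HDR statistics ->
within-network inference -> behavior, with a reproducibility manifest.

Every stage writes its outputs under one run directory; the manifest
records the seed, the full config, and a SHA-256 checksum of every file so
a rerun with the same config and seed can be verified byte by byte (all
randomness is funneled through the single config seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import anova, behavior, cpca, design, permutation, spatial, synthetic

log = logging.getLogger("taskcpca")

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Pipeline configuration with study-design defaults."""

    out_dir: str = "taskcpca_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    n_components: int = 4
    analysis_fraction: float = 0.10   # mask for group inference
    display_fraction: float = 0.05    # mask for display maps
    mask_sign: str = "absolute"
    n_permutations: int = 5000
    tfce: dict = field(default_factory=dict)
    alpha: float = 0.05
    bin_time_convention: str = "midpoint"
    drift_order: int = 2

    def __post_init__(self) -> None:
        for frac in (self.analysis_fraction, self.display_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("loading-threshold fractions must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self) -> synthetic.SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        if "volume_shape" in kwargs:
            kwargs["volume_shape"] = tuple(kwargs["volume_shape"])
        if "isi_range" in kwargs:
            kwargs["isi_range"] = tuple(kwargs["isi_range"])
        return synthetic.SimulationConfig(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    cohort: synthetic.SyntheticCohort
    model: cpca.CPCAModel
    scree: cpca.ScreeResult
    weights: pd.DataFrame
    anova_reports: dict[int, anova.StatReport]
    perm_results: dict[int, permutation.PermutationResult]
    cluster_tables: dict[int, pd.DataFrame]
    dice: dict[int, float]
    behavior_composite: behavior.CompositeResult | None
    brain_behavior: list[dict]
    manifest: dict


def prepare_subject(sub: synthetic.SubjectData, cfg: RunConfig,
                    conditions: list[str], n_bins: int, tr: float):
    """Residualize one subject's data and build their FIR design."""
    shape = sub.bold.shape
    Y = sub.bold.reshape(-1, shape[-1]).T          # scans x voxels
    N = design.build_nuisance(sub.motion, shape[-1], cfg.drift_order)
    Yr = design.residualize(Y, N)
    dm = design.build_fir_design(sub.events, shape[-1], tr, n_bins,
                                 conditions, cfg.bin_time_convention)
    return Yr, dm


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config()
    conditions = list(sim_cfg.force_levels)
    affine = None

    log.info("simulating cohort (%d controls, %d patients)",
             sim_cfg.n_controls, sim_cfg.n_patients)
    cohort = synthetic.simulate_cohort(sim_cfg)
    affine = cohort.subjects[0].affine
    vol_shape = tuple(sim_cfg.volume_shape)

    log.info("building designs and removing nuisance variance")
    per_subject = [
        prepare_subject(s, cfg, conditions, sim_cfg.n_bins, sim_cfg.tr)
        for s in cohort.subjects
    ]
    stacked = design.stack_subjects(
        per_subject, [s.subject_id for s in cohort.subjects])

    log.info("fitting CPCA with %d components", cfg.n_components)
    model = cpca.fit_cpca(stacked.Z, stacked.G, cfg.n_components,
                          columns=stacked.columns)
    scree_res = cpca.scree(model.singular_values, default=cfg.n_components)

    groups = {s.subject_id: s.group for s in cohort.subjects}
    weights = cpca.predictor_weights(model, stacked.G)
    weights["group"] = weights["subject"].map(groups)
    weights.to_csv(out / "predictor_weights.tsv", sep="\t", index=False)

    pd.DataFrame({
        "component": np.arange(1, cfg.n_components + 1),
        "task_variance_fraction": model.task_variance_fraction,
    }).to_csv(out / "variance_table.tsv", sep="\t", index=False)

    # per-component loading maps and display/analysis masks
    analysis_masks: dict[int, spatial.VolumeMask] = {}
    for k in range(cfg.n_components):
        lmap = model.loadings[:, k].reshape(vol_shape)
        nib.save(nib.Nifti1Image(lmap.astype(np.float32), affine),
                 out / f"component_{k + 1}_loadings.nii")
        analysis_masks[k + 1] = spatial.top_fraction_mask(
            lmap, cfg.analysis_fraction, cfg.mask_sign, affine)
        disp = spatial.top_fraction_mask(
            lmap, cfg.display_fraction, cfg.mask_sign, affine)
        nib.save(analysis_masks[k + 1].to_image(),
                 out / f"component_{k + 1}_mask10.nii")
        nib.save(disp.to_image(), out / f"component_{k + 1}_mask05.nii")

    # HDR ANOVAs per component
    log.info("running mixed ANOVAs on predictor weights")
    anova_reports: dict[int, anova.StatReport] = {}
    simple_tables = []
    for k in range(1, cfg.n_components + 1):
        wk = weights[weights["component"] == k]
        rep = anova.anova_from_frame(wk)
        anova_reports[k] = rep
        rep.table.assign(component=k).to_csv(
            out / f"anova_component_{k}.tsv", sep="\t", index=False)
        y, grp = _cell_array(wk)
        for contrast in ("force", "group"):
            se = anova.simple_effects(y, grp, contrast)
            se.insert(0, "component", k)
            se.insert(1, "contrast", contrast)
            simple_tables.append(se)
    pd.concat(simple_tables, ignore_index=True).to_csv(
        out / "simple_effects.tsv", sep="\t", index=False)

    # within-network permutation inference on component-expression maps
    log.info("permutation testing within network masks (%d permutations)",
             cfg.n_permutations)
    expr = cpca.subject_expression_maps(model, stacked)
    ctrl_ids = [s.subject_id for s in cohort.controls]
    pat_ids = [s.subject_id for s in cohort.patients]
    perm_results, cluster_tables = {}, {}
    scheme = permutation.PermutationScheme(
        n_permutations=cfg.n_permutations, seed=cfg.seed + 1)
    tfce_params = permutation.TfceParams(**cfg.tfce)
    for k in range(1, cfg.n_components + 1):
        maps_c = np.stack([expr[i][k - 1].reshape(vol_shape) for i in ctrl_ids])
        maps_p = np.stack([expr[i][k - 1].reshape(vol_shape) for i in pat_ids])
        res = permutation.permutation_test(
            maps_c, maps_p, scheme, tfce_params, analysis_masks[k].data)
        perm_results[k] = res
        cluster_tables[k] = permutation.cluster_summary(
            res.p_min, cfg.alpha, analysis_masks[k].data,
            tfce_params.connectivity)
        nib.save(nib.Nifti1Image(res.p_min.astype(np.float32), affine),
                 out / f"component_{k}_pfwe.nii")
        cluster_tables[k].to_csv(out / f"component_{k}_clusters.tsv",
                                 sep="\t", index=False)

    # lesion overlap and Dice against each network's analysis mask
    dice_by_comp: dict[int, float] = {}
    lesions = [s.lesion for s in cohort.patients if s.lesion is not None]
    if lesions:
        overlap = spatial.lesion_overlap(lesions)
        nib.save(nib.Nifti1Image(overlap.astype(np.int16), affine),
                 out / "lesion_overlap.nii")
        overlap_mask = spatial.VolumeMask(overlap > 0, affine)
        for k, m in analysis_masks.items():
            dice_by_comp[k] = spatial.dice(m, overlap_mask)
        pd.DataFrame({
            "component": list(dice_by_comp),
            "dice": list(dice_by_comp.values()),
        }).to_csv(out / "lesion_dice.tsv", sep="\t", index=False)

    # behavior: composite and correlation with significant-cluster activity
    composite = None
    brain_behavior_rows: list[dict] = []
    btable = cohort.behavior_table()
    if len(btable) >= 3:
        composite = behavior.composite_score(btable)
        btable = btable.assign(composite=composite.scores)
        btable.to_csv(out / "behavior_composite.tsv", sep="\t", index=False)
        for k, ct in cluster_tables.items():
            for _, row in ct.iterrows():
                cl_mask = permutation.cluster_mask(
                    perm_results[k].p_min, cfg.alpha, row["peak_voxel"],
                    analysis_masks[k].data, tfce_params.connectivity)
                activity = np.array([
                    expr[i][k - 1].reshape(vol_shape)[cl_mask].mean()
                    for i in pat_ids])
                r, p = behavior.brain_behavior_correlation(
                    activity, composite.scores)
                peak = tuple(row["peak_voxel"])
                direction = ("control>patient"
                             if perm_results[k].p_pos[peak] < cfg.alpha
                             else "patient>control")
                brain_behavior_rows.append({
                    "component": k, "cluster": int(row["cluster"]),
                    "size": int(row["size"]), "direction": direction,
                    "r": r, "p": p,
                    "orientation": composite.orientation})
        if brain_behavior_rows:
            pd.DataFrame(brain_behavior_rows).to_csv(
                out / "brain_behavior.tsv", sep="\t", index=False)

    manifest = _write_manifest(out, cfg, scree_res)
    return PipelineResult(
        out_dir=out, cohort=cohort, model=model, scree=scree_res,
        weights=weights, anova_reports=anova_reports,
        perm_results=perm_results, cluster_tables=cluster_tables,
        dice=dice_by_comp, behavior_composite=composite,
        brain_behavior=brain_behavior_rows, manifest=manifest)


def _cell_array(wk: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predictor-weight frame -> (subjects x time x force, group labels)."""
    t_levels = sorted(wk["bin"].unique())
    f_levels = sorted(wk["condition"].unique())
    wide = wk.pivot_table(index="subject", columns=["bin", "condition"],
                          values="weight")
    y = (wide[[(t, f) for t in t_levels for f in f_levels]]
         .to_numpy().reshape(-1, len(t_levels), len(f_levels)))
    grp = wk.drop_duplicates("subject").set_index("subject")["group"]
    return y, grp.loc[wide.index].to_numpy()


def _write_manifest(out: Path, cfg: RunConfig,
                    scree_res: cpca.ScreeResult) -> dict:
    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "suggested_components": scree_res.suggested,
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
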