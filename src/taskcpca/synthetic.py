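"""Synthetic multi-subject task-fMRI cohorts with known ground truth.

The generator emulates the study design the analysis targets: each subject
performs 50 visually cued isometric hand grips at two force levels (10% and
30% of maximum voluntary contraction) in randomized order, each grip
sustained 3 s and followed by a 3-7 s uniform interstimulus interval,
sampled at TR = 3.25 s.  The cohort has two groups — 24 "controls" and 17
"patients" — whose evoked network amplitudes differ by planted group
multipliers, and patients carry lesion masks and three behavioral scores
coupled to their planted sensorimotor amplitude.

Signal model per subject::

    Y(t, v) = sum_net  a[s, net] * (FIR event train ⊛ planted bin curve)(t) * map_net(v)
              + polynomial drift + AR(1) noise

where ``a[s, net]`` is the group multiplier times a per-subject lognormal
jitter.  The hemodynamic ground truth is specified directly as FIR bin
amplitudes so recovery tests compare like with like with the FIR estimator.
Ground truth (maps, bin curves, multipliers, per-subject amplitudes) is
stored losslessly on the returned objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import build_fir_design
from .spatial import VolumeMask

__all__ = [
    "NetworkTemplate",
    "SimulationConfig",
    "SubjectData",
    "SyntheticCohort",
    "default_templates",
    "simulate_events",
    "simulate_subject",
    "simulate_cohort",
    "simulate_behavior_cohort",
    "write_cohort",
]

CONTROL = "control"
PATIENT = "patient"


@dataclass
class NetworkTemplate:
    """One planted functional network.

    ``spatial_map`` holds per-voxel weights in [-1, 1]; ``hdr`` maps each
    condition label to its planted FIR bin amplitude curve; ``group_mult``
    scales the whole network per group.
    """

    name: str
    spatial_map: np.ndarray
    hdr: dict[str, np.ndarray]
    group_mult: dict[str, float]

    def __post_init__(self) -> None:
        self.spatial_map = np.asarray(self.spatial_map, dtype=float)
        self.hdr = {c: np.asarray(h, dtype=float) for c, h in self.hdr.items()}
        for m in self.group_mult.values():
            if not np.isfinite(m):
                raise ValueError("group multiplier must be finite")


def _blob(shape: tuple[int, int, int], center: tuple[float, float, float],
          sigma_rel: float = 0.10) -> np.ndarray:
    """Gaussian blob at relative coordinates, peak 1."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c * (n - 1)) / (sigma_rel * n)) ** 2
             for g, c, n in zip(grids, center, shape))
    return np.exp(-0.5 * d2)


def default_templates(shape: tuple[int, int, int] = (12, 12, 12),
                      force_levels: tuple[str, str] = ("10%", "30%"),
                      n_bins: int = 6) -> list[NetworkTemplate]:
    """Four networks mirroring the study's functional anatomy at toy scale.

    A bilateral dorsal attention network, a posterior visual network, a
    left-lateralized sensorimotor network (reduced in patients), and a
    midline default-mode network that deactivates during the grip (patients
    deactivate less).  The networks differ in the *shape* of their planted
    FIR bin curves — an early attentional transient, a sustained visual
    response, a mid-latency motor peak with undershoot, and a late
    deactivation — which is exactly the temporal structure the constrained
    PCA exploits to separate them.  Force levels modulate the visual and
    motor curves (30% > 10%); the left hemisphere occupies the low-x half
    of the grid.
    """
    levels = list(force_levels)
    lo, hi = levels[0], levels[-1]  # collapse gracefully for one level

    def curve(vals):
        return np.asarray(vals, dtype=float)[:n_bins]

    # peak-normalized shapes x network strength; strengths give a realistic
    # strongest-to-weakest hierarchy of task-variance fractions
    attn_c = 0.8 * curve([1.20, 0.20, -0.25, -0.10, 0.00, 0.00])
    vis_c = 1.1 * curve([0.45, 1.10, 0.60, 0.00, -0.15, 0.00])
    mot_c = 1.5 * curve([0.00, 0.35, 1.00, 0.80, 0.10, -0.30])
    dmn_c = 2.3 * curve([0.00, -0.20, -0.60, -1.10, -0.80, -0.30])

    attention = NetworkTemplate(
        "attention",
        _blob(shape, (0.24, 0.45, 0.86), 0.11)
        + _blob(shape, (0.76, 0.45, 0.86), 0.11),
        {lo: attn_c, hi: attn_c},
        {CONTROL: 1.0, PATIENT: 1.0},
    )
    visual = NetworkTemplate(
        "visual",
        _blob(shape, (0.50, 0.08, 0.35), 0.11),
        {lo: 0.85 * vis_c, hi: 1.15 * vis_c},
        {CONTROL: 1.0, PATIENT: 1.0},
    )
    motor_map = (_blob(shape, (0.18, 0.72, 0.55), 0.11)
                 - 0.45 * _blob(shape, (0.85, 0.72, 0.45), 0.09))
    motor = NetworkTemplate(
        "motor",
        motor_map,
        {lo: 0.80 * mot_c, hi: 1.20 * mot_c},
        {CONTROL: 1.0, PATIENT: 0.6},
    )
    dmn = NetworkTemplate(
        "dmn",
        _blob(shape, (0.50, 0.34, 0.68), 0.11)
        + _blob(shape, (0.50, 0.90, 0.55), 0.09),
        {lo: dmn_c, hi: 1.10 * dmn_c},
        {CONTROL: 1.0, PATIENT: 0.5},
    )
    return [attention, visual, motor, dmn]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults reproduce the emulated experiment: 24 controls + 17 patients,
    50 grips per subject at 10%/30% force in random order, 3 s grips, 3-7 s
    ISIs, TR = 3.25 s, 6 FIR bins, small desk-scale volumes.
    """

    n_controls: int = 24
    n_patients: int = 17
    volume_shape: tuple[int, int, int] = (12, 12, 12)
    tr: float = 3.25
    n_trials: int = 50
    grip_duration: float = 3.0
    isi_range: tuple[float, float] = (3.0, 7.0)
    force_levels: tuple[str, ...] = ("10%", "30%")
    n_bins: int = 6
    network_templates: list[NetworkTemplate] | None = None
    noise_ar1: float = 0.3
    noise_sd: float = 0.35
    drift_order: int = 2
    drift_sd: float = 0.5
    motion_step_sd: float = 0.02
    amplitude_jitter_sd: float = 0.25
    behavior_coupling: float = 100.0
    behavior_noise_sd: float = 10.0
    behavior_loadings: tuple[float, float, float] = (0.9, 0.9, 0.9)
    lesion_fraction: float = 1.0
    initial_rest: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range min must be <= max")
        if any(n < 4 for n in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 4")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if self.network_templates is None:
            self.network_templates = default_templates(
                self.volume_shape, self.force_levels[:2], self.n_bins)
        for t in self.network_templates:
            if t.spatial_map.shape != tuple(self.volume_shape):
                raise ValueError(
                    f"template {t.name!r} shape {t.spatial_map.shape} does not "
                    f"match volume_shape {self.volume_shape}")


@dataclass
class SubjectData:
    subject_id: str
    group: str
    bold: np.ndarray                      # (x, y, z, t)
    events: pd.DataFrame                  # onset, duration, condition
    motion: np.ndarray                    # (t, 6)
    behavior: np.ndarray | None           # 3 scores (% of unaffected hand)
    lesion: VolumeMask | None
    amplitudes: dict[str, float]          # planted per-network amplitude
    affine: np.ndarray

    @property
    def n_scans(self) -> int:
        return self.bold.shape[-1]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    subjects: list[SubjectData]
    templates: list[NetworkTemplate] = field(default_factory=list)

    @property
    def patients(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.group == PATIENT]

    @property
    def controls(self) -> list[SubjectData]:
        return [s for s in self.subjects if s.group == CONTROL]

    def behavior_table(self) -> pd.DataFrame:
        rows = [
            {"subject": s.subject_id, "group": s.group,
             "grip_strength": s.behavior[0], "nhpt": s.behavior[1],
             "bbt": s.behavior[2]}
            for s in self.subjects if s.behavior is not None
        ]
        return pd.DataFrame(rows)


def simulate_events(cfg: SimulationConfig, subject_seed: int) -> pd.DataFrame:
    """Randomized balanced grip schedule for one subject.

    Conditions are a random permutation of a balanced label vector;
    consecutive onsets are separated by grip duration plus a uniform ISI
    from ``isi_range``.  Deterministic given the seed.
    """
    levels = list(cfg.force_levels)
    if cfg.n_trials < len(levels):
        raise ValueError("n_trials must be at least the number of force levels")
    rng = np.random.default_rng(subject_seed)
    base, extra = divmod(cfg.n_trials, len(levels))
    labels = levels * base + levels[:extra]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    isis = rng.uniform(*cfg.isi_range, size=cfg.n_trials)
    onsets = cfg.initial_rest + np.concatenate(
        [[0.0], np.cumsum(cfg.grip_duration + isis[:-1])])
    return pd.DataFrame({
        "onset": onsets,
        "duration": np.full(cfg.n_trials, cfg.grip_duration),
        "condition": labels,
    })


def _n_scans(cfg: SimulationConfig, events: pd.DataFrame) -> int:
    """Scan count covering the schedule plus a full FIR tail."""
    end = events["onset"].iloc[-1] + cfg.n_bins * cfg.tr
    return int(np.ceil(end / cfg.tr)) + 1


def _affine(cfg: SimulationConfig) -> np.ndarray:
    # RAS, 1 mm voxels; x is the left-right axis, low x = left hemisphere
    aff = np.eye(4)
    aff[:3, 3] = -(np.asarray(cfg.volume_shape) - 1) / 2.0
    return aff


def simulate_subject(cfg: SimulationConfig, group: str,
                     subject_seed: int,
                     subject_id: str | None = None,
                     with_lesion: bool = False) -> SubjectData:
    """Forward-simulate one subject's 4D run, motion, and behavior."""
    if group not in (CONTROL, PATIENT):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    events = simulate_events(cfg, subject_seed)
    n_scans = _n_scans(cfg, events)
    shape = tuple(cfg.volume_shape)
    n_vox = int(np.prod(shape))
    conditions = list(cfg.force_levels)
    dm = build_fir_design(events, n_scans, cfg.tr, cfg.n_bins, conditions)

    Y = np.zeros((n_scans, n_vox))
    amplitudes: dict[str, float] = {}
    for tpl in cfg.network_templates:
        jitter = (np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd))
                  if cfg.amplitude_jitter_sd > 0 else 1.0)
        amp = tpl.group_mult[group] * jitter
        amplitudes[tpl.name] = amp
        h = np.concatenate([tpl.hdr[c] for c in conditions])
        tc = dm.G @ h                      # evoked time course of this network
        Y += amp * np.outer(tc, tpl.spatial_map.ravel())

    if cfg.drift_order > 0 and cfg.drift_sd > 0:
        t = np.linspace(-1.0, 1.0, n_scans)
        for d in range(1, cfg.drift_order + 1):
            basis = np.polynomial.legendre.Legendre.basis(d)(t)
            Y += np.outer(basis, rng.normal(0.0, cfg.drift_sd, n_vox))

    if cfg.noise_sd > 0:
        w = rng.normal(0.0, 1.0, (n_scans, n_vox))
        noise = np.empty_like(w)
        noise[0] = w[0]
        a = cfg.noise_ar1
        innov = np.sqrt(1.0 - a * a)
        for ti in range(1, n_scans):
            noise[ti] = a * noise[ti - 1] + innov * w[ti]
        Y += cfg.noise_sd * noise

    motion = np.cumsum(rng.normal(0.0, cfg.motion_step_sd, (n_scans, 6)), axis=0)

    behavior = None
    if group == PATIENT:
        motor_amp = next(
            (amplitudes[t.name] for t in cfg.network_templates
             if "motor" in t.name), next(iter(amplitudes.values())))
        behavior = np.clip(
            cfg.behavior_coupling * motor_amp * np.asarray(cfg.behavior_loadings)
            + rng.normal(0.0, cfg.behavior_noise_sd, 3),
            0.0, None)

    lesion = None
    if with_lesion and group == PATIENT:
        # small deep (subcortical-like) blob in the left (low-x) hemisphere,
        # below the cortical network blobs so spatial overlap stays minimal
        nx, ny, nz = shape
        cx = rng.integers(1, max(2, nx // 2 - 1))
        cy = rng.integers(ny // 3, 2 * ny // 3 + 1)
        cz = rng.integers(2, max(3, nz // 3) + 1)
        r = rng.integers(1, 3)
        gx, gy, gz = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        lesion_data = ((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2) <= r ** 2
        lesion_data &= gx < nx // 2
        lesion = VolumeMask(lesion_data, _affine(cfg))

    return SubjectData(
        subject_id=subject_id or f"sub-{subject_seed:08d}",
        group=group,
        bold=Y.T.reshape(shape + (n_scans,)),
        events=events,
        motion=motion,
        behavior=behavior,
        lesion=lesion,
        amplitudes=amplitudes,
        affine=_affine(cfg),
    )


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Simulate the full two-group cohort with per-subject seeds."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        cfg.n_controls + cfg.n_patients)
    n_lesioned = int(round(cfg.lesion_fraction * cfg.n_patients))
    subjects = []
    idx = 0
    for i in range(cfg.n_controls):
        subjects.append(simulate_subject(
            cfg, CONTROL, int(seeds[idx]), subject_id=f"sub-c{i + 1:02d}"))
        idx += 1
    for i in range(cfg.n_patients):
        subjects.append(simulate_subject(
            cfg, PATIENT, int(seeds[idx]), subject_id=f"sub-p{i + 1:02d}",
            with_lesion=i < n_lesioned))
        idx += 1
    return SyntheticCohort(config=cfg, subjects=subjects,
                           templates=list(cfg.network_templates))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write the cohort to disk: per-subject 4D NIfTI, BIDS-style 3-column
    event TSVs, 6-column motion text files, lesion masks, and a cohort
    table with group labels and behavioral scores."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(s.bold.astype(np.float32), s.affine),
                 sdir / "bold.nii")
        ev = s.events.rename(columns={"condition": "trial_type"})
        ev.to_csv(sdir / "events.tsv", sep="\t", index=False)
        np.savetxt(sdir / "motion.txt", s.motion, fmt="%.6f")
        if s.lesion is not None:
            nib.save(s.lesion.to_image(), sdir / "lesion.nii")
        row = {"subject": s.subject_id, "group": s.group}
        if s.behavior is not None:
            row.update(grip_strength=s.behavior[0], nhpt=s.behavior[1],
                       bbt=s.behavior[2])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "participants.tsv", sep="\t", index=False)
    return out


def simulate_behavior_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Patient-level planted amplitudes and behavioral scores only.

    Draws the same generative quantities as the full simulator — lognormal
    amplitude jitter per network and the coupling of the three motor
    measures to the planted sensorimotor amplitude — without rendering 4D
    volumes, for Monte-Carlo studies of the behavioral analysis.  One row
    per patient with the planted motor amplitude and the three measures.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_patients)
    motor_name = next((t.name for t in cfg.network_templates
                       if "motor" in t.name), cfg.network_templates[0].name)
    rows = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(int(seeds[i]))
        amps = {
            t.name: t.group_mult[PATIENT]
            * (np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd))
               if cfg.amplitude_jitter_sd > 0 else 1.0)
            for t in cfg.network_templates
        }
        scores = np.clip(
            cfg.behavior_coupling * amps[motor_name]
            * np.asarray(cfg.behavior_loadings)
            + rng.normal(0.0, cfg.behavior_noise_sd, 3),
            0.0, None)
        rows.append({"subject": f"sub-p{i + 1:02d}", "group": PATIENT,
                     "motor_amplitude": amps[motor_name],
                     "grip_strength": scores[0], "nhpt": scores[1],
                     "bbt": scores[2]})
    return pd.DataFrame(rows)


def noiseless(cfg: SimulationConfig, **overrides) -> SimulationConfig:
    """Copy of ``cfg`` with all stochastic nuisance terms switched off."""
    return replace(cfg, noise_sd=0.0, drift_order=0, amplitude_jitter_sd=0.0,
                   behavior_noise_sd=0.0, **overrides)
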