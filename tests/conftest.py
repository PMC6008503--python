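import numpy as np
import pytest

from taskcpca import design, synthetic
from taskcpca.pipeline import RunConfig, prepare_subject


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study config: fewer subjects/trials, tiny volume."""
    return synthetic.SimulationConfig(
        n_controls=6, n_patients=5, volume_shape=(8, 8, 8),
        n_trials=16, seed=7)


@pytest.fixture(scope="session")
def fitted_cohort():
    """Default-design cohort, residualized, stacked and CPCA-fitted once."""
    from taskcpca import cpca

    cfg = synthetic.SimulationConfig(seed=1)
    cohort = synthetic.simulate_cohort(cfg)
    rc = RunConfig()
    per = [prepare_subject(s, rc, list(cfg.force_levels), cfg.n_bins, cfg.tr)
           for s in cohort.subjects]
    stacked = design.stack_subjects(
        per, [s.subject_id for s in cohort.subjects])
    model = cpca.fit_cpca(stacked.Z, stacked.G, 4, columns=stacked.columns)
    return cfg, cohort, stacked, model


def best_match_correlations(templates, loadings):
    """|spatial r| between each planted map and its best-matching component."""
    return [
        max(abs(np.corrcoef(t.spatial_map.ravel(), loadings[:, k])[0, 1])
            for k in range(loadings.shape[1]))
        for t in templates
    ]
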