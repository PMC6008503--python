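"""Behavioral composite and brain-behavior correlation.

Collapses the three motor measures (grip strength, NHPT, BBT, each as % of
the unaffected hand) into a first-principal-component impairment composite
(oriented so higher = better performance), then correlates per-patient
activity in the sensorimotor network's significant activation cluster with
the composite.  Writes the composite scores and the correlation report.

Run:  python analysis/05_brain_behavior.py [--seed 1]
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from taskcpca import behavior, cpca, permutation, spatial

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

spec = importlib.util.spec_from_file_location("fit02", HERE / "02_fit_networks.py")
fit02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(fit02)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-permutations", type=int, default=1000)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg, cohort, stacked, model = fit02.fit(args.seed)
    shape = tuple(cfg.volume_shape)

    btable = cohort.behavior_table()
    comp = behavior.composite_score(btable)
    btable = btable.assign(composite=comp.scores)
    btable.to_csv(RESULTS / "behavior_composite.tsv", sep="\t", index=False)
    print(f"PC1 explains {100 * comp.variance_explained:.1f}% of the three "
          f"motor measures ({comp.orientation})")

    # sensorimotor component = best template match
    mot = next(t for t in cohort.templates if t.name == "motor")
    k = 1 + int(np.argmax([abs(np.corrcoef(mot.spatial_map.ravel(),
                                           model.loadings[:, j])[0, 1])
                           for j in range(4)]))
    expr = cpca.subject_expression_maps(model, stacked)
    ctrl = [s.subject_id for s in cohort.controls]
    pats = [s.subject_id for s in cohort.patients]
    mask = spatial.top_fraction_mask(
        model.loadings[:, k - 1].reshape(shape), 0.10, "absolute")
    res = permutation.permutation_test(
        np.stack([expr[i][k - 1].reshape(shape) for i in ctrl]),
        np.stack([expr[i][k - 1].reshape(shape) for i in pats]),
        permutation.PermutationScheme(args.n_permutations, seed=args.seed + 1),
        permutation.TfceParams(), mask.data)
    tab = permutation.cluster_summary(res.p_min, 0.05, mask.data)

    rows = []
    for _, row in tab.iterrows():
        cl = permutation.cluster_mask(res.p_min, 0.05, row["peak_voxel"],
                                      mask.data)
        act = np.array([expr[i][k - 1].reshape(shape)[cl].mean()
                        for i in pats])
        r, p = behavior.brain_behavior_correlation(act, comp.scores)
        direction = ("control>patient"
                     if res.p_pos[tuple(row["peak_voxel"])] < 0.05
                     else "patient>control")
        rows.append({"component": k, "cluster": int(row["cluster"]),
                     "size": int(row["size"]), "direction": direction,
                     "r": r, "p": p})
        print(f"motor-network cluster {int(row['cluster'])} "
              f"({direction}, {int(row['size'])} voxels): "
              f"r = {r:.2f}, p = {p:.2g}")
    pd.DataFrame(rows).to_csv(RESULTS / "brain_behavior.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
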