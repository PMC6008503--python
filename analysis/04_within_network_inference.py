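"""Within-network group inference and lesion overlap.

Inside each network's extreme-10% loading mask, subject component-
expression maps are compared between groups by TFCE permutation testing
with max-statistic FWE correction.  The lesion overlap map is compared to
each network mask by Dice similarity.  Writes cluster and Dice tables.

Run:  python analysis/04_within_network_inference.py [--seed 1]
         [--n-permutations 1000]
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from taskcpca import cpca, permutation, spatial

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
    expr = cpca.subject_expression_maps(model, stacked)
    ctrl = [s.subject_id for s in cohort.controls]
    pats = [s.subject_id for s in cohort.patients]
    scheme = permutation.PermutationScheme(
        n_permutations=args.n_permutations, seed=args.seed + 1)
    params = permutation.TfceParams()

    cluster_rows, dice_rows = [], []
    overlap = spatial.lesion_overlap(
        [s.lesion for s in cohort.patients if s.lesion is not None])
    overlap_mask = spatial.VolumeMask(overlap > 0)
    print(f"lesion overlap: max {overlap.max()} patients share a voxel")

    for k in range(1, 5):
        lmap = model.loadings[:, k - 1].reshape(shape)
        mask = spatial.top_fraction_mask(lmap, 0.10, "absolute")
        res = permutation.permutation_test(
            np.stack([expr[i][k - 1].reshape(shape) for i in ctrl]),
            np.stack([expr[i][k - 1].reshape(shape) for i in pats]),
            scheme, params, mask.data)
        tab = permutation.cluster_summary(res.p_min, 0.05, mask.data)
        for _, row in tab.iterrows():
            direction = ("control>patient"
                         if res.p_pos[tuple(row["peak_voxel"])] < 0.05
                         else "patient>control")
            cluster_rows.append({"component": k, **row.to_dict(),
                                 "direction": direction})
        d = spatial.dice(mask, overlap_mask)
        dice_rows.append({"component": k, "dice": d})
        print(f"component {k}: {len(tab)} FWE cluster(s); "
              f"Dice vs lesion overlap = {d:.3f}")

    pd.DataFrame(cluster_rows).to_csv(RESULTS / "within_network_clusters.tsv",
                                      sep="\t", index=False)
    pd.DataFrame(dice_rows).to_csv(RESULTS / "lesion_dice.tsv", sep="\t",
                                   index=False)


if __name__ == "__main__":
    main()
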