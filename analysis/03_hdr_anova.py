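"""Estimated HDR shapes and their mixed-design ANOVAs.

For each extracted network, predictor weights trace subject- and
condition-specific estimated hemodynamic responses over the six
poststimulus scans.  Each network's weights enter a 6 (Poststimulus Time)
x 2 (Force: 10%, 30%) x 2 (Group) mixed ANOVA with Greenhouse-Geisser
checks, followed by per-bin simple effects with Benjamini-Hochberg FDR.
Writes the weight table, ANOVA summaries, and simple-effect tables.

Run:  python analysis/03_hdr_anova.py [--seed 1]
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from taskcpca import anova, cpca

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

spec = importlib.util.spec_from_file_location("fit02", HERE / "02_fit_networks.py")
fit02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(fit02)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg, cohort, stacked, model = fit02.fit(args.seed)
    weights = cpca.predictor_weights(model, stacked.G)
    groups = {s.subject_id: s.group for s in cohort.subjects}
    weights["group"] = weights["subject"].map(groups)
    weights.to_csv(RESULTS / "predictor_weights.tsv", sep="\t", index=False)

    from taskcpca.pipeline import _cell_array

    summaries, simple_tabs = [], []
    for k in range(1, 5):
        wk = weights[weights["component"] == k]
        rep = anova.anova_from_frame(wk)
        summaries.append(rep.table.assign(component=k))
        print(f"--- component {k} ---")
        print(rep.summary())
        y, grp = _cell_array(wk)
        for contrast in ("force", "group"):
            tab = anova.simple_effects(y, grp, contrast)
            tab.insert(0, "component", k)
            tab.insert(1, "contrast", contrast)
            simple_tabs.append(tab)
            hits = tab.loc[tab["p_fdr"] < 0.05, "bin"].tolist()
            if hits:
                print(f"  {contrast} simple effects (p_FDR < .05) at bins:"
                      f" {hits}")
    pd.concat(summaries, ignore_index=True).to_csv(
        RESULTS / "anova_tables.tsv", sep="\t", index=False)
    pd.concat(simple_tabs, ignore_index=True).to_csv(
        RESULTS / "simple_effects.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
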