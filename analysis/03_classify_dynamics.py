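#!/usr/bin/env python
"""Classify proteins as dynamic or invariable with the both-baits >1.2-fold
rule (max/Ctrl or Ctrl/min over the HS10..Re10 window against HS0) and score
the calls against the planted truth.

Writes results/calls.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sglife import dynamics, quant

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--normdir", type=Path, default=ROOT / "results" / "normalized")
    ap.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--threshold", type=float, default=1.2)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "calls.tsv")
    args = ap.parse_args()

    mg = quant.read_quant_table(args.normdir / "normalized_g3bp1.tsv",
                                args.simdir / "design_g3bp1.tsv")
    mc = quant.read_quant_table(args.normdir / "normalized_caprin1.tsv",
                                args.simdir / "design_caprin1.tsv")
    fcg, excl_g = dynamics.fold_changes(mg, "G3BP1")
    fcc, excl_c = dynamics.fold_changes(mc, "CAPRIN1")
    calls = dynamics.classify_dynamic(fcg, fcc, threshold=args.threshold)

    by_g = {f.protein: f for f in fcg}
    by_c = {f.protein: f for f in fcc}
    df = pd.DataFrame([
        (c.protein, by_g[c.protein].fc_up, by_g[c.protein].fc_down,
         by_c[c.protein].fc_up, by_c[c.protein].fc_down, c.label)
        for c in calls
    ], columns=["accession", "fc_up_g3bp1", "fc_down_g3bp1",
                "fc_up_caprin1", "fc_down_caprin1", "label"])
    df.to_csv(args.out, sep="\t", index=False)

    truth = pd.read_csv(args.simdir / "truth.tsv", sep="\t").set_index("accession")
    merged = df.set_index("accession").join(truth)
    correct = ((merged["label"] == "dynamic")
               == (merged["true_class"] != "invariable")).mean()
    n_dyn = (df["label"] == "dynamic").sum()
    print(f"{n_dyn} dynamic / {len(df) - n_dyn} invariable "
          f"(excluded: {len(excl_g)} G3BP1, {len(excl_c)} CAPRIN1)")
    print(f"accuracy vs planted truth: {correct:.3f}")


if __name__ == "__main__":
    main()
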