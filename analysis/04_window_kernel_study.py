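#!/usr/bin/env python
"""Cross-validate every kernel at every window length.

Runs 10-fold stratified CV for the six SVM kernel configurations (linear,
quadratic, cubic, fine/medium/coarse Gaussian) on the selected features at
window lengths 1-5 min, and writes the accuracy matrix to
results/accuracy_matrix.csv.
"""

import argparse

import pandas as pd

from emgstress import classify, features, io, selection


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--selection", default="results/selection.json")
    parser.add_argument("--features-dir", default="results")
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", default="results/accuracy_matrix.csv")
    args = parser.parse_args()

    sel = selection.load_selection(args.selection)
    cv = classify.CVConfig(k=args.folds, seed=args.seed)
    specs = classify.kernel_grid(P=len(sel.selected))
    lengths = (1, 2, 3, 4, 5)

    matrix = pd.DataFrame(index=list(classify.KERNEL_NAMES),
                          columns=[f"{L}min" for L in lengths], dtype=float)
    for L in lengths:
        table = features.read_feature_table(f"{args.features_dir}/features_{L}min.csv")
        X = table[list(sel.selected)].to_numpy(dtype=float)
        y = (table["label"] == io.SC).to_numpy(dtype=int)
        for name in classify.KERNEL_NAMES:
            report = classify.crossvalidate(
                lambda name=name: classify.SVMStressClassifier(specs[name]), X, y, cv
            )
            matrix.loc[name, f"{L}min"] = report.accuracy

    matrix.rename_axis("kernel").to_csv(args.out)
    print(f"10-fold CV accuracy (%) on features {', '.join(sel.selected)}:")
    print(matrix.to_string(float_format=lambda v: f"{v:5.1f}"))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
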