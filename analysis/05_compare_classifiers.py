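#!/usr/bin/env python
"""Compare the SVM against the MLP comparator on the 5-min windows.

Cross-validates the cubic-kernel SVM and the 2-10-2 tanh MLP (trained by
Levenberg-Marquardt least squares) on the selected features and writes
accuracy and AUC for both to results/comparison.csv.
"""

import argparse

import pandas as pd

from emgstress import classify, features, io, selection


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", default="results/features_5min.csv")
    parser.add_argument("--selection", default="results/selection.json")
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", default="results/comparison.csv")
    args = parser.parse_args()

    sel = selection.load_selection(args.selection)
    table = features.read_feature_table(args.features)
    X = table[list(sel.selected)].to_numpy(dtype=float)
    y = (table["label"] == io.SC).to_numpy(dtype=int)
    cv = classify.CVConfig(k=args.folds, seed=args.seed)

    svm = classify.crossvalidate(
        lambda: classify.SVMStressClassifier(classify.kernel_grid(P=len(sel.selected))["cubic"]),
        X, y, cv,
    )
    mlp = classify.crossvalidate(
        lambda: classify.MLPStressClassifier(hidden=10, seed=args.seed), X, y, cv
    )

    comparison = pd.DataFrame(
        [
            {"classifier": "SVM (cubic)", "accuracy": svm.accuracy, "auc": svm.auc},
            {"classifier": "MLP", "accuracy": mlp.accuracy, "auc": mlp.auc},
        ]
    )
    comparison.to_csv(args.out, index=False)
    print(comparison.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        f"\nSVM sensitivity {svm.sensitivity:.1f}%, specificity {svm.specificity:.1f}% "
        f"(stress = positive class); wrote {args.out}"
    )


if __name__ == "__main__":
    main()
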