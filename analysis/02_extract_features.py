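#!/usr/bin/env python
"""Segment, normalize, and extract the 17 statistical time features.

Reads the cohort written by 01_simulate_cohort.py, cuts the five 5-min
scenario windows per subject, truncates them to each study length (1-5 min),
z-scores every window with its subject's rest baseline, and writes one
feature table per window length to results/.
"""

import argparse

from emgstress import experiment, features


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", default="scratch/cohort")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    cohort = experiment.load_cohort(args.cohort)
    for L in (1, 2, 3, 4, 5):
        table = experiment.feature_table_for_length(cohort, float(L))
        path = f"{args.out}/features_{L}min.csv"
        features.write_feature_table(table, path)
        n_values = table[list(features.FEATURE_NAMES)].size
        print(f"{path}: {len(table)} segments x 17 features = {n_values} values")
    counts = table.groupby("label").size()
    print(f"label balance: {counts['NSC']} NSC (rest) vs {counts['SC']} SC (city+highway)")


if __name__ == "__main__":
    main()
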