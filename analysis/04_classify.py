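"""Nested leave-one-out SVM classification of the three group pairs.

For each pairwise problem (AD-NC, aMCI-NC, AD-aMCI): min-max
normalization and Welch-t feature ranking inside every fold, inner-LOOCV
grid search over (C, gamma), outer-LOOCV evaluation. Emits per-subject
predictions, ROC points, the feature selection-frequency table and a
summary JSON, plus the hyperplane-distance vs MMSE correlation and a
repeated leave-4-out validation of the AD-NC problem.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import _path  # noqa: F401
from hipporad.classify import (
    SMALL_GRID,
    SVMGridConfig,
    hyperplane_score_correlation,
    nested_loocv,
    repeated_leave_k_out,
    roc_auc,
)
from hipporad.pipeline import read_feature_table
from hipporad.stats import adjust_covariates

PAIRS = (("AD", "NC"), ("aMCI", "NC"), ("AD", "aMCI"))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--k-features", type=int, default=30)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--full-grid",
        action="store_true",
        help="use the full 11x10 powers-of-two (C, gamma) grid instead of the quick 2x2 grid",
    )
    args = parser.parse_args()

    table = read_feature_table(args.features)
    adjusted = adjust_covariates(table.features, table.covariates)
    groups = adjusted.groups.to_numpy()
    grid = SVMGridConfig() if args.full_grid else SMALL_GRID

    args.out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    for pos, neg in PAIRS:
        keep = np.isin(groups, (pos, neg))
        X = adjusted.features.to_numpy()[keep]
        y = groups[keep]
        cv = nested_loocv(X, y, grid=grid, k_features=args.k_features, positive_label=pos)
        tag = f"{pos.lower()}_{neg.lower()}"
        pd.DataFrame(
            {
                "subject_id": adjusted.features.index[keep],
                "true": cv.true,
                "predicted": cv.predicted,
                "decision_value": cv.decision_values,
            }
        ).to_csv(args.out / f"predictions_{tag}.csv", index=False)
        _, curve = roc_auc(cv.decision_values, y, pos)
        pd.DataFrame(curve, columns=["fpr", "tpr"]).to_csv(
            args.out / f"roc_{tag}.csv", index=False
        )
        pd.DataFrame(
            {
                "feature": adjusted.features.columns,
                "selection_frequency": cv.selection_frequency,
            }
        ).sort_values("selection_frequency", ascending=False).head(200).to_csv(
            args.out / f"selection_frequency_{tag}.csv", index=False
        )
        summary[tag] = {
            "acc_pct": 100 * cv.acc,
            "sen_pct": 100 * cv.sen,
            "spe_pct": 100 * cv.spe,
            "auc": cv.auc,
            "k_features": cv.k_features,
            "fold_params": cv.fold_params,
        }
        print(
            f"{pos} vs {neg}: ACC {100 * cv.acc:.2f}%  SEN {100 * cv.sen:.2f}%  "
            f"SPE {100 * cv.spe:.2f}%  AUC {cv.auc:.2f}"
        )
        if (pos, neg) == ("AD", "NC"):
            mmse = adjusted.covariates["mmse"].to_numpy(dtype=float)[keep]
            r, p = hyperplane_score_correlation(cv.decision_values, mmse)
            summary[tag]["hyperplane_mmse_r"] = r
            summary[tag]["hyperplane_mmse_p"] = p
            print(f"  hyperplane distance vs MMSE (AD+NC): r = {r:.2f}, P = {p:.2g}")
            lko = repeated_leave_k_out(
                X, y, k=4, reps=200, seed=args.seed, grid=grid,
                k_features=args.k_features, positive_label=pos,
            )
            summary[tag]["leave4out"] = lko
            print(
                f"  leave-4-out x{lko['reps_used']}: ACC "
                f"{100 * lko['acc_mean']:.2f}% +/- {100 * lko['acc_sd']:.2f}%"
            )

    (args.out / "classification_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"summary written to {args.out / 'classification_summary.json'}")


if __name__ == "__main__":
    main()
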