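#!/usr/bin/env python
"""Group-difference statistics on the normalized lipidome: Kruskal-Wallis with
BH FDR across the three diagnosis groups, pairwise moderated fold-change
tables for volcano plots, class-level aggregates and lyso/diacyl ratios, and
per-species ROC AUC for SAD vs Control.
"""

import argparse
import os

import pandas as pd

from brainlipid import diff, integrate, preprocess


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/synthetic")
    args = ap.parse_args()

    log = pd.read_csv(os.path.join(args.data, "log2_normalized.csv"), index_col=0)
    cohort = pd.read_csv(os.path.join(args.data, "traits.csv"), index_col=0)
    groups = cohort.loc[log.index, "diagnosis"]

    kw = diff.kruskal_fdr(log, groups, fdr_threshold=0.7)
    kw.to_csv(os.path.join(args.data, "kruskal_fdr.csv"))
    print(f"Kruskal-Wallis: {(kw['q'] < 0.05).sum()} species at FDR<0.05; "
          f"top: {kw.index[0]} (p={kw['p'].iloc[0]:.2e})")

    for a, b in [("SAD", "Control"), ("AAD", "Control"), ("SAD", "AAD")]:
        fc = diff.fold_change_table(log, groups, a, b, moderation="empirical_bayes")
        fc.to_csv(os.path.join(args.data, f"foldchange_{a}_vs_{b}.csv"))
        n_sig = int((fc["p"] < 0.05).sum())
        print(f"{a} vs {b}: {n_sig} species at raw p<0.05")

    agg = preprocess.aggregate_classes_and_ratios(log)
    agg.class_log2.to_csv(os.path.join(args.data, "class_totals_log2.csv"))
    agg.ratios_log2.to_csv(os.path.join(args.data, "class_ratios_log2.csv"))
    for ratio in agg.ratios_log2.columns:
        by = agg.ratios_log2[ratio].groupby(groups).mean()
        print(f"ratio {ratio}: " +
              ", ".join(f"{g}={by[g]:.2f}" for g in ("Control", "AAD", "SAD")))

    keep = groups.isin(["SAD", "Control"])
    auc = integrate.per_feature_auc(
        log.loc[keep.to_numpy()], (groups[keep] == "SAD").astype(int).to_numpy()
    )
    auc.to_csv(os.path.join(args.data, "per_species_auc_SAD_vs_Control.csv"))
    extreme = auc.assign(dist=(auc["auc"] - 0.5).abs()).sort_values("dist")
    top = extreme.index[-1]
    print(f"most discriminative single species: {top} "
          f"(AUC={auc.loc[top, 'auc']:.3f}, p={auc.loc[top, 'p']:.2e})")


if __name__ == "__main__":
    main()
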