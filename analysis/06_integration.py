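#!/usr/bin/env python
"""Supervised classification and multi-omics integration: sPLS-DA with
one-vs-rest ROC/AUC, DIABLO-style multiblock fit of lipid modules + protein
modules + clinical traits, the |r| > 0.7 relevance network, and pairwise
lipid-protein association edges for the hub lipids of the strongest module.
"""

import argparse
import os

import numpy as np
import pandas as pd

from brainlipid import integrate, network


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/synthetic")
    args = ap.parse_args()

    log = pd.read_csv(os.path.join(args.data, "log2_normalized.csv"), index_col=0)
    cohort = pd.read_csv(os.path.join(args.data, "traits.csv"), index_col=0)
    me = pd.read_csv(os.path.join(args.data, "eigenlipids.csv"), index_col=0)
    proteins = pd.read_csv(os.path.join(args.data, "protein_modules.csv"), index_col=0)
    groups = cohort.loc[log.index, "diagnosis"]

    model = integrate.splsda_fit(log, list(groups), ncomp=2, seed=args.seed)
    scores, _ = integrate.splsda_predict(model, log)
    print("sPLS-DA explained variance:",
          [round(float(v), 3) for v in model.explained_variance])
    auc_rows = []
    for cls in model.classes:
        auc, p = integrate.roc_auc(
            scores[str(cls)].to_numpy(), (groups == cls).astype(int).to_numpy()
        )
        auc_rows.append({"class": cls, "auc": auc, "wilcoxon_p": p})
        print(f"  {cls} vs rest: AUC={auc:.3f} (Wilcoxon p={p:.1e})")
    pd.DataFrame(auc_rows).to_csv(os.path.join(args.data, "splsda_auc.csv"), index=False)

    common = [s for s in proteins.index if s in me.index]
    traits = cohort.loc[common, ["cognition", "gpath", "amyloid", "tangles"]].astype(float)
    blocks = {"lipid": me.loc[common], "protein": proteins.loc[common],
              "clinical": traits}
    y = list(groups.loc[common])
    diablo = integrate.diablo_fit(blocks, y, ncomp=2, seed=args.seed)
    diablo.pair_correlations.to_csv(
        os.path.join(args.data, "diablo_pair_correlations.csv"), index=False
    )
    c1 = diablo.pair_correlations.query("component == 1")
    best = c1.loc[c1["r"].abs().idxmax()]
    print(f"DIABLO component-1 block correlations: best pair "
          f"{best['block_a']}-{best['block_b']} (r={best['r']:.2f})")

    net = integrate.relevance_network(blocks, cutoff=0.7)
    net.edges.to_csv(os.path.join(args.data, "relevance_edges.tsv"),
                     sep="\t", index=False)
    print(f"relevance network at |r|>0.7: {len(net.edges)} edges")
    for _, e in net.edges.iterrows():
        print(f"  {e['source']} ({e['source_type']}) -- {e['target']} "
              f"({e['target_type']}): r={e['r']:.2f}")
    # the strongest lipid-protein couplings, whether or not they cross the cutoff
    strongest = []
    for mcol in me.columns:
        for pcol in proteins.columns:
            r = np.corrcoef(me.loc[common, mcol], proteins.loc[common, pcol])[0, 1]
            strongest.append((abs(r), mcol, pcol, r))
    for _, mcol, pcol, r in sorted(strongest, reverse=True)[:3]:
        print(f"  top lipid-protein coupling: {mcol} -- {pcol} (r={r:.2f})")

    # pairwise association of the most diagnosis-linked module's members vs proteins
    assoc = pd.read_csv(os.path.join(args.data, "module_trait.csv"))
    diag = assoc[assoc["trait"] == "diagnosis_code"].set_index("module")
    labels = pd.read_csv(os.path.join(args.data, "module_labels.csv"), index_col=0)["module"]
    if labels.max() >= 1 and len(diag):
        target = diag["r"].abs().idxmax()
        members = labels.index[labels == int(target[1:])]
        edges = integrate.pairwise_assoc(
            log.loc[common, members], proteins.loc[common],
            cor_cutoff=0.5, p_cutoff=0.05,
        )
        edges.to_csv(os.path.join(args.data, "lipid_protein_edges.tsv"),
                     sep="\t", index=False)
        print(f"pairwise lipid-protein edges (|r|>0.5, p<0.05) for {target} "
              f"(most diagnosis-linked module): {len(edges)}")
        if len(edges):
            top = edges.loc[edges["r"].abs().idxmax()]
            print(f"  strongest: {top['lipid']} -- {top['protein']} (r={top['r']:.2f})")


if __name__ == "__main__":
    main()
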