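"""Cohort-level analyses of the detected editing matrix: age correlation in
controls and cases, case-vs-control differential editing, Kullback-Leibler
divergence between the editing-type compositions of the two comparisons,
Ward-D2 clustering and PCA on the transformed levels, and detection of
control samples whose profiles cluster with the cases.

Reads results/detection/, writes tables under results/stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

import mirnaeditome as me
from mirnaeditome.core import EditingMatrix
from mirnaeditome.io import read_matrix, read_site_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--detection", type=Path, default=RESULTS / "detection")
    ap.add_argument("--out", type=Path, default=RESULTS / "stats")
    ap.add_argument("--case", default="PD")
    ap.add_argument("--control", default="ctl")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    levels = read_matrix(args.detection / "matrix.tsv")
    meta = pd.read_csv(args.detection / "matrix_metadata.tsv", sep="\t", index_col="sample_id")
    matrix = EditingMatrix(levels, meta)
    sites = read_site_table(args.detection / "sites.tsv")

    for group in (args.control, args.case):
        age = me.age_correlation(matrix, group, method="spearman")
        age.to_csv(args.out / f"age_correlation_{group}.tsv", sep="\t", index=False)
        print(f"age-related sites in {group}: {int(age.significant.sum())}/{len(age)}")

    diff = me.differential_editing(matrix, args.case, args.control)
    diff.to_csv(args.out / "differential_editing.tsv", sep="\t", index=False)
    n_up = int(((diff.direction == "increased") & diff.significant).sum())
    n_dn = int(((diff.direction == "decreased") & diff.significant).sum())
    print(f"differential sites ({args.case} vs {args.control}): "
          f"{int(diff.significant.sum())} ({n_up} increased, {n_dn} decreased)")

    # type compositions: differential sites vs the full retained set
    types = sites.set_index("name")["type"]
    all_counts = {t: 0 for t in me.TYPE_LABELS}
    diff_counts = {t: 0 for t in me.TYPE_LABELS}
    for name, t in types.items():
        all_counts[t] += 1
        if name in set(diff[diff.significant].site):
            diff_counts[t] += 1
    kl = me.kl_type_divergence(diff_counts, all_counts)
    print(f"KL(differential-site types || all-site types) = {kl:.3f} bits")

    # clustering/PCA use the differential sites' levels (the full retained
    # set is dominated by tailing sites that do not separate the groups)
    diff_sites = list(diff[diff.significant].site)
    if len(diff_sites) >= 2:
        matrix_for_clustering = EditingMatrix(
            matrix.levels.loc[diff_sites], matrix.metadata.copy()
        )
        print(f"clustering on {len(diff_sites)} differential sites")
    else:
        matrix_for_clustering = matrix
        print("fewer than 2 differential sites; clustering on all retained sites")
    transformed = me.transform_levels(matrix_for_clustering)
    clus = me.cluster_samples(transformed, k=2)
    clus.labels.rename("cluster").rename_axis("sample_id").to_csv(
        args.out / "clusters.tsv", sep="\t"
    )
    (args.out / "dendrogram.nwk").write_text(clus.to_newick() + "\n")
    pca = me.pca_samples(transformed)
    pca.scores.rename_axis("sample_id").to_csv(args.out / "pca_scores.tsv", sep="\t")
    print("PC1/PC2 explained variance: "
          f"{pca.explained_variance_ratio[0]:.2f}/{pca.explained_variance_ratio[1]:.2f}")

    pd_like = me.find_pd_like(
        clus.labels, matrix.metadata["group"].to_dict(), args.case, args.control
    )
    (args.out / "case_like_controls.txt").write_text(
        "\n".join(pd_like) + ("\n" if pd_like else "")
    )
    print(f"case-like control samples: {pd_like if pd_like else 'none'}")


if __name__ == "__main__":
    main()
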