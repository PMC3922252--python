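#!/usr/bin/env python
"""Ward-cluster the regions' predicted genetic-value vectors.

Per trait: fit the kernel Bayesian ridge regression on the full data for
each region kernel (four genic classes, IGR, all SNPs), form the matrix of
pairwise Euclidean norms between the predicted genetic-value vectors
g_hat = K alpha_hat, agglomerate under Ward's minimum-variance criterion,
and write the merge table, a Newick tree and a dendrogram figure.
"""

import os

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from regionpred import annotate, cluster, kernel, krr
from regionpred.genotypes import read_dosage_tsv

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data")
OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 5051
REGIONS = ("CDS", "Exons", "Genes", "Genes1kb", "IGR", "ALL")


def _plot(dendro, path, title):
    # draw from the merge list: x positions by leaf order, y by height
    import numpy as np
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    index = {leaf: i for i, leaf in enumerate(dendro.leaves)}
    Z = []
    sizes = {leaf: 1 for leaf in dendro.leaves}
    for k, (a, b, h) in enumerate(dendro.merges):
        ia, ib = index.pop(a), index.pop(b)
        size = sizes.pop(a) + sizes.pop(b)
        lab = f"({a}+{b})"
        index[lab] = len(dendro.leaves) + k
        sizes[lab] = size
        Z.append([ia, ib, np.sqrt(2 * h), size])
    fig, ax = plt.subplots(figsize=(6, 4))
    scipy_dendrogram(np.array(Z), labels=dendro.leaves, ax=ax)
    ax.set_title(title)
    ax.set_ylabel("merge height (sqrt scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main():
    geno = read_dosage_tsv(os.path.join(DATA, "dosages_clean.tsv"))
    snp_map = list(zip(geno.snp_ids, geno.chrom, geno.pos))
    part = annotate.build_partition(snp_map, os.path.join(DATA, "genome.gff3"))
    kernels = {n: (kernel.vanraden_g(geno) if n == "ALL"
                   else kernel.vanraden_g(geno, part[n])) for n in REGIONS}

    for trait in ("bw", "bm", "hhp"):
        adj = pd.read_csv(os.path.join(DATA, f"pheno_{trait}_adj.tsv"), sep="\t")
        y = adj.set_index("animal_id")["y_R"].reindex(geno.animal_ids).to_numpy()
        ghat = {}
        for i, (name, km) in enumerate(kernels.items()):
            chain = krr.gibbs_krr(y, km, config=krr.MCMCConfig.reduced(seed=SEED + i))
            ghat[name] = chain.ghat
        names, D = cluster.gvalue_distance_matrix(ghat)
        dendro = cluster.ward_cluster(D, labels=names)
        nwk = cluster.write_newick(dendro)
        with open(os.path.join(OUT, f"dendrogram_{trait}.nwk"), "w") as fh:
            fh.write(nwk + "\n")
        dendro.merge_table().to_csv(os.path.join(OUT, f"merges_{trait}.tsv"),
                                    sep="\t", index=False)
        _plot(dendro, os.path.join(OUT, f"dendrogram_{trait}.png"),
              f"Ward clustering of predicted genetic values ({trait})")
        a, b = dendro.root_split()
        print(f"{trait}: top split {sorted(a)} | {sorted(b)}")
        print(f"  newick: {nwk}")


if __name__ == "__main__":
    main()
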