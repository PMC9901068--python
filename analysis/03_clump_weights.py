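#!/usr/bin/env python
"""Build PTS weights: predicted-expression correlation, clumping,
duplicate-gene averaging.

Predicts expression into the reference genotype panel with each
panel's SNP weights, correlates units within 500 kb, greedily clumps
associations at r > 0.95, and averages Z for genes retained in
several panels.
"""

from pathlib import Path

from twaskit import clump as cl
from twaskit import genes as gn
from twaskit.io import read_study, write_table

IN = "results/analysis/inputs"
OUT = Path("results/analysis")


def main() -> None:
    study = read_study(IN)
    predicted = cl.predict_expression(study.weights, study.genotypes,
                                      study.variants)
    corr = cl.pairwise_predicted_correlation(predicted, study.gene_map)
    assoc = gn.fdr_correct(study.associations)
    result = cl.clump(assoc, corr, r_thresh=0.95)
    weights = cl.average_duplicate_genes(result)
    write_table(corr, OUT / "predicted_correlations.tsv")
    write_table(result.removed, OUT / "clump_removed.tsv")
    write_table(weights, OUT / "pts_weights.tsv")
    dup = weights[weights["n_panels"] > 1]
    print(f"{len(predicted.columns)} predicted units; "
          f"{len(corr)} windowed correlation pairs "
          f"({(corr['r'] > 0.95).sum()} above r=0.95)")
    print(f"clump: retained {len(result.retained)}, "
          f"removed {len(result.removed)}; "
          f"{len(weights)} gene weights ({len(dup)} averaged across panels)")


if __name__ == "__main__":
    main()
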