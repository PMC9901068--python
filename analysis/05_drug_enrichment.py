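#!/usr/bin/env python
"""Directional drug enrichment and ATC-class testing.

Codes drug-gene actions as -1/0/+1, tests each drug with the
co-regulation-aware GLS (at least 2 genes with TWAS statistics),
BH-corrects across drugs, and runs the two-sided ATC level-3 Wilcoxon
layer (groups of at least 5 drugs). Checks planted protective drugs
rise to the top.
"""

from pathlib import Path

import pandas as pd

from twaskit.config import PipelineConfig
from twaskit.io import read_study, write_table
from twaskit.pipeline import clump_stage, drug_stage
from twaskit import clump as cl
from twaskit import genes as gn

IN = "results/analysis/inputs"
OUT = Path("results/analysis")


def main() -> None:
    study = read_study(IN)
    cfg = PipelineConfig()
    _, correlations, gene_corr = clump_stage(study, cfg)
    assoc = gn.fdr_correct(study.associations)
    result = cl.clump(assoc, correlations, r_thresh=cfg.r_thresh)
    weights = cl.average_duplicate_genes(result)
    enr, atc = drug_stage(study, weights, gene_corr, cfg)
    write_table(enr, OUT / "drug_enrichment.tsv")
    write_table(atc, OUT / "atc_enrichment.tsv")

    merged = enr.merge(study.truth.drugs[["drug_id", "drug_class"]],
                       on="drug_id")
    by = merged.groupby("drug_class")["Z"].mean()
    print(f"{len(enr)} drugs tested; mean enrichment Z: "
          + ", ".join(f"{k} = {v:.2f}" for k, v in by.items()))
    sig = enr[enr["q"] < 0.05].merge(
        study.truth.drugs[["drug_id", "drug_class"]], on="drug_id")
    print(f"  {len(sig)} FDR-significant drugs, of which "
          f"{(sig['drug_class'] == 'protective').sum()} planted protective")
    truth_atc = study.truth.atc.set_index("atc_code")["enriched"]
    atc_sig = atc[atc["q"] < 0.05]
    hits = [c for c in atc_sig["atc_code"] if truth_atc.get(c, False)]
    print(f"  {len(atc)} ATC groups tested, {len(atc_sig)} FDR-significant "
          f"({len(hits)} of the planted enriched groups)")
    _ = pd


if __name__ == "__main__":
    main()
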