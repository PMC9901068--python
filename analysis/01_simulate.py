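#!/usr/bin/env python
"""Generate the synthetic study all later steps analyse.

Emulates the shape of a post-GWAS ALS integration study: TWAS/PWAS
tables over blood and brain panels, a reference genotype panel with
per-gene SNP weights, fine-mapping credible sets, two case-control
blood expression cohorts on different array platforms, and a
directional drug-gene database with ATC classes. Ground truth (signal
genes, directions, concordance, protective drugs) is written alongside.
"""

import sys

from twaskit.config import SyntheticConfig
from twaskit.io import write_study
from twaskit.synthetic import generate_study

OUT = "results/analysis/inputs"


def main(seed: int = 1) -> None:
    cfg = SyntheticConfig(seed=seed)
    study = generate_study(cfg)
    files = write_study(study, OUT)
    truth = study.truth
    n_signal = int(truth.genes["is_signal"].sum())
    print(f"wrote {len(files)} input files to {OUT}")
    print(f"  {cfg.n_genes} genes ({n_signal} signal), "
          f"{len(study.associations)} TWAS rows over {cfg.n_panels} panels")
    print(f"  cohorts: " + ", ".join(
        f"{c} ({e.shape[1]} samples)" for c, e in study.expression.items()))
    print(f"  {cfg.n_drugs} drugs "
          f"({(truth.drugs['drug_class'] == 'protective').sum()} protective), "
          f"{cfg.n_atc_groups} ATC groups")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
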