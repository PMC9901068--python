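#!/usr/bin/env python
"""Score PTS and test associations across outcomes, strata, thresholds.

Computes polytranscriptomic scores per cohort across p-value
thresholds for every stratum (all/blood/brain x any/colocalised),
regresses each outcome on the score with sex as covariate, converts
binary-outcome R2 to the liability scale (K = 1/300 for case-control,
0.5 for spinal-vs-bulbar onset), and pools cohorts by IVW.
"""

from pathlib import Path

from twaskit.config import PipelineConfig
from twaskit.io import read_study, write_table
from twaskit.pipeline import clump_stage, pts_stage

IN = "results/analysis/inputs"
OUT = Path("results/analysis")


def main() -> None:
    study = read_study(IN)
    cfg = PipelineConfig()
    _, correlations, _ = clump_stage(study, cfg)
    per_cohort, meta = pts_stage(study, correlations, cfg)
    write_table(per_cohort, OUT / "pts_associations.tsv")
    write_table(meta, OUT / "pts_meta.tsv")

    cc = meta[(meta["outcome"] == "case_control")
              & (meta["stratum"] == "all_any")]
    best = cc.loc[cc["r2_liability"].idxmax()]
    print(f"case-control PTS (all panels): best liability R2 = "
          f"{100 * best['r2_liability']:.2f}% at threshold "
          f"{best['threshold']:g} (p = {best['p']:.2e}, "
          f"{int(best['n_genes_used'])} genes, n = {int(best['n'])})")
    for outcome in ("site_of_onset", "age_at_onset", "survival"):
        sub = meta[(meta["outcome"] == outcome)
                   & (meta["stratum"] == "all_any")]
        if sub.empty:
            continue
        top = sub.loc[sub["p"].idxmin()]
        print(f"  {outcome}: min p = {top['p']:.3g} "
              f"(beta = {top['beta']:.3g}) across thresholds")


if __name__ == "__main__":
    main()
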