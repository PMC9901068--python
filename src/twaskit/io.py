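"""Readers and writers for the pipeline's plain-text interchange files.

All tables are TSV with header rows (the drug-gene interaction table
is CSV, mirroring its source database's column roles). Coordinates are
1-based inclusive; every genomic file carries a comment header saying
so. Floats are written with a fixed repr so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SyntheticStudy, GroundTruth

__all__ = ["write_study", "read_study", "write_table", "read_table"]

_FLOAT_FMT = "%.10g"
_COORD_HEADER = "# coordinates: 1-based inclusive\n"


def write_table(df: pd.DataFrame, path: Path, sep: str = "\t",
                header_comment: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment)
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")


def read_table(path: Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, str]:
    """Persist every generated input; returns {name: relative path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _w(name: str, df: pd.DataFrame, fname: str, sep: str = "\t",
           comment: str | None = None) -> None:
        write_table(df, out / fname, sep=sep, header_comment=comment)
        files[name] = fname

    _w("gene_map", study.gene_map, "gene_map.tsv", comment=_COORD_HEADER)
    _w("variants", study.variants, "variants.tsv", comment=_COORD_HEADER)
    geno = pd.DataFrame(study.genotypes,
                        columns=study.variants["variant_id"])
    geno.insert(0, "sample_id",
                [f"REF{i:04d}" for i in range(len(geno))])
    _w("genotypes", geno, "reference_genotypes.tsv")
    _w("weights", study.weights, "snp_weights.tsv")
    _w("twas", study.associations, "twas_associations.tsv")
    for cohort, expr in study.expression.items():
        _w(f"expression_{cohort}", expr.reset_index(names="gene_id"),
           f"expression_{cohort}.tsv")
        _w(f"phenotypes_{cohort}", study.phenotypes[cohort],
           f"phenotypes_{cohort}.tsv")
    _w("drug_gene", study.drug_gene, "drug_gene_interactions.csv", sep=",")
    _w("credible_sets", study.credible_sets, "credible_sets.tsv",
       comment=_COORD_HEADER)
    _w("truth_genes", study.truth.genes, "truth_genes.tsv")
    _w("truth_drugs", study.truth.drugs, "truth_drugs.tsv")
    _w("truth_atc", study.truth.atc, "truth_atc.tsv")
    with open(out / "config.json", "w") as fh:
        json.dump(study.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["config"] = "config.json"
    return files


def read_study(out_dir: str | Path) -> SyntheticStudy:
    """Read a persisted study back; truths round-trip exactly."""
    from .config import SyntheticConfig

    out = Path(out_dir)
    with open(out / "config.json") as fh:
        cfg = SyntheticConfig(**json.load(fh))
    gene_map = read_table(out / "gene_map.tsv")
    variants = read_table(out / "variants.tsv")
    geno = read_table(out / "reference_genotypes.tsv")
    genotypes = geno.drop(columns=["sample_id"]).to_numpy(dtype=np.int64)
    weights = read_table(out / "snp_weights.tsv")
    twas = read_table(out / "twas_associations.tsv")
    expression = {}
    phenotypes = {}
    for path in sorted(out.glob("expression_*.tsv")):
        cohort = path.stem.removeprefix("expression_")
        expression[cohort] = read_table(path).set_index("gene_id")
        phen = read_table(out / f"phenotypes_{cohort}.tsv")
        phen["site_of_onset"] = phen["site_of_onset"].fillna("")
        phenotypes[cohort] = phen
    drug_gene = read_table(out / "drug_gene_interactions.csv", sep=",")
    credible_sets = read_table(out / "credible_sets.tsv")
    truth = GroundTruth(
        genes=read_table(out / "truth_genes.tsv"),
        drugs=read_table(out / "truth_drugs.tsv"),
        atc=read_table(out / "truth_atc.tsv"),
    )
    return SyntheticStudy(
        config=cfg, gene_map=gene_map, genotypes=genotypes,
        variants=variants, associations=twas, weights=weights,
        expression=expression, phenotypes=phenotypes,
        drug_gene=drug_gene, credible_sets=credible_sets, truth=truth,
    )
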