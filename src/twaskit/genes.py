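"""High-confidence gene calling from fine-mapping, TWAS and PWAS evidence.

A gene is called high-confidence if it meets any of three criteria:
(1) the gene body contains every variant of a 95% fine-mapping credible
set; (2) an FDR-significant FUSION association that colocalises,
PP4/(PP3+PP4) > 0.8; (3) an FDR-significant SMR association passing the
HEIDI heterogeneity filter, p > 0.05. FDR correction pools all panels
within method (FUSION vs SMR), separately per molecular type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust

__all__ = [
    "fdr_correct",
    "coloc_pass",
    "heidi_pass",
    "credible_set_contained",
    "call_high_confidence",
]


def fdr_correct(associations: pd.DataFrame) -> pd.DataFrame:
    """Attach BH q-values within each (method, molecular_type) stratum.

    All panels of a method are pooled into one correction, FUSION and
    SMR corrected separately; protein panels form their own strata.
    """
    df = associations.copy()
    p = df["p"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    df["q"] = np.nan
    for _, idx in df.groupby(["method", "molecular_type"]).groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"])
    return df


def coloc_pass(pp3: float, pp4: float, ratio: float = 0.8) -> bool:
    """Colocalisation filter: PP4 / (PP3 + PP4) strictly above ``ratio``."""
    if pp3 < 0 or pp4 < 0:
        raise ValueError("posterior probabilities must be non-negative")
    total = pp3 + pp4
    if total == 0:
        raise ValueError("PP3 + PP4 = 0: colocalisation ratio undefined")
    return pp4 / total > ratio


def heidi_pass(heidi_p: float, alpha: float = 0.05) -> bool:
    """HEIDI filter: heterogeneity p strictly above ``alpha`` is
    consistent with a single shared causal variant."""
    if heidi_p is None or (isinstance(heidi_p, float) and np.isnan(heidi_p)):
        raise ValueError("SMR row lacks a HEIDI p-value")
    return heidi_p > alpha


def credible_set_contained(
    variant_chrom: str,
    variant_positions,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    window_bp: int = 0,
) -> bool:
    """True iff every credible-set variant lies within the gene interval
    (optionally padded by ``window_bp`` on each side)."""
    positions = np.asarray(list(variant_positions), dtype=int)
    if positions.size == 0:
        raise ValueError("credible set is empty")
    if variant_chrom != gene_chrom:
        return False
    lo, hi = gene_start - window_bp, gene_end + window_bp
    return bool(np.all((positions >= lo) & (positions <= hi)))


def call_high_confidence(
    associations: pd.DataFrame,
    credible_sets: pd.DataFrame,
    gene_map: pd.DataFrame,
    fdr_threshold: float = 0.05,
    coloc_ratio: float = 0.8,
    heidi_alpha: float = 0.05,
    window_bp: int = 0,
) -> pd.DataFrame:
    """Aggregate the three evidence routes into per-gene calls.

    Parameters
    ----------
    associations:
        FDR-annotated table (``fdr_correct`` output) with columns
        gene_id, method, Z, q, PP3/PP4 (FUSION) and heidi_p (SMR).
    credible_sets:
        Long table with columns locus_id, variant_id, chrom, pos; one
        row per credible-set variant.
    gene_map:
        gene_id, chrom, start, end.

    Returns one row per called gene with boolean evidence flags
    ``credible_set``, ``fusion_coloc``, ``smr_heidi`` and the count of
    supporting association rows.
    """
    if "q" not in associations.columns:
        raise ValueError("run fdr_correct before calling high-confidence genes")

    flags: dict[str, dict] = {}

    def _flag(gid: str, key: str) -> None:
        rec = flags.setdefault(
            gid, {"gene_id": gid, "credible_set": False,
                  "fusion_coloc": False, "smr_heidi": False, "n_support": 0})
        rec[key] = True
        rec["n_support"] += 1

    fus = associations[associations["method"] == "FUSION"]
    for _, row in fus.iterrows():
        if row["q"] < fdr_threshold and (row["PP3"] + row["PP4"]) > 0 and \
                coloc_pass(row["PP3"], row["PP4"], coloc_ratio):
            _flag(row["gene_id"], "fusion_coloc")

    smr = associations[associations["method"] == "SMR"]
    for _, row in smr.iterrows():
        if row["q"] < fdr_threshold and heidi_pass(row["heidi_p"], heidi_alpha):
            _flag(row["gene_id"], "smr_heidi")

    if len(credible_sets):
        gmap = gene_map.set_index("gene_id")
        for _, cs in credible_sets.groupby("locus_id"):
            chrom = cs["chrom"].iloc[0]
            if cs["chrom"].nunique() != 1:
                raise ValueError("credible set spans multiple chromosomes")
            positions = cs["pos"].to_numpy()
            for gid, g in gmap.iterrows():
                if credible_set_contained(chrom, positions, g["chrom"],
                                          g["start"], g["end"], window_bp):
                    _flag(str(gid), "credible_set")

    out = pd.DataFrame(
        list(flags.values()),
        columns=["gene_id", "credible_set", "fusion_coloc", "smr_heidi",
                 "n_support"],
    )
    return out.sort_values("gene_id").reset_index(drop=True)
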