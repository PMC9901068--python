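"""Predicted-expression correlation, clumping, and duplicate-gene averaging.

TWAS associations at nearby genes are not independent: their SNP-weight
models overlap, so their genetically predicted expression correlates.
Analogous to LD clumping of polygenic scores, associations are pruned
greedily on the Pearson correlation of expression predicted into a
reference genotype panel, computed for gene pairs within a proximity
window (default 500 kb), removing any unit correlated above r = 0.95
with a more significant lead. A gene retained in several panels after
clumping contributes the arithmetic mean of its retained Z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "predict_expression",
    "pairwise_predicted_correlation",
    "clump",
    "average_duplicate_genes",
    "ClumpResult",
]

Unit = tuple[str, str]  # (gene_id, panel_id)


def predict_expression(
    weights: pd.DataFrame,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Predict standardized expression per (gene, panel) unit.

    Per reference individual the raw score is the weight-genotype dot
    product; each unit's vector is then standardized to mean 0, sd 1
    (n-1 denominator). Units with zero predicted variance are excluded
    with a warning.

    Parameters
    ----------
    weights:
        Long table gene_id, panel_id, variant_id, weight.
    genotypes:
        n_samples x n_variants allele-count matrix.
    variants:
        Variant table whose row order matches the genotype columns;
        must contain variant_id.

    Returns a frame indexed by sample with one column per unit, column
    labels ``gene_id::panel_id``.
    """
    col_of = {v: i for i, v in enumerate(variants["variant_id"])}
    missing = set(weights["variant_id"]) - set(col_of)
    if missing:
        raise ValueError(f"weights reference unknown variants: {sorted(missing)[:5]}")
    out = {}
    for (gid, pid), grp in weights.groupby(["gene_id", "panel_id"], sort=True):
        idx = [col_of[v] for v in grp["variant_id"]]
        raw = genotypes[:, idx] @ grp["weight"].to_numpy(dtype=float)
        sd = raw.std(ddof=1)
        if sd == 0:
            logger.warning("unit %s::%s has zero predicted variance; excluded",
                           gid, pid)
            continue
        out[f"{gid}::{pid}"] = (raw - raw.mean()) / sd
    return pd.DataFrame(out)


def _gene_anchor(gene_map: pd.DataFrame, anchor: str) -> pd.DataFrame:
    g = gene_map.set_index("gene_id")
    if anchor == "start":
        pos = g["start"]
    elif anchor == "midpoint":
        pos = (g["start"] + g["end"]) // 2
    else:
        raise ValueError("anchor must be 'start' or 'midpoint'")
    return pd.DataFrame({"chrom": g["chrom"], "pos": pos})


def pairwise_predicted_correlation(
    predicted: pd.DataFrame,
    gene_map: pd.DataFrame,
    window_bp: int = 500_000,
    anchor: str = "start",
) -> pd.DataFrame:
    """Pearson r between predicted-expression units in proximity.

    Pairs are emitted only for units whose genes share a chromosome and
    whose anchor coordinates lie within ``window_bp``; absent pairs are
    treated as r = 0 downstream (never clumped together). Same-gene
    cross-panel pairs are always within the window.

    Returns a long frame unit_a, unit_b, r with unit_a < unit_b.
    """
    units = np.asarray(predicted.columns)
    pos = _gene_anchor(gene_map, anchor)
    X = predicted.to_numpy()
    if np.isnan(X).any():
        raise ValueError("predicted expression contains missing values")
    unit_genes = [u.split("::")[0] for u in units]
    chrom = pos.loc[unit_genes, "chrom"].to_numpy()
    coord = pos.loc[unit_genes, "pos"].to_numpy(dtype=np.int64)
    # standardized columns: r is the scaled dot product
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    frames = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        a, b = idx[ii], idx[jj]
        near = np.abs(coord[a] - coord[b]) <= window_bp
        a, b = a[near], b[near]
        if len(a) == 0:
            continue
        r = (Xc[:, a] * Xc[:, b]).sum(axis=0) / (norms[a] * norms[b])
        frames.append(pd.DataFrame(
            {"unit_a": units[a], "unit_b": units[b], "r": r}))
    if not frames:
        return pd.DataFrame(columns=["unit_a", "unit_b", "r"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class ClumpResult:
    """Outcome of greedy correlation clumping."""

    retained: pd.DataFrame  # association rows kept
    removed: pd.DataFrame   # removed rows with their lead unit

    @property
    def retained_units(self) -> set[Unit]:
        return set(zip(self.retained["gene_id"], self.retained["panel_id"]))


def _order_key(row) -> tuple:
    # ascending p; ties: larger |Z| first, then lexicographic unit id
    return (row["p"], -abs(row["Z"]), row["gene_id"], row["panel_id"])


def clump(
    associations: pd.DataFrame,
    correlations: pd.DataFrame,
    r_thresh: float = 0.95,
) -> ClumpResult:
    """Greedy clumping of (gene, panel) association units.

    Repeatedly takes the most significant remaining unit as lead and
    removes every unit correlated with it above ``r_thresh``. Pairs
    absent from ``correlations`` count as r = 0. Units without any
    predicted-expression entry cannot be clumped and are retained with
    a warning. Ties in p break on larger |Z|, then lexicographic
    (gene, panel).
    """
    df = associations.copy()
    units = list(zip(df["gene_id"], df["panel_id"]))
    if len(set(units)) != len(units):
        raise ValueError("duplicate (gene, panel) association units")

    rmap: dict[Unit, dict[Unit, float]] = {u: {} for u in units}
    known_units = set()
    for _, row in correlations.iterrows():
        ga, pa = row["unit_a"].split("::")
        gb, pb = row["unit_b"].split("::")
        a, b = (ga, pa), (gb, pb)
        known_units.update((a, b))
        if a in rmap and b in rmap:
            rmap[a][b] = row["r"]
            rmap[b][a] = row["r"]

    orphan = [u for u in units if u not in known_units]
    if orphan:
        logger.warning("%d association units lack correlation entries; "
                       "retained unclumped", len(orphan))

    df = df.sort_values(
        by=["p", "Z", "gene_id", "panel_id"],
        key=lambda s: -s.abs() if s.name == "Z" else s,
        kind="mergesort",
    ).reset_index(drop=True)

    alive = {u: True for u in zip(df["gene_id"], df["panel_id"])}
    lead_of: dict[Unit, Unit] = {}
    retained: list[Unit] = []
    for _, row in df.iterrows():
        u = (row["gene_id"], row["panel_id"])
        if not alive[u]:
            continue
        retained.append(u)
        alive[u] = False
        for v, r in rmap[u].items():
            if alive.get(v) and r > r_thresh:
                alive[v] = False
                lead_of[v] = u

    key = df.set_index(["gene_id", "panel_id"])
    ret = key.loc[retained].reset_index()
    rem_units = list(lead_of)
    rem = key.loc[rem_units].reset_index() if rem_units else \
        key.iloc[0:0].reset_index()
    rem["lead_gene_id"] = [lead_of[u][0] for u in rem_units]
    rem["lead_panel_id"] = [lead_of[u][1] for u in rem_units]
    return ClumpResult(retained=ret, removed=rem)


def average_duplicate_genes(result: ClumpResult) -> pd.DataFrame:
    """Per-gene PTS weights: mean retained Z across panels.

    Returns gene_id, Z (arithmetic mean), min_p (most significant
    retained p, used for thresholding), n_panels.
    """
    grp = result.retained.groupby("gene_id")
    out = grp.agg(Z=("Z", "mean"), min_p=("p", "min"), n_panels=("Z", "size"))
    return out.reset_index()
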