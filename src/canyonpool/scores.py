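"""Per-gene differential sweep scores across slopes.

For each gene, N is the number of NFS lines whose sweep regions contain
the gene, S the analogous SFS count; the differential sweep score is
N - S.  With 9 lines per slope the attainable range is exactly [-9, 9];
positive scores are NFS-prevalent, negative SFS-prevalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import spearmanr

from .config import NFS, SFS
from .hmm import SweepRegion
from .io import GeneModel


@dataclass
class GeneScore:
    gene_id: str
    N: int
    S: int
    score: int
    delta_tajima_d: float = float("nan")
    mean_het: float = float("nan")


def gene_in_region(
    gene: GeneModel, regions: list[SweepRegion], mode: str = "overlap"
) -> bool:
    """Whether the gene's span falls within any of one line's sweep regions.

    ``mode="overlap"`` (default) requires >= 1 bp overlap;
    ``mode="contain"`` requires the full gene span inside a region.
    """
    for r in regions:
        if r.chrom != gene.chrom:
            continue
        if mode == "overlap":
            if r.start <= gene.end and gene.start <= r.end:
                return True
        elif mode == "contain":
            if r.start <= gene.start and gene.end <= r.end:
                return True
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return False


def differential_score(
    gene: GeneModel,
    regions_by_line: dict[str, list[SweepRegion]],
    slopes: dict[str, str],
    mode: str = "overlap",
) -> GeneScore:
    unlabeled = [lid for lid in regions_by_line if lid not in slopes]
    if unlabeled:
        raise ValueError(f"lines without slope label: {unlabeled}")
    n = sum(
        gene_in_region(gene, regs, mode)
        for lid, regs in regions_by_line.items()
        if slopes[lid] == NFS
    )
    s = sum(
        gene_in_region(gene, regs, mode)
        for lid, regs in regions_by_line.items()
        if slopes[lid] == SFS
    )
    return GeneScore(gene_id=gene.gene_id, N=int(n), S=int(s), score=int(n - s))


def score_table(
    genes: list[GeneModel],
    regions_by_line: dict[str, list[SweepRegion]],
    slopes: dict[str, str],
    gene_stats_df: pd.DataFrame | None = None,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Differential sweep scores for all genes, joined (when available) to
    per-gene interslope Tajima's D difference and mean heterozygosity."""
    rows = []
    for gene in genes:
        gs = differential_score(gene, regions_by_line, slopes, mode)
        rows.append({"gene_id": gs.gene_id, "N": gs.N, "S": gs.S, "score": gs.score})
    df = pd.DataFrame(rows)
    if gene_stats_df is not None:
        df = df.merge(
            gene_stats_df[["gene_id", "delta_tajima_d", "delta_het", "mean_het"]],
            on="gene_id",
            how="left",
        )
    return df


def prevalent_genes(
    scores: pd.DataFrame, threshold: int = 6
) -> tuple[list[str], list[str]]:
    """(NFS-prevalent, SFS-prevalent) gene lists at a symmetric score
    threshold: score >= +threshold and score <= -threshold."""
    nfs = scores.loc[scores["score"] >= threshold, "gene_id"].tolist()
    sfs = scores.loc[scores["score"] <= -threshold, "gene_id"].tolist()
    return nfs, sfs


def score_correlations(scores: pd.DataFrame, min_genes: int = 10) -> dict:
    """Spearman rank correlations of the differential sweep score against
    per-gene statistics: the interslope differences in Tajima's D and in
    heterozygosity (both NFS minus SFS, the same orientation as the score)
    and the mean heterozygosity.  Constant inputs yield NaN with a flag
    rather than a coefficient."""
    out = {}
    for key, col in (
        ("delta_tajima_d", "delta_tajima_d"),
        ("delta_het", "delta_het"),
        ("mean_het", "mean_het"),
    ):
        if col not in scores.columns:
            continue
        sub = scores[["score", col]].dropna()
        if len(sub) < min_genes:
            out[key] = {"r": float("nan"), "p": float("nan"), "n": len(sub),
                        "flag": "too_few_genes"}
            continue
        if sub["score"].nunique() < 2 or sub[col].nunique() < 2:
            out[key] = {"r": float("nan"), "p": float("nan"), "n": len(sub),
                        "flag": "constant_input"}
            continue
        r, p = spearmanr(sub["score"], sub[col])
        out[key] = {"r": float(r), "p": float(p), "n": len(sub), "flag": None}
    return out
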