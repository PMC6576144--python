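"""Pooled-sequencing diversity and differentiation statistics.

Classical estimators evaluated on pooled allele-frequency estimates
(alternate reads / depth), with the small-sample factor n/(n-1) for the
pool's n haplotypes.  Statistics are reported per site, per window
(default 5 kb) and per gene; missing values propagate as NaN, never as
zeros.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import NFS, SFS, SLOPES
from .io import GeneModel


# ---------------------------------------------------------------------------
# constants of the classical Tajima's D derivation


def harmonic(n: int, power: int = 1) -> float:
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** power))


def tajima_constants(n_haploids: int) -> dict[str, float]:
    n = n_haploids
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


# ---------------------------------------------------------------------------
# per-site quantities


def site_frequency(ref_count, alt_count):
    """Pooled alternate-allele frequency estimate, alt / (ref + alt)."""
    ref_count = np.asarray(ref_count, dtype=float)
    alt_count = np.asarray(alt_count, dtype=float)
    depth = ref_count + alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(depth > 0, alt_count / depth, np.nan)
    return out if out.ndim else float(out)

def slope_frequency(ref_counts, alt_counts, weighted: bool = True):
    """Slope-level frequency across lines (rows): depth-weighted by default,
    optionally the unweighted mean of per-line frequencies."""
    R = np.asarray(ref_counts, dtype=float)
    A = np.asarray(alt_counts, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if weighted:
            depth = (R + A).sum(axis=0)
            out = np.where(depth > 0, A.sum(axis=0) / depth, np.nan)
        else:
            per_line = np.where(R + A > 0, A / (R + A), np.nan)
            out = np.nanmean(per_line, axis=0)
    return out


def fst_per_snp(p1, p2):
    """Per-SNP interslope F_ST = (H_T - mean H_S) / H_T from two slope
    frequencies; NaN where the pooled frequency is monomorphic."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# window-level estimators


def window_heterozygosity(p_hats, n_haploids: int) -> float:
    """Mean per-SNP expected heterozygosity 2p(1-p) * n/(n-1) over SNPs
    segregating in the pool; NaN when no SNP is present."""
    p = np.asarray(p_hats, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return math.nan
    return float(np.mean(2.0 * p * (1.0 - p)) * n_haploids / (n_haploids - 1))


def watterson_theta(n_snps: int, n_haploids: int, window_bp: int) -> float:
    """Per-site Watterson estimator S / (a_n * L)."""
    if n_haploids < 2:
        raise ValueError("n_haploids must be at least 2")
    return n_snps / (harmonic(n_haploids) * window_bp)


def tajima_d(p_hats, n_haploids: int, min_snps: int = 3) -> float:
    """Classical Tajima's D from pooled frequency estimates.

    pi = sum of 2p(1-p) * n/(n-1) over segregating SNPs, theta_W*L = S/a1,
    variance from the standard constants with n = n_haploids.  NaN when
    fewer than ``min_snps`` SNPs are available.
    """
    p = np.asarray(p_hats, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p < 1)]
    S = p.size
    if S < max(min_snps, 1):
        return math.nan
    c = tajima_constants(n_haploids)
    pi = float(np.sum(2.0 * p * (1.0 - p)) * n_haploids / (n_haploids - 1))
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / c["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# cohort aggregation


def combine_lines(
    tables: dict[str, pd.DataFrame], lines: list[str]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Align line site tables on (chrom, pos); returns the site scaffold and
    (n_lines, n_sites) ref/alt count matrices with 0 depth where a line has
    no record."""
    keyed = {}
    for lid in lines:
        t = tables[lid]
        keyed[lid] = t.set_index(["chrom", "pos"])
    index = None
    for lid in lines:
        ix = keyed[lid].index
        index = ix if index is None else index.union(ix)
    index = index.sortlevel()[0]
    R = np.zeros((len(lines), len(index)))
    A = np.zeros_like(R)
    ref = pd.Series("N", index=index)
    alt = pd.Series("N", index=index)
    for j, lid in enumerate(lines):
        t = keyed[lid].reindex(index)
        R[j] = t["ref_count"].fillna(0).to_numpy()
        A[j] = t["alt_count"].fillna(0).to_numpy()
        has = t["ref"].notna()
        ref[has] = t["ref"][has]
        alt[has] = t["alt"][has]
    sites = pd.DataFrame(
        {
            "chrom": index.get_level_values(0),
            "pos": index.get_level_values(1),
            "ref": ref.to_numpy(),
            "alt": alt.to_numpy(),
        }
    )
    return sites, R, A


def slope_site_frequencies(
    tables: dict[str, pd.DataFrame],
    slopes: dict[str, str],
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-site slope-level frequencies: chrom, pos, ref, alt, p_nfs, p_sfs."""
    lines = sorted(slopes)
    sites, R, A = combine_lines(tables, lines)
    out = sites.copy()
    for slope, col in ((NFS, "p_nfs"), (SFS, "p_sfs")):
        rows = [j for j, lid in enumerate(lines) if slopes[lid] == slope]
        if not rows:
            raise ValueError(f"no lines labeled {slope}")
        out[col] = slope_frequency(R[rows], A[rows], weighted=weighted)
    return out


def _segregating(p: np.ndarray) -> np.ndarray:
    return p[np.isfinite(p) & (p > 0.0) & (p < 1.0)]


def windowed_stats(
    tables: dict[str, pd.DataFrame],
    slopes: dict[str, str],
    n_haploids: int,
    chrom_lengths: dict[str, int],
    window: int = 5000,
    weighted: bool = True,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows and compute per-slope
    n_snps, heterozygosity, Watterson's theta and Tajima's D, plus the mean
    per-SNP interslope F_ST."""
    freqs = slope_site_frequencies(tables, slopes, weighted=weighted)
    rows = []
    for chrom, clen in chrom_lengths.items():
        sub = freqs[freqs["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        fst = fst_per_snp(sub["p_nfs"].to_numpy(), sub["p_sfs"].to_numpy())
        n_windows = (clen + window - 1) // window
        widx = (pos - 1) // window
        for w in range(n_windows):
            start, end = w * window + 1, min((w + 1) * window, clen)
            in_w = widx == w
            row = {"chrom": chrom, "start": start, "end": end}
            for slope, col in ((NFS, "p_nfs"), (SFS, "p_sfs")):
                p = _segregating(sub[col].to_numpy()[in_w])
                tag = slope.lower()
                row[f"n_snps_{tag}"] = p.size
                row[f"het_{tag}"] = window_heterozygosity(p, n_haploids) if p.size else math.nan
                row[f"theta_w_{tag}"] = watterson_theta(p.size, n_haploids, end - start + 1)
                row[f"tajima_d_{tag}"] = tajima_d(p, n_haploids)
            w_fst = fst[in_w]
            w_fst = w_fst[np.isfinite(w_fst)]
            row["fst"] = float(np.mean(w_fst)) if w_fst.size else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def gene_stats(
    tables: dict[str, pd.DataFrame],
    slopes: dict[str, str],
    genes: list[GeneModel],
    n_haploids: int,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-gene statistics from the gene's own sites (not window means):
    per-slope heterozygosity and Tajima's D, their interslope differences,
    mean heterozygosity, and mean per-SNP F_ST."""
    freqs = slope_site_frequencies(tables, slopes, weighted=weighted)
    by_chrom = {c: g for c, g in freqs.groupby("chrom")}
    rows = []
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        row: dict = {"gene_id": gene.gene_id, "chrom": gene.chrom,
                     "start": gene.start, "end": gene.end}
        if sub is None:
            sel = None
        else:
            pos = sub["pos"].to_numpy()
            sel = sub[(pos >= gene.start) & (pos <= gene.end)]
        hets = {}
        for slope, col in ((NFS, "p_nfs"), (SFS, "p_sfs")):
            tag = slope.lower()
            p = _segregating(sel[col].to_numpy()) if sel is not None else np.array([])
            row[f"n_snps_{tag}"] = p.size
            hets[slope] = window_heterozygosity(p, n_haploids) if p.size else math.nan
            row[f"het_{tag}"] = hets[slope]
            row[f"tajima_d_{tag}"] = tajima_d(p, n_haploids)
        row["delta_tajima_d"] = row["tajima_d_nfs"] - row["tajima_d_sfs"]
        row["delta_het"] = hets[NFS] - hets[SFS]
        row["mean_het"] = float(np.nanmean([hets[NFS], hets[SFS]])) if not all(
            math.isnan(hets[s]) for s in SLOPES
        ) else math.nan
        if sel is not None and len(sel):
            fst = fst_per_snp(sel["p_nfs"].to_numpy(), sel["p_sfs"].to_numpy())
            fst = fst[np.isfinite(fst)]
            row["fst"] = float(np.mean(fst)) if fst.size else math.nan
        else:
            row["fst"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def chromosome_summary(window_df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome means of the windowed statistics (the per-arm layout:
    Tajima's D and heterozygosity per slope, plus mean F_ST)."""
    cols = ["tajima_d_nfs", "tajima_d_sfs", "het_nfs", "het_sfs", "fst"]
    return window_df.groupby("chrom")[cols].mean().reset_index()


def line_theta(table: pd.DataFrame, n_haploids: int, genome_length: int) -> float:
    """Per-line Watterson estimate from the count of sites segregating in
    that line's pool (both alleles seen in its reads)."""
    seg = int(((table["alt_count"] > 0) & (table["ref_count"] > 0)).sum())
    return watterson_theta(seg, n_haploids, genome_length)
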