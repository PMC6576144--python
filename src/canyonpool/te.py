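"""Transposable-element insertion sharing, abundance, density and
divergence analysis for two-slope cohorts.

Input records are (family, chrom, pos, line, slope) calls; insertions of a
family at the same position across lines are one insertion *site*.  A site
is "shared" when it has carriers on both slopes.  All exact tests are
two-sided Fisher tests with the p-value defined as the sum of
probabilities of tables at least as extreme (probability <= observed)
under the hypergeometric null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .config import NFS, SFS
from .io import GeneModel


@dataclass
class TESharingStat:
    family: str
    n_sites_total: int
    n_sites_shared: int
    pct_shared: float  # percentage; round for display
    abundance_nfs: int  # insertion records (line-level copies) per slope
    abundance_sfs: int


def validate_te_matrix(records: pd.DataFrame) -> pd.DataFrame:
    dup = records.duplicated(subset=["family", "chrom", "pos", "line"])
    if dup.any():
        raise ValueError("duplicate (family, chrom, pos, line) insertion records")
    if (records["pos"] < 1).any():
        raise ValueError("positions must be 1-based")
    return records


# ---------------------------------------------------------------------------
# site collapsing


def collapse_sites(records: pd.DataFrame, merge_window: int = 0) -> pd.DataFrame:
    """Collapse per-line insertion records into per-site carrier sets.

    Records of the same family on the same chromosome within
    ``merge_window`` bp (transitively chained) form one site anchored at
    the smallest position.  The default (0) matches exact positions only.
    Returns one row per site: family, chrom, pos, n_nfs, n_sfs, lines.
    """
    validate_te_matrix(records)
    rows = []
    for (family, chrom), grp in records.groupby(["family", "chrom"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        new_site = np.concatenate([[True], np.diff(pos) > merge_window])
        site_id = np.cumsum(new_site)
        for _, sub in grp.groupby(site_id):
            lines = sorted(sub["line"])
            n_nfs = int((sub["slope"] == NFS).sum())
            n_sfs = int((sub["slope"] == SFS).sum())
            rows.append(
                {
                    "family": family,
                    "chrom": chrom,
                    "pos": int(sub["pos"].min()),
                    "n_nfs": n_nfs,
                    "n_sfs": n_sfs,
                    "lines": lines,
                }
            )
    return pd.DataFrame(rows, columns=["family", "chrom", "pos", "n_nfs", "n_sfs", "lines"])


# ---------------------------------------------------------------------------
# sharing and abundance


def family_sharing(
    records: pd.DataFrame, family: str, merge_window: int = 0
) -> TESharingStat:
    """Sharing statistics for one family: a site is shared when at least
    one line of each slope carries it."""
    if family not in set(records["family"]):
        raise KeyError(f"unknown TE family {family!r}")
    fam = records[records["family"] == family]
    sites = collapse_sites(fam, merge_window)
    shared = int(((sites["n_nfs"] > 0) & (sites["n_sfs"] > 0)).sum())
    total = len(sites)
    return TESharingStat(
        family=family,
        n_sites_total=total,
        n_sites_shared=shared,
        pct_shared=100.0 * shared / total if total else float("nan"),
        abundance_nfs=int((fam["slope"] == NFS).sum()),
        abundance_sfs=int((fam["slope"] == SFS).sum()),
    )


def abundance_test(c1: int, c2: int, total1: int, total2: int) -> float:
    """Two-sided Fisher exact p for a family's copy numbers (c1, c2) against
    the slopes' total insertion counts: table [[c1, T1-c1], [c2, T2-c2]]."""
    if not (0 <= c1 <= total1 and 0 <= c2 <= total2):
        raise ValueError("family counts exceed slope totals")
    table = [[c1, total1 - c1], [c2, total2 - c2]]
    if min(sum(r) for r in table) == 0 or min(
        table[0][j] + table[1][j] for j in range(2)
    ) == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def sharing_test(s: int, t: int, bg_shared: int, bg_total: int) -> float:
    """Two-sided Fisher exact p comparing one family's site sharing (s of t)
    to the background rate over all other families (bg includes the family;
    it is subtracted here): table [[s, t-s], [S-s, (T-t)-(S-s)]]."""
    if not (0 <= s <= t and 0 <= bg_shared <= bg_total and t <= bg_total):
        raise ValueError("inconsistent sharing counts")
    table = [[s, t - s], [bg_shared - s, (bg_total - t) - (bg_shared - s)]]
    if min(min(r) for r in table) < 0:
        raise ValueError("family counts exceed background")
    if min(sum(r) for r in table) == 0 or min(
        table[0][j] + table[1][j] for j in range(2)
    ) == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def family_table(records: pd.DataFrame, merge_window: int = 0) -> pd.DataFrame:
    """Per-family summary: sites, shared sites and percentage, per-slope
    abundance with its Fisher test, and the sharing-vs-background Fisher
    test."""
    fams = sorted(set(records["family"]))
    stats = [family_sharing(records, f, merge_window) for f in fams]
    t_nfs = int((records["slope"] == NFS).sum())
    t_sfs = int((records["slope"] == SFS).sum())
    bg_total = sum(st.n_sites_total for st in stats)
    bg_shared = sum(st.n_sites_shared for st in stats)
    rows = []
    for st in stats:
        rows.append(
            {
                "family": st.family,
                "n_sites_total": st.n_sites_total,
                "n_sites_shared": st.n_sites_shared,
                "pct_shared": st.pct_shared,
                "abundance_nfs": st.abundance_nfs,
                "abundance_sfs": st.abundance_sfs,
                "fisher_p_abundance": abundance_test(
                    st.abundance_nfs, st.abundance_sfs, t_nfs, t_sfs
                ),
                "fisher_p_sharing": sharing_test(
                    st.n_sites_shared, st.n_sites_total, bg_shared, bg_total
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densities, CDS disruption, divergence scores


def te_density(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    merge_window: int = 0,
) -> pd.DataFrame:
    """Insertion-site counts per non-overlapping window, per slope."""
    sites = collapse_sites(records, merge_window)
    rows = []
    for chrom, clen in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        widx = (sub["pos"].to_numpy() - 1) // window
        n_windows = (clen + window - 1) // window
        for w in range(n_windows):
            in_w = widx == w
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window + 1,
                    "end": min((w + 1) * window, clen),
                    "n_sites_nfs": int((sub["n_nfs"].to_numpy()[in_w] > 0).sum()),
                    "n_sites_sfs": int((sub["n_sfs"].to_numpy()[in_w] > 0).sum()),
                }
            )
    return pd.DataFrame(rows)


def cds_disruption(records: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Insertions whose position falls within a CDS interval (boundary
    inclusive), joined to gene IDs; one row per (record, gene)."""
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for s, e in gene.cds_intervals():
            tree.addi(s, e + 1, gene.gene_id)
    rows = []
    for row in records.itertuples(index=False):
        tree = trees.get(row.chrom)
        if not tree:
            continue
        for hit in sorted(tree[row.pos], key=lambda iv: iv.data):
            rows.append(
                {
                    "family": row.family,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "gene_id": hit.data,
                    "line": row.line,
                    "slope": row.slope,
                }
            )
    return pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "gene_id", "line", "slope"]
    )


def te_divergence_score(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site interslope divergence score: NFS carriers minus SFS carriers
    (computed like the gene-level differential sweep score)."""
    out = sites.copy()
    out["score"] = out["n_nfs"].astype(int) - out["n_sfs"].astype(int)
    return out
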