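"""Transspecies polymorphism: shared sites between two species, major-allele
co-occurrence, interslope-difference correlation, and the filter for
nonsynonymous slope-divergent shared SNPs.

Species site summaries are per-site slope-frequency tables (chrom, pos,
ref, alt, p_nfs, p_sfs).  "Major allele" means frequency > 0.5; exact ties
at 0.5 are excluded from major-allele comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact, spearmanr

from Bio.Seq import Seq

from .io import GeneModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# shared-site mapping


def map_shared_sites(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    coord_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sites polymorphic in both species with the same (strand-normalized)
    allele pair.

    ``coord_map`` columns: chrom_a, pos_a, chrom_b, pos_b, strand; ``None``
    means the identity mapping on shared coordinates.  Many-to-one mappings
    are rejected.
    """
    a = sites_a.rename(
        columns={"chrom": "chrom_a", "pos": "pos_a", "ref": "ref_a", "alt": "alt_a",
                 "p_nfs": "pa_nfs", "p_sfs": "pa_sfs"}
    )
    b = sites_b.rename(
        columns={"chrom": "chrom_b", "pos": "pos_b", "ref": "ref_b", "alt": "alt_b",
                 "p_nfs": "pb_nfs", "p_sfs": "pb_sfs"}
    )
    if coord_map is None:
        coord_map = pd.DataFrame(
            {
                "chrom_a": a["chrom_a"],
                "pos_a": a["pos_a"],
                "chrom_b": a["chrom_a"],
                "pos_b": a["pos_a"],
                "strand": "+",
            }
        )
    for side in ("a", "b"):
        dup = coord_map.duplicated(subset=[f"chrom_{side}", f"pos_{side}"])
        if dup.any():
            raise ValueError("coordinate map is not one-to-one")
    m = coord_map.merge(a, on=["chrom_a", "pos_a"]).merge(b, on=["chrom_b", "pos_b"])
    if len(m) == 0:
        return m
    minus = m["strand"] == "-"
    ref_b = np.where(minus, [s.translate(_COMPLEMENT) for s in m["ref_b"]], m["ref_b"])
    alt_b = np.where(minus, [s.translate(_COMPLEMENT) for s in m["alt_b"]], m["alt_b"])
    same = (m["ref_a"].to_numpy() == ref_b) & (m["alt_a"].to_numpy() == alt_b)
    swapped = (m["ref_a"].to_numpy() == alt_b) & (m["alt_a"].to_numpy() == ref_b)
    keep = same | swapped
    m = m[keep].copy()
    # orient B frequencies to A's alt allele where the pair is label-swapped
    sw = swapped[keep]
    m["pb_nfs"] = np.where(sw, 1.0 - m["pb_nfs"], m["pb_nfs"])
    m["pb_sfs"] = np.where(sw, 1.0 - m["pb_sfs"], m["pb_sfs"])
    poly_a = m[["pa_nfs", "pa_sfs"]].mean(axis=1).between(0, 1, inclusive="neither")
    poly_b = m[["pb_nfs", "pb_sfs"]].mean(axis=1).between(0, 1, inclusive="neither")
    m = m[poly_a & poly_b].reset_index(drop=True)
    m["ref"] = m["ref_a"]
    m["alt"] = m["alt_a"]
    return m.drop(columns=["ref_a", "alt_a", "ref_b", "alt_b"])


# ---------------------------------------------------------------------------
# major-allele co-occurrence


def _alt_major_fraction(p: np.ndarray) -> float:
    p = p[np.isfinite(p) & (p != 0.5)]
    if p.size == 0:
        return float("nan")
    return float(np.mean(p > 0.5))


def major_allele_cooccurrence(
    shared: pd.DataFrame,
    background_a: pd.DataFrame,
    background_b: pd.DataFrame,
    strata: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Fold enrichment of major-allele coincidence at shared sites.

    Observed: fraction of shared sites where the same allele is major in
    both species (per-site mean frequency > 0.5 on the same side).
    Expected: coincidence probability under independent major-allele
    assignment, computed from the alt-major fractions of the background
    sets (sites polymorphic in exactly one species).  Optional ``strata``
    maps stratum name -> boolean mask over ``shared`` (e.g. CDS,
    nonsynonymous); the overall stratum is always reported.
    """
    if len(shared) < 1:
        raise ValueError("no shared sites")
    pa = shared[["pa_nfs", "pa_sfs"]].mean(axis=1).to_numpy()
    pb = shared[["pb_nfs", "pb_sfs"]].mean(axis=1).to_numpy()
    m_a = _alt_major_fraction(
        background_a[["p_nfs", "p_sfs"]].mean(axis=1).to_numpy()
    )
    m_b = _alt_major_fraction(
        background_b[["p_nfs", "p_sfs"]].mean(axis=1).to_numpy()
    )
    expected = m_a * m_b + (1.0 - m_a) * (1.0 - m_b)
    all_strata: dict[str, pd.Series] = {"overall": pd.Series(True, index=shared.index)}
    if strata:
        all_strata.update(strata)
    rows = []
    for name, mask in all_strata.items():
        mask = mask.to_numpy() if hasattr(mask, "to_numpy") else np.asarray(mask)
        sa, sb = pa[mask], pb[mask]
        ok = (sa != 0.5) & (sb != 0.5)
        sa, sb = sa[ok], sb[ok]
        n = sa.size
        if n == 0:
            rows.append({"stratum": name, "n": 0, "observed": float("nan"),
                         "expected": expected, "fold": float("nan"),
                         "flag": "empty_stratum"})
            continue
        observed = float(np.mean((sa > 0.5) == (sb > 0.5)))
        rows.append(
            {
                "stratum": name,
                "n": int(n),
                "observed": observed,
                "expected": float(expected),
                "fold": observed / expected,
                "flag": None,
            }
        )
    return pd.DataFrame(rows)


def interslope_diff_correlation(
    shared: pd.DataFrame, strata: dict[str, pd.Series] | None = None
) -> pd.DataFrame:
    """Spearman correlation between species of the interslope frequency
    difference (p_NFS - p_SFS) at shared sites, overall and per stratum."""
    da = (shared["pa_nfs"] - shared["pa_sfs"]).to_numpy()
    db = (shared["pb_nfs"] - shared["pb_sfs"]).to_numpy()
    all_strata: dict[str, pd.Series] = {"overall": pd.Series(True, index=shared.index)}
    if strata:
        all_strata.update(strata)
    rows = []
    for name, mask in all_strata.items():
        mask = mask.to_numpy() if hasattr(mask, "to_numpy") else np.asarray(mask)
        xa, xb = da[mask], db[mask]
        ok = np.isfinite(xa) & np.isfinite(xb)
        xa, xb = xa[ok], xb[ok]
        if xa.size < 3 or len(set(xa)) < 2 or len(set(xb)) < 2:
            rows.append({"stratum": name, "n": int(xa.size), "r": float("nan"),
                         "p": float("nan"), "flag": "degenerate"})
            continue
        r, p = spearmanr(xa, xb)
        rows.append({"stratum": name, "n": int(xa.size), "r": float(r),
                     "p": float(p), "flag": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coding-effect annotation


class EffectAnnotator:
    """Classify SNPs as synonymous / nonsynonymous / noncoding against a
    reference sequence and gene CDS models (standard nuclear code).

    For genes with several transcripts the first transcript whose CDS
    contains the site is used.
    """

    def __init__(self, genes: list[GeneModel], ref_seqs: dict[str, str]):
        self.ref_seqs = ref_seqs
        self.trees: dict[str, IntervalTree] = {}
        self._tx: dict[str, tuple[GeneModel, np.ndarray]] = {}
        for gene in genes:
            for tx_id, cds in gene.transcripts.items():
                if not cds:
                    continue
                total = sum(e - s + 1 for s, e, _f in cds)
                if total % 3 != 0:
                    raise ValueError(
                        f"transcript {tx_id}: CDS length {total} not divisible by 3"
                    )
                # genomic positions in translation order
                pos = np.concatenate(
                    [np.arange(s, e + 1) for s, e, _f in sorted(cds)]
                )
                if gene.strand == "-":
                    pos = pos[::-1]
                frame = sorted(cds)[0][2] if gene.strand == "+" else sorted(cds)[-1][2]
                if frame:
                    pos = pos[frame:]
                self._tx[tx_id] = (gene, pos)
                tree = self.trees.setdefault(gene.chrom, IntervalTree())
                for s, e, _f in cds:
                    tree.addi(s, e + 1, tx_id)

    def annotate(self, chrom: str, pos: int, ref: str, alt: str) -> str:
        tree = self.trees.get(chrom)
        hits = sorted(tree[pos], key=lambda iv: iv.data) if tree else []
        if not hits:
            return "noncoding"
        for hit in hits:
            tx_id = hit.data
            gene, cds_pos = self._tx[tx_id]
            where = np.flatnonzero(cds_pos == pos)
            if where.size == 0:
                continue
            cds_i = int(where[0])
            codon_i = cds_i // 3
            codon_pos = cds_pos[codon_i * 3 : codon_i * 3 + 3]
            if codon_pos.size < 3:
                raise ValueError(f"incomplete codon at {chrom}:{pos} in {tx_id}")
            seq = self.ref_seqs[chrom]
            bases = [seq[p - 1] for p in codon_pos]
            sub = ref, alt
            if gene.strand == "-":
                bases = [b.translate(_COMPLEMENT) for b in bases]
                sub = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
            codon = "".join(bases)
            offset = cds_i % 3
            if codon[offset] != sub[0]:
                raise ValueError(
                    f"reference mismatch at {chrom}:{pos}: genome has "
                    f"{codon[offset]}, site table says {sub[0]}"
                )
            mutated = codon[:offset] + sub[1] + codon[offset + 1 :]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(mutated).translate())
            return "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return "noncoding"

    def in_cds(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree and tree[pos])


def annotate_shared(shared: pd.DataFrame, annotator: EffectAnnotator) -> pd.DataFrame:
    """Add an ``effect`` column to a shared-site table (species A coordinates)."""
    shared = shared.copy()
    shared["effect"] = [
        annotator.annotate(row.chrom_a, int(row.pos_a), row.ref, row.alt)
        for row in shared.itertuples(index=False)
    ]
    return shared


# ---------------------------------------------------------------------------
# slope-divergent nonsynonymous shared SNPs


def slope_divergent_filter(
    shared: pd.DataFrame, n_lines_per_slope: int = 9
) -> pd.DataFrame:
    """Retain shared SNPs that are (i) nonsynonymous, (ii) slope-divergent
    in each species (the major allele differs between slopes), and (iii)
    concordant across species (the same allele is major on the same slope
    in both).  Attaches a two-sided Fisher p per species on the interslope
    haploid-equivalent allele-count table (frequency x 2 x lines, rounded).
    """
    if "effect" not in shared.columns:
        raise ValueError("shared table lacks an 'effect' column; annotate first")
    df = shared[shared["effect"] == "nonsynonymous"].copy()
    cols = ["pa_nfs", "pa_sfs", "pb_nfs", "pb_sfs"]
    if len(df) == 0:
        df["fisher_p_a"] = df["fisher_p_b"] = []
        df["slope_divergent"] = []
        return df
    ties = (df[cols] == 0.5).any(axis=1)
    df = df[~ties]
    div_a = (df["pa_nfs"] > 0.5) != (df["pa_sfs"] > 0.5)
    div_b = (df["pb_nfs"] > 0.5) != (df["pb_sfs"] > 0.5)
    concord = ((df["pa_nfs"] > 0.5) == (df["pb_nfs"] > 0.5)) & (
        (df["pa_sfs"] > 0.5) == (df["pb_sfs"] > 0.5)
    )
    df = df[div_a & div_b & concord].copy()
    df["slope_divergent"] = True
    two_n = 2 * n_lines_per_slope
    for sp, (c1, c2), col in (
        ("a", ("pa_nfs", "pa_sfs"), "fisher_p_a"),
        ("b", ("pb_nfs", "pb_sfs"), "fisher_p_b"),
    ):
        ps = []
        for p_n, p_s in zip(df[c1], df[c2]):
            alt_n = int(round(p_n * two_n))
            alt_s = int(round(p_s * two_n))
            _, p = fisher_exact(
                [[alt_n, two_n - alt_n], [alt_s, two_n - alt_s]],
                alternative="two-sided",
            )
            ps.append(float(p))
        df[col] = ps
    return df.reset_index(drop=True)
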