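"""End-to-end orchestration: from a cohort (in memory or on disk) to
windowed statistics, sweep regions, gene scores, transspecies and TE
summaries."""

from __future__ import annotations

import pandas as pd

from . import hmm, scores, stats, te, transspecies
from .config import SFS
from .io import GeneModel
from .simulate import Cohort


def sweep_regions_for_lines(
    tables: dict[str, pd.DataFrame],
    genome_length: int,
    params: hmm.HmmParams | None = None,
    min_sites: int = 3,
) -> dict[str, list[hmm.SweepRegion]]:
    """Decode every line (theta estimated per line) and call sweep regions."""
    base = params or hmm.HmmParams()
    out: dict[str, list[hmm.SweepRegion]] = {}
    for lid, table in tables.items():
        theta = stats.line_theta(table, base.n_haploids, genome_length)
        line_params = hmm.HmmParams(
            n_haploids=base.n_haploids,
            min_cov=base.min_cov,
            max_cov=base.max_cov,
            base_qual=base.base_qual,
            k_transition=base.k_transition,
            theta=max(theta, 1e-9),
            tilt_gamma=base.tilt_gamma,
        )
        regions: list[hmm.SweepRegion] = []
        for chrom, sub in table.groupby("chrom", sort=True):
            res = hmm.decode(sub.reset_index(drop=True), line_params)
            regions.extend(hmm.call_regions(res, lid, chrom, min_sites=min_sites))
        out[lid] = regions
    return out


def analyze_cohort(
    cohort: Cohort,
    window: int = 5000,
    hmm_params: hmm.HmmParams | None = None,
    score_threshold: int = 6,
) -> dict:
    """Run the full analysis on an in-memory cohort; returns a dict of
    result tables keyed by stage."""
    cfg = cohort.config
    win = stats.windowed_stats(
        cohort.tables, cohort.slopes, cfg.haploids_per_pool, cohort.chrom_lengths,
        window=window,
    )
    genes_df = stats.gene_stats(
        cohort.tables, cohort.slopes, cohort.genes, cfg.haploids_per_pool
    )
    regions = sweep_regions_for_lines(
        cohort.tables, cfg.genome_length, params=hmm_params
    )
    classes = hmm.classify_regions(regions, cohort.slopes, cohort.chrom_lengths)
    score_df = scores.score_table(cohort.genes, regions, cohort.slopes, genes_df)
    nfs_prev, sfs_prev = scores.prevalent_genes(score_df, threshold=score_threshold)
    corr = scores.score_correlations(score_df)

    sites_a = stats.slope_site_frequencies(cohort.tables, cohort.slopes)
    sites_b = stats.slope_site_frequencies(
        cohort.species_b_tables, cohort.species_b_slopes
    )
    shared = transspecies.map_shared_sites(sites_a, sites_b)
    annotator = transspecies.EffectAnnotator(cohort.genes, cohort.ref_seqs)
    shared = transspecies.annotate_shared(shared, annotator)
    key_a = set(zip(shared["chrom_a"], shared["pos_a"]))
    key_b = set(zip(shared["chrom_b"], shared["pos_b"]))
    bg_a = sites_a[~pd.Series(list(zip(sites_a["chrom"], sites_a["pos"]))).isin(key_a)]
    bg_b = sites_b[~pd.Series(list(zip(sites_b["chrom"], sites_b["pos"]))).isin(key_b)]
    strata = {
        "cds": shared.apply(
            lambda r: annotator.in_cds(r["chrom_a"], int(r["pos_a"])), axis=1
        )
        if len(shared)
        else pd.Series(dtype=bool),
        "nonsynonymous": shared["effect"] == "nonsynonymous",
    }
    cooc = transspecies.major_allele_cooccurrence(shared, bg_a, bg_b, strata)
    diff_corr = transspecies.interslope_diff_correlation(shared, strata)
    divergent = transspecies.slope_divergent_filter(
        shared, n_lines_per_slope=cfg.n_lines_per_slope
    )

    fam_table = te.family_table(cohort.te_calls)
    density = te.te_density(cohort.te_calls, cohort.chrom_lengths)
    disruptions = te.cds_disruption(cohort.te_calls, cohort.genes)
    te_sites = te.te_divergence_score(te.collapse_sites(cohort.te_calls))

    return {
        "windows": win,
        "chromosome_summary": stats.chromosome_summary(win),
        "gene_stats": genes_df,
        "regions": regions,
        "region_classes": classes,
        "scores": score_df,
        "prevalent_nfs": nfs_prev,
        "prevalent_sfs": sfs_prev,
        "score_correlations": corr,
        "shared_sites": shared,
        "cooccurrence": cooc,
        "interslope_diff_correlation": diff_corr,
        "slope_divergent": divergent,
        "te_families": fam_table,
        "te_density": density,
        "te_cds_disruption": disruptions,
        "te_sites": te_sites,
    }


# ---------------------------------------------------------------------------
# truth-based evaluation (used by tests and the reproduction script)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def sweep_recovery(
    regions_by_line: dict[str, list[hmm.SweepRegion]],
    true_sweeps: dict[str, list[tuple[str, int, int]]],
    min_overlap: float = 0.5,
) -> dict:
    """Recall of planted sweep intervals and false-discovery proportion of
    called regions, at >= ``min_overlap`` reciprocal overlap, pooled over
    lines."""
    n_true = n_recovered = n_called = n_false = 0
    for lid, truths in true_sweeps.items():
        calls = [
            (r.chrom, r.start, r.end) for r in regions_by_line.get(lid, [])
        ]
        n_true += len(truths)
        n_called += len(calls)
        for chrom, s, e in truths:
            if any(
                c == chrom and _reciprocal_overlap((s, e), (cs, ce)) >= min_overlap
                for c, cs, ce in calls
            ):
                n_recovered += 1
        for c, cs, ce in calls:
            if not any(
                c == chrom
                and _reciprocal_overlap((s, e), (cs, ce)) >= min_overlap
                for chrom, s, e in truths
            ):
                n_false += 1
    return {
        "recall": n_recovered / n_true if n_true else float("nan"),
        "fdr": n_false / n_called if n_called else 0.0,
        "n_true": n_true,
        "n_called": n_called,
    }


def planted_gene_recall(
    score_df: pd.DataFrame,
    genes: list[GeneModel],
    sweeps: list,
    slope: str,
    threshold: int = 6,
) -> float:
    """Fraction of genes inside planted ``slope`` sweeps that reach the
    prevalence threshold on the matching side."""
    inside = [
        g.gene_id
        for g in genes
        for sw in sweeps
        if sw.slope == slope and g.chrom == sw.chrom
        and g.start >= sw.start and g.end <= sw.end
    ]
    if not inside:
        return float("nan")
    sub = score_df[score_df["gene_id"].isin(inside)]
    if slope == SFS:
        hit = (sub["score"] <= -threshold).sum()
    else:
        hit = (sub["score"] >= threshold).sum()
    return float(hit / len(inside))
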