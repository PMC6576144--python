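"""Synthetic two-slope pooled-sequencing cohorts with known ground truth.

The generator produces, per line, a site table of pooled read counts, plus
gene annotations, TE insertion calls, a second-species cohort sharing a
small fraction of polymorphic sites, and the ground truth needed to score
every downstream stage (planted sweep intervals, true slope frequencies,
TE carrier sets, the cross-species site map).

Frequency model
---------------
A site's population alternate-allele frequency is drawn from the neutral
site-frequency spectrum xi_i proportional to 1/i (i = 1..n-1 of n
haploids).  With probability ``migration_mix`` the two slopes share one
draw; otherwise each slope receives an independent draw.  This site-level
mixture keeps the marginal per-slope spectrum exactly neutral (so Tajima's
D is centred on zero away from sweeps) while ``migration_mix`` tunes
interslope F_ST monotonically from its maximum (0 sharing) down to the
pure-sampling floor (full sharing).

Inside a planted sweep interval, for the affected slope, only a fraction
``diversity_reduction`` of sites keep segregating and their frequencies q
are pushed toward the nearer extreme via q -> q**g (q < 1/2) or
1-(1-q)**g (q >= 1/2) with g = 1/diversity_reduction; the remaining sites
are fixed for the reference allele in that slope.  Pushing toward the
nearer extreme reproduces the post-hitchhiking phenotype — reduced
heterozygosity, rare-skewed spectrum, hence negative Tajima's D — whereas
a randomly chosen side would drag rare variants through intermediate
frequencies and inflate heterozygosity.  ``diversity_reduction = 1`` is an
exact no-op.

Observation model: per line, the pool frequency is Binomial(n, p)/n over
the pool's n haploids, coverage is Poisson(mean_depth), and alternate read
counts are Binomial(coverage, pool frequency).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NFS, SFS, SLOPES, SimulationConfig, SweepInterval
from .io import GeneModel, write_fasta, write_genes, write_sites, write_slopes, write_te_calls

_BASES = np.array(["A", "C", "G", "T"])


class CalibrationError(RuntimeError):
    """Raised when a divergence target cannot be bracketed by migration_mix."""


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream inference."""

    true_sweeps: dict[str, list[tuple[str, int, int]]]
    true_site_freqs: pd.DataFrame  # chrom, pos, p_nfs, p_sfs
    te_truth: pd.DataFrame  # family, chrom, pos, shared, n_nfs, n_sfs
    shared_site_map: pd.DataFrame  # chrom_a, pos_a, chrom_b, pos_b, strand

    def to_json(self, path) -> None:
        payload = {
            "true_sweeps": self.true_sweeps,
            "true_site_freqs": self.true_site_freqs.to_dict(orient="list"),
            "te_truth": self.te_truth.to_dict(orient="list"),
            "shared_site_map": self.shared_site_map.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class Cohort:
    """An in-memory synthetic cohort: the full input set of the pipeline."""

    config: SimulationConfig
    tables: dict[str, pd.DataFrame]  # line id -> site table
    slopes: dict[str, str]
    genes: list[GeneModel]
    te_calls: pd.DataFrame
    species_b_tables: dict[str, pd.DataFrame]
    species_b_slopes: dict[str, str]
    ref_seqs: dict[str, str]
    truth: GroundTruth
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Materialize the cohort as VCF/GFF3/TSV/FASTA/JSON files."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for lid, table in self.tables.items():
            write_sites(table, f"{outdir}/{lid}.vcf", lid, self.chrom_lengths)
        for lid, table in self.species_b_tables.items():
            write_sites(
                table, f"{outdir}/speciesB_{lid}.vcf", lid, self.chrom_lengths
            )
        write_slopes(self.slopes, f"{outdir}/slopes.tsv")
        write_genes(self.genes, f"{outdir}/genes.gff3")
        write_te_calls(self.te_calls, f"{outdir}/te_calls.tsv")
        write_fasta(self.ref_seqs, f"{outdir}/reference.fa")
        self.truth.to_json(f"{outdir}/truth.json")
        self.config.to_yaml(f"{outdir}/config.yaml")


# ---------------------------------------------------------------------------
# frequency machinery


def neutral_spectrum(n_haploids: int) -> np.ndarray:
    """Normalized neutral SFS over derived-allele counts 1..n-1."""
    i = np.arange(1, n_haploids)
    xi = 1.0 / i
    return xi / xi.sum()


def _draw_freqs(rng: np.random.Generator, n_sites: int, n: int) -> np.ndarray:
    xi = neutral_spectrum(n)
    counts = rng.choice(np.arange(1, n), size=n_sites, p=xi)
    return counts / n


def _slope_freqs(
    rng: np.random.Generator, n_sites: int, n: int, migration_mix: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slope frequencies: one shared draw with probability
    ``migration_mix``, otherwise independent draws with random allele
    orientation per slope.

    The orientation flip (p -> 1-p with probability 1/2 at slope-private
    sites) models the arbitrary choice of reference allele relative to each
    deme's derived allele; it preserves the folded spectrum — hence
    heterozygosity, segregating-site counts and Tajima's D — while letting
    the slopes sit at opposite frequency extremes, which widens the
    attainable interslope F_ST range."""
    shared = _draw_freqs(rng, n_sites, n)
    p_nfs = _draw_freqs(rng, n_sites, n)
    p_sfs = _draw_freqs(rng, n_sites, n)
    flip_n = rng.random(n_sites) < 0.5
    flip_s = rng.random(n_sites) < 0.5
    p_nfs = np.where(flip_n, 1.0 - p_nfs, p_nfs)
    p_sfs = np.where(flip_s, 1.0 - p_sfs, p_sfs)
    is_shared = rng.random(n_sites) < migration_mix
    p_nfs = np.where(is_shared, shared, p_nfs)
    p_sfs = np.where(is_shared, shared, p_sfs)
    return p_nfs, p_sfs


def _apply_sweeps(
    rng: np.random.Generator,
    pos: np.ndarray,
    freqs: dict[str, np.ndarray],
    sweeps: list[SweepInterval],
) -> None:
    """Distort slope frequencies in place inside planted sweep intervals."""
    for sw in sweeps:
        mask = (pos >= sw.start) & (pos <= sw.end)
        if not mask.any():
            continue
        n_in = int(mask.sum())
        gamma = 1.0 / sw.diversity_reduction
        keep = rng.random(n_in) < sw.diversity_reduction
        for slope in sw.affected_slopes():
            q = freqs[slope][mask]
            tilted = np.where(q < 0.5, q**gamma, 1.0 - (1.0 - q) ** gamma)
            freqs[slope][mask] = np.where(keep, tilted, 0.0)


def _sample_pool_reads(
    rng: np.random.Generator,
    p: np.ndarray,
    n_haploids: int,
    mean_depth: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage sampling: pool of haplotypes, then reads. Returns (ref, alt)."""
    pool = rng.binomial(n_haploids, p) / n_haploids
    depth = rng.poisson(mean_depth, size=p.shape)
    alt = rng.binomial(depth, pool)
    return depth - alt, alt


def _site_table(
    chrom: str,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    gq: int = 60,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ref_count": ref_counts.astype(np.int64),
            "alt_count": alt_counts.astype(np.int64),
            "gq": np.int64(gq),
        }
    )


# ---------------------------------------------------------------------------
# component generators


def _make_sites(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Draw the reference sequence and the polymorphic site scaffold."""
    L = config.genome_length
    seq = rng.choice(_BASES, size=L)
    a_n = np.sum(1.0 / np.arange(1, config.haploids_per_pool))
    n_sites = rng.poisson(config.theta_per_site * a_n * L)
    n_sites = min(max(n_sites, 1), L)
    pos = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1
    ref = seq[pos - 1]
    # alternate allele: one of the three non-reference bases
    shift = rng.integers(1, 4, size=n_sites)
    base_idx = np.searchsorted(_BASES, ref)
    alt = _BASES[(base_idx + shift) % 4]
    return pos, ref, alt, "".join(seq)


def _make_genes(config: SimulationConfig) -> list[GeneModel]:
    """Tile the chromosome with two-exon genes (900+900 bp CDS, frame 0)."""
    genes = []
    k = 0
    start = 2001
    while start + 2999 <= config.genome_length:
        k += 1
        gid = f"g{k:04d}"
        strand = "+" if k % 2 else "-"
        cds = [(start + 100, start + 999, 0), (start + 1500, start + 2399, 0)]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=config.chrom,
                start=start,
                end=start + 2999,
                strand=strand,
                transcripts={f"{gid}.t1": cds},
            )
        )
        start += config.gene_spacing
    return genes


def _make_te_calls(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TE insertion records per line plus per-site truth."""
    lines = {s: [f"{s}_{i+1}" for i in range(config.n_lines_per_slope)] for s in SLOPES}
    records = []
    truth_rows = []
    for fam in config.te_families:
        pos = np.sort(rng.choice(config.genome_length, size=fam.n_sites, replace=False)) + 1
        shared = rng.random(fam.n_sites) < fam.sharing_prob
        for p, is_shared in zip(pos, shared):
            carriers: dict[str, list[str]] = {NFS: [], SFS: []}
            if is_shared:
                target = SLOPES
            else:
                target = (SLOPES[int(rng.random() < 0.5)],)
            for slope in target:
                picks = [
                    lid
                    for lid in lines[slope]
                    if rng.random() < config.te_carrier_prob
                ]
                if not picks:
                    picks = [lines[slope][int(rng.integers(len(lines[slope])))]]
                carriers[slope] = picks
            for slope in SLOPES:
                for lid in carriers[slope]:
                    records.append((fam.name, config.chrom, int(p), lid, slope))
            truth_rows.append(
                (
                    fam.name,
                    config.chrom,
                    int(p),
                    bool(is_shared),
                    len(carriers[NFS]),
                    len(carriers[SFS]),
                )
            )
    te_calls = pd.DataFrame(
        records, columns=["family", "chrom", "pos", "line", "slope"]
    ).sort_values(["family", "chrom", "pos", "line"], kind="stable").reset_index(drop=True)
    te_truth = pd.DataFrame(
        truth_rows, columns=["family", "chrom", "pos", "shared", "n_nfs", "n_sfs"]
    )
    return te_calls, te_truth


def _make_species_b(
    rng: np.random.Generator,
    config: SimulationConfig,
    pos_a: np.ndarray,
    ref_a: np.ndarray,
    alt_a: np.ndarray,
    p_nfs_a: np.ndarray,
    p_sfs_a: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Second-species site scaffold and slope frequencies.

    A fraction ``shared_species_fraction`` of the first species' sites are
    copied (same position and allele pair) with jittered frequencies; the
    major allele coincides between species with probability
    ``species_cooccurrence`` and a ``species_convergent_fraction`` of shared
    sites copy the interslope frequency difference.  Private sites get
    independent neutral frequencies whose allele orientation (the two
    species are mapped to different reference assemblies, so orientations
    need not agree) is planted so that major-allele coincidence expected
    under independence equals ``species_background_coincidence``.
    """
    n_a = len(pos_a)
    n = config.haploids_per_pool
    lo, hi = 0.5 / n, 1.0 - 0.5 / n
    shared_mask = rng.random(n_a) < config.shared_species_fraction
    idx = np.flatnonzero(shared_mask)

    # shared sites
    pbar_a = (p_nfs_a[idx] + p_sfs_a[idx]) / 2.0
    d_a = p_nfs_a[idx] - p_sfs_a[idx]
    same_side = rng.random(len(idx)) < config.species_cooccurrence
    raw = np.clip(pbar_a + rng.normal(0.0, 0.10, size=len(idx)), lo, hi)
    a_alt_major = pbar_a > 0.5
    want_alt_major = np.where(same_side, a_alt_major, ~a_alt_major)
    raw = np.where((raw > 0.5) == want_alt_major, raw, 1.0 - raw)
    convergent = rng.random(len(idx)) < config.species_convergent_fraction
    d_b = np.where(
        convergent,
        d_a + rng.normal(0.0, 0.03, size=len(idx)),
        rng.normal(0.0, 0.12, size=len(idx)),
    )
    pb_nfs_sh = np.clip(raw + d_b / 2.0, lo, hi)
    pb_sfs_sh = np.clip(raw - d_b / 2.0, lo, hi)

    # private sites at positions where species A is not polymorphic
    n_private = max(len(pos_a) - len(idx), 1)
    all_pos = rng.choice(config.genome_length, size=min(2 * n_a, config.genome_length), replace=False) + 1
    private_pos = np.setdiff1d(all_pos, pos_a, assume_unique=False)[:n_private]
    private_pos = np.sort(private_pos)
    refs = rng.integers(0, 4, size=len(private_pos))
    alts = (refs + rng.integers(1, 4, size=len(private_pos))) % 4
    p_priv_nfs, p_priv_sfs = _slope_freqs(
        rng, len(private_pos), n, config.migration_mix
    )
    # Orient B-private sites so that the major-allele coincidence expected
    # under independent assignment, m_a*m_b + (1-m_a)(1-m_b), equals the
    # planted background level, given A's own alt-major fraction m_a.
    pbar_all_a = (p_nfs_a + p_sfs_a) / 2.0
    m_a = float(np.mean(pbar_all_a[pbar_all_a != 0.5] > 0.5))
    target = config.species_background_coincidence
    if abs(1.0 - 2.0 * m_a) < 1e-9:
        m_b = 0.5
    else:
        m_b = float(np.clip((1.0 - m_a - target) / (1.0 - 2.0 * m_a), 0.0, 1.0))
    pbar = (p_priv_nfs + p_priv_sfs) / 2.0
    want_alt = rng.random(len(private_pos)) < m_b
    flip = (pbar > 0.5) != want_alt
    p_priv_nfs = np.where(flip, 1.0 - p_priv_nfs, p_priv_nfs)
    p_priv_sfs = np.where(flip, 1.0 - p_priv_sfs, p_priv_sfs)

    pos_b = np.concatenate([pos_a[idx], private_pos])
    ref_b = np.concatenate([ref_a[idx], _BASES[refs]])
    alt_b = np.concatenate([alt_a[idx], _BASES[alts]])
    pb_nfs = np.concatenate([pb_nfs_sh, p_priv_nfs])
    pb_sfs = np.concatenate([pb_sfs_sh, p_priv_sfs])
    order = np.argsort(pos_b, kind="stable")
    return (
        pos_b[order],
        ref_b[order],
        alt_b[order],
        pb_nfs[order],
        pb_sfs[order],
        pos_a[idx],
    )


# ---------------------------------------------------------------------------
# public API


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a complete two-slope cohort.  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    n = config.haploids_per_pool

    pos, ref, alt, seq = _make_sites(rng, config)
    p_nfs, p_sfs = _slope_freqs(rng, len(pos), n, config.migration_mix)
    freqs = {NFS: p_nfs, SFS: p_sfs}
    _apply_sweeps(rng, pos, freqs, config.sweep_intervals)

    slopes = config.slope_of()
    tables = {}
    for lid in config.line_ids():
        refc, altc = _sample_pool_reads(
            rng, freqs[slopes[lid]], n, config.mean_depth
        )
        tables[lid] = _site_table(chrom, pos, ref, alt, refc, altc)

    genes = _make_genes(config)
    te_calls, te_truth = _make_te_calls(rng, config)

    pos_b, ref_b, alt_b, pb_nfs, pb_sfs, shared_pos = _make_species_b(
        rng, config, pos, ref, alt, freqs[NFS], freqs[SFS]
    )
    freqs_b = {NFS: pb_nfs, SFS: pb_sfs}
    b_tables = {}
    b_slopes = {}
    for lid in config.line_ids():
        refc, altc = _sample_pool_reads(
            rng, freqs_b[slopes[lid]], n, config.mean_depth
        )
        b_tables[lid] = _site_table(chrom, pos_b, ref_b, alt_b, refc, altc)
        b_slopes[lid] = slopes[lid]

    true_sweeps: dict[str, list[tuple[str, int, int]]] = {
        lid: [] for lid in config.line_ids()
    }
    for sw in config.sweep_intervals:
        for lid in config.line_ids():
            if slopes[lid] in sw.affected_slopes():
                true_sweeps[lid].append((sw.chrom, sw.start, sw.end))

    truth = GroundTruth(
        true_sweeps=true_sweeps,
        true_site_freqs=pd.DataFrame(
            {"chrom": chrom, "pos": pos, "p_nfs": freqs[NFS], "p_sfs": freqs[SFS]}
        ),
        te_truth=te_truth,
        shared_site_map=pd.DataFrame(
            {
                "chrom_a": chrom,
                "pos_a": shared_pos,
                "chrom_b": chrom,
                "pos_b": shared_pos,
                "strand": "+",
            }
        ),
    )
    return Cohort(
        config=config,
        tables=tables,
        slopes=slopes,
        genes=genes,
        te_calls=te_calls,
        species_b_tables=b_tables,
        species_b_slopes=b_slopes,
        ref_seqs={chrom: seq},
        truth=truth,
        chrom_lengths={chrom: config.genome_length},
    )


def _mean_fst_for_mix(config: SimulationConfig, mix: float, seeds) -> float:
    """Genome-wide mean per-SNP interslope F_ST at a given mix, including
    the config's planted sweeps (the calibration target is a genome-wide
    average, so sweep regions contribute)."""
    from .stats import fst_per_snp, slope_frequency

    vals = []
    for seed in seeds:
        cfg = config.replace(migration_mix=mix, seed=int(seed))
        rng = np.random.default_rng(cfg.seed)
        n = cfg.haploids_per_pool
        a_n = np.sum(1.0 / np.arange(1, n))
        n_sites = max(int(rng.poisson(cfg.theta_per_site * a_n * cfg.genome_length)), 1)
        n_sites = min(n_sites, cfg.genome_length)
        pos = np.sort(rng.choice(cfg.genome_length, size=n_sites, replace=False)) + 1
        p_nfs, p_sfs = _slope_freqs(rng, n_sites, n, mix)
        freqs = {NFS: p_nfs, SFS: p_sfs}
        _apply_sweeps(rng, pos, freqs, cfg.sweep_intervals)
        counts = {}
        for slope in SLOPES:
            R = np.empty((cfg.n_lines_per_slope, n_sites))
            A = np.empty_like(R)
            for j in range(cfg.n_lines_per_slope):
                R[j], A[j] = _sample_pool_reads(rng, freqs[slope], n, cfg.mean_depth)
            counts[slope] = (R, A)
        p1 = slope_frequency(*counts[NFS])
        p2 = slope_frequency(*counts[SFS])
        fst = fst_per_snp(p1, p2)
        vals.append(np.nanmean(fst))
    return float(np.mean(vals))


def calibrate_divergence(
    target_fst: float,
    config: SimulationConfig,
    n_seeds: int = 3,
    tol: float = 0.02,
    max_iter: int = 25,
) -> SimulationConfig:
    """Bisect ``migration_mix`` so the simulated mean per-SNP F_ST matches a
    target, averaged over ``n_seeds`` seeds.  Raises :class:`CalibrationError`
    when the target lies outside the achievable range.
    """
    if not 0.0 <= target_fst < 0.5:
        raise ValueError("target_fst must lie in [0, 0.5)")
    seeds = [config.seed + 1000 + k for k in range(n_seeds)]
    lo_mix, hi_mix = 0.0, 1.0
    f_hi = _mean_fst_for_mix(config, hi_mix, seeds)  # smallest achievable
    if target_fst <= f_hi:
        if f_hi - target_fst <= tol:
            return config.replace(migration_mix=1.0)
        raise CalibrationError(
            f"target F_ST {target_fst:.3f} below the sampling floor {f_hi:.3f}"
        )
    f_lo = _mean_fst_for_mix(config, lo_mix, seeds)  # largest achievable
    if target_fst >= f_lo:
        if target_fst - f_lo <= tol:
            return config.replace(migration_mix=0.0)
        raise CalibrationError(
            f"target F_ST {target_fst:.3f} above the maximum achievable {f_lo:.3f}"
        )
    mix = 0.5
    for _ in range(max_iter):
        mix = 0.5 * (lo_mix + hi_mix)
        f_mid = _mean_fst_for_mix(config, mix, seeds)
        if abs(f_mid - target_fst) <= tol / 2.0:
            break
        if f_mid > target_fst:  # too divergent -> more sharing
            lo_mix = mix
        else:
            hi_mix = mix
    return config.replace(migration_mix=float(mix))
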