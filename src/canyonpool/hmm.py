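"""Three-state HMM selective-sweep detection from pooled read counts.

Hidden states are Neutral, Intermediate and Selection, each tied to a
site-frequency spectrum over derived-allele counts 1..n-1: the neutral
spectrum xi_i ~ 1/i, an exponentially tilted spectrum concentrating mass
at extreme frequencies (the post-hitchhiking regime), and their
normalized elementwise geometric mean.  Emissions integrate binomial read
sampling over the spectrum; transitions use a single per-site switch
probability k (default 1e-10), so state changes require sustained
evidence.  Viterbi segmentation is authoritative for region calls;
forward-backward posteriors are reported for diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .config import NFS, SFS

NEUTRAL, INTERMEDIATE, SELECTION = 0, 1, 2
STATE_NAMES = ("Neutral", "Intermediate", "Selection")


@dataclass
class HmmParams:
    """Decoding parameters.

    ``theta`` is the per-line Watterson estimate (recorded per line; the
    spectra are conditioned on segregating sites, so theta does not enter
    the emissions).  ``tilt_gamma`` controls how strongly the Selection
    spectrum concentrates at extreme frequencies.
    """

    n_haploids: int = 40
    min_cov: int = 5
    max_cov: int = 250
    base_qual: int = 20
    k_transition: float = 1e-10
    theta: float | None = None
    tilt_gamma: float = 8.0

    def __post_init__(self) -> None:
        if self.n_haploids < 4:
            raise ValueError("n_haploids must be at least 4")
        if not 0.0 < self.k_transition < 1.0:
            raise ValueError("k_transition must lie in (0, 1)")
        if self.min_cov > self.max_cov:
            raise ValueError("min_cov must not exceed max_cov")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.tilt_gamma < 0:
            raise ValueError("tilt_gamma must be non-negative")


@dataclass
class SweepRegion:
    """A maximal run of Selection-state sites for one line."""

    line_id: str
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_posterior: float


@dataclass
class DecodeResult:
    positions: np.ndarray  # retained (coverage-filtered) site positions
    states: np.ndarray  # Viterbi path, values in {0, 1, 2}
    posteriors: np.ndarray  # (T, 3) forward-backward posteriors


# ---------------------------------------------------------------------------
# spectra and emissions


def state_spectra(params: HmmParams) -> np.ndarray:
    """Normalized (3, n-1) spectra for Neutral, Intermediate, Selection."""
    n = params.n_haploids
    i = np.arange(1, n, dtype=float)
    neutral = 1.0 / i
    neutral /= neutral.sum()
    sel = (1.0 / i) * np.exp(-params.tilt_gamma * np.minimum(i, n - i) / n)
    sel /= sel.sum()
    inter = np.sqrt(neutral * sel)
    inter /= inter.sum()
    return np.vstack([neutral, inter, sel])


def emission_logprob(ref_count: int, alt_count: int, spectrum, n_haploids: int) -> float:
    """log P(alt reads | spectrum) = log sum_i xi_i Binom(alt | depth, i/n)."""
    spectrum = np.asarray(spectrum, dtype=float)
    depth = ref_count + alt_count
    i = np.arange(1, n_haploids, dtype=float)
    lp = binom.logpmf(alt_count, depth, i / n_haploids)
    return float(logsumexp(lp + np.log(spectrum)))


def emission_matrix(
    depths: np.ndarray, alts: np.ndarray, spectra: np.ndarray, n_haploids: int
) -> np.ndarray:
    """(T, 3) emission log-probabilities for all sites and states."""
    i = np.arange(1, n_haploids, dtype=float)
    lp = binom.logpmf(alts[:, None], depths[:, None], (i / n_haploids)[None, :])
    return logsumexp(lp[:, None, :] + np.log(spectra)[None, :, :], axis=2)


# ---------------------------------------------------------------------------
# decoding


def _log_transition(k: float) -> np.ndarray:
    stay = math.log1p(-2.0 * k)
    switch = math.log(k)
    T = np.full((3, 3), switch)
    np.fill_diagonal(T, stay)
    return T


@numba.njit(cache=False)
def _viterbi_kernel(logE: np.ndarray, logA: np.ndarray) -> np.ndarray:
    T = logE.shape[0]
    K = logE.shape[1]
    delta = logE[0] - np.log(K)
    back = np.empty((T, K), dtype=np.int8)
    work = np.empty(K)
    for t in range(1, T):
        for j in range(K):
            best, arg = delta[0] + logA[0, j], 0
            for i in range(1, K):
                v = delta[i] + logA[i, j]
                if v > best:
                    best, arg = v, i
            work[j] = best + logE[t, j]
            back[t, j] = arg
        delta = work.copy()
    path = np.empty(T, dtype=np.int8)
    path[-1] = np.argmax(delta)
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


@numba.njit(cache=False)
def _lse(v: np.ndarray) -> float:
    m = v.max()
    return m + np.log(np.sum(np.exp(v - m)))


@numba.njit(cache=False)
def _fb_kernel(logE: np.ndarray, logA: np.ndarray) -> np.ndarray:
    T = logE.shape[0]
    K = logE.shape[1]
    fwd = np.empty((T, K))
    fwd[0] = logE[0] - np.log(K)
    tmp = np.empty(K)
    for t in range(1, T):
        for j in range(K):
            for i in range(K):
                tmp[i] = fwd[t - 1, i] + logA[i, j]
            fwd[t, j] = logE[t, j] + _lse(tmp)
    bwd = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            for j in range(K):
                tmp[j] = logA[i, j] + logE[t + 1, j] + bwd[t + 1, j]
            bwd[t, i] = _lse(tmp)
    post = fwd + bwd
    for t in range(T):
        post[t] -= _lse(post[t])
    return np.exp(post)


def viterbi(log_emissions: np.ndarray, k_transition: float) -> np.ndarray:
    """Most probable state path under uniform initial probabilities."""
    if len(log_emissions) == 0:
        return np.empty(0, dtype=np.int8)
    return _viterbi_kernel(
        np.ascontiguousarray(log_emissions, dtype=np.float64),
        _log_transition(k_transition),
    )


def forward_backward(log_emissions: np.ndarray, k_transition: float) -> np.ndarray:
    """(T, 3) posterior state probabilities."""
    if len(log_emissions) == 0:
        return np.empty((0, 3))
    return _fb_kernel(
        np.ascontiguousarray(log_emissions, dtype=np.float64),
        _log_transition(k_transition),
    )


def decode(table: pd.DataFrame, params: HmmParams) -> DecodeResult:
    """Decode one line's sites (one chromosome, sorted by position)."""
    depths = (table["ref_count"] + table["alt_count"]).to_numpy()
    keep = (depths >= params.min_cov) & (depths <= params.max_cov)
    sub = table.loc[keep]
    pos = sub["pos"].to_numpy()
    if len(pos) == 0:
        return DecodeResult(pos, np.empty(0, dtype=np.int8), np.empty((0, 3)))
    if np.any(np.diff(pos) < 0):
        raise ValueError("sites must be sorted by position")
    spectra = state_spectra(params)
    logE = emission_matrix(
        depths[keep].astype(float),
        sub["alt_count"].to_numpy(dtype=float),
        spectra,
        params.n_haploids,
    )
    path = viterbi(logE, params.k_transition)
    post = forward_backward(logE, params.k_transition)
    return DecodeResult(pos, path, post)


# ---------------------------------------------------------------------------
# region calls and cross-line classification


def call_regions(
    result: DecodeResult,
    line_id: str,
    chrom: str,
    min_sites: int = 3,
) -> list[SweepRegion]:
    """Maximal runs of Viterbi Selection state, reported as
    [first site position, last site position]; runs shorter than
    ``min_sites`` are dropped.  Adjacent runs are never merged."""
    regions: list[SweepRegion] = []
    sel = result.states == SELECTION
    if not sel.any():
        return regions
    edges = np.flatnonzero(np.diff(np.concatenate([[0], sel.view(np.int8), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        n = int(i1 - i0)
        if n < min_sites:
            continue
        regions.append(
            SweepRegion(
                line_id=line_id,
                chrom=chrom,
                start=int(result.positions[i0]),
                end=int(result.positions[i1 - 1]),
                n_sites=n,
                mean_posterior=float(result.posteriors[i0:i1, SELECTION].mean()),
            )
        )
    return regions


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line_id": r.line_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_sites": r.n_sites,
                "mean_posterior": r.mean_posterior,
            }
            for r in regions
        ],
        columns=["line_id", "chrom", "start", "end", "n_sites", "mean_posterior"],
    )


def classify_regions(
    regions_by_line: dict[str, list[SweepRegion]],
    slopes: dict[str, str],
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Partition the genome by slope sharing of sweep calls.

    Classes: "all" (swept in every line), "NFS" (in every NFS line but not
    every SFS line), "SFS" (the converse), "none" otherwise.  The strict
    all-lines rule applies: a region missing from a single line of a slope
    does not count for that slope.
    """
    missing = [lid for lid in regions_by_line if lid not in slopes]
    if missing:
        raise ValueError(f"lines without slope label: {missing}")
    nfs_lines = [lid for lid, s in slopes.items() if s == NFS]
    sfs_lines = [lid for lid, s in slopes.items() if s == SFS]
    chroms = sorted(
        {r.chrom for regs in regions_by_line.values() for r in regs}
        | (set(chrom_lengths) if chrom_lengths else set())
    )
    rows = []
    for chrom in chroms:
        cuts = {1}
        if chrom_lengths and chrom in chrom_lengths:
            cuts.add(chrom_lengths[chrom] + 1)
        per_line = {}
        for lid, regs in regions_by_line.items():
            ivs = [(r.start, r.end) for r in regs if r.chrom == chrom]
            per_line[lid] = ivs
            for s, e in ivs:
                cuts.add(s)
                cuts.add(e + 1)
        cuts = sorted(cuts)
        for s, e_next in zip(cuts, cuts[1:]):
            e = e_next - 1
            covered = {
                lid
                for lid, ivs in per_line.items()
                if any(a <= s and e <= b for a, b in ivs)
            }
            all_nfs = bool(nfs_lines) and all(l in covered for l in nfs_lines)
            all_sfs = bool(sfs_lines) and all(l in covered for l in sfs_lines)
            if all_nfs and all_sfs:
                cls = "all"
            elif all_nfs:
                cls = NFS
            elif all_sfs:
                cls = SFS
            else:
                cls = "none"
            rows.append({"chrom": chrom, "start": s, "end": e, "class": cls})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    # merge adjacent same-class segments
    merged = []
    for row in df.itertuples(index=False):
        if (
            merged
            and merged[-1]["chrom"] == row.chrom
            and merged[-1]["class"] == row._3
            and merged[-1]["end"] + 1 == row.start
        ):
            merged[-1]["end"] = row.end
        else:
            merged.append(
                {"chrom": row.chrom, "start": row.start, "end": row.end, "class": row._3}
            )
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "class"])
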