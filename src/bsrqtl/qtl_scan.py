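"""Genome-wide single-marker LOD scan with permutation thresholds, 1.5-LOD
support intervals, PVE and additive effects, and common-region reduction.

The scan regresses the mapping phenotype (typically the per-line BLUP or a
replicate's affected frequency) on the genotype code {0,1,2} at each marker
and reports LOD = (n/2) log10(RSS0 / RSS1).  This marker regression stands
in for interval mapping: with dense bin markers, between-marker imputation
adds essentially nothing.  Genome-wide significance uses the standard
permutation approach — the phenotype vector is shuffled, preserving the
genotype correlation structure, and the (1 - alpha) quantile of the max-LOD
distribution is the threshold.

Sign conventions follow the biparental cross: with the wild parent coded 2,
the reported additive effect a = (mean of code-0 lines - mean of code-2
lines) / 2 is negative when the wild allele raises the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval

__all__ = [
    "QTLPeak",
    "lod_scan",
    "permutation_threshold",
    "call_qtls",
    "common_region",
]

#: LOD ceiling used when a marker fits the phenotype exactly (RSS1 = 0).
LOD_CAP = 50.0


@dataclass(frozen=True)
class QTLPeak:
    """A called QTL: peak marker, LOD, PVE, additive effect and support."""

    marker: str
    chrom: str
    cm: float
    bp: int
    lod: float
    pve: float
    additive_effect: float
    interval: GenomicInterval
    cm_lo: float
    cm_hi: float


def _marker_stats(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (n_used, Sxx, RSS0, RSS1) for one or more phenotype columns.

    ``X`` is (n_lines, n_markers) with NaN for missing genotypes, ``Y`` is
    (n_lines, n_pheno).  Missing phenotype entries are dropped together with
    missing genotypes, marker-wise.
    """
    valid = ~np.isnan(X)
    y_ok = ~np.isnan(Y)
    Xv = np.where(valid, X, 0.0)
    # per-marker, per-phenotype counts and sums over jointly valid rows
    n = valid.T.astype(float) @ y_ok.astype(float)  # (m, p)
    Yz = np.where(y_ok, Y, 0.0)
    sy = valid.T.astype(float) @ Yz  # (m, p)
    syy = valid.T.astype(float) @ (Yz ** 2)
    sx = Xv.T @ y_ok.astype(float)
    sxx = (Xv ** 2).T @ y_ok.astype(float)
    sxy = Xv.T @ Yz
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx = sxx - sx ** 2 / n
        Sxy = sxy - sx * sy / n
        Syy = syy - sy ** 2 / n
    return n, Sxx, Syy, Sxy


def _lod_from_stats(
    n: np.ndarray, Sxx: np.ndarray, Syy: np.ndarray, Sxy: np.ndarray,
    cap: float,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD matrix and monomorphic flags from per-marker regression sums."""
    mono = Sxx <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = Syy - np.where(mono, 0.0, Sxy ** 2 / np.where(mono, 1.0, Sxx))
        ratio = np.where(rss1 > 0, Syy / np.where(rss1 > 0, rss1, 1.0), np.inf)
        lod = (n / 2.0) * np.log10(ratio)
    lod = np.where(mono | (Syy <= 0), 0.0, lod)
    # an exact fit (RSS1 = 0) would give an infinite LOD; replace by the cap
    lod = np.where(np.isfinite(lod), lod, cap)
    return lod, mono


def lod_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    map_df: pd.DataFrame,
    cap: float = LOD_CAP,
) -> pd.DataFrame:
    """Single-marker regression LOD scan.

    Returns a scan track: a DataFrame with columns ``marker, chrom, cm, bp,
    lod, monomorphic`` in map order.  Monomorphic markers get LOD 0 and a
    flag; an exact fit (RSS1 = 0) is capped at ``cap``.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 lines")
    y = phenotype.reindex(genotypes.index).to_numpy(dtype=float)[:, None]
    if np.isnan(y).all():
        raise ValueError("phenotype has no values for the genotyped lines")
    markers = map_df["marker"].tolist()
    X = genotypes[markers].to_numpy(dtype=float)
    n, Sxx, Syy, Sxy = _marker_stats(X, y)
    lod, mono = _lod_from_stats(n, Sxx, Syy, Sxy, cap)
    track = map_df[["marker", "chrom", "cm", "bp"]].copy()
    track["lod"] = lod[:, 0]
    track["monomorphic"] = mono[:, 0]
    return track


def permutation_threshold(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    map_df: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    cap: float = LOD_CAP,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Shuffles the phenotype vector ``n_perm`` times, records the maximum LOD
    of each permuted scan, and returns the (1 - alpha) quantile of that
    max-LOD distribution.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = phenotype.reindex(genotypes.index).to_numpy(dtype=float)
    markers = map_df["marker"].tolist()
    X = genotypes[markers].to_numpy(dtype=float)
    maxlod = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(1, X.shape[1])))
    for lo in range(0, n_perm, chunk):
        hi = min(n_perm, lo + chunk)
        Y = np.empty((len(y), hi - lo))
        for j in range(hi - lo):
            Y[:, j] = rng.permutation(y)
        n, Sxx, Syy, Sxy = _marker_stats(X, Y)
        lod, _ = _lod_from_stats(n, Sxx, Syy, Sxy, cap)
        maxlod[lo:hi] = lod.max(axis=0)
    return float(np.quantile(maxlod, 1.0 - alpha))


def call_qtls(
    track: pd.DataFrame,
    threshold: float,
    genotypes: pd.DataFrame | None = None,
    phenotype: pd.Series | None = None,
    drop: float = 1.5,
) -> list[QTLPeak]:
    """Call QTL peaks above a genome-wide threshold with LOD-drop support.

    Per chromosome, peaks are extracted greedily from the highest remaining
    above-threshold marker (leftmost marker of a plateau wins ties).  The
    support interval runs over the contiguous markers with LOD >= peak -
    ``drop``; any other above-threshold marker whose connecting valley stays
    within ``drop`` of its own LOD is merged into the same QTL rather than
    called separately.  Physical bounds are rounded outward by one flanking
    marker.  PVE = 100 (1 - 10^(-2 LOD / n)); the additive effect (computed
    when genotypes/phenotype are supplied) is (mean code-0 - mean code-2)/2
    at the peak marker.
    """
    peaks: list[QTLPeak] = []
    n_lines = len(genotypes) if genotypes is not None else None
    for chrom, sub in track.groupby("chrom", sort=False):
        lod = sub["lod"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        bp = sub["bp"].to_numpy(dtype=np.int64)
        names = sub["marker"].tolist()
        m = len(lod)
        free = lod > threshold
        while free.any():
            i = int(np.argmax(np.where(free, lod, -np.inf)))
            peak_lod = lod[i]
            lo = i
            while lo > 0 and lod[lo - 1] >= peak_lod - drop:
                lo -= 1
            hi = i
            while hi < m - 1 and lod[hi + 1] >= peak_lod - drop:
                hi += 1
            # absorb secondary peaks whose valley to this peak is shallow
            changed = True
            while changed:
                changed = False
                for j in np.flatnonzero(free):
                    if lo <= j <= hi:
                        continue
                    a, b = (j, lo) if j < lo else (hi, j)
                    valley = lod[a:b + 1].min()
                    if valley >= lod[j] - drop:
                        jlo = j
                        while jlo > 0 and lod[jlo - 1] >= lod[j] - drop:
                            jlo -= 1
                        jhi = j
                        while jhi < m - 1 and lod[jhi + 1] >= lod[j] - drop:
                            jhi += 1
                        lo, hi = min(lo, jlo), max(hi, jhi)
                        changed = True
            free[lo:hi + 1] = False

            if n_lines is not None:
                n_used = int(
                    (~genotypes[names[i]].isna()
                     & ~phenotype.reindex(genotypes.index).isna()).sum()
                )
            else:
                n_used = 0
            pve = (
                100.0 * (1.0 - 10.0 ** (-2.0 * peak_lod / n_used))
                if n_used
                else float("nan")
            )
            effect = float("nan")
            if genotypes is not None and phenotype is not None:
                g = genotypes[names[i]]
                y = phenotype.reindex(genotypes.index)
                m0 = y[g == 0].mean()
                m2 = y[g == 2].mean()
                effect = (m0 - m2) / 2.0
            bp_lo = int(bp[max(lo - 1, 0)])
            bp_hi = int(bp[min(hi + 1, m - 1)])
            peaks.append(
                QTLPeak(
                    marker=names[i],
                    chrom=chrom,
                    cm=float(cm[i]),
                    bp=int(bp[i]),
                    lod=float(peak_lod),
                    pve=float(pve),
                    additive_effect=float(effect),
                    interval=GenomicInterval(chrom, bp_lo, bp_hi),
                    cm_lo=float(cm[lo]),
                    cm_hi=float(cm[hi]),
                )
            )
    peaks.sort(key=lambda p: -p.lod)
    return peaks


def common_region(intervals: list[GenomicInterval]) -> GenomicInterval:
    """Common region of replicate QTL intervals: [max starts, min ends].

    All intervals must lie on one chromosome and pairwise overlap; disjoint
    inputs raise ``ValueError`` (the caller decides whether such a QTL is
    replicate-consistent at all).
    """
    if not intervals:
        raise ValueError("no intervals given")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start > end:
        raise ValueError("intervals are disjoint; no common region")
    return GenomicInterval(intervals[0].chrom, start, end)
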