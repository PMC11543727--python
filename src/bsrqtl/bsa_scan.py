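"""Bulked-segregant ΔSNP-index scan.

Stages, in pipeline order:

1. :func:`snp_index` — per-SNP index = alt / (alt + ref) in each bulk.
2. :func:`filter_snps` — drop SNPs with total depth < 3 in either bulk, and
   SNPs whose index is < 0.3 in *both* bulks (uninformative sites).
3. :func:`delta_index` — ΔSNP index = index(TRI) - index(MUL).
4. :func:`window_scan` — mean Δ in 1-Mbp windows advanced by 10-kbp steps;
   windows with fewer than 10 SNPs are skipped.  The window grid is anchored
   at position 1 of each chromosome.
5. :func:`permutation_cutoff` — two-sided 99% cutoffs for the window means
   from a simulated null.
6. :func:`call_regions` — merge consecutive windows beyond a cutoff into
   significant regions, separately per direction.

Null models for the cutoff
--------------------------
``"bulk"`` (default) simulates the full null of *unselected* bulks: for each
bulk, member-line haplotypes are drawn as Markov chains along the observed
SNP positions (selfing-RIL effective recombination from Haldane's map
function, using a cM/Mb scale), the bulk allele frequency is their mean, and
reads are binomially resampled at the observed depths.  This null carries
both the drift of a finite bulk (±1/sqrt(4k) per bulk around 0.5) and its
linkage-induced correlation along a window, which dominate the window-mean
null distribution at realistic bulk sizes; resampling reads alone
(``"binomial"``, alt ~ Binomial(depth, 0.5) per SNP independently) ignores
bulk composition and is anti-conservative for window means.  The binomial
null is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval
from .synthetic_data import haldane_r, ril_effective_recombination

__all__ = [
    "PermutationCutoff",
    "SignificantRegion",
    "snp_index",
    "filter_snps",
    "delta_index",
    "window_scan",
    "permutation_cutoff",
    "call_regions",
]

WINDOW_BP = 1_000_000
STEP_BP = 10_000
MIN_SNPS = 10


@dataclass(frozen=True)
class PermutationCutoff:
    """Two-sided window-mean cutoffs at a given null quantile."""

    lower: float
    upper: float
    quantile: float
    n_iter: int
    null_model: str


@dataclass(frozen=True)
class SignificantRegion:
    """A run of windows beyond the cutoff, merged into one interval.

    ``direction`` is ``"tri"`` for Δ > 0 (TRI-bulk alt enrichment) and
    ``"mul"`` for Δ < 0.
    """

    interval: GenomicInterval
    direction: str
    peak_mean: float
    cutoff: float


def snp_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute per-bulk depths and SNP indices from a bulk allele-count table.

    Adds ``depth_mul, depth_tri, index_mul, index_tri``; a zero-depth site
    gets an undefined (NaN) index and is removed downstream by the depth
    filter.
    """
    track = counts.copy()
    for bulk in ("mul", "tri"):
        depth = track[f"{bulk}_ref"] + track[f"{bulk}_alt"]
        track[f"depth_{bulk}"] = depth
        with np.errstate(invalid="ignore", divide="ignore"):
            track[f"index_{bulk}"] = np.where(
                depth > 0, track[f"{bulk}_alt"] / depth, np.nan
            )
    return track


def filter_snps(
    track: pd.DataFrame, min_depth: int = 3, min_index: float = 0.3
) -> pd.DataFrame:
    """Apply the depth and index filters.

    Keeps SNPs with total (ref+alt) depth >= ``min_depth`` in *each* bulk and
    with a SNP index >= ``min_index`` in at least one bulk (a site below the
    index floor in both bulks is excluded).  Removal counts per rule are
    stored in ``attrs["n_removed_depth"]`` / ``attrs["n_removed_index"]``.
    Idempotent.
    """
    depth_ok = (track["depth_mul"] >= min_depth) & (track["depth_tri"] >= min_depth)
    index_ok = (track["index_mul"] >= min_index) | (track["index_tri"] >= min_index)
    kept = track[depth_ok & index_ok].reset_index(drop=True)
    kept.attrs["n_removed_depth"] = int((~depth_ok).sum())
    kept.attrs["n_removed_index"] = int((depth_ok & ~index_ok).sum())
    return kept


def delta_index(track: pd.DataFrame) -> pd.DataFrame:
    """ΔSNP index = index(TRI) - index(MUL), appended as column ``delta``."""
    out = track.copy()
    out["delta"] = out["index_tri"] - out["index_mul"]
    return out


def _window_grid(
    pos: np.ndarray, window: int, step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Candidate windows [s, s+window-1] with s = 1, 1+step, ... and the
    index range [i0, i1) of sorted positions each window contains."""
    starts = np.arange(1, int(pos.max()) + 1, step, dtype=np.int64)
    ends = starts + window - 1
    i0 = np.searchsorted(pos, starts, side="left")
    i1 = np.searchsorted(pos, ends, side="right")
    return starts, ends, i0, i1


def window_scan(
    track: pd.DataFrame,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    min_snps: int = MIN_SNPS,
) -> pd.DataFrame:
    """Sliding-window mean of the ΔSNP index.

    Returns a DataFrame with ``chrom, start, end, n_snps, mean_delta`` for
    every window on the step grid holding at least ``min_snps`` SNPs.
    """
    frames = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        delta = sub["delta"].to_numpy(dtype=float)
        starts, ends, i0, i1 = _window_grid(pos, window, step)
        n = i1 - i0
        keep = n >= min_snps
        if not keep.any():
            continue
        # per-window np.mean keeps summation order identical to a direct
        # computation over the member SNPs (exact, not cumsum-differenced)
        means = np.array(
            [np.mean(delta[a:b]) for a, b in zip(i0[keep], i1[keep])]
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": ends[keep],
                    "n_snps": n[keep],
                    "mean_delta": means,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "mean_delta"]
        )
    return pd.concat(frames, ignore_index=True)


def permutation_cutoff(
    track: pd.DataFrame,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    min_snps: int = MIN_SNPS,
    n_iter: int = 100_000,
    quantile: float = 0.99,
    seed: int | None = None,
    null_model: str = "bulk",
    bulk_size: int = 30,
    cm_per_mb: float = 5.0,
    chunk: int = 200,
) -> PermutationCutoff:
    """Two-sided window-mean cutoffs from a simulated null.

    For each iteration a null Δ value is generated at every retained SNP and
    the window means are recomputed over the same windows (same SNP
    membership as the observed scan); the cutoff is the ``quantile`` of the
    pooled |null window mean| distribution, reported as ±cutoff.

    ``null_model="bulk"`` resamples both bulk composition (``bulk_size``
    member haplotypes as linked Markov chains, using ``cm_per_mb`` to convert
    physical gaps to map distance) and reads at the observed depths;
    ``"binomial"`` resamples reads only, alt ~ Binomial(depth, 0.5) per SNP.
    Deterministic for a fixed seed.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    if null_model not in ("bulk", "binomial"):
        raise ValueError(f"unknown null_model {null_model!r}")
    rng = np.random.default_rng(seed)
    abs_means: list[np.ndarray] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        d_mul = sub["depth_mul"].to_numpy(dtype=np.int64)
        d_tri = sub["depth_tri"].to_numpy(dtype=np.int64)
        _, _, i0, i1 = _window_grid(pos, window, step)
        n = i1 - i0
        keep = n >= min_snps
        if not keep.any():
            continue
        i0k, i1k, nk = i0[keep], i1[keep], n[keep]
        if null_model == "bulk":
            d_cm = np.diff(pos) * (cm_per_mb / 1e6)
            r_star = ril_effective_recombination(haldane_r(d_cm))
        for lo in range(0, n_iter, chunk):
            c = min(chunk, n_iter - lo)
            if null_model == "binomial":
                f_mul = rng.binomial(d_mul, 0.5, size=(c, len(pos))) / d_mul
                f_tri = rng.binomial(d_tri, 0.5, size=(c, len(pos))) / d_tri
            else:
                f_mul = _null_bulk_freq(rng, c, bulk_size, r_star, d_mul)
                f_tri = _null_bulk_freq(rng, c, bulk_size, r_star, d_tri)
            delta = f_tri - f_mul
            csum = np.concatenate(
                [np.zeros((c, 1)), np.cumsum(delta, axis=1)], axis=1
            )
            means = (csum[:, i1k] - csum[:, i0k]) / nk
            abs_means.append(np.abs(means.astype(np.float32)).ravel())
    if not abs_means:
        raise ValueError("no windows hold >= min_snps SNPs; cannot calibrate")
    cutoff = float(np.quantile(np.concatenate(abs_means), quantile))
    return PermutationCutoff(
        lower=-cutoff,
        upper=cutoff,
        quantile=quantile,
        n_iter=n_iter,
        null_model=null_model,
    )


def _null_bulk_freq(
    rng: np.random.Generator,
    n_iter: int,
    bulk_size: int,
    r_star: np.ndarray,
    depth: np.ndarray,
) -> np.ndarray:
    """Null read-level alt frequencies for one bulk: linked haplotype chains
    per member line, then binomial read sampling at the observed depths."""
    m = len(depth)
    state = np.empty((n_iter, bulk_size, m), dtype=np.uint8)
    state[:, :, 0] = rng.random((n_iter, bulk_size)) < 0.5
    if m > 1:
        state[:, :, 1:] = rng.random((n_iter, bulk_size, m - 1)) < r_star
        np.bitwise_xor.accumulate(state, axis=2, out=state)
    f = state.mean(axis=1)
    alt = rng.binomial(np.broadcast_to(depth, f.shape), f)
    return alt / depth


def call_regions(
    windows: pd.DataFrame, cutoff: PermutationCutoff
) -> list[SignificantRegion]:
    """Merge windows beyond the cutoff into significant regions.

    Windows exceeding the upper cutoff (or falling below the lower one) are
    merged per chromosome and direction whenever their intervals overlap or
    abut; the region interval is the union of its member windows and the
    reported peak mean is the member mean of largest magnitude.
    """
    regions: list[SignificantRegion] = []
    for direction, mask in (
        ("tri", windows["mean_delta"] > cutoff.upper),
        ("mul", windows["mean_delta"] < cutoff.lower),
    ):
        hits = windows[mask]
        for chrom, sub in hits.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            cur_start = cur_end = None
            cur_peak = 0.0
            for row in sub.itertuples(index=False):
                if cur_start is None:
                    cur_start, cur_end, cur_peak = row.start, row.end, row.mean_delta
                elif row.start <= cur_end + 1:
                    cur_end = max(cur_end, row.end)
                    if abs(row.mean_delta) > abs(cur_peak):
                        cur_peak = row.mean_delta
                else:
                    regions.append(
                        SignificantRegion(
                            GenomicInterval(chrom, int(cur_start), int(cur_end)),
                            direction,
                            float(cur_peak),
                            cutoff.upper if direction == "tri" else cutoff.lower,
                        )
                    )
                    cur_start, cur_end, cur_peak = row.start, row.end, row.mean_delta
            if cur_start is not None:
                regions.append(
                    SignificantRegion(
                        GenomicInterval(chrom, int(cur_start), int(cur_end)),
                        direction,
                        float(cur_peak),
                        cutoff.upper if direction == "tri" else cutoff.lower,
                    )
                )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.direction))
    return regions
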