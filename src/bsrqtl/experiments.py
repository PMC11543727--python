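"""End-to-end simulation studies: calibration and recovery experiments.

Each function runs the full pipeline on synthetic data generated under the
emulated study design and returns summary statistics.  They are used both by
the test suite and by ``scripts/acceptance.py``; all randomness derives from
an explicit seed.

Problem sizes
-------------
The experiments run at desk scale: genomes of 2–25 hundred SNPs, permutation
counts of 1000–2000 (the publication-scale ΔSNP cutoff uses 100,000
iterations; 2000 is the test profile, which changes the cutoff estimate's
Monte-Carlo error, not its meaning), and 10–20 replicate seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bsa_scan, phenotype_stats, qtl_scan, synthetic_data

__all__ = [
    "heritability_recovery",
    "lod_threshold_calibration",
    "bsa_null_calibration",
    "locus_recovery",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def heritability_recovery(
    n_lines: int = 500,
    n_env: int = 3,
    n_rep: int = 2,
    v_g: float = 4.0,
    v_ge: float = 1.0,
    v_eps: float = 1.0,
    n_seeds: int = 20,
    seed: int = 0,
) -> dict:
    """Recover H² from balanced Gaussian data with known components.

    Generates y_ijk = g_i + ge_ij + eps_ijk for ``n_lines`` lines ×
    ``n_env`` environments × ``n_rep`` replications, estimates the variance
    components by expected mean squares and evaluates the H² formula.
    Returns the true H², the mean estimated H² over seeds, and the mean
    absolute error.
    """
    true_vc = phenotype_stats.VarianceComponents(
        v_g=v_g, v_ge=v_ge, v_eps=v_eps, r=n_rep, l=n_env
    )
    h2_true = phenotype_stats.heritability(true_vc)
    estimates = []
    for s in _spawn_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        g = rng.normal(0, np.sqrt(v_g), n_lines)
        ge = rng.normal(0, np.sqrt(v_ge), (n_lines, n_env))
        eps = rng.normal(0, np.sqrt(v_eps), (n_lines, n_env, n_rep))
        y = g[:, None, None] + ge[:, :, None] + eps
        long = pd.DataFrame(
            {
                "line": np.repeat(np.arange(n_lines), n_env * n_rep),
                "env": np.tile(np.repeat(np.arange(n_env), n_rep), n_lines),
                "value": y.ravel(),
            }
        )
        vc = phenotype_stats.anova_variance_components(long)
        estimates.append(phenotype_stats.heritability(vc))
    estimates = np.asarray(estimates)
    return {
        "h2_true": float(h2_true),
        "h2_mean_estimate": float(estimates.mean()),
        "mean_abs_error": float(np.abs(estimates - h2_true).mean()),
        "n_seeds": n_seeds,
    }


def lod_threshold_calibration(
    n_lines: int = 200,
    n_chrom: int = 5,
    markers_per_chrom: int = 40,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_null_scans: int = 200,
    seed: int = 0,
) -> dict:
    """Genome-wide false-positive rate of the permutation LOD threshold.

    Draws one null dataset (RIL genotypes, N(0,1) phenotype), computes the
    1000-permutation threshold at ``alpha``, then applies it to
    ``n_null_scans`` fresh null phenotypes on the same genotypes.  Returns
    the observed rate of scans whose maximum LOD exceeds the threshold.
    """
    s_map, s_geno, s_pheno, s_perm, s_fresh = _spawn_seeds(seed, 5)
    map_df = synthetic_data.simulate_map(
        n_chrom=n_chrom, chrom_length_cm=100.0,
        markers_per_chrom=markers_per_chrom, bp_per_cm=300_000.0, seed=s_map,
    )
    geno = synthetic_data.simulate_ril_genotypes(
        map_df, n_lines=n_lines, residual_het=0.01, seed=s_geno
    )
    rng = np.random.default_rng(s_pheno)
    pheno = pd.Series(rng.normal(size=n_lines), index=geno.index)
    threshold = qtl_scan.permutation_threshold(
        geno, pheno, map_df, n_perm=n_perm, alpha=alpha, seed=s_perm
    )
    rng_fresh = np.random.default_rng(s_fresh)
    X = geno[map_df["marker"].tolist()].to_numpy(dtype=float)
    Y = rng_fresh.normal(size=(n_lines, n_null_scans))
    n, sxx, syy, sxy = qtl_scan._marker_stats(X, Y)
    lod, _ = qtl_scan._lod_from_stats(n, sxx, syy, sxy, qtl_scan.LOD_CAP)
    fpr = float((lod.max(axis=0) > threshold).mean())
    return {
        "threshold": float(threshold),
        "false_positive_rate": fpr,
        "n_null_scans": n_null_scans,
        "alpha": alpha,
    }


def _bsa_pipeline(
    geno: pd.DataFrame,
    pheno: pd.DataFrame,
    map_df: pd.DataFrame,
    bp_per_cm: float,
    bulk_k: int = 30,
    mean_depth: float = 30.0,
    n_iter: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, bsa_scan.PermutationCutoff, list]:
    """Select bulks, simulate pooled reads and run the full ΔSNP scan."""
    s_reads, s_perm = _spawn_seeds(seed, 2)
    bulks = synthetic_data.select_bulks(pheno, k=bulk_k)
    counts = synthetic_data.simulate_bulk_reads(
        geno, bulks, map_df, mean_depth=mean_depth, error_rate=0.001,
        seed=s_reads,
    )
    track = bsa_scan.delta_index(bsa_scan.filter_snps(bsa_scan.snp_index(counts)))
    windows = bsa_scan.window_scan(track)
    cutoff = bsa_scan.permutation_cutoff(
        track,
        n_iter=n_iter,
        seed=s_perm,
        null_model="bulk",
        bulk_size=bulk_k,
        cm_per_mb=1e6 / bp_per_cm,
    )
    regions = bsa_scan.call_regions(windows, cutoff)
    return windows, cutoff, regions


def bsa_null_calibration(
    n_seeds: int = 10,
    n_lines: int = 400,
    n_chrom: int = 2,
    markers_per_chrom: int = 1000,
    bulk_k: int = 30,
    mean_depth: float = 30.0,
    n_iter: int = 2000,
    seed: int = 0,
) -> dict:
    """Fraction of windows beyond the 99% cutoff with no trait signal.

    The phenotype carries zero genetic effect, so the extreme bulks are
    effectively random subsets; a calibrated cutoff should leave about 1%
    (and no more than a few percent) of retained windows beyond it.
    Returns the exceedance fraction averaged over seeds.
    """
    bp_per_cm = 200_000.0
    rates = []
    for s in _spawn_seeds(seed, n_seeds):
        s_map, s_geno, s_pheno, s_bsa = _spawn_seeds(s, 4)
        map_df = synthetic_data.simulate_map(
            n_chrom=n_chrom, chrom_length_cm=100.0,
            markers_per_chrom=markers_per_chrom, bp_per_cm=bp_per_cm,
            seed=s_map,
        )
        geno = synthetic_data.simulate_ril_genotypes(
            map_df, n_lines=n_lines, residual_het=0.01, seed=s_geno
        )
        model = synthetic_data.QTLModel(effects={})
        pheno = synthetic_data.simulate_phenotypes(
            geno, model,
            replicate_design=(("rep1", 10), ("rep2", 10), ("rep3", 10)),
            seed=s_pheno,
        )
        windows, cutoff, _ = _bsa_pipeline(
            geno, pheno, map_df, bp_per_cm,
            bulk_k=bulk_k, mean_depth=mean_depth, n_iter=n_iter, seed=s_bsa,
        )
        beyond = (
            (windows["mean_delta"] > cutoff.upper)
            | (windows["mean_delta"] < cutoff.lower)
        )
        rates.append(float(beyond.mean()))
    return {
        "mean_exceedance": float(np.mean(rates)),
        "per_seed": [float(r) for r in rates],
        "n_seeds": n_seeds,
    }


def locus_recovery(
    n_seeds: int = 20,
    effect: float = 1.0,
    n_lines: int = 400,
    n_chrom: int = 10,
    markers_per_chrom: int = 251,
    bulk_k: int = 30,
    mean_depth: float = 30.0,
    n_iter: int = 2000,
    cm_tolerance: float = 5.0,
    seed: int = 0,
) -> dict:
    """Recovery of a single planted QTL by both arms of the pipeline.

    Plants one QTL (additive liability effect ``effect``) at the middle
    marker of the middle chromosome, phenotypes 3 replicates of 10 seedlings,
    and measures over seeds: (a) how often a significant BSA region contains
    the true locus position, and (b) how often the genome-wide LOD-scan peak
    lies within ``cm_tolerance`` cM of the true marker.
    """
    bp_per_cm = 200_000.0
    bsa_hits = 0
    lod_hits = 0
    for s in _spawn_seeds(seed, n_seeds):
        s_map, s_geno, s_pheno, s_bsa = _spawn_seeds(s, 4)
        map_df = synthetic_data.simulate_map(
            n_chrom=n_chrom, chrom_length_cm=100.0,
            markers_per_chrom=markers_per_chrom, bp_per_cm=bp_per_cm,
            seed=s_map,
        )
        qtl_chrom = f"Gm{(n_chrom + 1) // 2:02d}"
        sub = map_df[map_df["chrom"] == qtl_chrom].reset_index(drop=True)
        qtl_row = sub.iloc[len(sub) // 2]
        geno = synthetic_data.simulate_ril_genotypes(
            map_df, n_lines=n_lines, residual_het=0.01, seed=s_geno
        )
        model = synthetic_data.QTLModel(effects={qtl_row["marker"]: effect})
        pheno = synthetic_data.simulate_phenotypes(
            geno, model,
            replicate_design=(("rep1", 10), ("rep2", 10), ("rep3", 10)),
            seed=s_pheno,
        )
        # linkage arm: BLUP phenotype, peak position of the scan
        blup = phenotype_stats.blup(pheno)
        track = qtl_scan.lod_scan(geno, blup, map_df)
        peak = track.loc[track["lod"].idxmax()]
        if peak["chrom"] == qtl_chrom and abs(peak["cm"] - qtl_row["cm"]) <= cm_tolerance:
            lod_hits += 1
        # BSA arm: significant region containing the true position
        _, _, regions = _bsa_pipeline(
            geno, pheno, map_df, bp_per_cm,
            bulk_k=bulk_k, mean_depth=mean_depth, n_iter=n_iter, seed=s_bsa,
        )
        if any(
            r.interval.contains(qtl_chrom, int(qtl_row["bp"])) for r in regions
        ):
            bsa_hits += 1
    return {
        "bsa_recovery_rate": bsa_hits / n_seeds,
        "lod_peak_recovery_rate": lod_hits / n_seeds,
        "n_seeds": n_seeds,
        "effect": effect,
    }
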