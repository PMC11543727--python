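"""Synthetic study generator: RIL genotypes, sporadic seedling-count
phenotypes with planted QTLs, extreme bulks, and pooled allele depths.

The defaults emulate the study design this pipeline targets: an interspecific
soybean RIL population (cultivar C08 × wild W05) of ~407 F7:8 lines genotyped
at ~6400 bin markers, a sporadically expressed multifoliolate-leaf trait
scored as affected-seedling counts over three replicates of 5/10/20 seedlings
per line, 30-line extreme bulks, and pooled short-read allele depths.

Model
-----
* Genotypes: each line is a two-state Markov chain along each chromosome with
  effective recombination R* = 2r/(1+2r) between adjacent markers (the
  standard selfing-RIL correction), where r comes from Haldane's map function
  on the cM gap.  Codes: 0 = C08 homozygote, 2 = W05 homozygote, 1 = residual
  heterozygote injected at a small rate.
* Phenotypes: a liability-scale logistic model.  Per line i and replicate j
  the liability is eta_ij = mu + sum_k a_k (x_ik - 1) + rep_j + gamma_ij +
  eps_ij with gamma ~ N(0, sigma_ge^2) and eps ~ N(0, sigma_eps^2); the
  affected count is Binomial(n_seedlings, logistic(eta_ij)).  With W05 coded
  2, a positive additive effect a means the wild allele raises the trait.
* Bulk reads: at each marker the bulk's true alt (W05) allele frequency is
  the mean genotype code / 2 over member lines; total depth is Poisson and
  alt reads Binomial with a symmetric sequencing error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "QTLModel",
    "default_study_model",
    "simulate_map",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "select_bulks",
    "simulate_bulk_reads",
    "haldane_r",
    "ril_effective_recombination",
    "DEFAULT_REPLICATE_DESIGN",
]

#: Replicate design of the emulated study: three seasons with 5, 10 and 20
#: seedlings scored per line.
DEFAULT_REPLICATE_DESIGN: tuple[tuple[str, int], ...] = (
    ("rep1", 5),
    ("rep2", 10),
    ("rep3", 20),
)


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from a map distance (cM), Haldane's function."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


def ril_effective_recombination(r: np.ndarray | float) -> np.ndarray | float:
    """Effective recombination R* = 2r/(1+2r) between selfing-RIL genotypes."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_map(
    n_chrom: int = 20,
    chrom_length_cm: float = 150.0,
    markers_per_chrom: int = 320,
    bp_per_cm: float = 300_000.0,
    spacing: str = "even",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a genetic/physical map.

    Returns a DataFrame with columns ``marker, chrom, cm, bp``; chromosomes
    are named ``Gm01..GmNN``. ``spacing`` is ``"even"`` (grid including both
    chromosome ends) or ``"uniform"`` (sorted uniform draws).
    """
    if n_chrom < 1 or markers_per_chrom < 2:
        raise ValueError("need >=1 chromosome and >=2 markers per chromosome")
    if chrom_length_cm <= 0 or bp_per_cm <= 0:
        raise ValueError("chromosome length and bp_per_cm must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chrom + 1):
        chrom = f"Gm{c:02d}"
        if spacing == "even":
            cm = np.linspace(0.0, chrom_length_cm, markers_per_chrom)
        elif spacing == "uniform":
            cm = np.sort(rng.uniform(0.0, chrom_length_cm, markers_per_chrom))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        bp = np.round(cm * bp_per_cm).astype(np.int64) + 1
        # physical positions must be strictly increasing for VCF output
        for i in range(1, len(bp)):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"{chrom}_m{i:04d}" for i in range(markers_per_chrom)],
                    "chrom": chrom,
                    "cm": cm,
                    "bp": bp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ril_genotypes(
    map_df: pd.DataFrame,
    n_lines: int = 407,
    residual_het: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate RIL genotypes (line × marker codes 0/1/2) along a map.

    Transmission is a Markov chain per chromosome with switch probability
    R* = 2r/(1+2r), r from Haldane's function on the cM gap. Heterozygous
    calls (code 1) are injected independently at rate ``residual_het``
    (default 0.01, about the F7 expectation).
    """
    if not 0.0 <= residual_het <= 0.05:
        raise ValueError("residual_het must be in [0, 0.05]")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    markers: list[str] = []
    for chrom, sub in map_df.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        m = len(cm)
        r_star = ril_effective_recombination(haldane_r(np.diff(cm)))
        state = np.empty((n_lines, m), dtype=np.uint8)
        state[:, 0] = rng.random(n_lines) < 0.5
        if m > 1:
            switches = rng.random((n_lines, m - 1)) < r_star[None, :]
            state[:, 1:] = switches
            np.bitwise_xor.accumulate(state, axis=1, out=state)
        blocks.append(state.astype(np.int8) * 2)
        markers.extend(sub["marker"].tolist())
    geno = np.concatenate(blocks, axis=1)
    if residual_het > 0:
        het = rng.random(geno.shape) < residual_het
        geno[het] = 1
    line_ids = [f"RIL{i:04d}" for i in range(1, n_lines + 1)]
    return pd.DataFrame(geno, index=pd.Index(line_ids, name="line"), columns=markers)


@dataclass
class QTLModel:
    """Liability-scale model for a sporadic (incompletely penetrant) trait.

    ``effects`` maps marker names to additive effects a on the liability
    scale; a genotype coded x in {0,1,2} contributes a*(x-1), so positive a
    ties trait expression to the parent coded 2 (W05). ``mu`` is the baseline
    liability (logit of the baseline per-seedling probability);
    ``replicate_effects`` shift the liability per replicate; ``sigma_ge`` and
    ``sigma_eps`` are the line-by-replicate interaction and residual SDs.
    """

    effects: Mapping[str, float] = field(default_factory=dict)
    mu: float = float(logit(0.2))
    replicate_effects: Mapping[str, float] = field(default_factory=dict)
    sigma_ge: float = 0.5
    sigma_eps: float = 0.5


def default_study_model(map_df: pd.DataFrame) -> QTLModel:
    """Several planted QTLs of unequal effect, spread over the genome.

    Effects span ~0.3–1.2 liability units, echoing a trait governed by one
    major and several minor loci; markers are taken near the middle of
    successive chromosomes.
    """
    chroms = list(dict.fromkeys(map_df["chrom"]))
    sizes = (1.2, 0.8, 0.6, 0.45, 0.3)
    effects: dict[str, float] = {}
    for a, chrom in zip(sizes, chroms[:: max(1, len(chroms) // len(sizes))]):
        sub = map_df[map_df["chrom"] == chrom]
        effects[sub["marker"].iloc[len(sub) // 2]] = a
    return QTLModel(
        effects=effects,
        replicate_effects={"rep1": 0.25, "rep2": 0.0, "rep3": -0.25},
    )


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    qtl_model: QTLModel,
    replicate_design: Sequence[tuple[str, int]] = DEFAULT_REPLICATE_DESIGN,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate affected-seedling counts per line × replicate.

    Returns a long DataFrame with columns ``line, replicate, affected,
    n_seedlings``.
    """
    rng = np.random.default_rng(seed)
    n = len(genotypes)
    missing = [m for m in qtl_model.effects if m not in genotypes.columns]
    if missing:
        raise KeyError(f"QTL markers not in genotype matrix: {missing}")
    genetic = np.zeros(n)
    for marker, a in qtl_model.effects.items():
        genetic += a * (genotypes[marker].to_numpy(dtype=float) - 1.0)
    rows = []
    for rep_name, n_seedlings in replicate_design:
        if n_seedlings < 1:
            raise ValueError(f"replicate {rep_name}: n_seedlings must be >= 1")
        rep_eff = float(qtl_model.replicate_effects.get(rep_name, 0.0))
        eta = (
            qtl_model.mu
            + genetic
            + rep_eff
            + rng.normal(0.0, qtl_model.sigma_ge, size=n)
            + rng.normal(0.0, qtl_model.sigma_eps, size=n)
        )
        counts = rng.binomial(n_seedlings, expit(eta))
        rows.append(
            pd.DataFrame(
                {
                    "line": genotypes.index,
                    "replicate": rep_name,
                    "affected": counts,
                    "n_seedlings": n_seedlings,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_bulks(
    phenotypes: pd.DataFrame, k: int = 30
) -> tuple[list[str], list[str]]:
    """Select the k highest- and k lowest-frequency lines as (MUL, TRI) bulks.

    The ranking statistic is the pooled affected frequency (total affected /
    total scored across replicates).  Lines are ordered by descending
    frequency with ties broken by line id; the MUL bulk is the first k and
    the TRI bulk the last k of that ordering, so the two bulks are always
    disjoint for k <= n/2 and partition the population at k = n/2.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = phenotypes.groupby("line")[["affected", "n_seedlings"]].sum()
    if 2 * k > len(totals):
        raise ValueError(f"k={k} too large for {len(totals)} lines")
    ranking = (totals["affected"] / totals["n_seedlings"]).rename("freq")
    order = ranking.reset_index().sort_values(
        ["freq", "line"], ascending=[False, True], kind="mergesort"
    )["line"].tolist()
    return order[:k], order[-k:]


def simulate_bulk_reads(
    genotypes: pd.DataFrame,
    bulks: tuple[Sequence[str], Sequence[str]],
    map_df: pd.DataFrame,
    mean_depth: float = 30.0,
    error_rate: float = 0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate pooled allele depths for the (MUL, TRI) bulks at map markers.

    Per SNP and bulk the true alt-allele frequency f is the mean genotype
    code / 2 over the bulk's lines; total depth ~ Poisson(mean_depth) and alt
    reads ~ Binomial(depth, f(1-e) + (1-f)e).  Returns a bulk allele-count
    table (see :data:`bsrqtl.formats_io.COUNT_COLUMNS`).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    mul_ids, tri_ids = (list(b) for b in bulks)
    if not mul_ids or not tri_ids:
        raise ValueError("bulks must be non-empty")
    rng = np.random.default_rng(seed)
    markers = map_df["marker"].tolist()
    out = {"chrom": map_df["chrom"].to_numpy(), "pos": map_df["bp"].to_numpy()}
    for name, ids in (("mul", mul_ids), ("tri", tri_ids)):
        sub = genotypes.loc[ids, markers].to_numpy(dtype=float)
        f = sub.mean(axis=0) / 2.0
        p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        depth = rng.poisson(mean_depth, size=len(markers))
        alt = rng.binomial(depth, p_alt)
        out[f"{name}_ref"] = depth - alt
        out[f"{name}_alt"] = alt
    return pd.DataFrame(out)[
        ["chrom", "pos", "mul_ref", "mul_alt", "tri_ref", "tri_alt"]
    ]
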