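"""Phenotype descriptive statistics, variance components, broad-sense
heritability and per-line BLUPs for line × replicate trial data.

The trait is an affected-seedling count per line and replicate; replicates
were grown in different seasons, so each replicate is treated as one
environment.  The working model is the two-way random-effects decomposition

    y_ijk = mu + env_j + g_i + (ge)_ij + eps_ijk,

with lines ``g`` and the line-by-environment interaction ``ge`` random and
environments fixed.  Broad-sense heritability on an entry-mean basis is

    H^2 = V_g / (V_g + V_ge / L + V_eps / (R L)),

where L is the number of environments and R the number of replications per
environment.  With one observation per line and environment (the usual case
here) V_ge and V_eps are confounded; the interaction variance is then
reported as 0 with a warning and its mass is carried by V_eps, which leaves
H^2 unchanged because V_ge/L + V_eps/L enters the denominator as a sum.

The response defaults to the affected-seedling *frequency* (count / number
scored) so replicates that scored 5, 10 and 20 seedlings per line are
comparable; raw counts are available via ``response="count"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "response_matrix",
    "population_cv",
    "replicate_correlations",
    "variance_components",
    "anova_variance_components",
    "heritability",
    "blup",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the two-way model plus the trial layout.

    ``v_g``: genotype variance; ``v_ge``: genotype-by-environment variance;
    ``v_eps``: residual variance; ``r``: replications per environment;
    ``l``: number of environments.
    """

    v_g: float
    v_ge: float
    v_eps: float
    r: int
    l: int

    def __post_init__(self) -> None:
        if min(self.v_g, self.v_ge, self.v_eps) < 0:
            raise ValueError("variance components must be non-negative")
        if self.r < 1 or self.l < 1:
            raise ValueError("r and l must be >= 1")


def response_matrix(phenotypes: pd.DataFrame, response: str = "freq") -> pd.DataFrame:
    """Pivot a phenotype table to a line × replicate response matrix.

    ``response`` is ``"freq"`` (affected / scored) or ``"count"``.
    """
    df = phenotypes.copy()
    if response == "freq":
        df["value"] = df["affected"] / df["n_seedlings"]
    elif response == "count":
        df["value"] = df["affected"].astype(float)
    else:
        raise ValueError(f"unknown response {response!r}")
    mat = df.pivot_table(index="line", columns="replicate", values="value",
                         aggfunc="mean", sort=True)
    return mat


def population_cv(phenotypes: pd.DataFrame, response: str = "freq") -> float:
    """Population coefficient of variation (%) of per-line mean response.

    CV = 100 * sd / mean over line means; a highly sporadic trait shows
    CV well above 50%.
    """
    means = response_matrix(phenotypes, response).mean(axis=1)
    m = float(means.mean())
    if m == 0:
        raise ValueError("CV undefined: mean response is zero")
    return 100.0 * float(means.std(ddof=1)) / m


def replicate_correlations(
    phenotypes: pd.DataFrame, response: str = "freq"
) -> pd.DataFrame:
    """Pairwise Pearson correlations of the response between replicates.

    Computed over lines present in both replicates of each pair.  A replicate
    with zero variance yields an undefined (NaN) entry and a warning rather
    than propagating NaN into other entries.
    """
    mat = response_matrix(phenotypes, response)
    reps = list(mat.columns)
    if len(reps) < 2:
        raise ValueError("need >=2 replicates")
    out = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            pair = mat[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"replicates {a},{b}: <3 shared lines")
            x = pair[a].to_numpy(float)
            y = pair[b].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"zero variance in replicate pair ({a}, {b}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def anova_variance_components(
    long: pd.DataFrame,
    value_col: str = "value",
    line_col: str = "line",
    env_col: str = "env",
    rep_col: str | None = None,
) -> VarianceComponents:
    """Estimate V_g, V_ge, V_eps from a balanced line × env (× rep) layout.

    Uses the expected-mean-squares equations of the two-way model with lines
    random:  E[MS_G] = s2_eps + R s2_ge + R L s2_g,
    E[MS_GxE] = s2_eps + R s2_ge,  E[MS_err] = s2_eps.
    Negative solutions are truncated at zero.  With R = 1 (no within-
    environment replication) the interaction and residual are confounded:
    V_ge is reported as 0 with a warning and MS_GxE is assigned to V_eps.
    A single environment likewise reports V_ge = 0.

    Raises ``ValueError`` on an unbalanced layout; unbalanced tables should
    be reduced to their balanced core first (see :func:`variance_components`).
    """
    df = long[[line_col, env_col, value_col]].copy()
    if rep_col is not None:
        df["_rep"] = long[rep_col]
    else:
        df["_rep"] = df.groupby([line_col, env_col]).cumcount()
    counts = df.groupby([line_col, env_col]).size()
    lines = df[line_col].unique()
    envs = df[env_col].unique()
    g, l = len(lines), len(envs)
    if len(counts) != g * l or counts.nunique() != 1:
        raise ValueError(
            "unbalanced line x environment layout; use "
            "variance_components(..., unbalanced='core') or supply a "
            "complete layout"
        )
    r = int(counts.iloc[0])

    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    cell = df.groupby([line_col, env_col])[value_col].mean()
    line_means = df.groupby(line_col)[value_col].mean()
    env_means = df.groupby(env_col)[value_col].mean()

    ss_g = l * r * float(((line_means - grand) ** 2).sum())
    cell_resid = (
        cell
        - line_means.reindex(cell.index.get_level_values(0)).to_numpy()
        - env_means.reindex(cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = r * float((cell_resid ** 2).sum())
    fitted = cell.reindex(
        pd.MultiIndex.from_arrays([df[line_col], df[env_col]])
    ).to_numpy()
    ss_err = float(((y - fitted) ** 2).sum())

    ms_g = ss_g / (g - 1) if g > 1 else 0.0
    if g > 1 and l > 1:
        ms_ge = ss_ge / ((g - 1) * (l - 1))
    else:
        ms_ge = 0.0
    if r > 1:
        ms_err = ss_err / (g * l * (r - 1))
    else:
        ms_err = None

    if l == 1:
        warnings.warn(
            "single environment: V_ge is inestimable and reported as 0",
            stacklevel=2,
        )
        v_eps = ms_err if ms_err is not None else 0.0
        v_ge = 0.0
        v_g = max(0.0, (ms_g - v_eps) / r)
    elif r == 1:
        warnings.warn(
            "one observation per line x environment: V_ge and V_eps are "
            "confounded; V_ge reported as 0",
            stacklevel=2,
        )
        v_eps = ms_ge
        v_ge = 0.0
        v_g = max(0.0, (ms_g - ms_ge) / l)
    else:
        v_eps = ms_err
        v_ge = max(0.0, (ms_ge - ms_err) / r)
        v_g = max(0.0, (ms_g - ms_ge) / (r * l))
    return VarianceComponents(v_g=v_g, v_ge=v_ge, v_eps=v_eps, r=r, l=l)


def variance_components(
    phenotypes: pd.DataFrame,
    response: str = "freq",
    unbalanced: str = "error",
) -> VarianceComponents:
    """Variance components of a phenotype table (replicate = environment).

    ``unbalanced="error"`` (default) raises on an incomplete line × replicate
    layout; ``unbalanced="core"`` estimates on the balanced core (lines
    scored in every replicate), a documented approximation for trials where
    a handful of lines were dropped from some replicates.
    """
    df = phenotypes.copy()
    if response == "freq":
        df["value"] = df["affected"] / df["n_seedlings"]
    elif response == "count":
        df["value"] = df["affected"].astype(float)
    else:
        raise ValueError(f"unknown response {response!r}")
    long = df.rename(columns={"replicate": "env"})[["line", "env", "value"]]
    n_env = long["env"].nunique()
    complete = long.groupby("line")["env"].nunique()
    if (complete < n_env).any() or len(long) != len(complete) * n_env:
        if unbalanced != "core":
            raise ValueError(
                "unbalanced layout: not every line was scored once in every "
                "replicate; pass unbalanced='core' to estimate on the "
                "balanced core"
            )
        keep = complete[complete == n_env].index
        long = long[long["line"].isin(keep)]
        counts = long.groupby(["line", "env"]).size()
        long = (
            long.groupby(["line", "env"], as_index=False)["value"].mean()
            if counts.nunique() != 1
            else long
        )
        warnings.warn(
            f"estimating on balanced core of {len(keep)} lines",
            stacklevel=2,
        )
    return anova_variance_components(long)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H^2 = V_g / (V_g + V_ge/L + V_eps/(R L))."""
    denom = vc.v_g + vc.v_ge / vc.l + vc.v_eps / (vc.r * vc.l)
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components zero")
    return vc.v_g / denom


def blup(
    phenotypes: pd.DataFrame,
    vc: VarianceComponents | None = None,
    response: str = "freq",
) -> pd.Series:
    """Per-line BLUP of the genetic value, reported on the response scale.

    In the balanced case the BLUP of line i is mu + s * (ybar_i - ybar) with
    shrinkage s = V_g / (V_g + V_ge/L + V_eps/(R L)) — a rank-preserving
    shrinkage of line means towards the grand mean.  V_g -> infinity returns
    the raw line means; V_g = 0 returns the grand mean for every line.
    """
    if vc is None:
        vc = variance_components(phenotypes, response=response, unbalanced="core")
    mat = response_matrix(phenotypes, response)
    line_means = mat.mean(axis=1, skipna=True)
    grand = float(line_means.mean())
    denom = vc.v_g + vc.v_ge / vc.l + vc.v_eps / (vc.r * vc.l)
    shrink = 1.0 if denom == 0 else vc.v_g / denom
    out = grand + shrink * (line_means - grand)
    out.name = "blup"
    return out
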