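"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bsrqtl import synthetic_data as sd


@pytest.fixture()
def tiny_map() -> pd.DataFrame:
    """Two chromosomes, 11 evenly spaced markers each (0..100 cM, 20 kb/cM)."""
    return sd.simulate_map(
        n_chrom=2, chrom_length_cm=100.0, markers_per_chrom=11,
        bp_per_cm=20_000.0, seed=0,
    )


@pytest.fixture()
def dense_map() -> pd.DataFrame:
    """One chromosome dense enough for 1-Mb / 10-kb windowing (50 SNPs/Mb)."""
    return sd.simulate_map(
        n_chrom=1, chrom_length_cm=100.0, markers_per_chrom=500,
        bp_per_cm=100_000.0, seed=0,
    )


@pytest.fixture()
def small_population(tiny_map: pd.DataFrame) -> pd.DataFrame:
    return sd.simulate_ril_genotypes(tiny_map, n_lines=120, residual_het=0.0, seed=1)


def make_phenotypes(
    lines: list[str],
    counts: dict[str, list[int]],
    n_seedlings: list[int] | None = None,
) -> pd.DataFrame:
    """Build a phenotype table from per-replicate count lists."""
    n_seedlings = n_seedlings or [10] * len(counts)
    rows = []
    for (rep, values), n in zip(counts.items(), n_seedlings):
        for line, c in zip(lines, values):
            rows.append({"line": line, "replicate": rep,
                         "affected": c, "n_seedlings": n})
    return pd.DataFrame(rows)
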