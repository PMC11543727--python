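"""ΔSNP-index pipeline: filter semantics on hand fixtures, window means vs a
brute-force oracle, cutoff behaviour and region calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsrqtl import bsa_scan as bs
from bsrqtl import synthetic_data as sd
from bsrqtl.bsa_scan import PermutationCutoff


def _counts(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "mul_ref", "mul_alt", "tri_ref", "tri_alt"]
    )


# ---------------------------------------------------------------------------
# SNP index + filters
# ---------------------------------------------------------------------------

def test_snp_index_arithmetic():
    track = bs.snp_index(
        _counts(
            [
                ("c", 1, 5, 5, 5, 5),
                ("c", 2, 12, 0, 3, 7),
                ("c", 3, 0, 0, 1, 1),
            ]
        )
    )
    assert track["index_mul"].tolist()[:2] == [0.5, 0.0]
    assert track["index_tri"].iloc[1] == pytest.approx(0.7)
    assert np.isnan(track["index_mul"].iloc[2])  # zero depth -> undefined


SIX_ROW_FIXTURE = [
    # (chrom, pos, mul_ref, mul_alt, tri_ref, tri_alt) -> hand-enumerated fate
    ("c", 10, 1, 1, 4, 5),      # MUL depth 2 < 3          -> depth rule
    ("c", 20, 2, 1, 2, 1),      # depth 3/3, idx .33/.33   -> kept
    ("c", 30, 8, 2, 9, 1),      # idx 0.2 / 0.1 both < .3  -> index rule
    ("c", 40, 5, 5, 9, 1),      # idx 0.5 / 0.1            -> kept
    ("c", 50, 30, 0, 1, 1),     # idx 0 / 0.5: TRI depth 2 -> depth rule
    ("c", 60, 15, 5, 16, 4),    # idx .25/.2 both < .3     -> index rule
]


def test_filter_semantics_on_hand_fixture():
    track = bs.snp_index(_counts(SIX_ROW_FIXTURE))
    kept = bs.filter_snps(track)
    assert kept["pos"].tolist() == [20, 40]
    assert kept.attrs["n_removed_depth"] == 2
    assert kept.attrs["n_removed_index"] == 2


def test_filter_boundary_cases():
    # depth exactly 3 passes (only "less than 3" is removed); index exactly
    # 0.3 passes (only "< 0.3 in both bulks" is removed)
    track = bs.snp_index(_counts([("c", 1, 2, 1, 20, 10), ("c", 2, 7, 3, 7, 3)]))
    assert bs.filter_snps(track)["pos"].tolist() == [1, 2]
    # indices 0.25 / 0.28: below the floor in both bulks, removed at any depth
    track = bs.snp_index(_counts([("c", 1, 75, 25, 72, 28)]))
    assert len(bs.filter_snps(track)) == 0


def test_filter_is_idempotent():
    track = bs.snp_index(_counts(SIX_ROW_FIXTURE))
    once = bs.filter_snps(track)
    twice = bs.filter_snps(once)
    pd.testing.assert_frame_equal(once, twice)


def test_delta_index_arithmetic_and_bounds():
    track = bs.delta_index(
        bs.snp_index(_counts([("c", 1, 1, 9, 9, 1), ("c", 2, 5, 5, 5, 5)]))
    )
    assert track["delta"].iloc[0] == pytest.approx(0.1 - 0.9)
    assert track["delta"].iloc[1] == 0.0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(*[st.integers(min_value=0, max_value=100)] * 4),
        min_size=1, max_size=30,
    )
)
def test_delta_bounded(rows):
    counts = _counts(
        [("c", i + 1, mr, ma, tr, ta) for i, (mr, ma, tr, ta) in enumerate(rows)]
    )
    track = bs.delta_index(bs.filter_snps(bs.snp_index(counts), min_depth=1))
    assert track["delta"].between(-1, 1).all()


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _window_oracle(track, window, step, min_snps):
    """Naive double loop over the step grid."""
    out = []
    for chrom in track["chrom"].unique():
        sub = track[track["chrom"] == chrom]
        start = 1
        while start <= sub["pos"].max():
            inside = sub[(sub["pos"] >= start) & (sub["pos"] <= start + window - 1)]
            if len(inside) >= min_snps:
                out.append((chrom, start, start + window - 1, len(inside),
                            inside["delta"].mean()))
            start += step
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "n_snps", "mean_delta"]
    )


def test_constant_delta_gives_constant_window_means():
    pos = np.arange(1, 2001, 10)
    counts = _counts([("c", int(p), 5, 5, 0, 10) for p in pos])
    track = bs.delta_index(bs.snp_index(counts))
    windows = bs.window_scan(track, window=500, step=100, min_snps=10)
    assert len(windows) > 0
    assert np.allclose(windows["mean_delta"], 0.5)


def test_window_below_min_snps_skipped():
    pos = [1, 2, 3, 4, 5, 6, 7, 8, 9]  # 9 SNPs only
    counts = _counts([("c", p, 5, 5, 5, 5) for p in pos])
    track = bs.delta_index(bs.snp_index(counts))
    assert len(bs.window_scan(track, window=100, step=10, min_snps=10)) == 0
    assert len(bs.window_scan(track, window=100, step=10, min_snps=9)) > 0


@pytest.mark.parametrize("n_snps,seed", [(50, 0), (200, 1), (500, 2)])
def test_window_means_match_brute_force_oracle(n_snps, seed):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 60_000), size=n_snps, replace=False))
    chrom = rng.choice(["GmA", "GmB"], size=n_snps)
    depth = rng.integers(5, 60, size=(n_snps, 2))
    alt = rng.binomial(depth, 0.5)
    counts = _counts(
        [
            (chrom[i], int(pos[i]), int(depth[i, 0] - alt[i, 0]), int(alt[i, 0]),
             int(depth[i, 1] - alt[i, 1]), int(alt[i, 1]))
            for i in range(n_snps)
        ]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    track = bs.delta_index(bs.filter_snps(bs.snp_index(counts), min_depth=1,
                                          min_index=0.0))
    window, step, min_snps = 10_000, 1_000, 5
    got = bs.window_scan(track, window, step, min_snps)
    expected = _window_oracle(track, window, step, min_snps)
    got = got.sort_values(["chrom", "start"]).reset_index(drop=True)
    expected = expected.sort_values(["chrom", "start"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        got.astype({"start": int, "end": int, "n_snps": int}),
        expected.astype({"start": int, "end": int, "n_snps": int}),
    )


# ---------------------------------------------------------------------------
# permutation cutoff
# ---------------------------------------------------------------------------

def _uniform_track(n_snps: int, spacing: int, depth: int = 30) -> pd.DataFrame:
    counts = _counts(
        [("c", 1 + i * spacing, depth // 2, depth - depth // 2,
          depth // 2, depth - depth // 2) for i in range(n_snps)]
    )
    return bs.delta_index(bs.snp_index(counts))


def test_cutoff_deterministic_for_fixed_seed():
    track = _uniform_track(300, 100)
    kw = dict(window=10_000, step=1_000, min_snps=10, n_iter=1000, seed=5)
    a = bs.permutation_cutoff(track, **kw)
    b = bs.permutation_cutoff(track, **kw)
    assert a == b
    assert a.lower == -a.upper


def test_binomial_cutoff_shrinks_with_snps_per_window():
    """Read-resampling null: the window-mean variance scales as 1/n_SNPs."""
    sparse = _uniform_track(200, 1000)   # 10 SNPs per 10-kb window
    dense = _uniform_track(2000, 100)    # 100 SNPs per 10-kb window
    kw = dict(window=10_000, step=5_000, min_snps=5, n_iter=2000,
              null_model="binomial", seed=0)
    c_sparse = bs.permutation_cutoff(sparse, **kw)
    c_dense = bs.permutation_cutoff(dense, **kw)
    assert c_dense.upper < c_sparse.upper


def test_median_cutoff_near_null_median():
    track = _uniform_track(300, 100)
    c = bs.permutation_cutoff(track, window=10_000, step=1_000, min_snps=10,
                              n_iter=2000, quantile=0.5, null_model="binomial",
                              seed=1)
    c99 = bs.permutation_cutoff(track, window=10_000, step=1_000, min_snps=10,
                                n_iter=2000, quantile=0.99,
                                null_model="binomial", seed=1)
    assert 0 < c.upper < c99.upper


def test_cutoff_input_validation():
    track = _uniform_track(50, 100)
    with pytest.raises(ValueError):
        bs.permutation_cutoff(track, n_iter=10)
    with pytest.raises(ValueError):
        bs.permutation_cutoff(track, n_iter=1000, null_model="bogus")


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def _windows(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "mean_delta"]
    )


CUT = PermutationCutoff(lower=-0.3, upper=0.3, quantile=0.99, n_iter=1000,
                        null_model="bulk")


def test_no_window_beyond_cutoff_gives_no_regions():
    w = _windows([("c", 1, 1000, 20, 0.1), ("c", 501, 1500, 20, -0.2)])
    assert bs.call_regions(w, CUT) == []


def test_isolated_window_becomes_single_region():
    w = _windows([("c", 1001, 2000, 20, 0.5)])
    (region,) = bs.call_regions(w, CUT)
    assert region.interval.start == 1001 and region.interval.end == 2000
    assert region.direction == "tri" and region.peak_mean == 0.5


def test_overlapping_windows_merge_and_directions_separate():
    w = _windows(
        [
            ("c", 1, 1000, 20, 0.4),
            ("c", 501, 1500, 20, 0.6),
            ("c", 1001, 2000, 20, 0.35),
            ("c", 5001, 6000, 20, -0.5),
        ]
    )
    regions = bs.call_regions(w, CUT)
    assert len(regions) == 2
    tri = [r for r in regions if r.direction == "tri"][0]
    assert (tri.interval.start, tri.interval.end) == (1, 2000)
    assert tri.peak_mean == 0.6
    mul = [r for r in regions if r.direction == "mul"][0]
    assert mul.cutoff == CUT.lower


def test_bulk_enrichment_direction_at_planted_qtl(dense_map):
    """Where the trait-raising allele comes from the parent coded 2, the MUL
    bulk's alt index exceeds the TRI bulk's, so delta = TRI - MUL < 0."""
    geno = sd.simulate_ril_genotypes(dense_map, n_lines=200, residual_het=0.0,
                                     seed=0)
    marker = dense_map["marker"].iloc[len(dense_map) // 2]
    pheno = sd.simulate_phenotypes(geno, sd.QTLModel(effects={marker: 1.5}),
                                   seed=1)
    bulks = sd.select_bulks(pheno, k=30)
    counts = sd.simulate_bulk_reads(geno, bulks, dense_map, mean_depth=40,
                                    seed=2)
    track = bs.delta_index(bs.filter_snps(bs.snp_index(counts)))
    qtl_pos = int(dense_map.loc[dense_map["marker"] == marker, "bp"].iloc[0])
    at_qtl = track.iloc[(track["pos"] - qtl_pos).abs().argsort()[:5]]
    assert (at_qtl["index_mul"] > at_qtl["index_tri"]).all()
    assert (at_qtl["delta"] < 0).all()
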