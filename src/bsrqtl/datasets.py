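"""Published interval coordinates for the soybean multifoliolate trait study
(C08 × W05 RIL population, Williams 82 v4 physical coordinates).

These tables are *inputs* to the integration stage: the linkage-mapping QTL
confidence regions (common regions across replicates) and the bulked-
segregant regions detected at the V0 (shoot apical bud) and V1 (first
compound leaf) stages.  Coordinates are 1-based base pairs as printed.

``printed_range_mb`` is the width as reported alongside each QTL; for one
locus (qMF-9) the reported width (0.85 Mb) disagrees with its own printed
bounds (which span 0.80 Mb), so width checks should rely on
``GenomicInterval.width_mb`` and treat the reported number as suspect there.
"""

from __future__ import annotations

from .formats_io import GenomicInterval

__all__ = [
    "LINKAGE_QTL_REGIONS",
    "BSA_REGIONS",
    "consistent_linkage_widths",
]

#: QTL name -> (confidence interval, printed width in Mb, printed gene count)
LINKAGE_QTL_REGIONS: dict[str, tuple[GenomicInterval, float, int]] = {
    "qMF-2-1": (GenomicInterval("Gm02", 5_550_000, 5_850_000), 0.3, 44),
    "qMF-2-2": (GenomicInterval("Gm02", 33_000_000, 40_350_000), 7.35, 154),
    "qMF-4-1": (GenomicInterval("Gm04", 0, 2_650_000), 2.65, 336),
    "qMF-4-2": (GenomicInterval("Gm04", 9_650_000, 44_250_000), 34.6, 641),
    "qMF-5": (GenomicInterval("Gm05", 29_050_000, 36_100_000), 7.05, 601),
    "qMF-6": (GenomicInterval("Gm06", 17_300_000, 20_700_000), 3.4, 138),
    "qMF-9": (GenomicInterval("Gm09", 5_650_000, 6_450_000), 0.85, 1),
    "qMF-12": (GenomicInterval("Gm12", 12_300_000, 20_050_000), 7.75, 206),
    "qMF-13": (GenomicInterval("Gm13", 42_800_000, 43_350_000), 0.55, 70),
    "qMF-20": (GenomicInterval("Gm20", 43_200_000, 44_750_000), 1.55, 179),
}

#: (QTL name, stage, BSA region, printed overlapping-gene count)
BSA_REGIONS: list[tuple[str, str, GenomicInterval, int]] = [
    ("qMF-2-2", "V0", GenomicInterval("Gm02", 32_820_000, 33_960_000), 18),
    ("qMF-2-2", "V0", GenomicInterval("Gm02", 34_440_000, 35_800_000), 12),
    ("qMF-2-2", "V1", GenomicInterval("Gm02", 34_610_000, 35_900_000), 12),
    ("qMF-4-2", "V1", GenomicInterval("Gm04", 28_670_000, 30_180_000), 13),
    ("qMF-4-2", "V1", GenomicInterval("Gm04", 33_460_000, 34_500_000), 7),
    ("qMF-4-2", "V1", GenomicInterval("Gm04", 35_890_000, 36_950_000), 5),
    ("qMF-6", "V0", GenomicInterval("Gm06", 17_560_000, 19_470_000), 82),
    ("qMF-12", "V1", GenomicInterval("Gm12", 11_650_000, 12_720_000), 9),
]


def consistent_linkage_widths() -> dict[str, tuple[GenomicInterval, float]]:
    """QTLs whose printed width matches their printed bounds exactly."""
    out = {}
    for name, (iv, printed, _) in LINKAGE_QTL_REGIONS.items():
        if iv.width_mb == printed:
            out[name] = (iv, printed)
    return out
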