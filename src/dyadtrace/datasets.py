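"""Small published summary tables bundled as worked-example inputs.

These are the printed per-ASV transfer accounting rows (the ten most
frequently transferred ASVs; the bifidobacterial ASVs) and the strain-typing
contingency tables from the motivating mother-infant transmission study,
used as inputs for the package's accounting and contingency statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_SUMMARY_COLS = [
    "asv_id", "taxon", "pct_identity", "n_maternal", "n_transfers",
    "n_both", "n_10d", "n_3mo",
]

# Ten most frequently transferred ASVs:
# (taxon, pct identity, maternal samples > threshold, transfers, both, 10d, 3mo)
_TOP_TRANSFERRED = [
    ("1", "Lactobacillus crispatus", 100.0, 380, 61, 0, 57, 4),
    ("2", "Bifidobacterium breve", 98.0, 43, 28, 11, 7, 10),
    ("3", "Actinomyces neuii subsp. anitratus", 100.0, 232, 23, 1, 16, 6),
    ("4", "Bifidobacterium longum subsp. longum", 100.0, 25, 15, 5, 5, 5),
    ("5", "Lactobacillus gasseri", 100.0, 146, 12, 0, 7, 5),
    ("6", "Shigella sonnei", 98.7, 23, 12, 6, 3, 3),
    ("7", "Escherichia coli", 100.0, 15, 8, 2, 2, 4),
    ("8", "Lactobacillus jensenii", 100.0, 203, 7, 0, 7, 0),
    ("9", "Bifidobacterium dentium", 98.7, 16, 4, 0, 3, 1),
    ("10", "Escherichia coli", 99.3, 9, 3, 0, 3, 0),
]

# All bifidobacterial ASVs undergoing potential transfer.
_BIFIDO = [
    ("1", "Bifidobacterium adolescentis", 100.0, 1, 1, 0, 1, 0),
    ("2", "Bifidobacterium adolescentis", 98.7, 1, 1, 0, 0, 1),
    ("3", "Bifidobacterium bifidum", 98.7, 4, 2, 0, 0, 2),
    ("4", "Bifidobacterium breve", 98.0, 43, 28, 11, 7, 10),
    ("5", "Bifidobacterium breve", 98.7, 6, 3, 2, 1, 0),
    ("6", "Bifidobacterium breve", 97.3, 3, 3, 0, 2, 1),
    ("7", "Bifidobacterium breve", 97.3, 4, 2, 0, 0, 2),
    ("8", "Bifidobacterium breve", 98.0, 10, 1, 0, 1, 0),
    ("9", "Bifidobacterium breve", 98.0, 1, 1, 1, 0, 0),
    ("10", "Bifidobacterium breve", 98.0, 1, 1, 0, 1, 0),
    ("11", "Bifidobacterium breve", 97.3, 2, 1, 0, 0, 1),
    ("12", "Bifidobacterium dentium", 98.7, 16, 4, 0, 3, 1),
    ("13", "Bifidobacterium longum subsp. infantis", 100.0, 2, 1, 1, 0, 0),
    ("14", "Bifidobacterium longum subsp. longum", 100.0, 25, 15, 5, 5, 5),
    ("15", "Bifidobacterium longum subsp. longum", 99.3, 12, 3, 0, 3, 0),
    ("16", "Bifidobacterium longum subsp. longum", 99.3, 3, 1, 0, 0, 1),
    ("17", "Bifidobacterium pseudocatenulatum", 99.3, 3, 1, 0, 1, 0),
]


def top_transferred_asvs() -> pd.DataFrame:
    """Per-ASV accounting rows for the 10 most frequently transferred ASVs."""
    return pd.DataFrame(_TOP_TRANSFERRED, columns=_SUMMARY_COLS)


def bifidobacterial_asvs() -> pd.DataFrame:
    """Per-ASV accounting rows for the 17 bifidobacterial ASVs."""
    return pd.DataFrame(_BIFIDO, columns=_SUMMARY_COLS)


def strain_typing_tables() -> dict[str, np.ndarray]:
    """Identical/nonidentical strain-call contingency tables by grouping.

    Rows are groups, columns are (identical, nonidentical) dyad or isolate
    counts, from pulsed-field gel electrophoresis typing of Bifidobacterium
    spp. and Enterococcus faecalis isolates.
    """
    return {
        "bifidobacterium_delivery_mode": np.array([[10, 5], [7, 5], [5, 1]]),
        "bifidobacterium_antibiotics": np.array([[8, 3], [14, 8]]),
        "bifidobacterium_time_point": np.array([[34, 9], [24, 21]]),
        "efaecalis_delivery_mode": np.array([[3, 0], [2, 2], [4, 2]]),
        "efaecalis_antibiotics": np.array([[2, 0], [7, 4]]),
        "efaecalis_time_point": np.array([[16, 8], [11, 7]]),
    }


def summary_totals(df: pd.DataFrame) -> dict[str, float]:
    """Aggregate printed per-ASV rows: total maternal detections, transfers,
    pooled transfer rate and category split."""
    n_mat = int(df["n_maternal"].sum())
    n_tr = int(df["n_transfers"].sum())
    return {
        "n_maternal_above_threshold": n_mat,
        "n_transfers": n_tr,
        "transfer_rate": n_tr / n_mat if n_mat else 0.0,
        "n_both": int(df["n_both"].sum()),
        "n_ten_day": int(df["n_10d"].sum()),
        "n_three_month": int(df["n_3mo"].sum()),
    }
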