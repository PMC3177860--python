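"""Warm/cool categorization indices and quadrant concordance.

Color-naming cluster counts per chip (N_w times "warm", N_c times "cool")
are condensed into the index

    I_wc = (N_w - N_c) / (N_w + N_c),

whose sign encodes the chip's two-way category and whose magnitude encodes
the consistency of that assignment across palettes.  The concordance between
categorization and an opponent channel is measured as the fraction of chips
falling in the first/third quadrants of the (response, index) plane, i.e.
chips where the two signs agree strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChipCounts",
    "compute_iwc",
    "quadrant_fraction",
    "QuadrantResult",
    "categorize_chips",
    "read_counts_tsv",
    "write_chip_table",
]


@dataclass(frozen=True)
class ChipCounts:
    """Warm/cool membership counts for one chip."""

    chip_id: str
    N_w: int
    N_c: int

    def __post_init__(self) -> None:
        if self.N_w < 0 or self.N_c < 0:
            raise ValueError("counts must be non-negative")


def compute_iwc(counts: ChipCounts) -> float:
    """Warm/cool index (N_w - N_c)/(N_w + N_c), in [-1, 1]."""
    total = counts.N_w + counts.N_c
    if total <= 0:
        raise ValueError(f"chip {counts.chip_id}: N_w + N_c must be positive")
    return (counts.N_w - counts.N_c) / total


class QuadrantResult(NamedTuple):
    n_concordant: int
    n_total: int
    fraction: float


def quadrant_fraction(pairs: Sequence[tuple[float, float]]) -> QuadrantResult:
    """Fraction of (index, response) pairs with strictly matching signs.

    A pair lies in quadrant 1 or 3 when both members are strictly positive
    or both strictly negative.  Pairs with either member exactly 0 sit on an
    axis: they count toward the total but are never concordant.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("no pairs supplied")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (index, response) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    concordant = int(np.sum(np.sign(arr[:, 0]) * np.sign(arr[:, 1]) > 0))
    total = int(arr.shape[0])
    return QuadrantResult(concordant, total, concordant / total)


def categorize_chips(chips: pd.DataFrame) -> pd.DataFrame:
    """Attach I_wc and quadrant flags to a chip table.

    ``chips`` must have columns ``chip_id, N_w, N_c, R_LM, R_Y`` (cone
    contrast columns ``C_L, C_M, C_S`` are carried through when present).
    Chips with N_w + N_c == 0 are dropped with a warning rather than failing
    the batch.  Returns a new DataFrame with ``I_wc`` and boolean
    ``concordant_rlm`` / ``concordant_ry`` columns.
    """
    required = {"chip_id", "N_w", "N_c", "R_LM", "R_Y"}
    missing = required - set(chips.columns)
    if missing:
        raise ValueError(f"chip table missing columns: {sorted(missing)}")
    total = chips["N_w"] + chips["N_c"]
    keep = total > 0
    if (~keep).any():
        dropped = chips.loc[~keep, "chip_id"].tolist()
        logger.warning("dropping %d chips with zero counts: %s", len(dropped), dropped)
    out = chips.loc[keep].copy()
    out["I_wc"] = (out["N_w"] - out["N_c"]) / (out["N_w"] + out["N_c"])
    out["concordant_rlm"] = np.sign(out["I_wc"]) * np.sign(out["R_LM"]) > 0
    out["concordant_ry"] = np.sign(out["I_wc"]) * np.sign(out["R_Y"]) > 0
    return out


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a counts table: chip_id, hue_label, value_label, N_w, N_c."""
    df = pd.read_csv(path, sep="\t")
    required = {"chip_id", "N_w", "N_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty counts table")
    for col in ("N_w", "N_c"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0][0]
            raise ValueError(f"{path}: negative {col} at row {bad + 2}")
    return df


def write_chip_table(df: pd.DataFrame, path) -> None:
    """Write the per-chip output table as TSV."""
    cols = [c for c in ("chip_id", "I_wc", "C_L", "C_M", "C_S", "R_LM", "R_Y",
                        "concordant_rlm", "concordant_ry") if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)
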