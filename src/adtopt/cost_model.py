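"""Antibody reagent cost, read allocation, and chip-loading arithmetic.

Reagent cost per sample is the sum over markers of
``concentration (ug/mL) x volume (mL) x price (USD/ug)``; the default price
of 32.5 USD/ug corresponds to a list price of 325 USD per 10 ug of
oligo-conjugated antibody. Read allocation summarizes how the panel's
sequencing output splits across markers and between cell-containing and
empty droplets (the empty-droplet share is sequencing spent on background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import AntibodyPanel

DEFAULT_PRICE_USD_PER_UG = 32.5


@dataclass
class CostConfig:
    price_usd_per_ug: float = DEFAULT_PRICE_USD_PER_UG
    volume_ul: float = 50.0

    def __post_init__(self) -> None:
        if self.price_usd_per_ug <= 0:
            raise ValueError("price must be > 0")
        if self.volume_ul <= 0:
            raise ValueError("volume must be > 0")


def panel_cost(
    concentrations: "pd.Series | Iterable[float] | AntibodyPanel",
    volume_ul: float,
    price_usd_per_ug: float = DEFAULT_PRICE_USD_PER_UG,
    condition_id: str | None = None,
) -> float:
    """Antibody cost per sample in USD.

    ``concentrations`` may be a sequence of per-marker concentrations in
    ug/mL or an AntibodyPanel together with ``condition_id``.
    """
    if isinstance(concentrations, AntibodyPanel):
        if condition_id is None:
            raise ValueError("condition_id required when passing a panel")
        concentrations = concentrations.concentrations(condition_id)
    values = np.asarray(list(concentrations), dtype=float)
    if volume_ul < 0 or price_usd_per_ug < 0 or (values < 0).any():
        raise ValueError("negative inputs to panel_cost")
    return float(values.sum() * (volume_ul / 1000.0) * price_usd_per_ug)


def comparison_stats(before: float, after: float) -> dict[str, float]:
    """Fold change and percent change between two totals.

    ``percent_change`` is signed (negative = reduction). Values are stored
    unrounded; presentation rounding (whole percents, one-decimal folds)
    belongs to the report layer.
    """
    if before <= 0:
        raise ValueError("before must be > 0")
    if after < 0:
        raise ValueError("after must be >= 0")
    if after == 0:
        raise ValueError("fold change undefined for after == 0")
    return {
        "fold_change": before / after,
        "percent_change": 100.0 * (after - before) / before,
    }


def read_allocation(metrics: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-marker share of total panel UMIs, split cell vs empty.

    ``metrics`` is the long-form metric frame for one condition (columns
    ``marker``, ``total_umis_cells``, ``total_umis_empty``). Returns a frame
    with each marker's share of all UMIs, of cell UMIs and of empty UMIs,
    plus its wasted (empty) share of its own UMIs — and the overall
    background share of sequencing.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    required = {"marker", "total_umis_cells", "total_umis_empty"}
    if not required <= set(metrics.columns):
        raise ValueError(f"metrics table lacks columns {sorted(required - set(metrics.columns))}")
    cells = metrics["total_umis_cells"].to_numpy(float)
    empty = metrics["total_umis_empty"].to_numpy(float)
    total = cells + empty
    grand = total.sum()
    if grand == 0:
        raise ValueError("no UMIs in metrics table")
    frame = pd.DataFrame({
        "marker": metrics["marker"].to_numpy(),
        "share_total": total / grand,
        "share_cells": cells / cells.sum() if cells.sum() else np.zeros_like(cells),
        "share_empty": empty / empty.sum() if empty.sum() else np.zeros_like(empty),
        "wasted_share": np.divide(empty, total, out=np.zeros_like(empty), where=total > 0),
    })
    background_share = float(empty.sum() / grand)
    return frame, background_share


def loading_concentration(target_cells: float, load_volume_ul: float) -> int:
    """Cells/uL needed to load ``target_cells`` in ``load_volume_ul``, nearest integer."""
    if target_cells <= 0 or load_volume_ul <= 0:
        raise ValueError("target_cells and load_volume_ul must be > 0")
    value = round(target_cells / load_volume_ul)
    if value < 1:
        raise ValueError("loading concentration rounds to 0 cells/uL; increase cells or reduce volume")
    return int(value)
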