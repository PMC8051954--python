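"""Split barcodes into cell-containing and empty droplets and apply QC.

The partition is keyed on the barcode-rank curve of per-barcode RNA UMI
totals: barcodes above the inflection point (the steepest descent of the
curve in log-log space) are candidate cells, everything below is treated as
an empty droplet whose ADT counts define the ambient background. QC then
re-labels low-quality candidate cells as ``removed`` so they contaminate
neither pool; HTO demultiplexing assigns cells to samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .data_model import CountMatrix, DropletExperiment

logger = logging.getLogger(__name__)


@dataclass
class RankCurve:
    """Per-barcode UMI totals sorted descending, with 1-based ranks."""

    barcodes: list[str]
    totals: np.ndarray  # same order as barcodes, non-increasing

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals)
        if len(self.barcodes) != len(self.totals):
            raise ValueError("barcodes and totals differ in length")
        if np.any(np.diff(self.totals) > 0):
            raise ValueError("totals must be non-increasing")

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.totals) + 1)


def barcode_rank_curve(counts: CountMatrix) -> RankCurve:
    """Rank barcodes by total UMIs, descending; ties broken by barcode string."""
    if counts.n_barcodes < 2:
        raise ValueError("need at least 2 barcodes to build a rank curve")
    totals = counts.barcode_totals()
    if int(totals.sum()) == 0:
        raise ValueError("all-zero count matrix has no rankable signal")
    order = sorted(range(len(totals)), key=lambda i: (-totals.iloc[i], counts.barcode_ids[i]))
    barcodes = [counts.barcode_ids[i] for i in order]
    return RankCurve(barcodes, totals.to_numpy()[order])


def find_inflection(
    curve: RankCurve,
    smoothing_window: int = 11,
    min_cells: int = 100,
    max_cells: int | None = None,
    slope_threshold: float = 1.0,
) -> int:
    """Locate the inflection point of a barcode-rank curve.

    Returns the 1-based rank ``r*`` of the steepest descent of
    log10(total) against log10(rank): the curve is smoothed by a centered
    moving average of ``smoothing_window`` ranks, the most negative forward
    difference within [min_cells, max_cells] is found, and the location is
    refined to the most negative *unsmoothed* forward difference within
    ``smoothing_window`` ranks of it. Barcodes with rank <= r* are candidate
    cells.

    ``max_cells`` defaults to half the barcodes with signal: the deep tail
    of the curve is extremely compressed in log-rank space, so a one-count
    drop among the last barcodes would otherwise out-slope the true knee.
    Callers that know the expected cell count should pass ~5x that number.

    Raises ValueError when no descent steeper than ``slope_threshold``
    (in log10 total per log10 rank) exists, which indicates the curve has no
    knee and a manual cutoff is needed.
    """
    nonzero = curve.totals > 0
    totals = curve.totals[nonzero].astype(float)
    n = len(totals)
    if n < max(2, min_cells):
        raise ValueError(f"curve has only {n} barcodes with signal; need at least {min_cells}")
    log_totals = np.log10(totals)
    log_ranks = np.log10(np.arange(1, n + 1, dtype=float))
    smoothed = uniform_filter1d(log_totals, size=max(1, int(smoothing_window)), mode="nearest")

    d_ranks = np.diff(log_ranks)
    deriv_smooth = np.diff(smoothed) / d_ranks
    deriv_raw = np.diff(log_totals) / d_ranks

    if max_cells is None:
        max_cells = max(n // 2, min_cells)
    hi = min(max_cells, n - 1)
    lo = max(min_cells, 1)
    if lo > hi:
        raise ValueError(f"no candidate ranks in [{min_cells}, {max_cells}] for a curve of {n} barcodes")
    # forward difference at index j (0-based) spans ranks j+1 -> j+2
    window = slice(lo - 1, hi)
    j0 = lo - 1 + int(np.argmin(deriv_smooth[window]))
    j_lo = max(lo - 1, j0 - smoothing_window)
    j_hi = min(hi - 1, j0 + smoothing_window)
    j_star = j_lo + int(np.argmin(deriv_raw[j_lo : j_hi + 1]))
    if deriv_raw[j_star] > -slope_threshold:
        raise ValueError(
            "no steep drop found in the barcode-rank curve "
            f"(steepest log-log slope {deriv_raw[j_star]:.3f} > -{slope_threshold}); "
            "set the cell/empty cutoff manually"
        )
    return j_star + 1


def partition_droplets(
    experiment: DropletExperiment,
    inflection_rank: int | None = None,
    smoothing_window: int = 11,
    min_cells: int = 100,
    max_cells: int | None = None,
) -> DropletExperiment:
    """Assign droplet_class = cell for ranks <= inflection, empty otherwise.

    The rank curve is computed on the RNA modality; when RNA is absent the
    ADT totals are used as a logged fallback. With ``inflection_rank`` given,
    detection is skipped and the provided rank is used.
    """
    if experiment.rna is not None:
        source = experiment.rna
    else:
        logger.warning("partition_droplets: no RNA modality; falling back to ADT totals")
        source = experiment.adt
    curve = barcode_rank_curve(source)
    if inflection_rank is None:
        inflection_rank = find_inflection(
            curve, smoothing_window=smoothing_window, min_cells=min_cells, max_cells=max_cells
        )
    cells = set(curve.barcodes[:inflection_rank])
    classes = ["cell" if b in cells else "empty" for b in experiment.metadata.index]
    experiment.metadata["droplet_class"] = classes
    n_cells = len(cells)
    n_empty = len(classes) - n_cells
    if n_empty == 0:
        logger.warning("partition_droplets: zero empty droplets (inflection at the last barcode)")
    logger.info("partition_droplets: %d cell-containing, %d empty droplets", n_cells, n_empty)
    return experiment


def qc_filter(
    experiment: DropletExperiment,
    min_genes: int = 60,
    max_mito_pct: float = 15.0,
    mito_prefix: str = "MT-",
) -> list[str]:
    """Relabel low-quality cells as ``removed``; return the kept cell barcodes.

    A candidate cell is kept when it has at least ``min_genes`` detected
    genes and a mitochondrial read percentage strictly below
    ``max_mito_pct``. Only barcodes with droplet_class == cell are examined;
    removed barcodes count toward neither the cell nor the empty pool.
    """
    if experiment.rna is None:
        raise ValueError("qc_filter requires the RNA modality")
    cells = experiment.cell_barcodes
    if not cells:
        return []
    rna = experiment.rna.subset_barcodes(cells)
    genes_detected = np.asarray((rna.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(rna.counts.sum(axis=0)).ravel()
    mito_rows = [i for i, f in enumerate(rna.feature_ids) if f.startswith(mito_prefix)]
    keep = genes_detected >= min_genes
    if mito_rows:
        mito = np.asarray(rna.counts[mito_rows, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(totals > 0, 100.0 * mito / np.maximum(totals, 1), 0.0)
        keep &= mito_pct < max_mito_pct
    else:
        logger.warning("qc_filter: no genes match prefix %r; mitochondrial criterion skipped", mito_prefix)
    removed = [b for b, ok in zip(cells, keep) if not ok]
    if removed:
        experiment.metadata.loc[removed, "droplet_class"] = "removed"
        logger.info("qc_filter: removed %d of %d cells", len(removed), len(cells))
    return [b for b, ok in zip(cells, keep) if ok]


def demux_hto(
    experiment: DropletExperiment,
    dominance_ratio: float = 3.0,
    min_umis: int = 10,
) -> pd.Series:
    """Assign each kept cell to a sample from its HTO counts.

    A cell is assigned to the hashtag with the highest count when that count
    is at least ``min_umis`` and dominates the runner-up by
    ``dominance_ratio``; it is a ``doublet`` when two hashtags both clear
    ``min_umis`` without dominance, and ``negative`` otherwise. The
    assignment is stored in metadata column ``sample``.
    """
    if experiment.hto is None:
        raise ValueError("demux_hto requires the HTO modality")
    if experiment.hto.n_features == 1:
        logger.warning("demux_hto: single-hashtag panel; all cells are sample %s or negative",
                       experiment.hto.feature_ids[0])
    cells = experiment.cell_barcodes
    hto = experiment.hto.subset_barcodes(cells)
    dense = hto.to_dense()  # hashtags x cells
    names = hto.feature_ids
    assignments = {}
    for j, barcode in enumerate(cells):
        counts = dense[:, j]
        order = np.argsort(-counts, kind="stable")
        top, second = counts[order[0]], (counts[order[1]] if len(counts) > 1 else 0)
        if top >= min_umis and (second == 0 or top / second >= dominance_ratio):
            assignments[barcode] = names[order[0]]
        elif top >= min_umis and second >= min_umis and top / second < dominance_ratio:
            assignments[barcode] = "doublet"
        else:
            assignments[barcode] = "negative"
    result = pd.Series(assignments, name="sample")
    experiment.metadata.loc[result.index, "sample"] = result
    return result
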