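"""Per-antibody metric suite and titration responses.

All metrics operate on raw UMI counts after the droplet partition:

* ``total_umis_cells`` — marker UMIs summed over kept cells;
* ``q90_expressing`` — 90th-percentile UMI count within the expressing cell
  cluster (linear-interpolation quantile);
* ``detection_threshold`` — empirical quantile of the marker's empty-droplet
  counts (with a floor); a cell is positive when its count exceeds it;
* ``snr`` — median UMI count of positive cells minus median of negative
  cells, in UMIs;
* ``umis_per_positive_pct`` — percent of the panel's cell UMIs used per
  positive cell (library balancing);
* ``background_pct`` — percent of the marker's UMIs found in empty droplets;
* ``freq_cells`` / ``freq_empty`` / ``freq_ratio`` — the marker's share of
  panel UMIs within each compartment and their ratio (cell-enrichment).

The titration response between a reference and a diluted condition is the
log2 ratio of a metric with a pseudocount, and its deviation from
log2(dilution factor) measures departure from linear response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DropletExperiment, strip_conjugate_suffix

logger = logging.getLogger(__name__)

EXCLUDED_SAMPLES = ("doublet", "negative")


@dataclass
class MarkerMetrics:
    marker: str
    condition_id: str
    total_umis_cells: int
    q90_expressing: float
    detection_threshold: float
    positive_fraction: float
    snr: float
    umis_per_positive_pct: float  # NaN when no positive cells
    background_pct: float
    freq_cells: float
    freq_empty: float
    freq_ratio: float  # NaN when freq_empty == 0
    expressing_cluster: str | None = None
    n_positive: int = 0
    total_umis_empty: int = 0


@dataclass
class TitrationRecord:
    marker: str
    ref: MarkerMetrics
    dil: MarkerMetrics
    dilution_factor: float
    log2_response: dict[str, float] = field(default_factory=dict)
    linearity_deviation: dict[str, float] = field(default_factory=dict)


def detection_threshold(
    empty_counts: np.ndarray,
    quantile: float = 0.99,
    floor: float = 1.0,
) -> float:
    """UMI threshold above background from the empty-droplet distribution."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    empty_counts = np.asarray(empty_counts)
    if empty_counts.size < 100:
        logger.warning(
            "detection_threshold: only %d empty droplets (<100); falling back to the floor",
            empty_counts.size,
        )
        return float(floor)
    return float(max(floor, np.quantile(empty_counts, quantile)))


def _metric_cells(experiment: DropletExperiment) -> list[str]:
    """Kept cells entering metric computation (doublets/negatives excluded)."""
    meta = experiment.metadata
    mask = meta["droplet_class"] == "cell"
    if "sample" in meta.columns:
        mask &= ~meta["sample"].isin(EXCLUDED_SAMPLES)
    return list(meta.index[mask])


def compute_thresholds(
    experiment: DropletExperiment,
    quantile: float = 0.99,
    floor: float = 1.0,
) -> pd.Series:
    """Detection threshold for every ADT feature, from the empty droplets."""
    empty = experiment.adt_by_class("empty")
    values = {
        feature: detection_threshold(empty.feature_vector(feature), quantile, floor)
        for feature in experiment.adt.feature_ids
    }
    return pd.Series(values, name="detection_threshold")


def marker_metrics(
    experiment: DropletExperiment,
    marker: str,
    threshold: float | None = None,
    expressing_cluster: str | None = None,
    quantile: float = 0.99,
    floor: float = 1.0,
    per_cell_denominator: str = "panel",
) -> MarkerMetrics:
    """Compute the full metric suite for one marker at one condition.

    ``expressing_cluster`` defaults to the panel's annotation or, failing
    that, to the cell type with the highest per-cell mean for the marker.
    ``per_cell_denominator`` selects the denominator of
    ``umis_per_positive_pct``: the panel's total cell UMIs (default) or the
    marker's own (``"marker"``).
    """
    if marker not in experiment.adt.feature_ids:
        raise KeyError(f"unknown marker {marker!r}")
    cells = _metric_cells(experiment)
    if not cells:
        raise ValueError("no cells available; run the partition (and QC) first")
    empties = experiment.empty_barcodes

    adt_cells = experiment.adt.subset_barcodes(cells)
    adt_empty = experiment.adt.subset_barcodes(empties) if empties else None
    counts_cells = adt_cells.feature_vector(marker)
    counts_empty = adt_empty.feature_vector(marker) if adt_empty is not None else np.zeros(0, dtype=int)

    if threshold is None:
        threshold = detection_threshold(counts_empty, quantile, floor)

    base = strip_conjugate_suffix(marker)
    if expressing_cluster is None:
        expressing_cluster = experiment.panel.expected_cluster(base) if base in experiment.panel.markers else None
    cell_types = (
        experiment.metadata.loc[cells, "cell_type"]
        if "cell_type" in experiment.metadata.columns
        else pd.Series(index=pd.Index(cells), dtype=object)
    )
    if expressing_cluster is None and cell_types.notna().any():
        means = pd.Series(counts_cells, index=cells).groupby(cell_types).mean()
        expressing_cluster = str(means.sort_index().idxmax())
    if expressing_cluster is not None and cell_types.notna().any():
        in_cluster = counts_cells[(cell_types == expressing_cluster).to_numpy()]
        if in_cluster.size == 0:
            raise ValueError(f"no cells in expressing cluster {expressing_cluster!r}")
    else:
        in_cluster = counts_cells
    q90 = float(np.quantile(in_cluster, 0.9)) if in_cluster.size else float("nan")

    positive = counts_cells > threshold
    n_pos = int(positive.sum())
    positive_fraction = n_pos / len(cells)
    if n_pos == 0:
        snr = 0.0
    else:
        median_pos = float(np.median(counts_cells[positive]))
        median_neg = float(np.median(counts_cells[~positive])) if (~positive).any() else 0.0
        snr = median_pos - median_neg

    total_cells_marker = int(counts_cells.sum())
    total_empty_marker = int(counts_empty.sum())
    panel_total_cells = int(adt_cells.counts.sum())
    panel_total_empty = int(adt_empty.counts.sum()) if adt_empty is not None else 0

    if n_pos == 0:
        umis_per_positive_pct = float("nan")
    else:
        numerator = total_cells_marker if per_cell_denominator == "marker" else total_cells_marker
        denom = total_cells_marker if per_cell_denominator == "marker" else panel_total_cells
        umis_per_positive_pct = 100.0 * (numerator / denom) / n_pos if denom else float("nan")

    marker_total = total_cells_marker + total_empty_marker
    background_pct = 100.0 * total_empty_marker / marker_total if marker_total else 0.0
    freq_cells = total_cells_marker / panel_total_cells if panel_total_cells else 0.0
    freq_empty = total_empty_marker / panel_total_empty if panel_total_empty else 0.0
    freq_ratio = freq_cells / freq_empty if freq_empty > 0 else float("nan")

    return MarkerMetrics(
        marker=marker,
        condition_id=experiment.condition.condition_id,
        total_umis_cells=total_cells_marker,
        q90_expressing=q90,
        detection_threshold=float(threshold),
        positive_fraction=positive_fraction,
        snr=snr,
        umis_per_positive_pct=umis_per_positive_pct,
        background_pct=background_pct,
        freq_cells=freq_cells,
        freq_empty=freq_empty,
        freq_ratio=freq_ratio,
        expressing_cluster=expressing_cluster,
        n_positive=n_pos,
        total_umis_empty=total_empty_marker,
    )


RESPONSE_METRICS = ("total_umis_cells", "q90_expressing")


def titration_response(
    ref: MarkerMetrics,
    dil: MarkerMetrics,
    dilution_factor: float,
    pseudocount: float = 1.0,
) -> TitrationRecord:
    """log2 response of each metric to dilution, and deviation from linearity."""
    if ref.marker != dil.marker:
        raise ValueError(f"marker mismatch: {ref.marker!r} vs {dil.marker!r}")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    expected = math.log2(dilution_factor)
    record = TitrationRecord(marker=ref.marker, ref=ref, dil=dil, dilution_factor=dilution_factor)
    for name in RESPONSE_METRICS:
        a = getattr(ref, name) + pseudocount
        b = getattr(dil, name) + pseudocount
        response = math.log2(a / b)
        record.log2_response[name] = response
        record.linearity_deviation[name] = abs(response - expected)
    return record


def metrics_to_frame(metrics: list[MarkerMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append({
            "marker": m.marker,
            "condition_id": m.condition_id,
            "total_umis_cells": m.total_umis_cells,
            "total_umis_empty": m.total_umis_empty,
            "q90_expressing": m.q90_expressing,
            "detection_threshold": m.detection_threshold,
            "positive_fraction": m.positive_fraction,
            "n_positive": m.n_positive,
            "snr": m.snr,
            "umis_per_positive_pct": m.umis_per_positive_pct,
            "background_pct": m.background_pct,
            "freq_cells": m.freq_cells,
            "freq_empty": m.freq_empty,
            "freq_ratio": m.freq_ratio,
            "expressing_cluster": m.expressing_cluster,
        })
    return pd.DataFrame(rows)


def responses_to_frame(records: list[TitrationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "marker": r.marker,
            "ref_condition": r.ref.condition_id,
            "dil_condition": r.dil.condition_id,
            "dilution_factor": r.dilution_factor,
        }
        for name in RESPONSE_METRICS:
            row[f"log2_response_{name}"] = r.log2_response[name]
            row[f"linearity_deviation_{name}"] = r.linearity_deviation[name]
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_table(
    experiments: dict[str, DropletExperiment],
    quantile: float = 0.99,
    floor: float = 1.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, MarkerMetrics]]]:
    """Metric suite for every (marker, condition) plus pairwise responses.

    Conditions must share the ADT panel. The condition with the smallest
    dilution factor is the reference; a titration record is produced for
    every other condition against it. Returns the long-form metrics frame,
    the responses frame, and the nested MarkerMetrics objects
    (condition -> marker -> metrics) for downstream classification.
    """
    if not experiments:
        raise ValueError("no experiments supplied")
    cond_ids = sorted(experiments, key=lambda c: (experiments[c].condition.dilution_factor, c))
    feature_sets = [tuple(experiments[c].adt.feature_ids) for c in cond_ids]
    if len(set(feature_sets)) != 1:
        raise ValueError("conditions have different ADT panels")
    markers = list(feature_sets[0])

    all_metrics: dict[str, dict[str, MarkerMetrics]] = {}
    for cond in cond_ids:
        exp = experiments[cond]
        thresholds = compute_thresholds(exp, quantile, floor)
        all_metrics[cond] = {
            marker: marker_metrics(exp, marker, threshold=thresholds[marker], quantile=quantile, floor=floor)
            for marker in markers
        }

    records: list[TitrationRecord] = []
    ref_cond = cond_ids[0]
    ref_df = experiments[ref_cond].condition.dilution_factor
    for cond in cond_ids[1:]:
        factor = experiments[cond].condition.dilution_factor / ref_df
        if factor <= 1:
            logger.warning("metrics_table: condition %s is not a dilution of %s; skipped", cond, ref_cond)
            continue
        for marker in markers:
            records.append(
                titration_response(all_metrics[ref_cond][marker], all_metrics[cond][marker], factor, pseudocount)
            )

    metrics_frame = metrics_to_frame([all_metrics[c][m] for c in cond_ids for m in markers])
    responses_frame = responses_to_frame(records)
    return metrics_frame, responses_frame, all_metrics
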