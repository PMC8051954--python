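"""Titration plots and the end-to-end pipeline.

Every figure writes a machine-readable sidecar CSV of its plotted values so
that output can be verified without image comparison. ``run_pipeline``
orchestrates the full sequence — simulate (or load) -> partition -> QC ->
demultiplex -> metrics -> classify -> recommend -> cost — and emits CSV
artifacts plus a run log sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .adt_metrics import metrics_table
from .cost_model import DEFAULT_PRICE_USD_PER_UG, comparison_stats, panel_cost, read_allocation
from .data_model import (
    AntibodyPanel,
    DropletExperiment,
    StainingCondition,
    build_experiment,
    read_counts_csv,
    read_counts_mtx,
    read_metadata_csv,
)
from .droplet_partition import demux_hto, partition_droplets, qc_filter
from .panel_classify import ClassifierConfig, adjust_panel, classify_marker, recommend_adjustment
from .synthetic_data import MarkerSpec, SimConfig, archetype_panel, simulate_titration_lane

logger = logging.getLogger(__name__)

CELL_TYPE_CMAP = "tab10"


def _log1p10(values: np.ndarray) -> np.ndarray:
    # log10(count + 1): zero-preserving transform for the count axis
    return np.log10(np.asarray(values, dtype=float) + 1.0)


def titration_plot(
    marker: str,
    experiments: Mapping[str, DropletExperiment],
    thresholds: Mapping[str, float],
    out_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> Path:
    """UMI count vs. cell rank per condition, with gating threshold and
    cell-type strip.

    For each condition the marker's kept-cell counts are plotted against
    descending rank on a log10(count+1) axis, with a marginal histogram, a
    horizontal line at the detection threshold, a strip showing cell type by
    rank, and the total cell-UMI count annotated. A sidecar CSV of the
    plotted values (condition, rank, count, cell type) is always written.
    """
    out_path = Path(out_path)
    conditions = sorted(experiments)
    for cond in conditions:
        if marker not in experiments[cond].adt.feature_ids:
            raise KeyError(f"unknown marker {marker!r} in condition {cond}")

    rows = []
    for cond in conditions:
        exp = experiments[cond]
        cells = exp.cell_barcodes
        counts = exp.adt.subset_barcodes(cells).feature_vector(marker)
        types = (
            exp.metadata.loc[cells, "cell_type"].to_numpy()
            if "cell_type" in exp.metadata.columns
            else np.array([None] * len(cells))
        )
        order = np.argsort(-counts, kind="stable")
        for rank, idx in enumerate(order, start=1):
            rows.append({
                "condition": cond,
                "rank": rank,
                "count": int(counts[idx]),
                "cell_type": types[idx],
            })
    sidecar = pd.DataFrame(rows, columns=["condition", "rank", "count", "cell_type"])
    sidecar_path = Path(sidecar_path) if sidecar_path else out_path.with_suffix(".csv")
    sidecar.to_csv(sidecar_path, index=False)

    all_types = sorted({t for t in sidecar["cell_type"].dropna().unique()})
    cmap = plt.get_cmap(CELL_TYPE_CMAP)
    type_color = {t: cmap(i % 10) for i, t in enumerate(all_types)}

    n = len(conditions)
    fig = plt.figure(figsize=(8, 4 + 0.3 * n))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[4, 1], height_ratios=[4, 0.4 * n], hspace=0.1, wspace=0.05
    )
    ax = fig.add_subplot(gs[0, 0])
    ax_hist = fig.add_subplot(gs[0, 1], sharey=ax)
    ax_strip = fig.add_subplot(gs[1, 0], sharex=ax)

    for k, cond in enumerate(conditions):
        sub = sidecar[sidecar["condition"] == cond]
        y = _log1p10(sub["count"].to_numpy())
        ax.plot(sub["rank"], y, drawstyle="steps-post", label=f"{cond} (n={int(sub['count'].sum())} UMIs)")
        ax_hist.hist(y, bins=30, orientation="horizontal", histtype="step")
        threshold = thresholds.get(cond)
        if threshold is not None:
            ax.axhline(_log1p10(np.array([threshold]))[0], linestyle="--", linewidth=0.8, color=f"C{k}")
        colors = [type_color.get(t, (0.8, 0.8, 0.8, 1.0)) for t in sub["cell_type"]]
        ax_strip.scatter(sub["rank"], np.full(len(sub), k), c=colors, marker="|", s=40)
    ax.set_ylabel("log10(UMI count + 1)")
    ax.legend(fontsize=8)
    ax.set_title(marker)
    ax_strip.set_yticks(range(n), conditions, fontsize=7)
    ax_strip.set_xlabel("cell rank")
    ax_strip.set_ylim(-0.5, n - 0.5)
    handles = [plt.Line2D([], [], marker="|", linestyle="", color=type_color[t], label=t) for t in all_types]
    if handles:
        ax_strip.legend(handles=handles, fontsize=6, ncol=min(4, len(handles)), loc="upper right")
    plt.setp(ax_hist.get_yticklabels(), visible=False)
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _condition_from_dict(spec: dict) -> StainingCondition:
    return StainingCondition(
        condition_id=str(spec["condition_id"]),
        volume_ul=float(spec.get("volume_ul", 50.0)),
        cells_stained=float(spec.get("cells_stained", 1e6)),
        dilution_factor=float(spec.get("dilution_factor", 1.0)),
        tissue=str(spec.get("tissue", "PBMC")),
    )


def _markers_from_config(sim_cfg: dict) -> list[MarkerSpec]:
    if sim_cfg.get("archetypes", True) and "markers" not in sim_cfg:
        return archetype_panel()
    return [
        MarkerSpec(
            name=m["name"],
            concentration_ug_ml=float(m["concentration_ug_ml"]),
            kd_ug_ml=float(m["kd_ug_ml"]),
            epitopes_per_cell={k: float(v) for k, v in m.get("epitopes_per_cell", {}).items()},
            ground_truth_category=m.get("ground_truth_category"),
        )
        for m in sim_cfg["markers"]
    ]


def _load_matrix(path_spec: str):
    path = Path(path_spec)
    if path.is_dir():
        return read_counts_mtx(path)
    return read_counts_csv(path)


def _experiments_from_config(config: dict) -> tuple[dict[str, DropletExperiment], dict]:
    """Build per-condition experiments from a config: simulation or files."""
    truths = {}
    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        conditions = [_condition_from_dict(c) for c in sim_cfg.pop("conditions")]
        markers = _markers_from_config(sim_cfg)
        sim_kwargs = {
            k: v
            for k, v in sim_cfg.items()
            if k in SimConfig.__dataclass_fields__
        }
        sim_kwargs.setdefault("seed", int(config.get("seed", 0)))
        sim = SimConfig(**sim_kwargs)
        lane = simulate_titration_lane(sim, markers, conditions)
        experiments = {cid: exp for cid, (exp, _) in lane.items()}
        truths = {cid: truth for cid, (_, truth) in lane.items()}
        return experiments, truths
    if "inputs" not in config:
        raise KeyError("config needs either a 'simulate' or an 'inputs' section")
    inputs = config["inputs"]
    if "panel" not in inputs:
        raise KeyError("config key 'inputs.panel' is missing")
    panel = AntibodyPanel.read_csv(inputs["panel"])
    experiments = {}
    for spec in inputs["conditions"]:
        condition = _condition_from_dict(spec)
        adt = _load_matrix(spec["adt"])
        rna = _load_matrix(spec["rna"]) if "rna" in spec else None
        hto = _load_matrix(spec["hto"]) if "hto" in spec else None
        metadata = read_metadata_csv(spec["metadata"]) if "metadata" in spec else None
        experiments[condition.condition_id] = build_experiment(
            adt=adt, panel=panel, condition=condition, rna=rna, hto=hto, metadata=metadata
        )
    return experiments, truths


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full titration analysis and write its artifacts.

    Emits partition.csv, metrics.csv, responses.csv, recommendations.csv,
    adjusted_panel.csv, cost.csv, allocation.csv, figures/ (with sidecar
    CSVs) and run_log.json into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    experiments, truths = _experiments_from_config(config)
    cond_ids = sorted(experiments, key=lambda c: (experiments[c].condition.dilution_factor, c))

    partition_cfg = config.get("partition", {})
    partition_rows = []
    for cid in cond_ids:
        exp = experiments[cid]
        partition_droplets(
            exp,
            smoothing_window=int(partition_cfg.get("smoothing_window", 11)),
            min_cells=int(partition_cfg.get("min_cells", 100)),
            max_cells=partition_cfg.get("max_cells"),
        )
        if exp.rna is not None:
            qc_filter(
                exp,
                min_genes=int(partition_cfg.get("min_genes", 60)),
                max_mito_pct=float(partition_cfg.get("max_mito_pct", 15.0)),
            )
        if exp.hto is not None:
            demux_hto(exp)
        totals = exp.adt.barcode_totals()
        rna_totals = exp.rna.barcode_totals() if exp.rna is not None else None
        for barcode in exp.barcodes:
            partition_rows.append({
                "condition": cid,
                "barcode": barcode,
                "droplet_class": exp.metadata.at[barcode, "droplet_class"],
                "sample": exp.metadata.at[barcode, "sample"] if "sample" in exp.metadata.columns else None,
                "adt_total": int(totals[barcode]),
                "rna_total": int(rna_totals[barcode]) if rna_totals is not None else None,
            })
    pd.DataFrame(partition_rows).to_csv(out / "partition.csv", index=False)

    metric_cfg = config.get("metrics", {})
    metrics_frame, responses_frame, all_metrics = metrics_table(
        experiments,
        quantile=float(metric_cfg.get("quantile", 0.99)),
        floor=float(metric_cfg.get("floor", 1.0)),
    )
    metrics_frame.to_csv(out / "metrics.csv", index=False)
    responses_frame.to_csv(out / "responses.csv", index=False)

    ref_cond = cond_ids[0]
    allocation_frames = []
    for cid in cond_ids:
        sub = metrics_frame[metrics_frame["condition_id"] == cid]
        alloc, background_share = read_allocation(sub)
        alloc.insert(0, "condition", cid)
        alloc["panel_background_share"] = background_share
        allocation_frames.append(alloc)
    pd.concat(allocation_frames, ignore_index=True).to_csv(out / "allocation.csv", index=False)

    recommendations = {}
    classifier = ClassifierConfig(**config.get("classifier", {}))
    panel = experiments[ref_cond].panel
    if len(cond_ids) > 1:
        from .adt_metrics import titration_response

        dil_cond = cond_ids[-1]  # classify against the strongest dilution
        factor = (
            experiments[dil_cond].condition.dilution_factor
            / experiments[ref_cond].condition.dilution_factor
        )
        rec_rows = []
        for marker in experiments[ref_cond].adt.feature_ids:
            record = titration_response(
                all_metrics[ref_cond][marker], all_metrics[dil_cond][marker], factor
            )
            category = classify_marker(record, classifier)
            rec = recommend_adjustment(
                category, panel.concentration(marker, ref_cond), record, classifier
            )
            recommendations[marker] = rec
            rec_rows.append({
                "marker": marker,
                "category": category,
                "action": rec.action,
                "multiplier": rec.multiplier,
                "drop_suggested": rec.drop_suggested,
                "review_flag": rec.review_flag,
                "rationale": rec.rationale,
            })
        pd.DataFrame(rec_rows).to_csv(out / "recommendations.csv", index=False)
        adjusted, audit = adjust_panel(panel, recommendations, source_condition=ref_cond)
        adjusted.write_csv(out / "adjusted_panel.csv")
        audit.to_csv(out / "panel_audit.csv", index=False)

        cost_cfg = config.get("cost", {})
        price = float(cost_cfg.get("price_usd_per_ug", DEFAULT_PRICE_USD_PER_UG))
        volume = float(cost_cfg.get("volume_ul", experiments[ref_cond].condition.volume_ul))
        before = panel_cost(panel, volume, price, condition_id=ref_cond)
        after = panel_cost(adjusted, volume, price, condition_id="adjusted")
        stats = comparison_stats(before, after) if after > 0 else {"fold_change": float("nan"), "percent_change": float("nan")}
        pd.DataFrame([
            {"quantity": "panel_cost_usd_ref", "value": before},
            {"quantity": "panel_cost_usd_adjusted", "value": after},
            {"quantity": "cost_fold_change", "value": stats["fold_change"]},
            {"quantity": "cost_percent_change", "value": stats["percent_change"]},
        ]).to_csv(out / "cost.csv", index=False)

    for cid, truth in truths.items():
        truth.table.reset_index().to_csv(out / f"truth_{cid}.csv", index=False)

    if config.get("figures", True):
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        thresholds_by_cond = {
            cid: {m.marker: m.detection_threshold for m in all_metrics[cid].values()}
            for cid in cond_ids
        }
        for marker in experiments[ref_cond].adt.feature_ids:
            titration_plot(
                marker,
                experiments,
                {cid: thresholds_by_cond[cid][marker] for cid in cond_ids},
                fig_dir / f"{marker}.{config.get('figure_format', 'png')}",
            )

    class_counts = {
        cid: experiments[cid].metadata["droplet_class"].value_counts().to_dict() for cid in cond_ids
    }
    run_log = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "conditions": cond_ids,
        "droplet_class_counts": class_counts,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True, default=str) + "\n")
    return out
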