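"""Titration-response categories A-E and concentration recommendations.

Each antibody's paired (reference, diluted) metric record is assigned one of
five categories:

* **A** — no response to dilution; positive signal saturated, absent, or
  obscured by high background. Reduce concentration.
* **B** — responds to dilution without losing the positive/negative
  separation. Reduce: economically beneficial.
* **C** — responds, but dilution erodes the separation or drags the
  detection threshold down to a few UMIs. Keep (or reduce slightly).
* **D** — (almost) ubiquitously expressed target sequestering many UMIs.
  Reduce, and consider dropping from the panel.
* **E** — no convincing positive population (missing epitope or
  non-functional antibody). Increase concentration and review.

The published category assignment was by expert inspection; here every
decision boundary is an explicit, documented config value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adt_metrics import MarkerMetrics, TitrationRecord
from .data_model import AntibodyPanel

logger = logging.getLogger(__name__)

CATEGORIES = ("A", "B", "C", "D", "E", "review")

#: cross-tissue reconciliation priority: a marker separating anywhere is not dead
TISSUE_PRIORITY = ("D", "B", "C", "A", "E", "review")


@dataclass
class ClassifierConfig:
    """Decision boundaries for the A-E classifier.

    r_min    minimal |log2 response| of the 90th-percentile signal to count
             as responding to dilution (log2 units).
    s_min    minimal signal-to-noise (median positive - median negative, in
             UMIs) to count as separating positive from negative cells.
    f_min    minimal positive fraction regarded as a real population; used
             to annotate rationale only.
    u_min    positive-fraction threshold for a ubiquitously expressed target.
    b_high   background percentage above which signal counts as obscured.
    e_max    maximal share of the panel's cell UMIs for a dead (category E)
             marker.
    t_low    "only a few UMIs" detection threshold for category C.
    """

    r_min: float = 0.5
    s_min: float = 5.0
    f_min: float = 0.005
    u_min: float = 0.90
    b_high: float = 50.0
    e_max: float = 0.002
    t_low: float = 3.0
    multipliers: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.5, "C": 1.0, "D": 0.25, "E": 3.0, "review": 1.0}
    )
    c_reduce_multiplier: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.u_min <= 1 or not 0 <= self.f_min <= 1:
            raise ValueError("u_min and f_min must be fractions")
        if not 0 <= self.b_high <= 100:
            raise ValueError("b_high is a percentage")
        if self.r_min < 0 or self.s_min < 0 or self.e_max < 0 or self.t_low < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class Recommendation:
    marker: str
    category: str
    action: str  # reduce | keep | increase | drop | review
    multiplier: float
    rationale: str
    drop_suggested: bool = False
    review_flag: bool = False

    def __post_init__(self) -> None:
        if self.action != "drop" and self.multiplier <= 0:
            raise ValueError("multiplier must be > 0 unless the action is drop")


def classify_marker(record: TitrationRecord, config: ClassifierConfig | None = None) -> str:
    """Assign a category by the first matching rule, evaluated in order D, E, A, B, C."""
    cfg = config or ClassifierConfig()
    ref, dil = record.ref, record.dil
    response = record.log2_response.get("q90_expressing", float("nan"))
    both_dim = ref.snr < cfg.s_min and dil.snr < cfg.s_min

    if ref.positive_fraction >= cfg.u_min and ref.snr >= cfg.s_min:
        return "D"
    if both_dim and ref.freq_cells < cfg.e_max:
        return "E"
    if np.isfinite(response) and abs(response) < cfg.r_min and (both_dim or ref.background_pct >= cfg.b_high):
        return "A"
    if np.isfinite(response) and response >= cfg.r_min and ref.snr >= cfg.s_min and dil.snr >= cfg.s_min:
        return "B"
    if (
        np.isfinite(response)
        and response >= cfg.r_min
        and ref.snr >= cfg.s_min
        and (dil.snr < cfg.s_min or dil.detection_threshold <= cfg.t_low)
    ):
        return "C"
    return "review"


def _metrics_from_row(row: pd.Series) -> MarkerMetrics:
    return MarkerMetrics(
        marker=str(row["marker"]),
        condition_id=str(row["condition_id"]),
        total_umis_cells=int(row["total_umis_cells"]),
        q90_expressing=float(row["q90_expressing"]),
        detection_threshold=float(row["detection_threshold"]),
        positive_fraction=float(row["positive_fraction"]),
        snr=float(row["snr"]),
        umis_per_positive_pct=float(row["umis_per_positive_pct"]),
        background_pct=float(row["background_pct"]),
        freq_cells=float(row["freq_cells"]),
        freq_empty=float(row["freq_empty"]),
        freq_ratio=float(row["freq_ratio"]),
        n_positive=int(row.get("n_positive", 0)),
        total_umis_empty=int(row.get("total_umis_empty", 0)),
    )


def records_from_frames(metrics: pd.DataFrame, responses: pd.DataFrame) -> dict[str, TitrationRecord]:
    """Rebuild TitrationRecords from the long-form metrics/responses CSVs."""
    indexed = metrics.set_index(["marker", "condition_id"])

    def metrics_at(marker: str, condition: str) -> MarkerMetrics:
        row = indexed.loc[(marker, condition)].copy()
        row["marker"] = marker
        row["condition_id"] = condition
        return _metrics_from_row(row)

    records: dict[str, TitrationRecord] = {}
    for _, row in responses.iterrows():
        marker = str(row["marker"])
        record = TitrationRecord(
            marker=marker,
            ref=metrics_at(marker, str(row["ref_condition"])),
            dil=metrics_at(marker, str(row["dil_condition"])),
            dilution_factor=float(row["dilution_factor"]),
        )
        for name in ("total_umis_cells", "q90_expressing"):
            record.log2_response[name] = float(row[f"log2_response_{name}"])
            record.linearity_deviation[name] = float(row[f"linearity_deviation_{name}"])
        records[marker] = record
    return records


def reconcile_categories(per_tissue: dict[str, str]) -> str:
    """Combine per-tissue categories: a marker separating in any tissue is not dead."""
    if not per_tissue:
        raise ValueError("no per-tissue categories to reconcile")
    for category in TISSUE_PRIORITY:
        if category in per_tissue.values():
            return category
    return "review"


def recommend_adjustment(
    category: str,
    current_conc: float,
    record: TitrationRecord,
    config: ClassifierConfig | None = None,
) -> Recommendation:
    """Concentration recommendation for a classified marker."""
    cfg = config or ClassifierConfig()
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    ref, dil = record.ref, record.dil
    multiplier = cfg.multipliers[category]
    drop_suggested = False
    review_flag = False
    if category == "A":
        action = "reduce"
        rationale = (
            f"no dilution response (log2 response {record.log2_response['q90_expressing']:.2f}) "
            f"with background {ref.background_pct:.0f}%; signal saturated, absent or obscured"
        )
    elif category == "B":
        action = "reduce"
        rationale = (
            f"responds to dilution (log2 response {record.log2_response['q90_expressing']:.2f}) "
            f"while separation holds (snr {ref.snr:.0f} -> {dil.snr:.0f} UMIs)"
        )
    elif category == "C":
        if ref.detection_threshold > 2 * cfg.t_low:
            multiplier = cfg.c_reduce_multiplier
            action = "reduce"
            rationale = (
                f"dilution erodes separation (snr {dil.snr:.1f} UMIs, threshold {dil.detection_threshold:.0f}) "
                f"but reference threshold {ref.detection_threshold:.0f} leaves headroom for a slight reduction"
            )
        else:
            action = "keep"
            rationale = (
                f"dilution erodes separation (snr {dil.snr:.1f} UMIs, "
                f"threshold {dil.detection_threshold:.0f} UMIs); keep the concentration"
            )
    elif category == "D":
        action = "reduce"
        drop_suggested = True
        rationale = (
            f"ubiquitous target ({100 * ref.positive_fraction:.0f}% positive cells) sequestering "
            f"{100 * ref.freq_cells:.1f}% of cell UMIs; reduce, and consider dropping from the panel"
        )
    elif category == "E":
        action = "increase"
        review_flag = True
        population = (
            "no convincing positive population"
            if ref.positive_fraction < cfg.f_min
            else "weak positive population"
        )
        rationale = (
            f"{population} (snr {ref.snr:.1f}/{dil.snr:.1f} UMIs, panel share "
            f"{100 * ref.freq_cells:.2f}%); increase concentration or try a different clone"
        )
    else:
        action = "review"
        review_flag = True
        rationale = "rules inconclusive; inspect the titration plot"
    return Recommendation(
        marker=record.marker,
        category=category,
        action=action,
        multiplier=multiplier,
        rationale=rationale,
        drop_suggested=drop_suggested,
        review_flag=review_flag,
    )


def adjust_panel(
    panel: AntibodyPanel,
    recommendations: dict[str, Recommendation],
    source_condition: str,
    new_condition: str = "adjusted",
    confirm_drops: bool = False,
) -> tuple[AntibodyPanel, pd.DataFrame]:
    """Apply recommendations to a panel, producing the adjusted concentrations.

    Every marker needs a recommendation. Drop-suggested markers are removed
    only when ``confirm_drops`` is set; the returned audit frame records
    old -> new concentration (NaN new value = dropped).
    """
    if not recommendations:
        raise ValueError("empty recommendation set")
    missing = [m for m in panel.markers if m not in recommendations]
    if missing:
        raise ValueError(f"markers without a recommendation: {missing}")
    old = panel.concentrations(source_condition)
    audit_rows = []
    new_table = panel.table.copy()
    dropped = []
    for marker in panel.markers:
        rec = recommendations[marker]
        if confirm_drops and rec.drop_suggested:
            dropped.append(marker)
            new_value = float("nan")
        else:
            new_value = old[marker] * rec.multiplier
        audit_rows.append({
            "marker": marker,
            "category": rec.category,
            "action": rec.action,
            "multiplier": rec.multiplier,
            "old_concentration_ug_ml": old[marker],
            "new_concentration_ug_ml": new_value,
            "dropped": marker in dropped,
        })
        if marker not in dropped:
            new_table.loc[marker, f"concentration_{new_condition}"] = new_value
    if dropped:
        logger.info("adjust_panel: dropped markers %s", dropped)
        new_table = new_table.drop(index=dropped)
    audit = pd.DataFrame(audit_rows)
    return AntibodyPanel(new_table), audit
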