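"""Droplet-experiment simulator with known ground truth.

The generative model realizes, mechanistically, the phenomena a titration
experiment manipulates:

* **Equilibrium binding with depletion.** Each antibody binds its epitope
  pool by single-site equilibrium. With total antibody concentration
  ``C_tot``, total epitope concentration ``R_tot`` (cells stained x epitope
  copies per cell, expressed in the same ug/mL units via the IgG molecular
  weight) and dissociation constant ``Kd``, the free concentration is the
  nonnegative root of ``C_free^2 + (R_tot + Kd - C_tot) C_free - Kd C_tot = 0``
  and per-epitope occupancy is ``theta = C_free / (C_free + Kd)``. This is
  the simplest model exhibiting the saturation plateau, the linear
  concentration range, and the staining-volume and cell-number effects.
* **Ambient background from residual free antibody.** A fraction
  ``wash_retention`` of post-equilibrium free antibody survives the washes
  into the emulsion and is Poisson-distributed over all droplets — cell
  containing and empty alike — at rate ``ambient_scale x wash_retention x
  C_free`` per droplet. Markers stained at high concentration against
  absent epitopes therefore dominate the empty droplets.
* **Pooled lanes share one ambient pool.** When several staining conditions
  are hashed into a single lane, the free-antibody pool they release is
  common to every droplet: :func:`simulate_titration_lane` pools C_free
  across conditions so that background does not titrate with any single
  condition, which is why obscured markers show no apparent dilution
  response.
* **Finite depth.** Each captured molecule is observed with probability
  ``1 - exp(-reads_per_umi)`` (Poisson-reads approximation), applied as
  binomial thinning.

RNA counts are a deliberately minimal two-component mixture (cells deep,
ambient shallow) — just enough to exercise barcode-rank partitioning and QC,
not a realistic transcriptome. Epitope copy numbers are fixed per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import (
    AntibodyPanel,
    CountMatrix,
    DropletExperiment,
    StainingCondition,
    build_experiment,
)

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
IGG_MW_DA = 150_000.0  # molecular weight used for antibody/epitope molarity conversion
UG_PER_MOLECULE = IGG_MW_DA / AVOGADRO * 1e6


@dataclass
class MarkerSpec:
    """Simulation parameters for one antibody.

    ``concentration_ug_ml`` is the staining concentration at dilution factor
    1; ``epitopes_per_cell`` maps cell type -> epitope copies (absent types
    carry none); ``ground_truth_category`` labels archetype markers.
    """

    name: str
    concentration_ug_ml: float
    kd_ug_ml: float
    epitopes_per_cell: dict[str, float] = field(default_factory=dict)
    ground_truth_category: str | None = None

    def __post_init__(self) -> None:
        if self.kd_ug_ml <= 0:
            raise ValueError("kd must be > 0")
        if self.concentration_ug_ml < 0:
            raise ValueError("concentration must be >= 0")
        if any(v < 0 for v in self.epitopes_per_cell.values()):
            raise ValueError("epitope copies must be >= 0")

    def epitopes(self, cell_type: str) -> float:
        return float(self.epitopes_per_cell.get(cell_type, 0.0))


DEFAULT_CELL_TYPES = {"T": 0.45, "B": 0.20, "Mono": 0.20, "NK": 0.15}


@dataclass
class SimConfig:
    """Study conditions of the simulated droplet run.

    Defaults mirror a super-loaded lane in miniature: empty droplets
    outnumber cells tenfold, four immune cell types, 50 uL staining of 1e6
    cells (set per condition), a few percent of free antibody retained
    through the washes, and near-saturating sequencing depth.
    """

    cell_type_proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    n_cells: int = 500
    n_empty: int = 5000
    wash_retention: float = 0.05
    capture_efficiency: float = 0.02
    ambient_scale: float = 130.0
    reads_per_umi: float = 3.0
    rna_genes: int = 120
    rna_mito_genes: int = 6
    rna_mean_cell_total: float = 1000.0
    rna_mean_empty_total: float = 10.0
    hto_cell_rate: float = 150.0
    hto_ambient_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_type_proportions:
            raise ValueError("need at least one cell type")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {total}, not 1")
        if self.n_cells <= 0 or self.n_empty < 0:
            raise ValueError("n_cells must be > 0 and n_empty >= 0")
        if not 0 <= self.wash_retention <= 1:
            raise ValueError("wash_retention must be in [0, 1]")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.ambient_scale < 0 or self.reads_per_umi <= 0:
            raise ValueError("ambient_scale >= 0 and reads_per_umi > 0 required")


@dataclass
class SimTruth:
    """Ground truth for one simulated condition: per-marker table with
    columns c_tot, r_tot, c_free, theta, lambda_ambient, mean_specific,
    expected_background_fraction, category."""

    condition_id: str
    table: pd.DataFrame
    ambient_c_free: pd.Series  # the (possibly pooled) free concentration driving ambient

    @property
    def expected_panel_background_share(self) -> float:
        """Expected share of all panel UMIs found in empty droplets."""
        t = self.table
        empty = t["n_empty"] * t["lambda_ambient"]
        cells = t["n_cells"] * (t["mean_specific"] + t["lambda_ambient"])
        return float(empty.sum() / (empty.sum() + cells.sum()))


# ---------------------------------------------------------------------------
# Equilibrium binding
# ---------------------------------------------------------------------------

def free_antibody_equilibrium(c_tot, r_tot, kd):
    """Free antibody concentration at single-site equilibrium with depletion.

    Solves ``C_free + R_tot * C_free / (C_free + Kd) = C_tot`` in closed
    form (the unique nonnegative root of the mass-balance quadratic), in a
    cancellation-safe formulation. Accepts scalars or arrays.
    """
    c_tot = np.asarray(c_tot, dtype=float)
    r_tot = np.asarray(r_tot, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be > 0")
    if np.any(c_tot < 0) or np.any(r_tot < 0):
        raise ValueError("concentrations must be >= 0")
    b = r_tot + kd - c_tot
    disc = np.sqrt(b * b + 4.0 * kd * c_tot)
    # two algebraically equal forms; pick the one avoiding subtraction of near-equal terms
    denom = b + disc
    ratio_form = np.divide(
        2.0 * kd * c_tot, denom, out=np.zeros(np.broadcast(b, disc).shape), where=denom > 0
    )
    result = np.where(b > 0, ratio_form, (disc - b) / 2.0)
    result = np.where(c_tot == 0, 0.0, result)
    return result.item() if result.ndim == 0 else result


def occupancy(c_free, kd):
    """Equilibrium epitope occupancy theta = C_free / (C_free + Kd)."""
    c_free = np.asarray(c_free, dtype=float)
    kd = np.asarray(kd, dtype=float)
    result = np.where(c_free == 0, 0.0, c_free / (c_free + kd))
    return result.item() if result.ndim == 0 else result


def epitope_pool_concentration(
    mean_epitopes_per_cell: float, cells_stained: float, volume_ul: float
) -> float:
    """Total epitope concentration in ug/mL equivalents (IgG molecular weight)."""
    if volume_ul <= 0:
        raise ValueError("volume must be > 0")
    molecules = mean_epitopes_per_cell * cells_stained
    return molecules * UG_PER_MOLECULE / (volume_ul / 1000.0)


def marker_equilibrium(
    marker: MarkerSpec,
    condition: StainingCondition,
    proportions: Mapping[str, float],
) -> tuple[float, float, float, float]:
    """(c_tot, r_tot, c_free, theta) for a marker at one staining condition."""
    c_tot = marker.concentration_ug_ml / condition.dilution_factor
    mean_epitopes = sum(proportions[t] * marker.epitopes(t) for t in proportions)
    r_tot = epitope_pool_concentration(mean_epitopes, condition.cells_stained, condition.volume_ul)
    c_free = free_antibody_equilibrium(c_tot, r_tot, marker.kd_ug_ml)
    return c_tot, r_tot, float(c_free), float(occupancy(c_free, marker.kd_ug_ml))


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _cell_type_counts(proportions: Mapping[str, float], n_cells: int) -> dict[str, int]:
    """Deterministic largest-remainder allocation of cells to types."""
    types = sorted(proportions)
    raw = {t: proportions[t] * n_cells for t in types}
    counts = {t: int(np.floor(raw[t])) for t in types}
    remainder = n_cells - sum(counts.values())
    by_frac = sorted(types, key=lambda t: (-(raw[t] - counts[t]), t))
    for t in by_frac[:remainder]:
        counts[t] += 1
    return counts


def _depth_probability(reads_per_umi: float) -> float:
    return 1.0 - float(np.exp(-reads_per_umi))


def simulate_experiment(
    config: SimConfig,
    markers: Sequence[MarkerSpec],
    condition: StainingCondition,
    ambient_c_free: Mapping[str, float] | None = None,
    hto_names: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DropletExperiment, SimTruth]:
    """Simulate one staining condition's droplets with ground truth.

    ``ambient_c_free`` overrides the free concentration that drives the
    ambient background (used by :func:`simulate_titration_lane` to share one
    ambient pool across hashed conditions); by default the condition's own
    equilibrium is used. All draws come from one seeded generator stream.
    """
    if not config.cell_type_proportions:
        raise ValueError("zero cell types")
    if not markers:
        raise ValueError("no markers to simulate")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    proportions = config.cell_type_proportions
    marker_names = [m.name for m in markers]
    p_depth = _depth_probability(config.reads_per_umi)

    type_counts = _cell_type_counts(proportions, config.n_cells)
    cell_types: list[str] = []
    for t in sorted(type_counts):
        cell_types.extend([t] * type_counts[t])
    n_cells, n_empty = config.n_cells, config.n_empty
    n_drop = n_cells + n_empty
    barcodes = [f"{condition.condition_id}-BC{i:06d}" for i in range(n_drop)]

    truth_rows = []
    adt = np.zeros((len(markers), n_drop), dtype=np.int64)
    for i, marker in enumerate(markers):
        c_tot, r_tot, c_free, theta = marker_equilibrium(marker, condition, proportions)
        amb_free = float(ambient_c_free[marker.name]) if ambient_c_free is not None else c_free
        lam_amb = config.ambient_scale * config.wash_retention * amb_free
        lam_spec = np.array(
            [marker.epitopes(t) * theta * config.capture_efficiency for t in cell_types]
        )
        lam = np.concatenate([lam_spec + lam_amb, np.full(n_empty, lam_amb)])
        molecules = rng.poisson(lam)
        adt[i] = rng.binomial(molecules, p_depth)
        mean_specific = sum(
            proportions[t] * marker.epitopes(t) * theta * config.capture_efficiency for t in proportions
        )
        exp_empty = n_empty * lam_amb
        exp_cells = n_cells * (mean_specific + lam_amb)
        truth_rows.append({
            "marker": marker.name,
            "c_tot": c_tot,
            "r_tot": r_tot,
            "c_free": c_free,
            "theta": theta,
            "ambient_c_free": amb_free,
            "lambda_ambient": lam_amb,
            "mean_specific": mean_specific,
            "n_cells": n_cells,
            "n_empty": n_empty,
            "expected_background_fraction": exp_empty / (exp_empty + exp_cells) if exp_empty + exp_cells else 0.0,
            "category": marker.ground_truth_category,
        })

    # RNA: cells deep, ambient shallow; first rna_mito_genes genes are MT-
    gene_names = [f"MT-G{i}" if i < config.rna_mito_genes else f"GENE{i}" for i in range(config.rna_genes)]
    rate_cell = config.rna_mean_cell_total / config.rna_genes
    rate_empty = config.rna_mean_empty_total / config.rna_genes
    rna = np.concatenate(
        [
            rng.poisson(rate_cell, size=(config.rna_genes, n_cells)),
            rng.poisson(rate_empty, size=(config.rna_genes, n_empty)),
        ],
        axis=1,
    )

    own_hto = f"HTO-{condition.condition_id}"
    hto_names = list(hto_names) if hto_names is not None else [own_hto]
    if own_hto not in hto_names:
        raise ValueError(f"hto_names must include {own_hto}")
    hto = rng.poisson(config.hto_ambient_rate, size=(len(hto_names), n_drop))
    own_row = hto_names.index(own_hto)
    hto[own_row, :n_cells] += rng.poisson(config.hto_cell_rate, size=n_cells)

    # embedding: Gaussian blob per cell type on a circle (an *input* downstream)
    centers = {
        t: (10.0 * np.cos(2 * np.pi * k / len(type_counts)), 10.0 * np.sin(2 * np.pi * k / len(type_counts)))
        for k, t in enumerate(sorted(type_counts))
    }
    emb = np.full((n_drop, 2), np.nan)
    for j, t in enumerate(cell_types):
        emb[j] = centers[t] + rng.normal(0, 1.0, size=2)

    panel_table = pd.DataFrame(
        {
            f"concentration_{condition.condition_id}": [
                m.concentration_ug_ml / condition.dilution_factor for m in markers
            ],
            "is_isotype_control": [not m.epitopes_per_cell for m in markers],
        },
        index=pd.Index(marker_names, name="name"),
    )
    expected = [
        max(m.epitopes_per_cell, key=lambda t: (m.epitopes_per_cell[t], t)) if m.epitopes_per_cell else None
        for m in markers
    ]
    panel_table["expected_expressing_cluster"] = expected
    panel = AntibodyPanel(panel_table)

    metadata = pd.DataFrame(
        {
            "droplet_class_truth": ["cell"] * n_cells + ["empty"] * n_empty,
            "cell_type": cell_types + [None] * n_empty,
            "sample": [own_hto] * n_cells + [None] * n_empty,
            "emb_x": emb[:, 0],
            "emb_y": emb[:, 1],
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    experiment = build_experiment(
        adt=CountMatrix(marker_names, barcodes, sp.csr_matrix(adt)),
        rna=CountMatrix(gene_names, barcodes, sp.csr_matrix(rna)),
        hto=CountMatrix(hto_names, barcodes, sp.csr_matrix(hto)),
        panel=panel,
        condition=condition,
        metadata=metadata,
    )
    truth = SimTruth(
        condition_id=condition.condition_id,
        table=pd.DataFrame(truth_rows).set_index("marker"),
        ambient_c_free=pd.Series(
            {row["marker"]: row["ambient_c_free"] for row in truth_rows}, name="ambient_c_free"
        ),
    )
    return experiment, truth


def simulate_titration_lane(
    config: SimConfig,
    markers: Sequence[MarkerSpec],
    conditions: Sequence[StainingCondition],
) -> dict[str, tuple[DropletExperiment, SimTruth]]:
    """Simulate hashed conditions sharing one lane and one ambient pool.

    The post-wash free concentration of each marker is pooled (mean across
    conditions) and drives the ambient rate of *every* condition's droplets,
    so background does not titrate with any single condition — the situation
    that makes obscured (category A) markers look unresponsive.
    """
    if not conditions:
        raise ValueError("no conditions")
    ids = [c.condition_id for c in conditions]
    if len(set(ids)) != len(ids):
        raise ValueError("conditions must have unique ids")
    proportions = config.cell_type_proportions
    pooled: dict[str, float] = {}
    for marker in markers:
        frees = [marker_equilibrium(marker, cond, proportions)[2] for cond in conditions]
        pooled[marker.name] = float(np.mean(frees))
    hto_names = [f"HTO-{c}" for c in ids]
    rng = np.random.default_rng(config.seed)
    results = {}
    for cond in conditions:
        results[cond.condition_id] = simulate_experiment(
            config, markers, cond, ambient_c_free=pooled, hto_names=hto_names, rng=rng
        )
    return results


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

def default_conditions(dilution_factor: float = 4.0) -> list[StainingCondition]:
    """The canonical titration pair: starting panel vs fourfold dilution,
    both staining 1e6 cells in 50 uL."""
    return [
        StainingCondition("DF1", volume_ul=50.0, cells_stained=1e6, dilution_factor=1.0),
        StainingCondition("DF4", volume_ul=50.0, cells_stained=1e6, dilution_factor=dilution_factor),
    ]


def archetype_panel() -> list[MarkerSpec]:
    """Ten markers, two per response category, with ground-truth labels.

    Parameters are chosen so each archetype realizes its category's
    mechanism under the default :class:`SimConfig` and
    :func:`default_conditions`:

    * A — high concentration (5-10 ug/mL), essentially no epitopes: signal
      is all shared-pool ambient, so dilution changes nothing while the
      empty droplets soak up >80% of the marker's UMIs.
    * B — linear-range concentration (C ~ Kd/10) against an abundant,
      cell-type-restricted epitope: responds ~2 log2 to fourfold dilution
      with the positive population separated at both conditions.
    * C — linear-range concentration against a sparse epitope: the diluted
      signal drops to a handful of UMIs and separation collapses.
    * D — any concentration against a ubiquitous epitope: every cell
      positive, large UMI share.
    * E — low concentration, no epitopes: dim at both conditions with a
      negligible share of the panel's UMIs.
    """
    all_types = sorted(DEFAULT_CELL_TYPES)
    return [
        MarkerSpec("MK-A1", 10.0, 1.0, {}, "A"),
        MarkerSpec("MK-A2", 5.0, 0.5, {}, "A"),
        MarkerSpec("MK-B1", 0.4, 4.0, {"T": 4.0e4}, "B"),
        MarkerSpec("MK-B2", 0.3, 3.0, {"Mono": 5.0e4, "B": 5.0e4}, "B"),
        MarkerSpec("MK-C1", 0.1, 1.0, {"NK": 5.0e3}, "C"),
        MarkerSpec("MK-C2", 0.08, 1.2, {"B": 6.0e3}, "C"),
        MarkerSpec("MK-D1", 1.0, 2.0, {t: 1.0e5 for t in all_types}, "D"),
        MarkerSpec("MK-D2", 0.5, 1.0, {t: 6.0e4 for t in all_types}, "D"),
        MarkerSpec("MK-E1", 0.05, 5.0, {}, "E"),
        MarkerSpec("MK-E2", 0.1, 8.0, {}, "E"),
    ]
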