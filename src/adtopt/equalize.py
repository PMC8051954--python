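"""Make staining conditions directly comparable.

Three levellers are provided: equal per-cell-type cell counts across
conditions (sampling down to the minimum), greedy nearest-neighbor matching
of cells between two samples in a shared embedding, and hypergeometric
thinning of UMI counts to a common sequencing total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .data_model import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Kept barcodes per condition after equalization/matching."""

    kept: dict[str, list[str]]
    per_type: pd.DataFrame  # index cell type, one column per condition
    seed: int

    def frame(self) -> pd.DataFrame:
        rows = [
            {"barcode": b, "condition": cond, "kept": True}
            for cond in sorted(self.kept)
            for b in self.kept[cond]
        ]
        return pd.DataFrame(rows, columns=["barcode", "condition", "kept"])


def equalize_celltypes(
    cell_types: dict[str, pd.Series],
    seed: int = 0,
) -> SelectionResult:
    """Down-sample each condition to equal per-cell-type counts.

    ``cell_types`` maps condition id -> Series of cell-type labels indexed by
    barcode. For every cell type shared by all conditions the kept count is
    the minimum across conditions, sampled uniformly without replacement.
    Types absent from some condition are dropped with a warning.
    """
    if not cell_types:
        raise ValueError("no conditions supplied")
    conditions = sorted(cell_types)
    type_sets = [set(cell_types[c].dropna().unique()) for c in conditions]
    shared = sorted(set.intersection(*type_sets))
    dropped = sorted(set.union(*type_sets) - set(shared))
    if dropped:
        logger.warning("equalize_celltypes: dropping types absent from some condition: %s", dropped)
    if not shared:
        raise ValueError("conditions share no cell types")
    rng = np.random.default_rng(seed)
    kept: dict[str, list[str]] = {c: [] for c in conditions}
    counts = {}
    for cell_type in shared:
        pools = {c: sorted(cell_types[c].index[cell_types[c] == cell_type]) for c in conditions}
        n = min(len(p) for p in pools.values())
        counts[cell_type] = n
        for cond in conditions:
            pool = pools[cond]
            chosen = pool if len(pool) == n else sorted(rng.choice(pool, size=n, replace=False))
            kept[cond].extend(chosen)
    per_type = pd.DataFrame({c: counts for c in conditions}).rename_axis("cell_type")
    return SelectionResult(kept=kept, per_type=per_type, seed=seed)


def match_in_embedding(
    coordinates: pd.DataFrame,
    clusters: pd.Series,
    samples: pd.Series,
    seed: int = 0,
) -> SelectionResult:
    """Greedy nearest-neighbor matching of two samples in a shared embedding.

    Within each cluster, every cell of the smaller sample is paired with its
    nearest (Euclidean) not-yet-used neighbor in the larger sample, cells
    processed in a seed-shuffled order. The output keeps equal per-cluster
    counts for both samples.
    """
    if coordinates.isna().to_numpy().any():
        raise ValueError("embedding coordinates contain missing values")
    names = sorted(samples.dropna().unique())
    if len(names) != 2:
        raise ValueError(f"match_in_embedding requires exactly two samples, got {names}")
    common = coordinates.index
    if not clusters.index.equals(common) or not samples.index.equals(common):
        clusters = clusters.reindex(common)
        samples = samples.reindex(common)
        if clusters.isna().any() or samples.isna().any():
            raise ValueError("clusters/samples do not cover all embedded cells")
    rng = np.random.default_rng(seed)
    kept: dict[str, list[str]] = {names[0]: [], names[1]: []}
    per_type: dict[str, int] = {}
    for cluster in sorted(pd.unique(clusters.dropna())):
        in_cluster = clusters.index[clusters == cluster]
        groups = {
            s: sorted(b for b in in_cluster if samples[b] == s) for s in names
        }
        small, large = sorted(names, key=lambda s: (len(groups[s]), s))
        if not groups[small] or not groups[large]:
            logger.warning("match_in_embedding: cluster %r present in one sample only; skipped", cluster)
            per_type[str(cluster)] = 0
            continue
        small_bcs = list(groups[small])
        rng.shuffle(small_bcs)
        large_bcs = groups[large]
        dist = cdist(coordinates.loc[small_bcs].to_numpy(float), coordinates.loc[large_bcs].to_numpy(float))
        used = np.zeros(len(large_bcs), dtype=bool)
        for i, barcode in enumerate(small_bcs):
            row = np.where(used, np.inf, dist[i])
            j = int(np.argmin(row))
            used[j] = True
            kept[small].append(barcode)
            kept[large].append(large_bcs[j])
        per_type[str(cluster)] = len(small_bcs)
    for s in names:
        kept[s] = sorted(kept[s])
    per_type_frame = pd.DataFrame({s: per_type for s in names}).rename_axis("cluster")
    return SelectionResult(kept=kept, per_type=per_type_frame, seed=seed)


def thin_counts(matrix: CountMatrix, target_total: int, seed: int = 0) -> CountMatrix:
    """Down-sample a count matrix to ``target_total`` UMIs exactly.

    The kept UMIs are a uniform random subsample without replacement of the
    original ones (multivariate hypergeometric over the nonzero entries), so
    every entry of the result is bounded by the original entry and the grand
    total equals ``target_total``.
    """
    total = int(matrix.counts.sum())
    if not 0 <= target_total <= total:
        raise ValueError(f"target_total {target_total} outside [0, {total}]")
    if target_total == total:
        return CountMatrix(list(matrix.feature_ids), list(matrix.barcode_ids), matrix.counts.copy())
    coo = matrix.counts.tocoo()
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(coo.data, target_total, method="marginals")
    thinned = sp.csr_matrix((kept, (coo.row, coo.col)), shape=coo.shape)
    return CountMatrix(list(matrix.feature_ids), list(matrix.barcode_ids), thinned)


def thin_counts_read_level(
    matrix: CountMatrix,
    keep_read_fraction: float,
    reads_per_umi: float,
    seed: int = 0,
) -> CountMatrix:
    """Two-stage thinning: inflate UMIs to reads, thin reads, re-collapse.

    Each observed UMI is assigned a read multiplicity drawn from a
    zero-truncated Poisson with mean ``reads_per_umi``; reads survive
    independently with probability ``keep_read_fraction`` and a UMI is kept
    when at least one of its reads survives. This reproduces the
    UMI-collapse nonlinearity of read-level down-sampling and is meant for
    saturation-sensitive comparisons; plain :func:`thin_counts` is exact at
    the UMI level.
    """
    if not 0 <= keep_read_fraction <= 1:
        raise ValueError("keep_read_fraction must be in [0, 1]")
    if reads_per_umi <= 0:
        raise ValueError("reads_per_umi must be > 0")
    rng = np.random.default_rng(seed)
    coo = matrix.counts.tocoo()
    kept = np.zeros(len(coo.data), dtype=np.int64)
    for k, n_umis in enumerate(coo.data):
        reads = rng.poisson(reads_per_umi, size=int(n_umis))
        reads = np.maximum(reads, 1)  # every observed UMI had >= 1 read
        surviving = rng.binomial(reads, keep_read_fraction)
        kept[k] = int(np.count_nonzero(surviving))
    thinned = sp.csr_matrix((kept, (coo.row, coo.col)), shape=coo.shape)
    return CountMatrix(list(matrix.feature_ids), list(matrix.barcode_ids), thinned)


def sequencing_saturation(n_reads: int, n_umis: int) -> float:
    """Sequencing saturation, 1 - UMIs/reads (the 10x convention)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if n_umis < 0:
        raise ValueError("n_umis must be >= 0")
    if n_umis > n_reads:
        raise ValueError("n_umis cannot exceed n_reads")
    return 1.0 - n_umis / n_reads
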