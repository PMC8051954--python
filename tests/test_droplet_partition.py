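import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from adtopt.data_model import CountMatrix, build_experiment
from adtopt.droplet_partition import (
    RankCurve,
    barcode_rank_curve,
    demux_hto,
    find_inflection,
    partition_droplets,
    qc_filter,
)
from adtopt.synthetic_data import SimConfig, StainingCondition, archetype_panel, simulate_experiment


def step_curve(n_cells=100, n_empty=900, high=1000, low=1):
    totals = np.array([high] * n_cells + [low] * n_empty)
    barcodes = [f"BC{i:05d}" for i in range(len(totals))]
    return RankCurve(barcodes, totals)


class TestRankCurve:
    def test_orders_descending_with_lexicographic_ties(self):
        counts = CountMatrix(["f"], ["a", "b", "c"], sp.csr_matrix(np.array([[5, 10, 1]])))
        curve = barcode_rank_curve(counts)
        assert curve.barcodes == ["b", "a", "c"]
        assert curve.totals.tolist() == [10, 5, 1]
        tied = CountMatrix(["f"], ["z", "m", "a"], sp.csr_matrix(np.array([[3, 3, 3]])))
        assert barcode_rank_curve(tied).barcodes == ["a", "m", "z"]

    def test_all_zero_matrix_errors(self):
        counts = CountMatrix(["f"], ["a", "b"], sp.csr_matrix((1, 2), dtype=np.int64))
        with pytest.raises(ValueError, match="no rankable signal"):
            barcode_rank_curve(counts)


class TestFindInflection:
    def test_step_curve_knee_at_the_step(self):
        assert find_inflection(step_curve()) == 100

    def test_flat_curve_has_no_knee(self):
        flat = RankCurve([f"b{i}" for i in range(500)], np.full(500, 50))
        with pytest.raises(ValueError, match="cutoff manually"):
            find_inflection(flat)

    def test_logistic_transition_matches_brute_force_derivative_scan(self):
        # two plateaus joined by a logistic drop in log-log space (seedless,
        # continuous totals centered at rank 300 with width 0.05 log-ranks)
        ranks = np.arange(1, 2001)
        log_totals = 3.0 - 2.5 / (1.0 + np.exp(-(np.log10(ranks) - np.log10(300.0)) / 0.05))
        totals = 10.0 ** log_totals
        curve = RankCurve([f"b{i:05d}" for i in range(2000)], totals)
        window = 11
        detected = find_inflection(curve, smoothing_window=window)
        # oracle: exhaustive scan for the steepest unsmoothed discrete derivative
        lt = np.log10(totals)
        lr = np.log10(np.arange(1, 2001, dtype=float))
        deriv = np.diff(lt) / np.diff(lr)
        lo, hi = 100 - 1, 1000 - 1  # candidate r* in [min_cells, n//2]
        oracle = lo + int(np.argmin(deriv[lo:hi])) + 1
        assert abs(detected - oracle) <= window

    def test_invariant_to_uniform_scaling(self):
        curve = step_curve()
        scaled = RankCurve(curve.barcodes, curve.totals * 17)
        assert find_inflection(curve) == find_inflection(scaled)


class TestPartition:
    def _step_experiment(self, small_panel_factory=None):
        n_cells, n_empty = 100, 900
        barcodes = [f"BC{i:05d}" for i in range(n_cells + n_empty)]
        rna = np.zeros((1, n_cells + n_empty), dtype=int)
        rna[0, :n_cells] = 1000
        rna[0, n_cells:] = 1
        adt = np.ones((1, n_cells + n_empty), dtype=int)
        panel = pd.DataFrame({"concentration_DF1": [1.0]}, index=pd.Index(["CD3"], name="name"))
        from adtopt.data_model import AntibodyPanel

        return build_experiment(
            adt=CountMatrix(["CD3"], barcodes, sp.csr_matrix(adt)),
            rna=CountMatrix(["G1"], barcodes, sp.csr_matrix(rna)),
            panel=AntibodyPanel(panel),
            condition=StainingCondition("DF1", volume_ul=50, cells_stained=1e6),
        )

    def test_step_experiment_partitions_100_900(self):
        experiment = partition_droplets(self._step_experiment())
        counts = experiment.metadata["droplet_class"].value_counts()
        assert counts["cell"] == 100 and counts["empty"] == 900

    def test_partition_is_exhaustive(self):
        experiment = partition_droplets(self._step_experiment())
        classes = experiment.metadata["droplet_class"]
        assert set(classes.unique()) <= {"cell", "empty", "removed"}
        assert len(classes) == 1000

    def test_forced_inflection_at_last_barcode_leaves_zero_empty(self, caplog):
        experiment = self._step_experiment()
        partition_droplets(experiment, inflection_rank=1000)
        assert experiment.metadata["droplet_class"].value_counts()["cell"] == 1000

    def test_simulated_lane_recovers_cell_count(self):
        config = SimConfig(n_cells=500, n_empty=5000, seed=7)
        condition = StainingCondition("DF1", volume_ul=50, cells_stained=1e6)
        experiment, _ = simulate_experiment(config, archetype_panel(), condition)
        partition_droplets(experiment)
        n_cells = len(experiment.cell_barcodes)
        assert abs(n_cells - 500) <= 25

    def test_empty_droplets_match_ambient_distribution(self):
        """Empty-droplet marker counts are indistinguishable from the
        simulator's ambient-only distribution (rank-sum, alpha=0.01)."""
        config = SimConfig(n_cells=500, n_empty=5000, seed=11)
        condition = StainingCondition("DF1", volume_ul=50, cells_stained=1e6)
        experiment, truth = simulate_experiment(config, archetype_panel(), condition)
        partition_droplets(experiment)
        marker = "MK-A1"
        empty_counts = experiment.adt.subset_barcodes(experiment.empty_barcodes).feature_vector(marker)
        lam = truth.table.loc[marker, "lambda_ambient"] * (1 - np.exp(-config.reads_per_umi))
        oracle = np.random.default_rng(12).poisson(lam, size=5000)
        assert len(empty_counts) >= 1000
        assert mannwhitneyu(empty_counts, oracle).pvalue > 0.01


class TestQcFilter:
    @staticmethod
    def _experiment(columns, n_genes=70):
        """One candidate cell per column; row 0 is the mitochondrial gene."""
        barcodes = [f"BC{i}" for i in range(len(columns))]
        genes = ["MT-CO1"] + [f"G{i}" for i in range(1, n_genes)]
        rna = np.column_stack([np.pad(c, (0, n_genes - len(c))) for c in columns])
        adt = np.ones((1, len(barcodes)), dtype=int)
        from adtopt.data_model import AntibodyPanel

        panel = pd.DataFrame({"concentration_DF1": [1.0]}, index=pd.Index(["CD3"], name="name"))
        experiment = build_experiment(
            adt=CountMatrix(["CD3"], barcodes, sp.csr_matrix(adt)),
            rna=CountMatrix(genes, barcodes, sp.csr_matrix(rna)),
            panel=AntibodyPanel(panel),
            condition=StainingCondition("DF1", volume_ul=50, cells_stained=1e6),
        )
        experiment.metadata["droplet_class"] = "cell"
        return experiment

    def test_gene_and_mito_boundaries(self):
        # BC0: 59 detected genes, no mito -> removed (needs >= 60)
        # BC1: 60 genes, 14/94 = 14.9% mito -> kept (below 15%)
        # BC2: 60 genes, 16/100 = 16.0% mito -> removed
        col0 = np.array([0] + [1] * 59)
        col1 = np.array([14, 22] + [1] * 58)
        col2 = np.array([16, 26] + [1] * 58)
        experiment = self._experiment([col0, col1, col2])
        kept = qc_filter(experiment)
        assert kept == ["BC1"]
        assert experiment.metadata.loc["BC0", "droplet_class"] == "removed"
        assert experiment.metadata.loc["BC2", "droplet_class"] == "removed"

    def test_missing_mito_prefix_skips_criterion(self, caplog):
        experiment = self._experiment([np.array([0] + [1] * 64)])
        kept = qc_filter(experiment, mito_prefix="XYZ-")
        assert kept == ["BC0"]
        assert any("mitochondrial criterion skipped" in r.message for r in caplog.records)


class TestDemuxHto:
    def _experiment(self, hto_counts):
        hto_counts = np.asarray(hto_counts).T  # hashtags x cells
        n = hto_counts.shape[1]
        barcodes = [f"BC{i}" for i in range(n)]
        names = [f"HTO-{k}" for k in range(hto_counts.shape[0])]
        adt = np.ones((1, n), dtype=int)
        from adtopt.data_model import AntibodyPanel

        panel = pd.DataFrame({"concentration_DF1": [1.0]}, index=pd.Index(["CD3"], name="name"))
        experiment = build_experiment(
            adt=CountMatrix(["CD3"], barcodes, sp.csr_matrix(adt)),
            hto=CountMatrix(names, barcodes, sp.csr_matrix(hto_counts)),
            panel=AntibodyPanel(panel),
            condition=StainingCondition("DF1", volume_ul=50, cells_stained=1e6),
        )
        experiment.metadata["droplet_class"] = "cell"
        return experiment

    def test_dominant_doublet_and_negative_rules(self):
        experiment = self._experiment([[100, 2, 1], [50, 45, 2], [4, 1, 0]])
        result = demux_hto(experiment)
        assert result.tolist() == ["HTO-0", "doublet", "negative"]

    def test_single_hashtag_warns(self, caplog):
        experiment = self._experiment([[100], [3]])
        demux_hto(experiment)
        assert any("single-hashtag" in r.message for r in caplog.records)
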