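import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexpnet import preprocess
from coexpnet.data import CountMatrix, DataError, DETable, SampleSheet

from .conftest import make_two_group_experiment


def _matrix_with_zero_counts(zero_counts, n_samples):
    """One gene per requested number of zero samples."""
    rows = []
    genes = []
    for i, nz in enumerate(zero_counts):
        row = [0] * nz + [5] * (n_samples - nz)
        rows.append(row)
        genes.append(f"g{i}_{nz}zeros")
    return CountMatrix(
        pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(n_samples)])
    )


class TestFilterLowExpression:
    def test_paper_boundary_43_of_170(self):
        cm = _matrix_with_zero_counts([42, 43, 44], 170)
        kept = preprocess.filter_low_expression(cm, 0.25).genes
        assert kept == ["g0_42zeros"]

    def test_all_nonzero_unchanged(self):
        cm = _matrix_with_zero_counts([0, 0], 10)
        assert preprocess.filter_low_expression(cm).genes == cm.genes

    def test_eight_sample_boundary_enumeration(self):
        # ceiling(0.25 * 8) = 2: genes with >= 2 zeros are removed
        cm = _matrix_with_zero_counts([0, 1, 2, 3], 8)
        kept = preprocess.filter_low_expression(cm, 0.25).genes
        expected = [g for g in cm.genes if int(g.split("_")[1][0]) < 2]
        assert kept == expected

    def test_empty_result_warns(self):
        cm = _matrix_with_zero_counts([5, 6], 8)
        with pytest.warns(UserWarning, match="every gene"):
            out = preprocess.filter_low_expression(cm, 0.25)
        assert out.shape == (0, 8)

    def test_order_stable_subsequence(self, default_sim):
        cm, _, _ = default_sim
        kept = preprocess.filter_low_expression(cm, 0.02).genes
        it = iter(cm.genes)
        assert all(g in it for g in kept)  # subsequence check


class TestSizeFactors:
    def test_doubled_column(self):
        cm = CountMatrix(
            pd.DataFrame(
                {"a": [10, 20, 30], "b": [20, 40, 60]}, index=["g1", "g2", "g3"]
            )
        )
        f = preprocess.size_factors(cm)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_identical_columns_unit_factors(self):
        cm = CountMatrix(
            pd.DataFrame({"a": [5, 7], "b": [5, 7], "c": [5, 7]}, index=["g1", "g2"])
        )
        assert np.allclose(preprocess.size_factors(cm), 1.0)

    def test_hand_computed_worksheet(self):
        # geomeans: g1 sqrt(8), g2 sqrt(27), g3 8
        # s1 ratios (2/2.828, 3/5.196, 8/8) -> median 1/sqrt(2)
        # s2 ratios (4/2.828, 9/5.196, 8/8) -> median sqrt(2)
        cm = CountMatrix(
            pd.DataFrame({"s1": [2, 3, 8], "s2": [4, 9, 8]}, index=["g1", "g2", "g3"])
        )
        f = preprocess.size_factors(cm)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2))
        assert f["s2"] == pytest.approx(math.sqrt(2))

    def test_no_common_gene_errors(self):
        cm = CountMatrix(
            pd.DataFrame({"a": [0, 3], "b": [2, 0]}, index=["g1", "g2"])
        )
        with pytest.raises(DataError, match="size factors"):
            preprocess.size_factors(cm)


class TestBHAdjust:
    @staticmethod
    def _brute_force(p):
        """Literal step-up: padj_i = min over j with p_j >= p_i of p_j * n / rank_j."""
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running_min = 1.0
        for rank_from_top in range(n - 1, -1, -1):
            i = order[rank_from_top]
            running_min = min(running_min, p[i] * n / (rank_from_top + 1))
            adj[i] = running_min
        return adj

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(preprocess.bh_adjust(p), self._brute_force(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(preprocess.bh_adjust(p), expected)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        adj = preprocess.bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDifferentialExpression:
    def test_log2fc_arithmetic(self):
        # majority of genes unchanged -> size factors 1; focal means 40 vs 10
        background = np.tile([[20], [50], [80], [120], [250], [31], [77], [9], [64]], (1, 3))
        treated = np.vstack([np.full((1, 3), 40), background])
        control = np.vstack([np.full((1, 3), 10), background])
        cm, sheet = make_two_group_experiment(treated, control)
        det = preprocess.differential_expression(cm, sheet)
        assert det.table.loc[0, "log2fc"] == pytest.approx(math.log2(40.5 / 10.5))

    def test_identical_groups_zero_lfc(self):
        cm, sheet = make_two_group_experiment(
            [[12, 8, 10], [100, 90, 110]], [[12, 8, 10], [100, 90, 110]]
        )
        det = preprocess.differential_expression(cm, sheet)
        assert np.allclose(det.table["log2fc"], 0.0)

    def test_null_type_one_error(self):
        """NB null: rejection rate within 2x binomial SE of alpha (2000 genes)."""
        rng = np.random.default_rng(42)
        n_genes, nrep, disp = 2000, 8, 0.05
        base = np.exp(rng.normal(5, 1, n_genes))
        size = 1 / disp
        draw = lambda: rng.negative_binomial(
            size, size / (size + base[:, None]), (n_genes, nrep)
        )
        cm, sheet = make_two_group_experiment(draw(), draw())
        det = preprocess.differential_expression(cm, sheet)
        for alpha in (0.05, 0.1):
            rate = (det.table["p"] < alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / n_genes)
            assert abs(rate - alpha) <= 2 * se, f"alpha={alpha}, rate={rate}"

    def test_planted_lfc_recovery(self):
        """Planted log2fc = 2 recovered within +/-0.25 averaged over 500 genes."""
        rng = np.random.default_rng(7)
        n_signal, n_null, nrep, disp = 500, 4500, 8, 0.1
        base = np.exp(rng.normal(5, 0.8, n_signal + n_null))
        mu_t = base.copy()
        mu_t[:n_signal] *= 4.0  # planted log2fc = 2 on the first 500 genes
        size = 1 / disp
        treated = rng.negative_binomial(
            size, size / (size + mu_t[:, None]), (len(base), nrep)
        )
        control = rng.negative_binomial(
            size, size / (size + base[:, None]), (len(base), nrep)
        )
        cm, sheet = make_two_group_experiment(treated, control)
        det = preprocess.differential_expression(cm, sheet)
        assert det.table["log2fc"].head(n_signal).mean() == pytest.approx(2.0, abs=0.25)

    def test_external_table_round_trip(self, tmp_path, default_de, default_sim):
        cm, sheet, _ = default_sim
        path = tmp_path / "de.tsv"
        default_de.to_tsv(path)
        det2 = preprocess.differential_expression(
            cm, sheet, method="external_table", external_path=path
        )
        pd.testing.assert_frame_equal(det2.table, default_de.table)

    def test_padj_within_comparison(self, default_de):
        for _, sub in default_de.table.groupby("treatment"):
            assert np.allclose(
                sub["padj"], preprocess.bh_adjust(sub["p"].to_numpy())
            )


class TestFilterDEGenes:
    def _det(self, padj_by_gene, n_treatments=4):
        rows = []
        for gene, padjs in padj_by_gene.items():
            for i, padj in enumerate(padjs):
                rows.append(
                    {"gene": gene, "treatment": f"T{i}", "log2fc": 1.0,
                     "p": padj, "padj": padj}
                )
        return DETable(pd.DataFrame(rows))

    def test_paper_boundary_3_of_33(self):
        padj = {"kept": [0.01] * 3 + [0.9] * 30, "dropped": [0.01] * 2 + [0.9] * 31}
        det = self._det(padj, 33)
        assert preprocess.filter_de_genes(det, 3, 0.05) == ["kept"]

    def test_alpha_one_keeps_all(self):
        det = self._det({"a": [0.99, 0.99, 0.99, 0.99], "b": [0.5] * 4})
        assert preprocess.filter_de_genes(det, 3, alpha=1.0) == ["a", "b"]

    def test_toy_enumeration(self):
        padj = {
            "g1": [0.01, 0.02, 0.03, 0.9],   # 3 hits -> kept
            "g2": [0.01, 0.9, 0.9, 0.9],     # 1 hit -> dropped
            "g3": [0.04, 0.04, 0.04, 0.04],  # 4 hits -> kept
            "g4": [0.06, 0.06, 0.06, 0.06],  # 0 hits -> dropped
            "g5": [0.01, 0.01, 0.9, 0.9],    # 2 hits -> dropped
        }
        det = self._det(padj)
        assert preprocess.filter_de_genes(det, 3, 0.05) == ["g1", "g3"]

    def test_order_stability(self):
        padj = {f"g{i}": [0.01] * 4 for i in range(10)}
        det = self._det(padj)
        assert preprocess.filter_de_genes(det) == [f"g{i}" for i in range(10)]

    def test_empty_table_errors(self):
        det = DETable(pd.DataFrame(columns=["gene", "treatment", "log2fc", "p", "padj"]))
        with pytest.raises(DataError):
            preprocess.filter_de_genes(det)


class TestBuildFCMatrix:
    def test_cellwise_equal_to_de_table(self, default_de):
        genes = default_de.genes[:20]
        fc = preprocess.build_fc_matrix(default_de, genes)
        sub = default_de.table.set_index(["gene", "treatment"])
        for g in genes[:5]:
            for t in fc.columns[:3]:
                assert fc.loc[g, t] == sub.loc[(g, t), "log2fc"]

    def test_row_order_preserved(self, default_de):
        genes = default_de.genes[10:2:-1]
        fc = preprocess.build_fc_matrix(default_de, genes)
        assert list(fc.index) == genes

    def test_missing_gene_errors(self, default_de):
        with pytest.raises(DataError, match="absent"):
            preprocess.build_fc_matrix(default_de, ["not_a_gene"])


class TestWardClusterTreatments:
    def test_two_planted_classes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        from coexpnet.simulate import SimConfig, generate_compendium

        cfg = SimConfig(seed=11, n_other_treatments=0, effect_size_log2=3.0,
                        response_spread=0.0, gene_multiplier_range=(0.5, 1.0))
        cm, sheet, truth = generate_compendium(cfg)
        det = preprocess.differential_expression(cm, sheet)
        genes = preprocess.filter_de_genes(det)
        fc = preprocess.build_fc_matrix(det, genes)
        _, labels = preprocess.ward_cluster_treatments(fc, k=2)
        true_labels = [sheet.class_of(t) for t in fc.columns]
        assert adjusted_rand_score(true_labels, labels.to_numpy()) == 1.0

    def test_k_equals_n_singletons(self, default_de):
        fc = preprocess.build_fc_matrix(default_de, default_de.genes[:30])
        _, labels = preprocess.ward_cluster_treatments(fc, k=fc.shape[1])
        assert labels.nunique() == fc.shape[1]

    def test_duplicated_column_co_clusters(self, default_de):
        fc = preprocess.build_fc_matrix(default_de, default_de.genes[:30])
        fc = fc.copy()
        fc["dup"] = fc.iloc[:, 0]
        _, labels = preprocess.ward_cluster_treatments(fc, k=5)
        assert labels["dup"] == labels[fc.columns[0]]

    def test_k_too_large_errors(self, default_de):
        fc = preprocess.build_fc_matrix(default_de, default_de.genes[:10])
        with pytest.raises(ValueError):
            preprocess.ward_cluster_treatments(fc, k=fc.shape[1] + 1)


class TestCountResponsiveChemicals:
    def _det_and_sheet(self):
        rows = []
        for t, (p, lfc) in {
            "F1": (0.001, 2.0), "F2": (0.2, 2.0), "F3": (0.001, 0.5), "A1": (0.001, 3.0)
        }.items():
            rows.append({"gene": "g", "treatment": t, "log2fc": lfc, "p": p, "padj": p})
        det = DETable(pd.DataFrame(rows))
        sheet_rows = []
        for t in ["F1", "F2", "F3", "A1"]:
            cls = "FRC" if t.startswith("F") else "AHR2_Activator"
            for r in (1, 2):
                sheet_rows.append({"sample": f"{t}_r{r}", "treatment": t,
                                   "control_for": "C", "class": cls, "replicate": r})
        for r in (1, 2):
            sheet_rows.append({"sample": f"C_r{r}", "treatment": "C",
                               "control_for": "", "class": "control", "replicate": r})
        return det, SampleSheet(pd.DataFrame(sheet_rows))

    def test_loose_criteria_counts_all_in_class(self):
        det, sheet = self._det_and_sheet()
        crit = preprocess.ResponseCriteria(alpha=1.0, min_abs_lfc=0.0)
        assert preprocess.count_responsive_chemicals(det, "g", ["FRC"], crit, sheet) == 3

    def test_toy_enumeration(self):
        det, sheet = self._det_and_sheet()
        crit = preprocess.ResponseCriteria(alpha=0.05, min_abs_lfc=1.0)
        # FRC: F1 passes both, F2 fails p, F3 fails lfc
        assert preprocess.count_responsive_chemicals(det, "g", ["FRC"], crit, sheet) == 1
        assert preprocess.count_responsive_chemicals(det, "g", None, crit) == 2

    def test_no_response_zero(self):
        det, sheet = self._det_and_sheet()
        crit = preprocess.ResponseCriteria(alpha=0.0001, min_abs_lfc=5.0)
        assert preprocess.count_responsive_chemicals(det, "g", ["FRC"], crit, sheet) == 0

    def test_unknown_gene_errors(self):
        det, sheet = self._det_and_sheet()
        crit = preprocess.ResponseCriteria()
        with pytest.raises(DataError, match="unknown gene"):
            preprocess.count_responsive_chemicals(det, "nope", None, crit)


def test_full_pipeline_null_fc_mean_near_zero():
    from coexpnet.simulate import SimConfig, generate_compendium

    cfg = SimConfig(seed=13, effect_size_log2=0.0, n_genes=200, module_sizes=(20, 20),
                    treatments_per_class=4, n_other_treatments=0)
    cm, sheet, _ = generate_compendium(cfg)
    cm = preprocess.filter_low_expression(cm)
    det = preprocess.differential_expression(cm, sheet)
    fc = preprocess.build_fc_matrix(det, det.genes)
    assert abs(fc.to_numpy().mean()) < 0.02
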