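"""Vote scoring, score-matrix aggregation, quadrant groups, clustering."""

import numpy as np
import pytest

from chemoatlas import (
    Contrast,
    GeneResult,
    StageComparison,
    build_score_matrix,
    classify_groups,
    classify_point,
    cluster_genes,
    ratio_of_significant_difference,
    score_gene,
)
from chemoatlas.integrate import ScoreMatrix
import pandas as pd


def result(gene="G", log2fc=0.0, q=1.0):
    return GeneResult(gene=gene, log2fc=log2fc, p_value=min(q, 1.0), q_value=q,
                      n_test=5, n_ref=5)


def comparison(dataset_id, stage, gene_results, reference="healthy_control"):
    comp = StageComparison(dataset_id=dataset_id,
                           contrast=Contrast(stage, reference))
    for r in gene_results:
        comp.results[r.gene] = r
    return comp


class TestScoreGene:
    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [
            (2.1, 0.01, 1),     # significant up
            (0.5, 0.001, 0),    # fold-change gate fails
            (-1.5, 0.2, 0),     # q gate fails
            (-2.0, 0.01, -1),   # significant down
            (1.0, 0.01, 0),     # exactly at the threshold is not beyond it
            (-1.0, 0.01, 0),
            (1.5, 0.05, 0),     # q exactly at threshold fails the strict gate
        ],
    )
    def test_vote_rules(self, log2fc, q, expected):
        assert score_gene(result(log2fc=log2fc, q=q)) == expected

    def test_thresholds_configurable(self):
        assert score_gene(result(log2fc=0.8, q=0.01), fc_threshold=0.5) == 1

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            score_gene(result(log2fc=float("nan"), q=0.01))


class TestRatioOfSignificantDifference:
    def test_three_of_four_datasets(self):
        assert ratio_of_significant_difference([1, 1, 1, 0]) == 0.75

    def test_no_significant_datasets(self):
        assert ratio_of_significant_difference([0, 0]) == 0.0

    def test_conflicting_datasets_cancel(self):
        assert ratio_of_significant_difference([1, -1]) == 0.0

    def test_empty_is_an_error_not_zero(self):
        with pytest.raises(ValueError):
            ratio_of_significant_difference([])


class TestBuildScoreMatrix:
    def test_worked_example_three_of_four(self):
        comps = [
            comparison(f"ibd_{i}", "IBD",
                       [result("CCL20", log2fc=2.5, q=0.01)]) for i in range(3)
        ]
        comps.append(comparison("ibd_4", "IBD", [result("CCL20", 0.2, 0.8)]))
        matrix = build_score_matrix(comps)
        assert matrix.values.loc["CCL20", "IBD"] == 0.75
        assert matrix.counts.loc["CCL20", "IBD"] == 4

    def test_uncovered_gene_cell_is_missing_not_zero(self):
        comps = [comparison("a1", "adenoma", [result("CXCL1", 2.0, 0.01)])]
        matrix = build_score_matrix(comps, genes=["CXCL1", "CCL2"])
        assert np.isnan(matrix.values.loc["CCL2", "adenoma"])
        assert matrix.counts.loc["CCL2", "adenoma"] == 0

    def test_unanimous_downregulation(self):
        comps = [
            comparison(f"c{i}", "primary_carcinoma",
                       [result("CXCL12", -3.0, 0.001)]) for i in range(2)
        ]
        matrix = build_score_matrix(comps)
        assert matrix.values.loc["CXCL12", "primary_carcinoma"] == -1.0

    def test_mixed_reference_stages_rejected(self):
        comps = [
            comparison("a", "IBD", [result()]),
            comparison("b", "metastasis", [result()], reference="primary_carcinoma"),
        ]
        with pytest.raises(ValueError, match="reference"):
            build_score_matrix(comps)

    def test_cell_equals_signed_count_ratio_on_random_inputs(self):
        rng = np.random.default_rng(42)
        genes = [f"G{i}" for i in range(12)]
        comps, votes = [], {g: [] for g in genes}
        for d in range(6):
            results = []
            for g in genes:
                if rng.random() < 0.2:  # platform gap
                    continue
                lfc = rng.normal(0, 2)
                q = rng.uniform(0, 0.2)
                results.append(result(g, lfc, q))
                votes[g].append(
                    (1 if (q < 0.05 and lfc > 1) else -1 if (q < 0.05 and lfc < -1) else 0)
                )
            comps.append(comparison(f"d{d}", "IBD", results))
        matrix = build_score_matrix(comps, genes=genes)
        for g in genes:
            cell = matrix.values.loc[g, "IBD"]
            if not votes[g]:
                assert np.isnan(cell)
                continue
            up = sum(v == 1 for v in votes[g])
            down = sum(v == -1 for v in votes[g])
            assert cell == pytest.approx((up - down) / len(votes[g]))
            assert matrix.counts.loc[g, "IBD"] == len(votes[g])


class TestClassifyPoint:
    @pytest.mark.parametrize(
        "x,y,group",
        [
            (2.0, 2.5, "i"),
            (2.5, 0.1, "ii"),
            (0.0, 0.0, "iii"),
            (0.2, -2.0, "iv"),
            (-2.0, 0.0, "iii"),     # down in IBD only: no named pattern
            (-1.5, -2.0, "iii"),
            (1.0, 1.0, "iii"),      # exactly at the cutoff: less-extreme side
            (1.0 + 1e-12, 0.0, "ii"),
            (2.0, 1.0, "ii"),       # y exactly at cutoff stays in the band
            (3.0, -1.5, "ii"),      # conflict corner: |x| wins
            (1.5, -3.0, "iv"),      # conflict corner: |y| wins
            (2.0, -2.0, "iii"),     # conflict corner: exact tie
        ],
    )
    def test_quadrant_rule(self, x, y, group):
        assert classify_point(x, y) == group

    def test_invariant_under_tiny_perturbation_away_from_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x, y = rng.uniform(-3, 3, 2)
            if min(abs(abs(x) - 1), abs(abs(y) - 1)) < 1e-6:
                continue  # not "away from thresholds"
            base = classify_point(x, y)
            for dx, dy in ((1e-10, 0), (-1e-10, 0), (0, 1e-10), (0, -1e-10)):
                assert classify_point(x + dx, y + dy) == base


class TestClassifyGroups:
    def _comps(self):
        ibd = [comparison("i1", "IBD", [result("A", 2.0), result("B", 2.5),
                                        result("C", 0.0), result("D", 0.2)])]
        adenoma = [comparison("a1", "adenoma", [result("A", 2.0), result("B", 0.0),
                                                result("C", 0.0), result("D", -1.8)])]
        carcinoma = [comparison("c1", "primary_carcinoma",
                                [result("A", 3.0), result("B", 0.2),
                                 result("C", 0.0), result("D", -2.2)])]
        return ibd, adenoma, carcinoma

    def test_partition_and_expected_groups(self):
        ibd, adenoma, carcinoma = self._comps()
        assignments, unclassifiable = classify_groups(
            ibd, adenoma, carcinoma, ["A", "B", "C", "D"]
        )
        assert unclassifiable == []
        groups = {a.gene: a.group for a in assignments}
        assert groups == {"A": "i", "B": "ii", "C": "iii", "D": "iv"}
        # y is the mean of the two tumor-stage means
        a = {x.gene: x for x in assignments}["A"]
        assert a.y == pytest.approx((2.0 + 3.0) / 2)

    def test_every_gene_gets_exactly_one_label(self):
        ibd, adenoma, carcinoma = self._comps()
        assignments, _ = classify_groups(ibd, adenoma, carcinoma, list("ABCD"))
        assert sorted(a.gene for a in assignments) == list("ABCD")

    def test_gene_without_axis_coverage_reported_unclassifiable(self):
        ibd, adenoma, carcinoma = self._comps()
        assignments, unclassifiable = classify_groups(
            ibd, adenoma, carcinoma, ["A", "ZZZ"]
        )
        assert [g for g, _ in unclassifiable] == ["ZZZ"]
        assert {a.gene for a in assignments} == {"A"}

    def test_single_tumor_stage_coverage_is_enough(self):
        ibd, adenoma, carcinoma = self._comps()
        adenoma = []  # gene covered only on the carcinoma side of the y axis
        assignments, unclassifiable = classify_groups(ibd, adenoma, carcinoma, ["A"])
        assert unclassifiable == []
        assert assignments[0].y == pytest.approx(3.0)


class TestClusterGenes:
    def _matrix(self, rows):
        values = pd.DataFrame(
            rows, index=[f"G{i}" for i in range(len(rows))],
            columns=["IBD", "adenoma", "primary_carcinoma", "metastasis"][: len(rows[0])],
            dtype=float,
        )
        return ScoreMatrix(values=values, counts=values.notna().astype(int))

    def test_k_equals_n_separated_rows_gives_singletons(self):
        matrix = self._matrix(
            [(1, 1, 1, 1), (1, 0, 0, 0), (0, 0, 0, 0), (0, -1, -1, -1)]
        )
        labels = cluster_genes(matrix, k=4).labels
        assert len(set(labels.values())) == 4

    def test_identical_rows_share_a_cluster(self):
        matrix = self._matrix(
            [(1, 1, 1, 1), (1, 1, 1, 1), (0, 0, 0, 0), (-1, -1, -1, -1),
             (0.5, -0.5, 0, 0)]
        )
        labels = cluster_genes(matrix, k=4).labels
        assert labels["G0"] == labels["G1"]

    def test_missing_cells_imputed_as_zero_only_inside_clustering(self):
        rows = [(1.0, np.nan), (1.0, 0.0), (-1.0, 0.0), (0.0, 0.0)]
        matrix = self._matrix([r + (0.0, 0.0) for r in rows])
        labels = cluster_genes(matrix, k=3).labels
        assert labels["G0"] == labels["G1"]  # NaN treated as 0 for distances
        assert np.isnan(matrix.values.loc["G0"].iloc[1])  # matrix untouched

    def test_fewer_genes_than_k_is_an_error(self):
        matrix = self._matrix([(1, 0), (0, 1)])
        with pytest.raises(ValueError):
            cluster_genes(matrix, k=4)

    def test_deterministic_given_gene_set(self):
        rng = np.random.default_rng(5)
        rows = [tuple(rng.uniform(-1, 1, 3)) for _ in range(10)]
        m1 = self._matrix(rows)
        m2 = self._matrix(rows)
        assert cluster_genes(m1).labels == cluster_genes(m2).labels
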