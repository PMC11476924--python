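"""Stage harmonization, log2 standardization, probe collapse, file I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoatlas import (
    ExpressionDataset,
    SampleAnnotation,
    collapse_probes,
    harmonize_stage,
    read_dataset,
    read_series_matrix,
    to_log2,
    write_dataset,
)
from chemoatlas.errors import ParseError, StageAnnotationError
from chemoatlas.ingest import detect_scale


class TestHarmonizeStage:
    @pytest.mark.parametrize(
        "label,stage",
        [
            ("none", "healthy_control"),
            ("control", "healthy_control"),
            ("normal", "healthy_control"),
            ("normal colonic mucosa", "healthy_control"),
            ("IBD", "IBD"),
            ("UC", "IBD"),
            ("CD", "IBD"),
            ("colon adenoma", "adenoma"),
            ("adenoma", "adenoma"),
            ("colorectal cancer", "primary_carcinoma"),
            ("primary tumor", "primary_carcinoma"),
            ("carcinoma", "primary_carcinoma"),
            ("metastatic cancer", "metastasis"),
            ("liver metastasis", "metastasis"),
            ("lung metastasis", "metastasis"),
        ],
    )
    def test_builtin_vocabulary_is_total(self, label, stage):
        assert harmonize_stage(label) == stage

    def test_case_and_whitespace_normalization(self):
        assert harmonize_stage("Normal ") == "healthy_control"
        assert harmonize_stage("  uc") == "IBD"

    def test_user_rules_take_precedence(self):
        assert harmonize_stage("UC", {"uc": "healthy_control"}) == "healthy_control"
        assert harmonize_stage("polyp", {"polyp": "adenoma"}) == "adenoma"

    def test_unknown_label_raises_naming_it(self):
        with pytest.raises(StageAnnotationError, match="polyp\\?"):
            harmonize_stage("polyp?")


def _dataset(matrix: pd.DataFrame, scale="linear", probe_map=None, stages=None):
    samples = [
        SampleAnnotation(sample_id=c, raw_label="control",
                         stage=(stages or {}).get(c, "healthy_control"))
        for c in matrix.columns
    ]
    return ExpressionDataset(
        dataset_id="toy", species="human", scale=scale, matrix=matrix,
        probe_gene_map=probe_map or {p: p for p in matrix.index}, samples=samples,
    )


class TestToLog2:
    def test_linear_values_transformed(self):
        ds = _dataset(pd.DataFrame({"s1": [8.0], "s2": [1024.0]}, index=["p"]))
        out = to_log2(ds)
        assert out.scale == "log2"
        assert out.matrix.loc["p", "s1"] == pytest.approx(3.0)
        assert out.matrix.loc["p", "s2"] == pytest.approx(10.0)

    def test_nonpositive_values_clamped_to_zero(self):
        ds = _dataset(pd.DataFrame({"s1": [0.0], "s2": [-5.0]}, index=["p"]))
        out = to_log2(ds)
        assert (out.matrix.to_numpy() == 0.0).all()

    def test_idempotent_on_log2_data(self):
        ds = _dataset(pd.DataFrame({"s1": [3.5]}, index=["p"]), scale="log2")
        assert to_log2(ds) is ds

    def test_missing_values_stay_missing(self):
        ds = _dataset(pd.DataFrame({"s1": [np.nan], "s2": [4.0]}, index=["p"]))
        out = to_log2(ds)
        assert math.isnan(out.matrix.loc["p", "s1"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=1.0, max_value=1e6),
           st.floats(min_value=1.0, max_value=1e6))
    def test_monotone_on_positive_values(self, a, b):
        ds = _dataset(pd.DataFrame({"s1": [a], "s2": [b]}, index=["p"]))
        out = to_log2(ds).matrix
        assert (out.loc["p", "s1"] <= out.loc["p", "s2"]) == (a <= b)

    def test_scale_detection(self):
        linear = pd.DataFrame({"s": [20000.0, 3.0]}, index=["a", "b"])
        logged = pd.DataFrame({"s": [12.0, 3.0]}, index=["a", "b"])
        assert detect_scale(linear) == "linear"
        assert detect_scale(logged) == "log2"


class TestCollapseProbes:
    def test_strongest_mean_probe_selected(self):
        matrix = pd.DataFrame(
            {"s1": [7.0, 9.0], "s2": [7.4, 9.2]}, index=["A", "B"]
        )
        ds = _dataset(matrix, scale="log2", probe_map={"A": "G1", "B": "G1"})
        table = collapse_probes(ds)
        assert list(table.values.loc["G1"]) == [9.0, 9.2]

    def test_tie_breaks_to_lexicographically_smallest_probe_id(self):
        matrix = pd.DataFrame(
            {"s1": [5.0, 4.0], "s2": [4.0, 5.0]}, index=["P2", "P10"]
        )
        ds = _dataset(matrix, scale="log2", probe_map={"P2": "G", "P10": "G"})
        table = collapse_probes(ds)
        # equal means; "P10" < "P2" as strings
        assert list(table.values.loc["G"]) == [4.0, 5.0]

    def test_single_probe_per_gene_is_pure_relabeling(self):
        matrix = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["pA", "pB"]
        )
        ds = _dataset(matrix, scale="log2", probe_map={"pA": "GA", "pB": "GB"})
        table = collapse_probes(ds)
        assert list(table.genes) == ["GA", "GB"]
        np.testing.assert_array_equal(table.values.to_numpy(), matrix.to_numpy())

    def test_absent_genes_are_omitted_not_filled(self):
        matrix = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["pA"])
        ds = _dataset(matrix, scale="log2", probe_map={"pA": "GA"})
        table = collapse_probes(ds, genes=["GA", "MISSING"])
        assert list(table.genes) == ["GA"]

    def test_requires_log2_scale(self):
        ds = _dataset(pd.DataFrame({"s1": [8.0]}, index=["p"]))
        with pytest.raises(ValueError, match="log2"):
            collapse_probes(ds)


class TestSeriesMatrixIO:
    def _write_fixture(self, tmp_path, labels, extra_meta=""):
        sample_ids = [f"s{i + 1}" for i in range(len(labels))]
        matrix = tmp_path / "matrix.tsv"
        lines = ["!scale\tlinear", "!dataset_id\tfix1"]
        lines.append("probe_id\t" + "\t".join(sample_ids))
        lines.append("p1\t" + "\t".join(str(4.0 * (i + 1)) for i in range(len(labels))))
        matrix.write_text("\n".join(lines) + "\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text(
            "sample_id\traw_label\n"
            + "".join(f"{s}\t{l}\n" for s, l in zip(sample_ids, labels))
        )
        pm = tmp_path / "pm.tsv"
        pm.write_text("probe_id\tgene_symbol\np1\tCXCL8\n")
        return matrix, ann, pm

    def test_reads_and_harmonizes_mixed_labels(self, tmp_path):
        paths = self._write_fixture(
            tmp_path, ["normal colonic mucosa", "normal colonic mucosa", "UC", "UC", "UC"]
        )
        ds = read_series_matrix(*paths)
        stages = [s.stage for s in ds.samples]
        assert stages.count("healthy_control") == 2
        assert stages.count("IBD") == 3
        assert ds.scale == "linear"
        assert ds.dataset_id == "fix1"

    def test_unknown_label_error_names_it(self, tmp_path):
        paths = self._write_fixture(tmp_path, ["normal", "polyp?"])
        with pytest.raises(StageAnnotationError, match="polyp\\?"):
            read_series_matrix(*paths)

    def test_empty_sample_set_is_an_error(self, tmp_path):
        matrix, ann, pm = self._write_fixture(tmp_path, ["normal"])
        ann.write_text("sample_id\traw_label\n")
        with pytest.raises(ParseError):
            read_series_matrix(matrix, ann, pm)

    def test_write_read_round_trip(self, tmp_path):
        matrix = pd.DataFrame(
            {"a1": [1.5, 2.0], "a2": [2.5, 3.0], "a3": [1.0, 0.5], "a4": [2.2, 1.2]},
            index=["pX", "pY"],
        )
        samples = [
            SampleAnnotation("a1", "control", "healthy_control", "P1"),
            SampleAnnotation("a2", "normal", "healthy_control", "P2"),
            SampleAnnotation("a3", "UC", "IBD", "P1"),
            SampleAnnotation("a4", "CD", "IBD", "P2"),
        ]
        ds = ExpressionDataset(
            dataset_id="rt", species="human", scale="log2", matrix=matrix,
            probe_gene_map={"pX": "CXCL1", "pY": "CCL2"}, samples=samples,
            paired=True,
        )
        write_dataset(ds, tmp_path / "rt")
        back = read_dataset(tmp_path / "rt")
        assert back.dataset_id == "rt"
        assert back.paired is True
        assert back.scale == "log2"
        assert [s.pair_id for s in back.samples] == ["P1", "P2", "P1", "P2"]
        np.testing.assert_allclose(back.matrix.to_numpy(), matrix.to_numpy())
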