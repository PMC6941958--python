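"""Parsing, validation, and round-trip fidelity of every artifact format."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverlens import formats_io as fio
from driverlens.errors import ConsistencyError, FormatError, VocabularyError


def _write_matrix(tmp_path, text, conditions="sample\tcondition\nsA\tnormal\nsB\ttumor\n"):
    m = tmp_path / "expr.tsv"
    c = tmp_path / "cond.tsv"
    m.write_text(text)
    c.write_text(conditions)
    return m, c


class TestReadExpression:
    def test_small_fixture_shapes_and_labels(self, tmp_path):
        m, c = _write_matrix(
            tmp_path, "gene\tsA\tsB\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n"
        )
        expr = fio.read_expression(m, c)
        assert expr.values.shape == (3, 2)
        assert set(expr.condition_map.values()) == {"normal", "tumor"}
        assert expr.gene_ids == ["g1", "g2", "g3"]

    def test_duplicate_sample_header_rejected(self, tmp_path):
        m, c = _write_matrix(
            tmp_path,
            "gene\tsA\tsA\ng1\t1\t2\n",
            "sample\tcondition\nsA\tnormal\n",
        )
        with pytest.raises(FormatError, match="duplicate"):
            fio.read_expression(m, c)

    def test_duplicate_gene_rejected(self, tmp_path):
        m, c = _write_matrix(tmp_path, "gene\tsA\tsB\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(FormatError, match="duplicate gene"):
            fio.read_expression(m, c)

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        m, c = _write_matrix(tmp_path, "gene\tsA\tsB\ng1\t1\tx7\n")
        with pytest.raises(FormatError, match="'x7'.*'g1'.*'sB'"):
            fio.read_expression(m, c)

    def test_sample_missing_from_condition_map(self, tmp_path):
        m, c = _write_matrix(
            tmp_path,
            "gene\tsA\tsB\ng1\t1\t2\n",
            "sample\tcondition\nsA\tnormal\n",
        )
        with pytest.raises(ConsistencyError, match="sB"):
            fio.read_expression(m, c)

    def test_expression_rejects_missing_but_methylation_accepts(self, tmp_path):
        m, c = _write_matrix(tmp_path, "gene\tsA\tsB\ng1\t0.5\t\n")
        with pytest.raises(FormatError, match="missing"):
            fio.read_expression(m, c)
        beta = fio.read_methylation(m, c)
        assert np.isnan(beta.values.loc["g1", "sB"])

    def test_seeded_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(42)
        values = pd.DataFrame(
            rng.lognormal(3.0, 1.0, size=(50, 20)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(20)],
        )
        cmap = {f"s{j}": ("normal" if j < 10 else "tumor") for j in range(20)}
        expr = fio.ExpressionMatrix(values, cmap, counts=False)
        fio.write_expression(expr, tmp_path / "m.tsv", tmp_path / "c.tsv")
        back = fio.read_expression(tmp_path / "m.tsv", tmp_path / "c.tsv", counts=False)
        assert np.array_equal(back.values.to_numpy(), values.to_numpy())
        assert back.condition_map == cmap

    def test_mtx_triplet_roundtrip(self, tmp_path):
        import scipy.io
        import scipy.sparse

        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, size=(6, 4)).astype(float)
        scipy.io.mmwrite(tmp_path / "m.mtx", scipy.sparse.coo_matrix(dense))
        (tmp_path / "m.rows.txt").write_text("".join(f"g{i}\n" for i in range(6)))
        (tmp_path / "m.cols.txt").write_text("".join(f"s{j}\n" for j in range(4)))
        cond = tmp_path / "c.tsv"
        cond.write_text(
            "sample\tcondition\n" + "".join(f"s{j}\tnormal\n" for j in range(4))
        )
        expr = fio.read_expression(tmp_path / "m.mtx", cond)
        assert np.array_equal(expr.values.to_numpy(), dense)

    @settings(max_examples=20, deadline=None)
    @given(
        n_genes=st.integers(1, 8),
        n_samples=st.integers(1, 6),
        seed=st.integers(0, 1000),
    )
    def test_roundtrip_property(self, tmp_path_factory, n_genes, n_samples, seed):
        """write then read is the identity on fuzzed valid matrices."""
        tmp = tmp_path_factory.mktemp("rt")
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)) * 10.0 ** rng.integers(-3, 4),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        expr = fio.ExpressionMatrix(
            values, {f"s{j}": "x" for j in range(n_samples)}, counts=False
        )
        fio.write_expression(expr, tmp / "m.tsv", tmp / "c.tsv")
        back = fio.read_expression(tmp / "m.tsv", tmp / "c.tsv", counts=False)
        assert np.array_equal(back.values.to_numpy(), values.to_numpy())


class TestKnowledge:
    def test_fixture_counts(self, tmp_path, tiny_knowledge):
        fio.write_knowledge(tiny_knowledge, tmp_path / "e.tsv", tmp_path / "f.tsv")
        back = fio.read_knowledge(tmp_path / "e.tsv", tmp_path / "f.tsv")
        assert len(back.entries) == 8
        assert len(back.process_effect) == 2

    def test_unknown_direction_token(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene\tprocess\tdirection\tpublication_count\ng1\tp1\tUp\t3\n"
        )
        (tmp_path / "f.tsv").write_text("process\teffect\np1\tpromotes_cancer\n")
        with pytest.raises(VocabularyError, match="Up"):
            fio.read_knowledge(tmp_path / "e.tsv", tmp_path / "f.tsv")

    def test_duplicate_entry_rejected(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene\tprocess\tdirection\tpublication_count\n"
            "g1\tp1\tIncreased\t3\ng1\tp1\tDecreased\t2\n"
        )
        (tmp_path / "f.tsv").write_text("process\teffect\np1\tpromotes_cancer\n")
        with pytest.raises(FormatError, match="duplicate"):
            fio.read_knowledge(tmp_path / "e.tsv", tmp_path / "f.tsv")

    def test_process_without_effect_record(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene\tprocess\tdirection\tpublication_count\ng1\tp1\tIncreased\t3\n"
        )
        (tmp_path / "f.tsv").write_text("process\teffect\np2\tpromotes_cancer\n")
        with pytest.raises(ConsistencyError, match="p1"):
            fio.read_knowledge(tmp_path / "e.tsv", tmp_path / "f.tsv")


class TestDriverCalls:
    def _calls(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene", "condition", "role", "z_growth", "z_death"]
        )
        return fio.DriverCallSet(df, growth_process="growth", death_process="death")

    def test_summary_counts(self, tmp_path):
        calls = self._calls(
            [
                ("g1", "brca", "OCG", 2.0, -2.0),
                ("g2", "brca", "OCG", 1.5, -0.5),
                ("g3", "brca", "TSG", -2.0, 2.0),
            ]
        )
        assert calls.summary() == {
            "brca": {"OCG": 2, "TSG": 1, "unclassified": 0, "dual_role": 0}
        }

    def test_empty_call_set_roundtrip(self, tmp_path):
        calls = self._calls([])
        fio.write_driver_calls(calls, tmp_path / "calls.tsv")
        back = fio.read_driver_calls(tmp_path / "calls.tsv")
        assert len(back.calls) == 0
        assert back.summary() == {}

    def test_roundtrip_preserves_fields(self, tmp_path):
        calls = self._calls(
            [("g1", "a", "OCG", 2.25, -1.75), ("g1", "b", "TSG", -3.0, 1.0)]
        )
        calls.calls.loc[0, "critical_epigenetic"] = True
        calls.calls["dual_role"] = True
        fio.write_driver_calls(calls, tmp_path / "calls.tsv")
        back = fio.read_driver_calls(tmp_path / "calls.tsv")
        pd.testing.assert_frame_equal(back.calls, calls.calls)
        assert back.growth_process == "growth"

    def test_duplicate_gene_condition_rejected(self):
        with pytest.raises(FormatError, match="unique"):
            self._calls(
                [("g1", "a", "OCG", 1.0, -1.0), ("g1", "a", "TSG", -1.0, 1.0)]
            )


def test_gene_list_roundtrip(tmp_path):
    (tmp_path / "genes.txt").write_text("TP53\nBRCA1\n\nMYC\n")
    assert fio.read_gene_list(tmp_path / "genes.txt") == {"TP53", "BRCA1", "MYC"}


def test_evidence_vocabulary_enforced():
    bad = pd.DataFrame(
        [("g1", "a", "methylation", "amplified")],
        columns=["gene", "condition", "evidence_kind", "evidence_value"],
    )
    with pytest.raises(VocabularyError):
        fio.EvidenceTable(bad)
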