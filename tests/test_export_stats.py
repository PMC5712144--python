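import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from metapep.export_stats import (
    fb_ratio,
    normalize_matrix,
    pearson_distance,
    read_biom,
    validate_biom,
    validity_filter,
    write_biom,
    write_result_tables,
)
from metapep.io_formats import PeptideRecord
from metapep.taxonomy import TaxonomyTree, TaxonNode, quantify_taxa

NODES = {
    1: TaxonNode(1, 1, "no rank", "root"),
    2: TaxonNode(2, 1, "superkingdom", "Bacteria"),
    3: TaxonNode(3, 2, "phylum", "Firmicutes"),
    4: TaxonNode(4, 2, "phylum", "Bacteroidetes"),
    5: TaxonNode(5, 3, "species", "firmicute A"),
    6: TaxonNode(6, 4, "species", "bacteroidete B"),
}


@pytest.fixture()
def tree():
    return TaxonomyTree(dict(NODES))


def make_table(tree, intensities, counts=None, samples=("A", "B", "C")):
    """Quantify peptides planted directly at species 5 and 6."""
    peptides = []
    for i, (node, per_sample) in enumerate(intensities):
        counts_i = counts[i] if counts else {s: 1 for s in per_sample}
        p = PeptideRecord(f"AAAAAA{i:03d}K", dict(counts_i), dict(per_sample),
                          lca=node, lineage=tree.lineage(node))
        peptides.append(p)
    return quantify_taxa(peptides, tree)


class TestBiom:
    def test_shape_and_nnz(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 10.0, "B": 0.0, "C": 5.0}),
                                  (6, {"A": 0.0, "B": 3.0, "C": 0.0})])
        doc = write_biom(table, "species", "intensity", tmp_path / "t.biom")
        assert doc["shape"] == [2, 3]
        rows, cols, matrix, _ = read_biom(tmp_path / "t.biom")
        assert np.count_nonzero(matrix) == 3

    def test_round_trip_fidelity(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 10.0, "B": 2.0, "C": 5.0}),
                                  (6, {"A": 1.0, "B": 3.0, "C": 7.0})])
        write_biom(table, "all", "intensity", tmp_path / "t.biom")
        rows, cols, matrix, doc = read_biom(tmp_path / "t.biom")
        expected = table.intensity.loc[[int(r) for r in rows], cols].to_numpy()
        assert np.allclose(matrix, expected)
        validate_biom(doc)

    def test_peptide_count_mode_is_integral(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 10.0, "B": 2.0, "C": 5.0})])
        doc = write_biom(table, "all", "peptide_count", tmp_path / "t.biom")
        assert doc["matrix_element_type"] == "int"
        values = (
            [v for _, _, v in doc["data"]]
            if doc["matrix_type"] == "sparse"
            else [v for row in doc["data"] for v in row]
        )
        assert all(isinstance(v, int) for v in values)

    def test_empty_rank_is_error(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 1.0})])
        with pytest.raises(ValueError):
            write_biom(table, "genus", "intensity", tmp_path / "t.biom")

    def test_validator_catches_broken_documents(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 1.0})])
        doc = write_biom(table, "all", "intensity", tmp_path / "t.biom")
        broken = dict(doc)
        del broken["shape"]
        with pytest.raises(ValueError, match="shape"):
            validate_biom(broken)
        broken = dict(doc, shape=[99, 99])
        with pytest.raises(ValueError):
            validate_biom(broken)

    def test_r_biomformat_reads_export(self, tree, tmp_path):
        """Independent oracle: the Bioconductor biomformat parser."""
        table = make_table(tree, [(5, {"A": 10.0, "B": 2.0, "C": 5.0}),
                                  (6, {"A": 1.0, "B": 3.0, "C": 7.0})])
        path = tmp_path / "t.biom"
        write_biom(table, "all", "intensity", path)
        script = (
            'suppressMessages(library(biomformat));'
            f'b <- read_biom("{path}");'
            'm <- as(biom_data(b), "matrix");'
            'cat(nrow(m), ncol(m), sum(m))'
        )
        out = subprocess.run(
            [shutil.which("Rscript") or "Rscript", "-e", script],
            capture_output=True, text=True, check=True,
        )
        n_rows, n_cols, total = out.stdout.split()
        assert int(n_rows) == len(table.taxa)
        assert int(n_cols) == 3
        assert float(total) == pytest.approx(table.intensity.to_numpy().sum())


class TestResultTables:
    def test_files_and_headers(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 10.0, "B": 2.0, "C": 5.0})])
        peptides = [PeptideRecord("AAAAAA000K", {"A": 1}, {"A": 10.0},
                                  lca=5, lineage=tree.lineage(5)),
                    PeptideRecord("UNASSIGNEDK", {"A": 1}, {"A": 1.0})]
        paths = write_result_tables(peptides, table, tmp_path, tree)
        pep = pd.read_csv(paths["peptides"], sep="\t")
        taxa = pd.read_csv(paths["taxa"], sep="\t")
        assert "sequence" in pep.columns and "lineage" in pep.columns
        assert (pep.loc[pep.sequence == "UNASSIGNEDK", "lineage"] == "unassigned").all()
        assert len(taxa) == len(table)  # LCAs plus all ancestors

    def test_deterministic_bytes(self, tree, tmp_path):
        table = make_table(tree, [(5, {"A": 10.0, "B": 2.0, "C": 5.0})])
        peptides = [PeptideRecord("AAAAAA000K", {"A": 1}, {"A": 10.0},
                                  lca=5, lineage=tree.lineage(5))]
        p1 = write_result_tables(peptides, table, tmp_path / "r1", tree)
        p2 = write_result_tables(peptides, table, tmp_path / "r2", tree)
        assert p1["taxa"].read_bytes() == p2["taxa"].read_bytes()
        assert p1["peptides"].read_bytes() == p2["peptides"].read_bytes()


class TestFbRatio:
    def test_hand_computed_ratio(self, tree):
        table = make_table(tree, [(5, {"A": 300.0}), (6, {"A": 150.0})])
        assert fb_ratio(table, "A") == pytest.approx(2.0)

    def test_equal_quantities_give_one(self, tree):
        table = make_table(tree, [(5, {"A": 5.0}), (6, {"A": 5.0})])
        assert fb_ratio(table, "A") == pytest.approx(1.0)

    def test_zero_denominator_is_nan(self, tree):
        table = make_table(tree, [(5, {"A": 5.0, "B": 1.0}), (6, {"A": 0.0, "B": 1.0})])
        assert np.isnan(fb_ratio(table, "A"))

    def test_through_quantification(self, tree):
        # hand calculation through quantify_taxa: two peptides on Firmicutes
        table = make_table(tree, [(5, {"A": 100.0}), (5, {"A": 50.0}), (6, {"A": 75.0})])
        assert fb_ratio(table, "A") == pytest.approx(150.0 / 75.0)


class TestValidityFilter:
    def build(self, tree, peptide_counts):
        # peptide_counts: node -> list of per-sample unique peptide counts
        samples = [f"S{i}" for i in range(len(next(iter(peptide_counts.values()))))]
        peptides = []
        i = 0
        for node, counts in peptide_counts.items():
            for k in range(max(counts)):
                per_sample = {s: 1.0 if counts[j] > k else 0.0 for j, s in enumerate(samples)}
                sc = {s: 1 if counts[j] > k else 0 for j, s in enumerate(samples)}
                peptides.append(PeptideRecord(f"AAAA{i:04d}K", sc, per_sample,
                                              lca=node, lineage=tree.lineage(node)))
                i += 1
        return quantify_taxa(peptides, tree)

    def test_three_peptides_in_nine_samples_kept(self, tree):
        table = self.build(tree, {5: [3] * 9})
        assert validity_filter(table) == [5]

    def test_valid_in_exactly_eight_samples_dropped(self, tree):
        table = self.build(tree, {5: [3] * 8 + [0]})
        assert validity_filter(table) == []

    def test_two_peptides_everywhere_dropped(self, tree):
        table = self.build(tree, {5: [2] * 12})
        assert validity_filter(table) == []


class TestNormalize:
    def test_hand_arithmetic(self):
        m = pd.DataFrame({"A": [10.0, 100.0, 1000.0]})
        out = normalize_matrix(m)
        assert out["A"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_identical_columns_identical_output(self):
        m = pd.DataFrame({"A": [1.0, 5.0, 9.0], "B": [1.0, 5.0, 9.0]})
        out = normalize_matrix(m)
        assert out["A"].tolist() == pytest.approx(out["B"].tolist())

    def test_median_scale_invariance(self, rng):
        col = rng.uniform(1, 100, size=20)
        m = pd.DataFrame({"A": col, "B": col * 7.0})
        out = normalize_matrix(m)
        assert out["A"].tolist() == pytest.approx(out["B"].tolist())

    def test_zeros_become_missing(self):
        m = pd.DataFrame({"A": [0.0, 10.0, 100.0]})
        out = normalize_matrix(m)
        assert np.isnan(out["A"].iloc[0])

    def test_all_zero_column_is_error(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(ValueError, match="B"):
            normalize_matrix(m)


class TestPearsonDistance:
    def test_perfect_correlation_zero_distance(self):
        m = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.0, 4.0, 6.0]})
        d = pearson_distance(m)
        assert d.at["A", "B"] == pytest.approx(0.0)
        assert d.at["A", "A"] == 0.0

    def test_anticorrelation_distance_two(self):
        m = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [3.0, 2.0, 1.0]})
        assert pearson_distance(m).at["A", "B"] == pytest.approx(2.0)

    def test_matches_formula_oracle(self, rng):
        m = pd.DataFrame(rng.uniform(0, 1, size=(20, 5)), columns=list("ABCDE"))
        d = pearson_distance(m)
        for a in "ABCDE":
            for b in "ABCDE":
                x, y = m[a].to_numpy(), m[b].to_numpy()
                r = np.sum((x - x.mean()) * (y - y.mean())) / (
                    np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
                )
                expected = 0.0 if a == b else 1.0 - r
                assert d.at[a, b] == pytest.approx(expected)

    def test_constant_column_undefined(self):
        m = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        assert np.isnan(pearson_distance(m).at["A", "B"])
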