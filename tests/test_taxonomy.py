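import numpy as np
import pytest

from metapep.io_formats import PeptideRecord
from metapep.pep2tax import build_index
from metapep.taxonomy import (
    TaxonNode,
    TaxonomyTree,
    assign_lcas,
    filter_nodes,
    lca,
    quantify_taxa,
    rank_distinctive,
)

from .conftest import random_tree

# A small fixed taxonomy:
#   root(1) > Bacteria(2) > Firmicutes(3) > Clostridia(4) > orderA(5)
#     > famA(6) > genusA(7) > speciesA(8), speciesB(9)
#     > famA(6) > genusB(10) > "bacterium 999"(11)
#   Bacteria(2) > "environmental samples"(12, no rank) > envspecies(13)
FIXED_NODES = {
    1: TaxonNode(1, 1, "no rank", "root"),
    2: TaxonNode(2, 1, "superkingdom", "Bacteria"),
    3: TaxonNode(3, 2, "phylum", "Firmicutes"),
    4: TaxonNode(4, 3, "class", "Clostridia"),
    5: TaxonNode(5, 4, "order", "orderA"),
    6: TaxonNode(6, 5, "family", "famA"),
    7: TaxonNode(7, 6, "genus", "genusA"),
    8: TaxonNode(8, 7, "species", "Escherichia coli"),
    9: TaxonNode(9, 7, "species", "speciesB"),
    10: TaxonNode(10, 6, "genus", "genusB"),
    11: TaxonNode(11, 10, "species", "bacterium 999"),
    12: TaxonNode(12, 2, "no rank", "environmental samples"),
    13: TaxonNode(13, 12, "species", "envspecies"),
}


@pytest.fixture()
def tree():
    return TaxonomyTree(dict(FIXED_NODES))


class TestLoading:
    def test_tsv_and_taxdump_agree(self, tree, tmp_path):
        tree.to_tsv(tmp_path / "tax.tsv")
        tree.to_taxdump(tmp_path / "dump")
        from_tsv = TaxonomyTree.load(tmp_path / "tax.tsv")
        from_dump = TaxonomyTree.load(tmp_path / "dump")
        assert from_tsv.nodes == tree.nodes
        assert {t: n.parent for t, n in from_dump.nodes.items()} == {
            t: n.parent for t, n in tree.nodes.items()
        }
        assert from_dump.name(8) == "Escherichia coli"

    def test_missing_parent_rejected(self):
        nodes = {1: TaxonNode(1, 1, "no rank", "root"), 2: TaxonNode(2, 99, "species", "x")}
        with pytest.raises(ValueError, match="parent"):
            TaxonomyTree(nodes)

    def test_cycle_rejected(self):
        nodes = {
            1: TaxonNode(1, 1, "no rank", "root"),
            2: TaxonNode(2, 3, "no rank", "a"),
            3: TaxonNode(3, 2, "no rank", "b"),
        }
        with pytest.raises(ValueError, match="cycle"):
            TaxonomyTree(nodes)

    def test_two_roots_rejected(self):
        nodes = {1: TaxonNode(1, 1, "no rank", "r1"), 2: TaxonNode(2, 2, "no rank", "r2")}
        with pytest.raises(ValueError, match="root"):
            TaxonomyTree(nodes)


class TestFilterNodes:
    def test_named_species_retained_under_both_policies(self, tree):
        assert filter_nodes({8}, tree, "permissive") == {8}
        assert filter_nodes({8}, tree, "unipept-like") == {8}

    def test_digit_species_removed_only_by_unipept_like(self, tree):
        assert filter_nodes({11}, tree, "permissive") == {11}
        assert filter_nodes({11}, tree, "unipept-like") == set()

    def test_environmental_samples_child_removed(self, tree):
        assert filter_nodes({13}, tree, "unipept-like") == set()
        assert filter_nodes({13}, tree, "permissive") == {13}

    def test_digit_rule_not_applied_above_species(self, tree):
        nodes = dict(FIXED_NODES)
        nodes[14] = TaxonNode(14, 6, "genus", "genus 42")
        t = TaxonomyTree(nodes)
        assert filter_nodes({14}, t, "unipept-like") == {14}

    def test_unknown_id_is_error(self, tree):
        with pytest.raises(KeyError):
            filter_nodes({999}, tree, "permissive")

    def test_permissive_superset_property(self, tree, rng):
        ids = list(FIXED_NODES)
        for _ in range(50):
            subset = set(rng.choice(ids, size=int(rng.integers(1, 6)), replace=False).tolist())
            assert filter_nodes(subset, tree, "unipept-like").issubset(
                filter_nodes(subset, tree, "permissive")
            )


class TestLca:
    def test_singleton(self, tree):
        assert lca({8}, tree) == 8

    def test_sister_species_meet_at_genus(self, tree):
        assert lca({8, 9}, tree) == 7

    def test_cross_family_meet_at_family(self, tree):
        assert lca({8, 11}, tree) == 6

    def test_empty_set_unassigned(self, tree):
        assert lca(set(), tree) is None

    def test_matches_brute_force_on_random_trees(self, rng):
        t = random_tree(rng, n_nodes=120)
        ids = list(t.nodes)
        for _ in range(300):
            subset = rng.choice(ids, size=int(rng.integers(1, 8)), replace=False).tolist()
            # oracle: intersect full root paths, take the deepest node
            common = set(t.lineage(subset[0]))
            for tid in subset[1:]:
                common &= set(t.lineage(tid))
            expected = max(common, key=t.depth)
            assert lca(set(subset), t) == expected


class TestAssignAndRank:
    def make_index(self, tree, tmp_path):
        from metapep.io_formats import ProteinRecord

        db = [
            ProteinRecord("u8", "u8", "AAASPECEEK", taxon_id=8),      # unique to species 8
            ProteinRecord("g1", "g1", "CCCGENESAK", taxon_id=8),      # shared in genusA
            ProteinRecord("g2", "g2", "CCCGENESAK", taxon_id=9),
            ProteinRecord("f1", "f1", "DDDFAMILYK", taxon_id=8),      # shared across genera
            ProteinRecord("f2", "f2", "DDDFAMILYK", taxon_id=11),
        ]
        return build_index(db, tree, out_path=tmp_path / "i.p2t")

    def test_lineages(self, tree, tmp_path):
        index = self.make_index(tree, tmp_path)
        peptides = [
            PeptideRecord("AAASPECEEK", {"A": 1}, {"A": 10.0}),
            PeptideRecord("CCCGENESAK", {"A": 1}, {"A": 10.0}),
            PeptideRecord("DDDFAMILYK", {"A": 1}, {"A": 10.0}),
            PeptideRecord("NEVERSEENK", {"A": 1}, {"A": 10.0}),
        ]
        assign_lcas(peptides, index, tree)
        assert peptides[0].lca == 8 and peptides[0].lineage[-1] == 8
        assert peptides[1].lca == 7  # genus
        assert peptides[2].lca == 6  # family
        assert peptides[3].lca is None

    def test_rank_distinctive(self, tree, tmp_path):
        index = self.make_index(tree, tmp_path)
        peptides = [
            PeptideRecord("AAASPECEEK", {"A": 1}, {"A": 10.0}),
            PeptideRecord("DDDFAMILYK", {"A": 1}, {"A": 10.0}),
        ]
        assign_lcas(peptides, index, tree)
        assert len(rank_distinctive(peptides, "species", tree)) == 1
        assert len(rank_distinctive(peptides, "genus", tree)) == 1
        assert len(rank_distinctive(peptides, "family", tree)) == 2
        assert len(rank_distinctive(peptides, "phylum", tree)) == 2
        with pytest.raises(ValueError, match="rank"):
            rank_distinctive(peptides, "tribe", tree)

    def test_permissive_lca_never_deeper_than_unipept(self, tree, tmp_path):
        from metapep.io_formats import ProteinRecord

        db = [
            ProteinRecord("a", "a", "EEESHAREDK", taxon_id=8),
            ProteinRecord("b", "b", "EEESHAREDK", taxon_id=11),  # digit species
        ]
        index = build_index(db, tree, out_path=tmp_path / "j.p2t")
        pep_m = [PeptideRecord("EEESHAREDK", {"A": 1}, {"A": 1.0})]
        pep_u = [PeptideRecord("EEESHAREDK", {"A": 1}, {"A": 1.0})]
        assign_lcas(pep_m, index, tree, policy="permissive")
        assign_lcas(pep_u, index, tree, policy="unipept-like")
        assert pep_m[0].lca == 6       # family (both species kept)
        assert pep_u[0].lca == 8       # digit species dropped -> deeper LCA
        assert tree.depth(pep_m[0].lca) <= tree.depth(pep_u[0].lca)


class TestQuantify:
    def test_summation_rule(self, tree):
        peptides = [
            PeptideRecord("AAAAAAK", {"A": 1}, {"A": 100.0}, lca=8),
            PeptideRecord("CCCCCCK", {"A": 1}, {"A": 50.0}, lca=7),
        ]
        for p in peptides:
            p.lineage = tree.lineage(p.lca)
        table = quantify_taxa(peptides, tree)
        assert table.intensity.at[8, "A"] == pytest.approx(100.0)
        assert table.intensity.at[7, "A"] == pytest.approx(150.0)
        assert table.intensity.at[1, "A"] == pytest.approx(150.0)

    def test_empty_input_empty_table(self, tree):
        table = quantify_taxa([], tree)
        assert len(table) == 0

    def test_conservation_identity_random_fixture(self, tree, rng):
        leaves = [8, 9, 11, 13]
        samples = ["A", "B", "C"]
        peptides = []
        for i in range(60):
            node = int(rng.choice(list(tree.nodes)))
            counts = {s: int(rng.integers(0, 5)) for s in samples}
            intens = {s: float(rng.integers(0, 100)) for s in samples}
            p = PeptideRecord(f"PEPTIDE{i:03d}K", counts, intens, lca=node,
                              lineage=tree.lineage(node))
            peptides.append(p)
        table = quantify_taxa(peptides, tree)
        own = {mode: {} for mode in table.MODES}
        for p in peptides:
            for mode in table.MODES:
                acc = own[mode].setdefault(p.lca, dict.fromkeys(samples, 0.0))
                for s in samples:
                    if mode == "peptide_count":
                        acc[s] += 1 if (p.spectral_count.get(s, 0) > 0
                                        or p.intensity.get(s, 0) > 0) else 0
                    elif mode == "spectral_count":
                        acc[s] += p.spectral_count.get(s, 0)
                    else:
                        acc[s] += p.intensity.get(s, 0.0)
        for mode in table.MODES:
            m = table.matrix(mode)
            for node in table.taxa:
                children = [c for c in tree.children(node) if c in set(table.taxa)]
                for s in samples:
                    expected = sum(m.at[c, s] for c in children) + own[mode].get(
                        node, {}
                    ).get(s, 0.0)
                    assert m.at[node, s] == pytest.approx(expected)

    def test_root_equals_total_assigned(self, tree, rng):
        peptides = []
        for i in range(30):
            node = int(rng.choice([8, 9, 11, 13, 7, 6]))
            p = PeptideRecord(f"AAA{i:03d}K", {"A": 1}, {"A": float(i)}, lca=node,
                              lineage=tree.lineage(node))
            peptides.append(p)
        table = quantify_taxa(peptides, tree)
        assert table.intensity.at[1, "A"] == pytest.approx(sum(float(i) for i in range(30)))
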