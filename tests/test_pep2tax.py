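import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapep.io_formats import ProteinRecord
from metapep.pep2tax import (
    DigestConfig,
    Pep2TaxIndex,
    build_index,
    cleavage_sites,
    digest,
)
from metapep.taxonomy import TaxonNode, TaxonomyTree


def brute_force_digest(sequence, config):
    """Independent enumeration: all substrings delimited by cleavage-site
    boundaries, counting internal sites, filtered by length."""
    if not sequence:
        return set()
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (config.proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    bounds = [0] + sites + [len(sequence)]
    out = set()
    for a, b in itertools.combinations(range(len(bounds)), 2):
        missed = b - a - 1
        if missed > config.max_missed_cleavages:
            continue
        pep = sequence[bounds[a]:bounds[b]]
        if config.min_length <= len(pep) <= config.max_length:
            out.add(pep)
    return out


def small_tree(taxon_ids):
    nodes = {1: TaxonNode(1, 1, "no rank", "root")}
    for tid in taxon_ids:
        nodes[tid] = TaxonNode(tid, 1, "species", f"species {tid}")
    return TaxonomyTree(nodes)


class TestDigest:
    def test_proline_rule_and_length_filter(self):
        assert digest("MKRPEPTIDEK") == {"RPEPTIDEK", "MKRPEPTIDEK"}

    def test_no_cleavage_site_whole_sequence(self):
        assert digest("ACDEFGHILM") == {"ACDEFGHILM"}

    def test_long_uncleavable_sequence_discarded(self):
        assert digest("A" * 40) == set()

    def test_empty_sequence(self):
        assert digest("") == set()

    def test_missed_cleavage_zero(self):
        cfg = DigestConfig(max_missed_cleavages=0)
        assert digest("AAAAAKCCCCCK", cfg) == {"AAAAAK", "CCCCCK"}

    def test_matches_brute_force_on_random_sequences(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        cfg = DigestConfig()
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=int(rng.integers(1, 80))))
            assert digest(seq, cfg) == brute_force_digest(seq, cfg)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=60))
    def test_products_are_valid_tryptic_substrings(self, seq):
        cfg = DigestConfig()
        for pep in digest(seq, cfg):
            assert cfg.min_length <= len(pep) <= cfg.max_length
            assert pep in seq
            # internal missed-cleavage count within the allowance
            internal = sum(
                1
                for i in range(len(pep) - 1)
                if pep[i] in "KR" and pep[i + 1] != "P"
            )
            assert internal <= cfg.max_missed_cleavages
        assert digest(seq, cfg) == brute_force_digest(seq, cfg)

    def test_proline_rule_off(self):
        cfg = DigestConfig(proline_rule=False)
        assert cleavage_sites("AKPAAA", cfg) == [2]
        assert cleavage_sites("AKPAAA", DigestConfig()) == []


class TestBuildIndex:
    def test_shared_peptide_unions_taxa(self, tmp_path):
        db = [
            ProteinRecord("A", "A", "AAAPEPTIDEK", taxon_id=10),
            ProteinRecord("B", "B", "CCCPEPTLDEKAAAPEPTIDEK", taxon_id=20),
        ]
        index = build_index(db, small_tree([10, 20]), out_path=tmp_path / "i.p2t")
        assert index.lookup("AAAPEPTIDEK") == {10, 20}

    def test_single_protein_maps_to_its_taxon(self, tmp_path):
        db = [ProteinRecord("A", "A", "MKRPEPTIDEKAAAAAK", taxon_id=10)]
        index = build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")
        assert len(index) > 0
        for pep, taxa in index.items():
            assert taxa == {10}

    def test_matches_in_memory_oracle(self, rng, tmp_path):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        db = []
        for i in range(100):
            seq = "".join(rng.choice(letters, size=int(rng.integers(20, 120))))
            db.append(ProteinRecord(f"P{i}", f"P{i}", seq, taxon_id=int(rng.integers(10, 20))))
        cfg = DigestConfig()
        oracle: dict = {}
        for rec in db:
            for pep in digest(rec.sequence, cfg):
                if "X" not in pep:
                    oracle.setdefault(pep, set()).add(rec.taxon_id)
        index = build_index(db, small_tree(range(10, 20)), cfg,
                            out_path=tmp_path / "i.p2t", chunk_size=500)
        assert dict(index.items()) == oracle

    def test_proteins_without_taxon_skipped(self, tmp_path):
        db = [
            ProteinRecord("A", "A", "AAAPEPTIDEK", taxon_id=10),
            ProteinRecord("B", "B", "CCCPEPTLDEK", taxon_id=None),
        ]
        index = build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")
        assert index.lookup("CCCPEPTLDEK") == set()
        assert index.header["n_proteins_skipped"] == 1

    def test_unknown_taxon_is_error(self, tmp_path):
        db = [ProteinRecord("A", "A", "AAAPEPTIDEK", taxon_id=99)]
        with pytest.raises(KeyError, match="99"):
            build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")

    def test_peptides_with_x_dropped(self, tmp_path):
        db = [ProteinRecord("A", "A", "AAXPEPTIDEK", taxon_id=10)]
        index = build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")
        assert all("X" not in pep for pep, _ in index.items())

    def test_monotone_under_protein_addition(self, tmp_path, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        db = [
            ProteinRecord(f"P{i}", f"P{i}",
                          "".join(rng.choice(letters, size=60)), taxon_id=10 + i)
            for i in range(6)
        ]
        small = build_index(db[:3], small_tree(range(10, 16)), out_path=tmp_path / "a.p2t")
        large = build_index(db, small_tree(range(10, 16)), out_path=tmp_path / "b.p2t")
        for pep, taxa in small.items():
            assert taxa.issubset(large.lookup(pep))


class TestIndexFile:
    def test_disk_round_trip(self, tmp_path):
        db = [ProteinRecord("A", "A", "MKRPEPTIDEKAAAAAKCCCCCK", taxon_id=10)]
        built = build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")
        reopened = Pep2TaxIndex.open(tmp_path / "i.p2t")
        assert dict(built.items()) == dict(reopened.items())

    def test_fingerprint_mismatch_refused(self, tmp_path):
        db = [ProteinRecord("A", "A", "MKRPEPTIDEK", taxon_id=10)]
        build_index(db, small_tree([10]), DigestConfig(), out_path=tmp_path / "i.p2t")
        with pytest.raises(ValueError, match="fingerprint"):
            Pep2TaxIndex.open(tmp_path / "i.p2t",
                              expect_config=DigestConfig(max_missed_cleavages=1))

    def test_bad_magic_refused(self, tmp_path):
        path = tmp_path / "junk.p2t"
        path.write_text("not an index\n")
        with pytest.raises(ValueError, match="magic"):
            Pep2TaxIndex.open(path)

    def test_closed_index_errors(self, tmp_path):
        db = [ProteinRecord("A", "A", "MKRPEPTIDEK", taxon_id=10)]
        index = build_index(db, small_tree([10]), out_path=tmp_path / "i.p2t")
        index.close()
        with pytest.raises(ValueError, match="closed"):
            index.lookup("RPEPTIDEK")

    def test_equate_il_folds_lookups(self, tmp_path):
        db = [ProteinRecord("A", "A", "AAAPEPTIDEK", taxon_id=10)]
        cfg = DigestConfig(equate_il=True)
        index = build_index(db, small_tree([10]), cfg, out_path=tmp_path / "i.p2t")
        assert index.lookup("AAAPEPTLDEK") == {10}
        assert index.lookup("AAAPEPTIDEK") == {10}
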