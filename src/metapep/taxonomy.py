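"""Taxonomy tree handling, LCA assignment and taxon quantification.

Peptides are mapped through the pep2tax index to the set of taxa whose
proteins could have produced them, and each peptide is assigned the
lowest common ancestor (LCA) of that set.  Two node-filtering policies
are provided: ``permissive`` keeps every node (including provisional
species whose names contain digits and descendants of "environmental
samples", on the view that discarding them loses information), while
``unipept-like`` removes them before the LCA is computed.

Quantification follows the distinctive-peptide rule: a peptide
contributes its per-sample intensity, spectral count, and a peptide
count of 1 to every node on its LCA lineage (the LCA and all its
ancestors).  Peptides shared more widely than a node's subtree never
contribute to that node, and the resulting table satisfies the
conservation identity value(node) = sum over child nodes present +
peptides whose LCA is exactly the node.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import PeptideRecord
from .pep2tax import Pep2TaxIndex

CANONICAL_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

POLICIES = ("permissive", "unipept-like")


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: int
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """NCBI-style taxonomy: every node points to its parent; the root is
    its own parent.  Ranks outside :data:`CANONICAL_RANKS` are allowed
    ("no rank") but excluded from rank projections."""

    def __init__(self, nodes: dict[int, TaxonNode]):
        if not nodes:
            raise ValueError("taxonomy has no nodes")
        roots = [tid for tid, n in nodes.items() if n.parent == tid]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        self.nodes = nodes
        self.root_id = roots[0]
        self._lineages: dict[int, tuple[int, ...]] = {}
        self._validate()

    def _validate(self) -> None:
        ok: set[int] = {self.root_id}
        for tid in self.nodes:
            path = []
            cur = tid
            seen = set()
            while cur not in ok:
                if cur in seen:
                    raise ValueError(f"taxonomy cycle involving id {cur}")
                seen.add(cur)
                path.append(cur)
                parent = self.nodes[cur].parent
                if parent not in self.nodes:
                    raise ValueError(f"node {cur} has missing parent {parent}")
                cur = parent
            ok.update(path)

    # -- accessors ---------------------------------------------------------
    def name(self, tid: int) -> str:
        return self.nodes[tid].name

    def rank(self, tid: int) -> str:
        return self.nodes[tid].rank

    def parent(self, tid: int) -> int:
        return self.nodes[tid].parent

    def lineage(self, tid: int) -> list[int]:
        """Node ids from the root down to ``tid`` (inclusive)."""
        cached = self._lineages.get(tid)
        if cached is None:
            if tid not in self.nodes:
                raise KeyError(f"unknown taxon id {tid}")
            path = [tid]
            cur = tid
            while cur != self.root_id:
                cur = self.nodes[cur].parent
                path.append(cur)
            cached = tuple(reversed(path))
            self._lineages[tid] = cached
        return list(cached)

    def depth(self, tid: int) -> int:
        return len(self.lineage(tid)) - 1

    def is_ancestor(self, anc: int, tid: int) -> bool:
        return anc in self.lineage(tid)

    def children(self, tid: int) -> list[int]:
        return sorted(
            c for c, n in self.nodes.items() if n.parent == tid and c != tid
        )

    def rank_node(self, tid: int, rank: str) -> int | None:
        """The ancestor of ``tid`` (or itself) at ``rank``, if any."""
        for node in self.lineage(tid):
            if self.nodes[node].rank == rank:
                return node
        return None

    # -- construction ------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "TaxonomyTree":
        """Load a taxonomy from an NCBI taxdump directory or a 4-column TSV."""
        path = Path(path)
        if path.is_dir():
            return cls.from_taxdump(path)
        return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """TSV dialect: ``taxon_id <tab> parent_id <tab> rank <tab> name``."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["taxon_id", "parent", "rank", "name"],
            comment="#",
            dtype={"taxon_id": int, "parent": int, "rank": str, "name": str},
        )
        nodes = {
            int(r.taxon_id): TaxonNode(int(r.taxon_id), int(r.parent), r.rank, r.name)
            for r in df.itertuples()
        }
        if len(nodes) != len(df):
            raise ValueError(f"{path}: duplicate taxon ids")
        return cls(nodes)

    @classmethod
    def from_taxdump(cls, directory: str | Path) -> "TaxonomyTree":
        """NCBI taxdump dialect: ``nodes.dmp`` and ``names.dmp`` with
        ``\\t|\\t``-separated fields; only scientific names are used."""
        directory = Path(directory)
        parents: dict[int, tuple[int, str]] = {}
        for line in (directory / "nodes.dmp").read_text().splitlines():
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("|").split("\t|\t")]
            tid, parent, rank = int(fields[0]), int(fields[1]), fields[2].rstrip("\t|").strip()
            parents[tid] = (parent, rank)
        names: dict[int, str] = {}
        for line in (directory / "names.dmp").read_text().splitlines():
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\t|").split("\t|\t")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[int(fields[0])] = fields[1]
        nodes = {
            tid: TaxonNode(tid, parent, rank, names.get(tid, f"taxon {tid}"))
            for tid, (parent, rank) in parents.items()
        }
        return cls(nodes)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{tid}\t{n.parent}\t{n.rank}\t{n.name}\n")

    def to_taxdump(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "nodes.dmp", "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{tid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
        with open(directory / "names.dmp", "w") as fh:
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                fh.write(f"{tid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    return TaxonomyTree.load(path)


def filter_nodes(
    taxon_set: Iterable[int], tree: TaxonomyTree, policy: str = "permissive"
) -> set[int]:
    """Apply the node-cleanup policy before LCA computation.

    ``permissive`` keeps everything.  ``unipept-like`` removes species-rank
    nodes (and nodes below species) whose name contains a digit, and any
    node with an ancestor named "environmental samples".
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    taxa = set(taxon_set)
    for tid in taxa:
        if tid not in tree.nodes:
            raise KeyError(f"unknown taxon id {tid}")
    if policy == "permissive":
        return taxa

    def keep(tid: int) -> bool:
        lineage = tree.lineage(tid)
        if any(tree.name(a) == "environmental samples" for a in lineage[:-1]):
            return False
        at_or_below_species = tree.rank_node(tid, "species") is not None
        if at_or_below_species and any(ch.isdigit() for ch in tree.name(tid)):
            return False
        return True

    return {tid for tid in taxa if keep(tid)}


def lca(taxon_set: Iterable[int], tree: TaxonomyTree) -> int | None:
    """Deepest node present on every member's root path; ``None`` if empty."""
    taxa = list(taxon_set)
    if not taxa:
        return None
    common = tree.lineage(taxa[0])
    for tid in taxa[1:]:
        other = tree.lineage(tid)
        limit = min(len(common), len(other))
        i = 0
        while i < limit and common[i] == other[i]:
            i += 1
        common = common[:i]
        if not common:  # different roots cannot happen in a validated tree
            return None
    return common[-1]


def assign_lcas(
    peptides: Sequence[PeptideRecord],
    index: Pep2TaxIndex,
    tree: TaxonomyTree,
    policy: str = "permissive",
) -> list[PeptideRecord]:
    """Assign each peptide an LCA lineage via index lookup + node policy.

    Peptides absent from the index (or whose taxa are all removed by the
    policy) are marked unassigned (``lca is None``).  Returns the same
    records, mutated.
    """
    for p in peptides:
        taxa = index.lookup(p.sequence)
        filtered = filter_nodes(taxa, tree, policy) if taxa else set()
        node = lca(filtered, tree)
        p.lca = node
        p.lineage = tree.lineage(node) if node is not None else None
    return list(peptides)


def rank_distinctive(
    peptides: Sequence[PeptideRecord], rank: str, tree: TaxonomyTree
) -> list[PeptideRecord]:
    """Peptides uniquely attributable at ``rank``: their LCA lineage
    contains a node of that canonical rank (LCA at the rank or deeper)."""
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {CANONICAL_RANKS}")
    out = []
    for p in peptides:
        if p.lineage and any(tree.rank(t) == rank for t in p.lineage):
            out.append(p)
    return out


class TaxonQuantTable:
    """Per-taxon, per-sample abundances in three modes.

    Rows are the identified LCAs plus all their ancestors; columns are
    samples.  ``matrix(mode)`` returns the pandas DataFrame for
    ``peptide_count``, ``spectral_count`` or ``intensity``.
    """

    MODES = ("peptide_count", "spectral_count", "intensity")

    def __init__(
        self,
        peptide_count: pd.DataFrame,
        spectral_count: pd.DataFrame,
        intensity: pd.DataFrame,
        tree: TaxonomyTree,
    ):
        self.peptide_count = peptide_count
        self.spectral_count = spectral_count
        self.intensity = intensity
        self.tree = tree

    def matrix(self, mode: str) -> pd.DataFrame:
        if mode not in self.MODES:
            raise ValueError(f"unknown quantification mode {mode!r}")
        return getattr(self, mode)

    @property
    def taxa(self) -> list[int]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def rank_taxa(self, rank: str) -> list[int]:
        if rank not in CANONICAL_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return [t for t in self.taxa if self.tree.rank(t) == rank]

    def lineage_names(self, tid: int) -> list[str]:
        return [self.tree.name(t) for t in self.tree.lineage(tid)]

    def __len__(self) -> int:
        return len(self.taxa)


def quantify_taxa(
    peptides: Sequence[PeptideRecord], tree: TaxonomyTree
) -> TaxonQuantTable:
    """Sum each peptide's quantities over every node of its LCA lineage.

    A peptide counts once (peptide_count), its per-sample MS2 spectral
    count, and its per-sample intensity toward its LCA and all ancestors;
    unassigned peptides contribute nothing.  A peptide's peptide_count in
    a sample is 1 when it was observed there (nonzero count or intensity).
    """
    assigned = [p for p in peptides if p.lca is not None and p.lineage]
    samples = sorted(set().union(*(p.samples() for p in assigned)) if assigned else set())
    acc = {
        mode: {}
        for mode in TaxonQuantTable.MODES
    }
    for p in assigned:
        present = {
            s
            for s in samples
            if p.spectral_count.get(s, 0) > 0 or p.intensity.get(s, 0.0) > 0
        }
        for node in p.lineage:
            for mode in TaxonQuantTable.MODES:
                row = acc[mode].setdefault(node, dict.fromkeys(samples, 0.0))
                if mode == "peptide_count":
                    for s in present:
                        row[s] += 1
                elif mode == "spectral_count":
                    for s, v in p.spectral_count.items():
                        row[s] += v
                else:
                    for s, v in p.intensity.items():
                        row[s] += v
    taxa = sorted(acc["intensity"])
    frames = {}
    for mode in TaxonQuantTable.MODES:
        dtype = float if mode == "intensity" else int
        df = pd.DataFrame(
            [[acc[mode][t][s] for s in samples] for t in taxa],
            index=pd.Index(taxa, name="taxon_id"),
            columns=samples,
            dtype=dtype,
        )
        frames[mode] = df
    return TaxonQuantTable(frames["peptide_count"], frames["spectral_count"], frames["intensity"], tree)
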