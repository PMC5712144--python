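"""Sample-specific protein database construction.

Searching community samples against multi-million-entry gene catalogs is
slow and hurts FDR estimation, so the catalog is first reduced to the
proteins actually evidenced by the samples.  Two strategies:

* **iterative**: every sample is searched against the full catalog at a
  permissive first-round acceptance; the proteins carrying any accepted
  peptide form an intermediate database, all samples are searched again
  against it under strict FDR, and the final database holds the proteins
  identified in that second search.
* **clustering**: all spectra are pooled and clustered first; only the
  delegate (consensus) spectra are searched once against the catalog,
  and the proteins containing any FDR-accepted peptide form the reduced
  database.  This trades one cheap clustering pass for the second full
  search.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .clustering import ClusteringConfig, cluster_spectra, reduction_stats
from .io_formats import ParameterSet, ProteinRecord, Spectrum
from .search_engine import DECOY_PREFIX, build_candidates, filter_fdr, generate_decoys, search

logger = logging.getLogger(__name__)


@dataclass
class ReductionReport:
    strategy: str
    n_original_proteins: int
    n_reduced_proteins: int
    n_delegate_spectra: int | None = None
    n_peptides_round1: int = 0

    def __post_init__(self) -> None:
        if self.n_reduced_proteins > self.n_original_proteins:
            raise ValueError("reduced database cannot exceed the original")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_original_proteins": self.n_original_proteins,
            "n_reduced_proteins": self.n_reduced_proteins,
            "n_delegate_spectra": self.n_delegate_spectra,
            "n_peptides_round1": self.n_peptides_round1,
        }


def extract_proteins(
    peptides: Sequence[str], db: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Proteins containing at least one listed peptide as an exact substring.

    Order of the database is preserved; decoys are excluded.  An empty
    peptide list is an error (it would produce an empty database).
    """
    pep_list = [p for p in peptides]
    if not pep_list:
        raise ValueError("empty peptide list would produce an empty database")
    pep_set = set(pep_list)
    out = []
    for rec in db:
        if rec.accession.startswith(DECOY_PREFIX):
            continue
        if any(p in rec.sequence for p in pep_set):
            out.append(rec)
    return out


def _subset_by_accession(
    accessions: set[str], db: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    return [rec for rec in db if rec.accession in accessions]


def reduce_iterative(
    spectra_by_sample: Mapping[str, Sequence[Spectrum]],
    db: Sequence[ProteinRecord],
    params: ParameterSet | None = None,
) -> tuple[list[ProteinRecord], ReductionReport]:
    """Two-round iterative reduction.

    Round 1 searches each sample separately against the full database and
    accepts target PSMs at a permissive score cut
    (``params.round1_min_score``; no FDR filter — the strict FDR applies
    only in the final search).  Round 2 searches all samples against the
    union of round-1 proteins; the final database holds the proteins
    identified in round 2.
    """
    params = params or ParameterSet()
    if not spectra_by_sample:
        raise ValueError("at least one sample is required")
    decoys = generate_decoys(db)
    searchable = list(db) + decoys
    candidates = build_candidates(searchable, params)
    round1_accessions: set[str] = set()
    round1_peptides: set[str] = set()
    for sample in sorted(spectra_by_sample):
        psms = search(spectra_by_sample[sample], searchable, params, candidates=candidates)
        for p in psms:
            if not p.is_decoy and p.score >= params.round1_min_score:
                round1_accessions.update(p.protein_accessions)
                round1_peptides.add(p.sequence)
    if not round1_accessions:
        raise ValueError(
            "no identifications in round 1: "
            f"{sum(len(v) for v in spectra_by_sample.values())} spectra vs "
            f"{len(db)} proteins produced no accepted PSMs"
        )
    intermediate = _subset_by_accession(round1_accessions, db)
    logger.info("iterative round 1: %d proteins, %d peptides", len(intermediate), len(round1_peptides))

    all_spectra = [s for sample in sorted(spectra_by_sample) for s in spectra_by_sample[sample]]
    searchable2 = intermediate + generate_decoys(intermediate)
    psms2 = search(all_spectra, searchable2, params)
    accepted = filter_fdr(psms2, params.fdr_threshold)
    final_accessions = {a for p in accepted for a in p.protein_accessions}
    if not final_accessions:
        raise ValueError("no identifications survived the second-round FDR filter")
    reduced = _subset_by_accession(final_accessions, db)
    _log_duplicates(reduced)
    report = ReductionReport(
        strategy="iterative",
        n_original_proteins=len(db),
        n_reduced_proteins=len(reduced),
        n_peptides_round1=len(round1_peptides),
    )
    return reduced, report


def reduce_clustering(
    spectra_all: Sequence[Spectrum],
    db: Sequence[ProteinRecord],
    params: ParameterSet | None = None,
) -> tuple[list[ProteinRecord], ReductionReport]:
    """Clustering-first reduction.

    All spectra (pooled across samples) are clustered; the delegate
    spectra are searched once against the full database, peptides are
    FDR-filtered, and the reduced database is the set of proteins
    containing any accepted peptide.
    """
    params = params or ParameterSet()
    if not spectra_all:
        raise ValueError("at least one spectrum is required")
    config = ClusteringConfig.from_params(params)
    clusters = cluster_spectra(list(spectra_all), config)
    stats = reduction_stats(list(spectra_all), clusters)
    delegates = [c.delegate for c in clusters]
    searchable = list(db) + generate_decoys(db)
    psms = search(delegates, searchable, params)
    accepted = filter_fdr(psms, params.fdr_threshold)
    peptides = sorted({p.sequence for p in accepted})
    if not peptides:
        raise ValueError(
            f"no peptides identified from {stats.n_clusters} delegate spectra "
            f"({stats.n_input} input) against {len(db)} proteins"
        )
    reduced = extract_proteins(peptides, db)
    _log_duplicates(reduced)
    report = ReductionReport(
        strategy="clustering",
        n_original_proteins=len(db),
        n_reduced_proteins=len(reduced),
        n_delegate_spectra=stats.n_clusters,
        n_peptides_round1=len(peptides),
    )
    return reduced, report


def _log_duplicates(db: Sequence[ProteinRecord]) -> None:
    # identical sequences are kept in the reduced database; report their count
    seqs: dict[str, int] = {}
    for rec in db:
        seqs[rec.sequence] = seqs.get(rec.sequence, 0) + 1
    n_dup = sum(n - 1 for n in seqs.values() if n > 1)
    if n_dup:
        logger.info("reduced database keeps %d duplicate sequences", n_dup)
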