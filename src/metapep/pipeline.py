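"""End-to-end workflow orchestration.

Runs the three-stage pipeline — sample-specific database construction,
peptide identification/quantification with FDR control, and taxonomic
profiling — and writes the standard result directory:

``database/``
    the reduced FASTA and the pep2tax index built from the catalog;
``parameter/``
    the normalized parameter file, the reduction report and the run log;
``result/pre_processing/``
    delegate spectra and the spectrum -> cluster map (clustering strategy);
``result/pep_iden/``
    the PSM table and the peptide table;
``result/taxonomy/``
    peptides with LCA lineages, the taxa table, and a BIOM export.

Each stage consumes the previous stage's artifacts, and stages can be
toggled off and replaced by user-supplied substitutes (e.g. an imported
peptide table feeding taxonomy directly).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import db_reduction, export_stats
from .clustering import ClusteringConfig, cluster_spectra, reduction_stats, write_cluster_table
from .io_formats import (
    ParameterSet,
    PeptideRecord,
    ProteinRecord,
    Spectrum,
    read_fasta,
    read_mgf,
    read_peptide_table,
    write_fasta,
    write_mgf,
    write_peptide_table,
)
from .pep2tax import DigestConfig, Pep2TaxIndex, build_index
from .search_engine import aggregate_peptides, filter_fdr, generate_decoys, search, write_psm_table
from .taxonomy import TaxonomyTree, TaxonQuantTable, assign_lcas, quantify_taxa


@dataclass
class PipelineResult:
    outdir: Path
    params: ParameterSet
    reduced_db: list[ProteinRecord] | None
    reduction_report: db_reduction.ReductionReport | None
    peptides: list[PeptideRecord]
    taxa_table: TaxonQuantTable | None
    paths: dict[str, Path]
    log: list[str]


def _prepare_outdir(outdir: Path) -> None:
    for sub in ("database", "parameter", "result/pre_processing", "result/pep_iden", "result/taxonomy"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)


def run_pipeline(
    params: ParameterSet,
    outdir: str | Path,
    mgf_paths: Sequence[str | Path] | None = None,
    spectra_by_sample: Mapping[str, Sequence[Spectrum]] | None = None,
    fasta: str | Path | Sequence[ProteinRecord] | None = None,
    taxonomy: str | Path | TaxonomyTree | None = None,
    peptide_table: str | Path | Sequence[PeptideRecord] | None = None,
    index_path: str | Path | None = None,
) -> PipelineResult:
    """Execute the enabled steps in order (reduce -> search -> taxonomy -> export).

    Inputs may be file paths or in-memory objects.  Sample ids of MGF
    inputs are the file stems.  A failing stage raises after the partial
    outputs of earlier stages are on disk; the log records each stage.
    """
    outdir = Path(outdir)
    _prepare_outdir(outdir)
    log: list[str] = []
    paths: dict[str, Path] = {}

    params_path = outdir / "parameter" / "parameters.json"
    params.save(params_path)
    paths["parameters"] = params_path

    def note(msg: str) -> None:
        log.append(msg)
        with open(outdir / "parameter" / "run.log", "a") as fh:
            fh.write(msg + "\n")

    (outdir / "parameter" / "run.log").write_text("")

    if spectra_by_sample is None and mgf_paths:
        spectra_by_sample = {Path(p).stem: read_mgf(p) for p in mgf_paths}
    spectra_by_sample = dict(spectra_by_sample or {})
    all_spectra = [s for sid in sorted(spectra_by_sample) for s in spectra_by_sample[sid]]

    db: list[ProteinRecord] | None
    if fasta is None:
        db = None
    elif isinstance(fasta, (str, Path)):
        db = read_fasta(fasta)
    else:
        db = list(fasta)

    tree: TaxonomyTree | None
    if taxonomy is None:
        tree = None
    elif isinstance(taxonomy, TaxonomyTree):
        tree = taxonomy
    else:
        tree = TaxonomyTree.load(taxonomy)

    steps = params.steps
    reduced: list[ProteinRecord] | None = db
    report = None

    if steps.get("reduce", True) and all_spectra and db:
        note(f"reduce: strategy={params.strategy} spectra={len(all_spectra)} proteins={len(db)}")
        if params.strategy == "iterative":
            reduced, report = db_reduction.reduce_iterative(spectra_by_sample, db, params)
        else:
            config = ClusteringConfig.from_params(params)
            clusters = cluster_spectra(all_spectra, config)
            stats = reduction_stats(all_spectra, clusters)
            write_mgf(
                [c.delegate for c in clusters], outdir / "result" / "pre_processing" / "delegates.mgf"
            )
            write_cluster_table(clusters, outdir / "result" / "pre_processing" / "clusters.tsv")
            paths["delegates"] = outdir / "result" / "pre_processing" / "delegates.mgf"
            paths["clusters"] = outdir / "result" / "pre_processing" / "clusters.tsv"
            note(
                f"clustering: {stats.n_input} spectra -> {stats.n_clusters} delegates "
                f"(retained {stats.retained_fraction:.3f})"
            )
            searchable = list(db) + generate_decoys(db)
            psms = search([c.delegate for c in clusters], searchable, params)
            accepted = filter_fdr(psms, params.fdr_threshold)
            peptide_list = sorted({p.sequence for p in accepted})
            if not peptide_list:
                raise ValueError("no peptides identified from delegate spectra")
            reduced = db_reduction.extract_proteins(peptide_list, db)
            report = db_reduction.ReductionReport(
                strategy="clustering",
                n_original_proteins=len(db),
                n_reduced_proteins=len(reduced),
                n_delegate_spectra=stats.n_clusters,
                n_peptides_round1=len(peptide_list),
            )
        reduced_path = outdir / "database" / "reduced.fasta"
        write_fasta(reduced, reduced_path)
        paths["reduced_fasta"] = reduced_path
        report_path = outdir / "parameter" / "reduction_report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        paths["reduction_report"] = report_path
        note(f"reduce: {report.n_original_proteins} -> {report.n_reduced_proteins} proteins")

    peptides: list[PeptideRecord] = []
    imported: list[PeptideRecord] | None = None
    if peptide_table is not None:
        imported = (
            read_peptide_table(peptide_table)
            if isinstance(peptide_table, (str, Path))
            else list(peptide_table)
        )

    if steps.get("search", True) and all_spectra and reduced:
        searchable = list(reduced) + generate_decoys(reduced)
        psms = search(all_spectra, searchable, params)
        accepted = filter_fdr(psms, params.fdr_threshold)
        note(f"search: {len(psms)} PSMs, {len(accepted)} accepted at FDR {params.fdr_threshold}")
        psm_path = outdir / "result" / "pep_iden" / "psms.tsv"
        write_psm_table(accepted, psm_path)
        paths["psms"] = psm_path
        peptides = aggregate_peptides(accepted, all_spectra, imported=imported)
        # lossless adapter table; export_stats writes the human-readable
        # peptides.tsv (with lineages) next to it later
        pep_path = outdir / "result" / "pep_iden" / "peptide_table.tsv"
        write_peptide_table(peptides, pep_path)
        paths["peptide_table"] = pep_path
        note(f"search: {len(peptides)} unique peptides")
    elif imported is not None:
        peptides = imported
        note(f"search skipped: {len(peptides)} peptides imported")

    taxa_table: TaxonQuantTable | None = None
    if steps.get("taxonomy", True) and peptides and tree is not None and db:
        if index_path is not None:
            index = Pep2TaxIndex.open(index_path, expect_config=DigestConfig())
        else:
            idx_path = outdir / "database" / "pep2tax.p2t"
            index = build_index(db, tree, DigestConfig(), out_path=idx_path)
            paths["pep2tax"] = idx_path
        assign_lcas(peptides, index, tree, policy="permissive")
        n_assigned = sum(1 for p in peptides if p.lca is not None)
        note(f"taxonomy: {n_assigned}/{len(peptides)} peptides assigned an LCA")
        taxa_table = quantify_taxa(peptides, tree)
        note(f"taxonomy: {len(taxa_table)} taxa quantified")
        if steps.get("export", True):
            table_paths = export_stats.write_result_tables(
                peptides, taxa_table, outdir / "result", tree
            )
            paths["peptides_tsv"] = table_paths["peptides"]
            paths["taxa_tsv"] = table_paths["taxa"]
            biom_path = outdir / "result" / "taxonomy" / "taxa_intensity.biom"
            export_stats.write_biom(taxa_table, "all", "intensity", biom_path)
            paths["biom"] = biom_path
            note("export: taxa.tsv, peptides.tsv, taxa_intensity.biom written")

    return PipelineResult(
        outdir=outdir,
        params=params,
        reduced_db=reduced,
        reduction_report=report,
        peptides=peptides,
        taxa_table=taxa_table,
        paths=paths,
        log=log,
    )
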