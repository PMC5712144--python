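"""Result serialization (BIOM 1.0, TSV) and downstream statistics.

The taxon quantification table is exported as BIOM 1.0 JSON — the
interchange format metagenomics tools such as MEGAN consume — with MS
intensities (or counts) in place of read counts.  Also provided are the
common gut-microbiome summaries operating on those tables: the
Firmicutes/Bacteroidetes ratio, a validity filter for high-confidence
species, nonzero-median normalization with log transform, and a
Pearson-correlation distance matrix for sample clustering.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import PeptideRecord
from .taxonomy import CANONICAL_RANKS, TaxonomyTree, TaxonQuantTable

BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
BIOM_URL = "http://biom-format.org"
#: Fixed timestamp written into BIOM headers so identical runs produce
#: byte-identical exports; pass ``date=`` to override.
BIOM_DEFAULT_DATE = "2017-12-02T00:00:00"

_REQUIRED_BIOM_KEYS = (
    "id",
    "format",
    "format_url",
    "type",
    "generated_by",
    "date",
    "rows",
    "columns",
    "matrix_type",
    "matrix_element_type",
    "shape",
    "data",
)


def write_biom(
    table: TaxonQuantTable,
    rank: str,
    mode: str,
    path: str | Path,
    generated_by: str = "metapep",
    date: str = BIOM_DEFAULT_DATE,
) -> dict:
    """Export one quantification mode at one rank (or ``"all"``) as BIOM 1.0.

    Observations are taxa with full-lineage ``taxonomy`` metadata, columns
    are samples.  Sparse CSR-style encoding is used when density < 0.5.
    Returns the document that was written.
    """
    if rank != "all" and rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    taxa = table.taxa if rank == "all" else table.rank_taxa(rank)
    if not taxa:
        raise ValueError(f"no taxa to export at rank {rank!r}")
    df = table.matrix(mode).loc[taxa, table.samples]
    values = df.to_numpy()
    integral = mode != "intensity"
    nnz = int(np.count_nonzero(values))
    density = nnz / values.size if values.size else 0.0
    if density < 0.5:
        matrix_type = "sparse"
        data = [
            [int(i), int(j), int(values[i, j]) if integral else float(values[i, j])]
            for i, j in zip(*np.nonzero(values))
        ]
    else:
        matrix_type = "dense"
        cast = int if integral else float
        data = [[cast(v) for v in row] for row in values]
    doc = {
        "id": f"metapep:{mode}:{rank}",
        "format": BIOM_FORMAT,
        "format_url": BIOM_URL,
        "type": "OTU table",
        "generated_by": generated_by,
        "date": date,
        "rows": [
            {"id": str(t), "metadata": {"taxonomy": table.lineage_names(t)}} for t in taxa
        ],
        "columns": [{"id": s, "metadata": None} for s in table.samples],
        "matrix_type": matrix_type,
        "matrix_element_type": "int" if integral else "float",
        "shape": [len(taxa), len(table.samples)],
        "data": data,
    }
    validate_biom(doc)
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")
    return doc


def validate_biom(doc: dict) -> None:
    """Check the structural requirements of the BIOM 1.0 JSON schema."""
    for key in _REQUIRED_BIOM_KEYS:
        if key not in doc:
            raise ValueError(f"BIOM document missing required field {key!r}")
    n_rows, n_cols = doc["shape"]
    if len(doc["rows"]) != n_rows or len(doc["columns"]) != n_cols:
        raise ValueError("BIOM shape does not match rows/columns lengths")
    if doc["matrix_type"] not in ("sparse", "dense"):
        raise ValueError(f"invalid matrix_type {doc['matrix_type']!r}")
    if doc["matrix_element_type"] not in ("int", "float", "unicode"):
        raise ValueError(f"invalid matrix_element_type {doc['matrix_element_type']!r}")
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, _ = entry
            if not (0 <= i < n_rows and 0 <= j < n_cols):
                raise ValueError(f"sparse entry {entry} outside shape {doc['shape']}")
    else:
        if len(doc["data"]) != n_rows or any(len(r) != n_cols for r in doc["data"]):
            raise ValueError("dense data does not match shape")


def read_biom(path: str | Path) -> tuple[list[str], list[str], np.ndarray, dict]:
    """Read a BIOM 1.0 JSON file back as (row ids, column ids, dense matrix, doc)."""
    doc = json.loads(Path(path).read_text())
    validate_biom(doc)
    n_rows, n_cols = doc["shape"]
    matrix = np.zeros((n_rows, n_cols), dtype=float)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            matrix[i, j] = v
    else:
        matrix[:] = np.asarray(doc["data"], dtype=float)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    return rows, cols, matrix, doc


# ---------------------------------------------------------------------------
# Result tables


def write_result_tables(
    peptides: Sequence[PeptideRecord],
    table: TaxonQuantTable,
    outdir: str | Path,
    tree: TaxonomyTree | None = None,
) -> dict[str, Path]:
    """Write ``peptides.tsv`` and ``taxa.tsv`` in the standard result layout.

    ``pep_iden/peptides.tsv`` carries per-peptide scores, the LCA lineage
    string (or ``unassigned``), and per-sample counts/intensities;
    ``taxonomy/taxa.tsv`` carries all nodes (LCAs plus ancestors) with
    the three quantification modes.  Output is deterministic: rows sorted,
    floats formatted with %.6g.
    """
    tree = tree or table.tree
    outdir = Path(outdir)
    for sub in ("pre_processing", "pep_iden", "taxonomy"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    samples = table.samples or sorted(
        set().union(*(p.samples() for p in peptides)) if peptides else set()
    )
    pep_rows = []
    for p in sorted(peptides, key=lambda r: r.sequence):
        if p.lca is not None and p.lineage:
            lca_name = tree.name(p.lca)
            lineage = ";".join(tree.name(t) for t in p.lineage)
            lca_id = str(p.lca)
        else:
            lca_name, lineage, lca_id = "unassigned", "unassigned", ""
        row = {
            "sequence": p.sequence,
            "best_score": p.best_score,
            "lca_id": lca_id,
            "lca_name": lca_name,
            "lineage": lineage,
        }
        for s in samples:
            row[f"spectra.{s}"] = p.spectral_count.get(s, 0)
        for s in samples:
            row[f"intensity.{s}"] = p.intensity.get(s, 0.0)
        pep_rows.append(row)
    peptides_path = outdir / "pep_iden" / "peptides.tsv"
    pd.DataFrame(pep_rows).to_csv(peptides_path, sep="\t", index=False, float_format="%.6g")

    tax_rows = []
    for tid in table.taxa:
        row = {
            "taxon_id": tid,
            "name": tree.name(tid),
            "rank": tree.rank(tid),
            "lineage": ";".join(tree.name(t) for t in tree.lineage(tid)),
        }
        for mode in TaxonQuantTable.MODES:
            m = table.matrix(mode)
            for s in samples:
                row[f"{mode}.{s}"] = m.at[tid, s]
        tax_rows.append(row)
    taxa_path = outdir / "taxonomy" / "taxa.tsv"
    pd.DataFrame(tax_rows).to_csv(taxa_path, sep="\t", index=False, float_format="%.6g")
    return {"peptides": peptides_path, "taxa": taxa_path}


# ---------------------------------------------------------------------------
# Downstream statistics


def fb_ratio(
    table: TaxonQuantTable,
    sample: str,
    mode: str = "intensity",
    numerator: str = "Firmicutes",
    denominator: str = "Bacteroidetes",
) -> float:
    """Firmicutes-to-Bacteroidetes abundance ratio for one sample.

    Phyla are located by scientific name at phylum rank.  A zero
    denominator yields NaN (undefined) rather than an exception.
    """
    by_name = {table.tree.name(t): t for t in table.rank_taxa("phylum")}
    for name in (numerator, denominator):
        if name not in by_name:
            raise ValueError(f"phylum {name!r} not present in the taxa table")
    m = table.matrix(mode)
    num = float(m.at[by_name[numerator], sample])
    den = float(m.at[by_name[denominator], sample])
    if den == 0:
        return float("nan")
    return num / den


def validity_filter(
    table: TaxonQuantTable,
    rank: str = "species",
    min_unique_peptides: int = 3,
    min_valid_samples: int = 8,
) -> list[int]:
    """High-confidence taxa for cluster analysis.

    A taxon is *valid* in a sample when its unique peptide count there is
    >= ``min_unique_peptides``; taxa valid in strictly more than
    ``min_valid_samples`` samples are kept.
    """
    taxa = table.rank_taxa(rank)
    if not taxa:
        return []
    pc = table.peptide_count.loc[taxa]
    n_valid = (pc >= min_unique_peptides).sum(axis=1)
    return sorted(int(t) for t in n_valid.index[n_valid > min_valid_samples])


def normalize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median normalization followed by log10 transform.

    Each column (sample) is divided by its median over *nonzero* entries,
    then log10-transformed; zeros propagate as NaN (missing).  An
    all-zero column is an error.
    """
    df = matrix.astype(float)
    if (df < 0).any().any():
        raise ValueError("matrix must be nonnegative")
    out = df.where(df > 0)
    medians = out.median(axis=0, skipna=True)
    dead = [c for c in df.columns if not np.isfinite(medians[c])]
    if dead:
        raise ValueError(f"all-zero sample columns: {dead}")
    return np.log10(out.div(medians, axis=1))


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample distance ``d(i, j) = 1 - pearson(i, j)``.

    Samples are columns; missing values (NaN) are excluded pairwise.
    Constant columns produce NaN entries (undefined correlation); the
    diagonal is zero.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    corr = matrix.corr(method="pearson", min_periods=2)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return dist
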