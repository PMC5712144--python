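"""Readers/writers for the external formats shared by every pipeline stage.

The interchange formats are deliberately plain: MGF for MS/MS peak lists
(one ``BEGIN IONS`` block per scan), FASTA for protein databases whose
headers may carry a taxon identifier, TSV for peptide quantification
tables, and a single JSON document for the full parameter set.  Vendor
raw formats are out of scope; convert upstream (e.g. with msconvert).
"""
from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _pyfasta
from pyteomics import mgf as _pymgf

#: Mass of a proton in Da (charge carrier for m/z conversions).
PROTON_MASS = 1.007276466879

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Protein sequences may additionally contain X (unknown residue).
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

CANONICAL_MODE_NAMES = ("high-high", "high-low")


@dataclass
class Spectrum:
    """One MS/MS scan.

    Parameters
    ----------
    spectrum_id:
        Opaque identifier, unique within a run (MGF ``TITLE``).
    sample_id:
        Name of the sample/experiment the scan belongs to.
    precursor_mz:
        Precursor mass-to-charge ratio in Th.
    precursor_charge:
        Positive integer; 0 encodes "unknown" and matches any charge
        downstream.
    precursor_intensity:
        MS1 precursor intensity (arbitrary units, >= 0).
    retention_time:
        Retention time in minutes.
    mz, intensity:
        Fragment peak arrays; sorted ascending by m/z on construction.
    """

    spectrum_id: str
    sample_id: str
    precursor_mz: float
    precursor_charge: int = 0
    precursor_intensity: float = 0.0
    retention_time: float = 0.0
    mz: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("peak m/z and intensity arrays must be 1-D and equal length")
        if not np.isfinite(self.precursor_mz):
            raise ValueError(f"non-finite precursor m/z in spectrum {self.spectrum_id!r}")
        if not np.isfinite(self.retention_time) or self.retention_time < 0:
            raise ValueError(f"invalid retention time in spectrum {self.spectrum_id!r}")
        if self.precursor_charge < 0:
            raise ValueError("precursor charge must be >= 0 (0 = unknown)")
        if self.precursor_intensity < 0 or not np.isfinite(self.precursor_intensity):
            raise ValueError("precursor intensity must be finite and >= 0")
        if self.mz.size:
            if not np.all(np.isfinite(self.mz)):
                raise ValueError(f"non-finite fragment m/z in spectrum {self.spectrum_id!r}")
            if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
                raise ValueError(f"invalid peak intensity in spectrum {self.spectrum_id!r}")
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as ``(fragment_mz, intensity)`` tuples."""
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @classmethod
    def from_peaks(cls, peaks: Sequence[tuple[float, float]], **kwargs) -> "Spectrum":
        mz = np.array([p[0] for p in peaks], dtype=float)
        inten = np.array([p[1] for p in peaks], dtype=float)
        return cls(mz=mz, intensity=inten, **kwargs)

    def approx_equal(self, other: "Spectrum", rtol: float = 1e-6, atol: float = 1e-4) -> bool:
        return (
            self.spectrum_id == other.spectrum_id
            and self.precursor_charge == other.precursor_charge
            and np.isclose(self.precursor_mz, other.precursor_mz, rtol=rtol, atol=atol)
            and np.isclose(self.retention_time, other.retention_time, rtol=rtol, atol=atol)
            and np.isclose(self.precursor_intensity, other.precursor_intensity, rtol=rtol, atol=atol)
            and self.n_peaks == other.n_peaks
            and np.allclose(self.mz, other.mz, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry; ``taxon_id`` is parsed from the header when present."""

    accession: str
    description: str
    sequence: str
    taxon_id: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.accession!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.accession!r} contains non-amino-acid letters: {sorted(bad)}"
            )


@dataclass
class PeptideRecord:
    """Peptide-level identification/quantification across samples.

    ``spectral_count`` and ``intensity`` are per-sample channels keyed by
    sample id; absent samples read as zero.  ``lca`` / ``lineage`` are
    filled by the taxonomy stage (``None`` = unassigned).
    """

    sequence: str
    spectral_count: dict[str, int] = field(default_factory=dict)
    intensity: dict[str, float] = field(default_factory=dict)
    best_score: float = 0.0
    lca: int | None = None
    lineage: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptide sequence must be non-empty")
        if any(v < 0 for v in self.spectral_count.values()):
            raise ValueError("spectral counts must be >= 0")
        if any(v < 0 for v in self.intensity.values()):
            raise ValueError("intensities must be >= 0")

    def samples(self) -> set[str]:
        return set(self.spectral_count) | set(self.intensity)


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path, sample_id: str | None = None) -> list[Spectrum]:
    """Read an MGF peak list into :class:`Spectrum` objects.

    ``RTINSECONDS`` is converted to minutes; a missing ``CHARGE`` line maps
    to charge 0 (unknown).  ``sample_id`` defaults to the file stem, which
    mirrors naming samples after the raw-file/experiment name.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    out: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        it = iter(reader)
        block = 0
        while True:
            try:
                entry = next(it)
            except StopIteration:
                break
            except Exception as exc:  # malformed block inside pyteomics
                raise ValueError(f"malformed MGF block {block} in {path}: {exc}") from exc
            params = entry.get("params", {})
            if "pepmass" not in params:
                raise ValueError(f"malformed MGF block {block} in {path}: missing PEPMASS")
            pepmass = params["pepmass"]
            if isinstance(pepmass, (tuple, list)):
                prec_mz = float(pepmass[0])
                prec_int = float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] is not None else 0.0
            else:
                prec_mz, prec_int = float(pepmass), 0.0
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 0
            rt_seconds = float(params.get("rtinseconds", 0.0))
            title = str(params.get("title", f"{sid}.{block}"))
            try:
                out.append(
                    Spectrum(
                        spectrum_id=title,
                        sample_id=sid,
                        precursor_mz=prec_mz,
                        precursor_charge=max(charge, 0),
                        precursor_intensity=prec_int,
                        retention_time=rt_seconds / 60.0,
                        mz=entry["m/z array"] if entry["m/z array"] is not None else [],
                        intensity=entry["intensity array"]
                        if entry["intensity array"] is not None
                        else [],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed MGF block {block} in {path}: {exc}") from exc
            block += 1
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; ``read_mgf`` inverts this up to float formatting.

    Unknown charge (0) omits the ``CHARGE`` line by convention.
    """
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id}
        if s.precursor_intensity > 0:
            params["pepmass"] = (s.precursor_mz, s.precursor_intensity)
        else:
            params["pepmass"] = (s.precursor_mz,)
        params["rtinseconds"] = s.retention_time * 60.0
        if s.precursor_charge > 0:
            params["charge"] = s.precursor_charge
        entries.append({"m/z array": s.mz, "intensity array": s.intensity, "params": params})
    _pymgf.write(entries, output=str(path), file_mode="w")


# ---------------------------------------------------------------------------
# FASTA

_DEFAULT_TAXON_RE = re.compile(r"(?:OX=|taxid\|)(\d+)")


def default_taxon_parser(header: str) -> int | None:
    """Extract a taxon id from a FASTA header (``OX=<int>`` or ``taxid|<int>``)."""
    m = _DEFAULT_TAXON_RE.search(header)
    return int(m.group(1)) if m else None


def read_fasta(
    path: str | Path,
    taxon_parser: Callable[[str], int | None] | str | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA; headers without a parsable taxon id get ``None``.

    ``taxon_parser`` may be a callable or a regex whose first group is the
    integer taxon id; the default accepts the UniProt ``OX=`` convention
    and ``taxid|<int>`` tokens.
    """
    if taxon_parser is None:
        parser = default_taxon_parser
    elif isinstance(taxon_parser, str):
        rex = re.compile(taxon_parser)

        def parser(header: str, _rex=rex) -> int | None:
            m = _rex.search(header)
            return int(m.group(1)) if m else None

    else:
        parser = taxon_parser

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with _pyfasta.FASTA(str(path)) as reader:
        for description, sequence in reader:
            accession = description.split()[0]
            seen[accession] = seen.get(accession, 0) + 1
            records.append(
                ProteinRecord(
                    accession=accession,
                    description=description,
                    sequence=sequence.upper(),
                    taxon_id=parser(description),
                )
            )
    dups = sorted(acc for acc, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate accessions in {path}: {dups}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Peptide quantification tables (generic adapter for external engines)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide TSV: ``sequence`` plus per-sample ``intensity.<sample>``
    and optional ``spectra.<sample>`` columns.  Missing cells read as 0."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: peptide table must have a 'sequence' column")
    if df["sequence"].duplicated().any():
        dups = sorted(df.loc[df["sequence"].duplicated(), "sequence"].unique())
        raise ValueError(f"{path}: duplicate peptide sequences: {dups}")
    intensity_cols = [c for c in df.columns if c.startswith("intensity.")]
    spectra_cols = [c for c in df.columns if c.startswith("spectra.")]
    df[intensity_cols + spectra_cols] = df[intensity_cols + spectra_cols].fillna(0)
    records = []
    for _, row in df.iterrows():
        intensity = {c.split(".", 1)[1]: float(row[c]) for c in intensity_cols}
        counts = {c.split(".", 1)[1]: int(row[c]) for c in spectra_cols}
        records.append(
            PeptideRecord(sequence=row["sequence"], spectral_count=counts, intensity=intensity)
        )
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    """Write peptides in the adapter TSV format that ``read_peptide_table`` parses."""
    samples = sorted(set().union(*(r.samples() for r in records)) if records else set())
    rows = []
    for r in sorted(records, key=lambda r: r.sequence):
        row: dict = {"sequence": r.sequence, "best_score": r.best_score}
        for s in samples:
            row[f"intensity.{s}"] = r.intensity.get(s, 0.0)
        for s in samples:
            row[f"spectra.{s}"] = r.spectral_count.get(s, 0)
        rows.append(row)
    # full-precision floats so the table is a lossless pipeline intermediate
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Parameter file


@dataclass
class ParameterSet:
    """The single JSON parameter document driving a pipeline run.

    Defaults follow common high-resolution shotgun practice:
    carbamidomethyl-C fixed; oxidation-M and protein N-terminal acetyl
    variable; trypsin with two missed cleavages; FDR 0.01.
    ``precursor_tolerance`` is the *search* precursor window in Da (the
    much wider 2 Da window used for clustering lives in ``clustering``).
    """

    fixed_modifications: list = field(default_factory=lambda: [["C", 57.02146]])
    variable_modifications: list = field(
        default_factory=lambda: [["M", 15.99491], ["protein-nterm", 42.01057]]
    )
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    fragment_tolerance: float = 0.02
    precursor_tolerance: float = 0.01
    instrument_mode: str = "high-high"
    fdr_threshold: float = 0.01
    clustering: dict = field(default_factory=dict)
    steps: dict = field(
        default_factory=lambda: {"reduce": True, "search": True, "taxonomy": True, "export": True}
    )
    strategy: str = "clustering"
    round1_min_score: float = 0.0
    max_variable_mods: int = 2

    def __post_init__(self) -> None:
        if self.instrument_mode not in CANONICAL_MODE_NAMES:
            raise ValueError(f"instrument_mode must be one of {CANONICAL_MODE_NAMES}")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.fragment_tolerance <= 0 or self.precursor_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.strategy not in ("iterative", "clustering"):
            raise ValueError("strategy must be 'iterative' or 'clustering'")
        for pair in list(self.fixed_modifications) + list(self.variable_modifications):
            if len(pair) != 2:
                raise ValueError("modifications are (residue-or-terminus, mass delta) pairs")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        return cls.from_json(Path(path).read_text())
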