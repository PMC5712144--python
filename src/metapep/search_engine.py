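"""Minimal peptide-spectrum matching with target-decoy FDR control.

This is deliberately a small shared-peak-count engine: candidate tryptic
peptides are selected by precursor mass, scored by the number of singly
charged b/y fragments matched within the fragment tolerance (normalized
by the square root of the number of theoretical fragments), and filtered
at a target-decoy false discovery rate.  It makes the pipeline runnable
and testable end to end without a licensed external engine; production
identifications from an external engine can be imported through the
generic peptide-table adapter in :mod:`metapep.io_formats` and take
precedence during aggregation.

Peptide intensities are summed precursor (MS1) intensities of the
matched spectra — a simplification of XIC-based label-free quantification
that preserves proportionality on the synthetic data this package ships.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pymass

from .io_formats import AMINO_ACIDS, PROTON_MASS, ParameterSet, PeptideRecord, ProteinRecord, Spectrum
from .pep2tax import DigestConfig, digest_spans

logger = logging.getLogger(__name__)

WATER_MASS = 18.0105646863
DECOY_PREFIX = "REV_"

_AA_MONO = dict(_pymass.std_aa_mass)

#: Charges tried when a spectrum's precursor charge is unknown (0).
UNKNOWN_CHARGE_TRIALS = (2, 3)


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match."""

    spectrum_id: str
    peptide: str  # sequence with modification annotations, e.g. PEM[+15.99]K
    sequence: str  # unmodified sequence
    protein_accessions: frozenset[str]
    score: float
    is_decoy: bool
    precursor_error: float
    sample_id: str
    n_modifications: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError("PSM score must be finite and >= 0")
        if not self.is_decoy and any(a.startswith(DECOY_PREFIX) for a in self.protein_accessions):
            raise ValueError("target PSM mapping to decoy accessions")
        if self.is_decoy and not all(a.startswith(DECOY_PREFIX) for a in self.protein_accessions):
            raise ValueError("decoy PSM mapping to target accessions")


def generate_decoys(db: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, accession-prefixed ``REV_``."""
    if not db:
        raise ValueError("cannot generate decoys for an empty database")
    decoys = []
    n_palindromes = 0
    for rec in db:
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            n_palindromes += 1
        decoys.append(
            ProteinRecord(
                accession=DECOY_PREFIX + rec.accession,
                description=DECOY_PREFIX + rec.description,
                sequence=rev,
                taxon_id=None,
            )
        )
    if n_palindromes:
        logger.warning("%d palindromic sequences produce decoys equal to their targets", n_palindromes)
    return decoys


def _fixed_mod_map(params: ParameterSet) -> dict[str, float]:
    return {res: float(delta) for res, delta in params.fixed_modifications if res in AMINO_ACIDS}


def _variable_sites(seq: str, is_protein_nterm: bool, params: ParameterSet) -> list[tuple[int, float, str]]:
    """Applicable variable-modification sites as (position, delta, label).

    Position -1 denotes the peptide N-terminus (protein N-terminal mods
    apply only to protein-start peptides).
    """
    sites: list[tuple[int, float, str]] = []
    for res, delta in params.variable_modifications:
        if res == "protein-nterm":
            if is_protein_nterm:
                sites.append((-1, float(delta), "protein-nterm"))
        elif res in AMINO_ACIDS:
            sites.extend((i, float(delta), res) for i, aa in enumerate(seq) if aa == res)
    return sites


def enumerate_forms(
    seq: str, is_protein_nterm: bool, params: ParameterSet
) -> list[tuple[float, tuple[tuple[int, float, str], ...]]]:
    """All modification states (fixed always on; each variable present or
    absent, up to ``params.max_variable_mods`` at once) as
    ``(neutral monoisotopic mass, applied variable sites)``."""
    fixed = _fixed_mod_map(params)
    base = sum(_AA_MONO[aa] + fixed.get(aa, 0.0) for aa in seq) + WATER_MASS
    sites = _variable_sites(seq, is_protein_nterm, params)
    forms = []
    for k in range(min(params.max_variable_mods, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            forms.append((base + sum(d for _, d, _ in combo), combo))
    return forms


def _fragment_mzs(
    seq: str, fixed: dict[str, float], var_sites: tuple[tuple[int, float, str], ...], charge: int = 1
) -> np.ndarray:
    """Singly-charged-by-default b/y fragment m/z for one modification state."""
    residues = np.array([_AA_MONO[aa] + fixed.get(aa, 0.0) for aa in seq], dtype=float)
    for pos, delta, _ in var_sites:
        residues[max(pos, 0)] += delta
    prefix = np.cumsum(residues)
    L = len(seq)
    b = prefix[: L - 1] + charge * PROTON_MASS
    y = (prefix[-1] - prefix[: L - 1]) + WATER_MASS + charge * PROTON_MASS
    return np.sort(np.concatenate([b, y]) / charge)


def theoretical_fragments(
    peptide: str, charge: int = 1, params: ParameterSet | None = None, is_protein_nterm: bool = False
) -> np.ndarray:
    """b/y fragment m/z values for a peptide at the given fragment charge.

    Fixed modifications are always applied; every variable-modification
    state is enumerated and the union of fragment m/z values returned
    (deduplicated, sorted).
    """
    params = params or ParameterSet()
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residues in peptide {peptide!r}: {sorted(bad)}")
    fixed = _fixed_mod_map(params)
    frags = [
        _fragment_mzs(peptide, fixed, sites, charge)
        for _, sites in enumerate_forms(peptide, is_protein_nterm, params)
    ]
    return np.unique(np.concatenate(frags))


def _annotate(seq: str, var_sites: tuple[tuple[int, float, str], ...]) -> str:
    if not var_sites:
        return seq
    out = []
    nterm = [s for s in var_sites if s[0] == -1]
    if nterm:
        out.append(f"[+{nterm[0][1]:.2f}]-")
    by_pos = {pos: delta for pos, delta, _ in var_sites if pos >= 0}
    for i, aa in enumerate(seq):
        out.append(aa)
        if i in by_pos:
            out.append(f"[+{by_pos[i]:.2f}]")
    return "".join(out)


@dataclass
class _CandidateSet:
    """Pre-digested database: modification forms sorted by neutral mass."""

    masses: np.ndarray
    peptides: list[str]
    var_sites: list[tuple]
    accessions: list[frozenset[str]]
    is_decoy: list[bool]
    fixed: dict[str, float]


def build_candidates(db: Sequence[ProteinRecord], params: ParameterSet) -> _CandidateSet:
    digest_cfg = DigestConfig(max_missed_cleavages=params.max_missed_cleavages)
    info: dict[str, dict] = {}
    for rec in db:
        for start, end in digest_spans(rec.sequence, digest_cfg):
            pep = rec.sequence[start:end]
            if "X" in pep:
                continue
            entry = info.setdefault(pep, {"acc": set(), "nterm": False})
            entry["acc"].add(rec.accession)
            if start == 0:
                entry["nterm"] = True
    fixed = _fixed_mod_map(params)
    masses: list[float] = []
    peptides: list[str] = []
    var_sites: list[tuple] = []
    accessions: list[frozenset[str]] = []
    decoy_flags: list[bool] = []
    for pep in sorted(info):
        entry = info[pep]
        targets = {a for a in entry["acc"] if not a.startswith(DECOY_PREFIX)}
        is_decoy = not targets
        accs = frozenset(targets if targets else entry["acc"])
        for mass_value, sites in enumerate_forms(pep, entry["nterm"], params):
            masses.append(mass_value)
            peptides.append(pep)
            var_sites.append(sites)
            accessions.append(accs)
            decoy_flags.append(is_decoy)
    order = np.argsort(np.array(masses), kind="stable")
    return _CandidateSet(
        masses=np.array(masses)[order],
        peptides=[peptides[i] for i in order],
        var_sites=[var_sites[i] for i in order],
        accessions=[accessions[i] for i in order],
        is_decoy=[decoy_flags[i] for i in order],
        fixed=fixed,
    )


def _count_matched(theoretical: np.ndarray, observed: np.ndarray, tol: float) -> int:
    if observed.size == 0 or theoretical.size == 0:
        return 0
    idx = np.searchsorted(observed, theoretical)
    left = np.abs(theoretical - observed[np.clip(idx - 1, 0, observed.size - 1)])
    right = np.abs(theoretical - observed[np.clip(idx, 0, observed.size - 1)])
    return int(np.sum(np.minimum(left, right) <= tol))


def search(
    spectra: Sequence[Spectrum],
    db: Sequence[ProteinRecord],
    params: ParameterSet | None = None,
    candidates: _CandidateSet | None = None,
) -> list[PSM]:
    """Match each spectrum to its best tryptic candidate within the
    precursor window.

    Score = matched b/y fragment count / sqrt(number of theoretical
    fragments); ties break toward fewer modifications, then the
    lexicographically smaller peptide.  Spectra with no candidate in the
    window, or matching zero fragments, yield no PSM.
    """
    params = params or ParameterSet()
    if not db:
        raise ValueError("search requires a non-empty database")
    cand = candidates if candidates is not None else build_candidates(db, params)
    psms: list[PSM] = []
    for s in spectra:
        charges = (s.precursor_charge,) if s.precursor_charge > 0 else UNKNOWN_CHARGE_TRIALS
        best_key = None
        best = None
        for z in charges:
            neutral = (s.precursor_mz - PROTON_MASS) * z
            lo = np.searchsorted(cand.masses, neutral - params.precursor_tolerance, side="left")
            hi = np.searchsorted(cand.masses, neutral + params.precursor_tolerance, side="right")
            for j in range(lo, hi):
                pep = cand.peptides[j]
                theor = _fragment_mzs(pep, cand.fixed, cand.var_sites[j])
                matched = _count_matched(theor, s.mz, params.fragment_tolerance)
                if matched == 0:
                    continue
                score = matched / math.sqrt(theor.size)
                key = (-score, len(cand.var_sites[j]), pep, cand.is_decoy[j])
                if best_key is None or key < best_key:
                    best_key = key
                    best = PSM(
                        spectrum_id=s.spectrum_id,
                        peptide=_annotate(pep, cand.var_sites[j]),
                        sequence=pep,
                        protein_accessions=cand.accessions[j],
                        score=score,
                        is_decoy=cand.is_decoy[j],
                        precursor_error=neutral - float(cand.masses[j]),
                        sample_id=s.sample_id,
                        n_modifications=len(cand.var_sites[j]),
                    )
        if best is not None:
            psms.append(best)
    return psms


def filter_fdr(psms: Sequence[PSM], q: float) -> list[PSM]:
    """Accept target PSMs at estimated FDR <= ``q``.

    PSMs are sorted by descending score and the lowest score threshold t
    with (#decoys >= t)/(#targets >= t) <= q is chosen, maximizing the
    accepted set; equal scores fall on the same side of the threshold,
    with decoys counted first at a tie (conservative).  Returns accepted
    targets only; monotone in ``q``.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    if not any(not p.is_decoy for p in psms):
        return []
    # decoys sort before targets at equal score so a tied decoy blocks the cut
    ordered = sorted(psms, key=lambda p: (-p.score, not p.is_decoy))
    n_targets = 0
    n_decoys = 0
    best_prefix = 0
    for i, p in enumerate(ordered):
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        boundary = i + 1 == len(ordered) or ordered[i + 1].score < p.score
        if boundary and n_targets > 0 and n_decoys / n_targets <= q:
            best_prefix = i + 1
    return [p for p in ordered[:best_prefix] if not p.is_decoy]


def aggregate_peptides(
    psms: Sequence[PSM],
    spectra: Sequence[Spectrum],
    imported: Sequence[PeptideRecord] | None = None,
) -> list[PeptideRecord]:
    """Group accepted PSMs by unmodified sequence into peptide records.

    Per sample, spectral_count is the number of PSMs and intensity the
    sum of the matched spectra's precursor intensities.  Records from an
    imported peptide-quantification table take precedence for sequences
    they cover.
    """
    by_id = {s.spectrum_id: s for s in spectra}
    samples = sorted({p.sample_id for p in psms})
    grouped: dict[str, PeptideRecord] = {}
    for p in psms:
        if p.is_decoy:
            continue
        rec = grouped.get(p.sequence)
        if rec is None:
            rec = PeptideRecord(
                sequence=p.sequence,
                spectral_count=dict.fromkeys(samples, 0),
                intensity=dict.fromkeys(samples, 0.0),
                best_score=p.score,
            )
            grouped[p.sequence] = rec
        rec.spectral_count[p.sample_id] = rec.spectral_count.get(p.sample_id, 0) + 1
        spectrum = by_id.get(p.spectrum_id)
        if spectrum is not None:
            rec.intensity[p.sample_id] = (
                rec.intensity.get(p.sample_id, 0.0) + spectrum.precursor_intensity
            )
        rec.best_score = max(rec.best_score, p.score)
    if imported:
        for ext in imported:
            if ext.sequence in grouped:
                rec = grouped[ext.sequence]
                rec.intensity = dict(ext.intensity)
                if ext.spectral_count:
                    rec.spectral_count = dict(ext.spectral_count)
    return [grouped[seq] for seq in sorted(grouped)]


def write_psm_table(psms: Iterable[PSM], path) -> None:
    """Generic PSM TSV (adapter format for external engines)."""
    with open(path, "w") as fh:
        fh.write("spectrum_id\tsample_id\tpeptide\tsequence\tscore\tis_decoy\tprecursor_error\tproteins\n")
        for p in psms:
            prots = ";".join(sorted(p.protein_accessions))
            fh.write(
                f"{p.spectrum_id}\t{p.sample_id}\t{p.peptide}\t{p.sequence}\t"
                f"{p.score:.6g}\t{int(p.is_decoy)}\t{p.precursor_error:.6g}\t{prots}\n"
            )
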