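"""Synthetic microbial communities with known ground truth.

Generates, from a single seed: a seven-rank taxonomy (with the naming
quirks that exercise node-filter policies — provisional species whose
names contain digits, and a subtree under an "environmental samples"
node); per-species proteomes assembled from unique tryptic peptides with
a controlled fraction shared between sister species (so the shared
peptides' LCA is the genus); multi-sample communities with known species
abundances; and redundant, noisy fragment spectra whose precursor
intensities are proportional to species abundance.

Every stage of the pipeline can therefore be scored against exact truth:
which peptide produced each spectrum, which taxa carry each peptide, and
the planted abundance of every species in every sample.

Spectrum simulation reuses the search engine's b/y fragment model (so
identification tests have a consistent mass scale) and layers an
independent noise model on top (peak dropout, fragment m/z jitter,
intensity jitter) which is what clustering tests actually probe.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import PROTON_MASS, ParameterSet, ProteinRecord, Spectrum, write_fasta, write_mgf
from .pep2tax import DigestConfig, digest
from .search_engine import WATER_MASS, _AA_MONO, _fixed_mod_map, _fragment_mzs
from .taxonomy import TaxonNode, TaxonomyTree

#: Residues used inside generated peptides: no K/R (interior cleavage
#: sites) and no P (would complicate the proline rule at junctions).
_PEPTIDE_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))
_PHYLUM_NAMES = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _letters(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = _LETTERS[r] + out
    return out


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community.

    Defaults describe a desk-scale gut-microbiome-like experiment:
    8 species across up to 4 phyla, 20 proteins per species, a 10%
    peptide-sharing fraction between sister species, 3-fold spectrum
    redundancy, and a mild noise model (5% peak dropout, 3 mDa fragment
    jitter, 20% intensity CV) over a 120-minute gradient.  ``abundances``
    (samples x species, rows summing to 1) may be given explicitly;
    otherwise per-sample abundances are lognormal with ``abundance_sigma``
    and normalized.
    """

    n_species: int = 8
    n_samples: int = 4
    proteins_per_species: int = 20
    peptides_per_protein: int = 6
    peptides_observed_per_species: int = 10
    peptide_length: tuple[int, int] = (7, 16)
    sharing_fraction: float = 0.1
    redundancy: int = 3
    drop_prob: float = 0.05
    mz_jitter_sd: float = 0.003
    intensity_cv: float = 0.2
    rt_jitter_minutes: float = 2.0
    gradient_minutes: float = 120.0
    abundance_sigma: float = 1.0
    base_intensity: float = 1e9
    abundances: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.redundancy < 1:
            raise ValueError("redundancy k must be >= 1")
        if not (0 <= self.sharing_fraction <= 1):
            raise ValueError("sharing_fraction must be in [0, 1]")
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if ab.shape != (self.n_samples, self.n_species):
                raise ValueError("abundances must be (n_samples, n_species)")
            if np.any(ab < 0):
                raise ValueError("abundances must be nonnegative")
            self.abundances = ab / ab.sum(axis=1, keepdims=True)

    def noise_free(self) -> "CommunitySpec":
        return dataclasses.replace(self, drop_prob=0.0, mz_jitter_sd=0.0, intensity_cv=0.0)

    def low_noise(self) -> "CommunitySpec":
        return dataclasses.replace(self, drop_prob=0.0, mz_jitter_sd=0.0, intensity_cv=0.05)


@dataclass
class TruthSpectrum:
    spectrum_id: str
    sample_id: str
    peptide: str
    taxon_id: int


@dataclass
class SyntheticCommunity:
    """Everything one seed generates, bundled with its ground truth."""

    spec: CommunitySpec
    tree: TaxonomyTree
    proteins: list[ProteinRecord]
    truth_index: dict[str, frozenset[int]]
    species_ids: list[int]
    observed_peptides: dict[int, list[str]]
    abundances: np.ndarray  # (n_samples, n_species), rows sum to 1
    spectra_by_sample: dict[str, list[Spectrum]]
    truth_spectra: list[TruthSpectrum]

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.spectra_by_sample)

    def all_spectra(self) -> list[Spectrum]:
        return [s for sid in self.sample_ids for s in self.spectra_by_sample[sid]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, taxonomy (taxdump + TSV) and per-sample MGFs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        fasta = outdir / "proteins.fasta"
        write_fasta(self.proteins, fasta)
        paths["fasta"] = fasta
        self.tree.to_taxdump(outdir / "taxdump")
        paths["taxdump"] = outdir / "taxdump"
        tsv = outdir / "taxonomy.tsv"
        self.tree.to_tsv(tsv)
        paths["taxonomy_tsv"] = tsv
        for sid in self.sample_ids:
            p = outdir / f"{sid}.mgf"
            write_mgf(self.spectra_by_sample[sid], p)
            paths[sid] = p
        return paths


# ---------------------------------------------------------------------------
# Taxonomy


def make_taxonomy(spec: CommunitySpec) -> TaxonomyTree:
    """Full seven-rank tree over ``spec.n_species`` species.

    Species are distributed round-robin over up to four named phyla
    (Firmicutes first, then Bacteroidetes, ...), paired into genera so
    that sister species exist, every third species gets a digit-bearing
    provisional name, and the last species is parented by a "no rank"
    node named "environmental samples" — the constructs the node-filter
    policies disagree about.
    """
    n_phyla = min(len(_PHYLUM_NAMES), max(2, (spec.n_species + 3) // 4))
    nodes: dict[int, TaxonNode] = {}
    next_id = 1

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        tid = next_id
        next_id += 1
        nodes[tid] = TaxonNode(tid, parent if parent else tid, rank, name)
        return tid

    root = add(0, "no rank", "root")
    superkingdom = add(root, "superkingdom", "Bacteria")
    phylum_ids = [add(superkingdom, "phylum", _PHYLUM_NAMES[i]) for i in range(n_phyla)]
    family_of: dict[int, int] = {}
    for i, pid in enumerate(phylum_ids):
        cls = add(pid, "class", f"{_PHYLUM_NAMES[i]} classis")
        order = add(cls, "order", f"{_PHYLUM_NAMES[i]} ordo")
        family_of[i] = add(order, "family", f"{_PHYLUM_NAMES[i]} familia")

    by_phylum: dict[int, list[int]] = {i: [] for i in range(n_phyla)}
    for s in range(spec.n_species):
        by_phylum[s % n_phyla].append(s)

    species_ids: dict[int, int] = {}
    env_species = spec.n_species - 1 if spec.n_species >= 3 else None
    for i in range(n_phyla):
        members = [s for s in by_phylum[i] if s != env_species]
        genus_count = 0
        for g in range(0, len(members), 2):
            genus = add(
                family_of[i], "genus", f"{_PHYLUM_NAMES[i][:6]}genus {_letters(genus_count)}"
            )
            genus_count += 1
            for s in members[g : g + 2]:
                if s % 3 == 0:
                    name = f"synthetic bacterium {100 + s}"
                else:
                    name = f"{_PHYLUM_NAMES[i][:6]}genus species {_letters(s)}"
                species_ids[s] = add(genus, "species", name)
    if env_species is not None:
        env = add(family_of[0], "no rank", "environmental samples")
        species_ids[env_species] = add(
            env, "species", f"uncultured bacterium {200 + env_species}"
        )
    tree = TaxonomyTree(nodes)
    tree._species_order = [species_ids[s] for s in range(spec.n_species)]  # type: ignore[attr-defined]
    return tree


# ---------------------------------------------------------------------------
# Proteomes


def _random_peptide(rng: np.random.Generator, spec: CommunitySpec, used: set[str]) -> str:
    lo, hi = spec.peptide_length
    while True:
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in used:
            used.add(pep)
            return pep


def make_proteomes(
    tree: TaxonomyTree, spec: CommunitySpec, rng: np.random.Generator
) -> tuple[list[ProteinRecord], dict[str, frozenset[int]], dict[int, list[str]]]:
    """Per-species proteomes from unique tryptic peptides.

    Each species gets ``proteins_per_species`` proteins of
    ``peptides_per_protein`` concatenated tryptic peptides.  With
    probability ``sharing_fraction`` a peptide slot copies a peptide from
    an already-generated sister species (same genus), making that
    peptide's true LCA the genus.  Returns the records, the exact
    peptide -> taxon-set truth map (from digesting the written proteins,
    so missed-cleavage junction peptides are included), and the designed
    zero-missed-cleavage peptide pool per species.
    """
    species_ids: list[int] = getattr(tree, "_species_order")
    used: set[str] = set()
    pools: dict[int, list[str]] = {}
    records: list[ProteinRecord] = []
    for tid in species_ids:
        genus = tree.parent(tid)
        sisters = [s for s in pools if tree.parent(s) == genus]
        pool: list[str] = []
        n_slots = spec.proteins_per_species * spec.peptides_per_protein
        for _ in range(n_slots):
            if sisters and spec.sharing_fraction > 0 and rng.random() < spec.sharing_fraction:
                donor = pools[sisters[int(rng.integers(len(sisters)))]]
                pool.append(donor[int(rng.integers(len(donor)))])
            else:
                pool.append(_random_peptide(rng, spec, used))
        pools[tid] = pool
        for k in range(spec.proteins_per_species):
            peps = pool[k * spec.peptides_per_protein : (k + 1) * spec.peptides_per_protein]
            seq = "".join(peps)
            acc = f"S{tid}P{k:03d}"
            records.append(
                ProteinRecord(
                    accession=acc,
                    description=f"{acc} synthetic protein OX={tid}",
                    sequence=seq,
                    taxon_id=tid,
                )
            )
    truth: dict[str, set[int]] = {}
    cfg = DigestConfig()
    for rec in records:
        for pep in digest(rec.sequence, cfg):
            truth.setdefault(pep, set()).add(rec.taxon_id)
    truth_index = {pep: frozenset(taxa) for pep, taxa in truth.items()}

    observed: dict[int, list[str]] = {}
    for tid in species_ids:
        # observed pool: species' own designed peptides, deduplicated, in
        # generation order; a fixed subset keeps simulations desk-scale
        uniq = list(dict.fromkeys(pools[tid]))
        n = min(spec.peptides_observed_per_species, len(uniq))
        idx = rng.choice(len(uniq), size=n, replace=False)
        observed[tid] = [uniq[i] for i in sorted(idx)]
    return records, truth_index, observed


# ---------------------------------------------------------------------------
# Spectra


def make_abundances(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    if spec.abundances is not None:
        return np.asarray(spec.abundances, dtype=float)
    ab = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=(spec.n_samples, spec.n_species))
    return ab / ab.sum(axis=1, keepdims=True)


def simulate_spectra(
    observed_peptides: dict[int, list[str]],
    abundances: np.ndarray,
    spec: CommunitySpec,
    rng: np.random.Generator,
    params: ParameterSet | None = None,
    species_order: Sequence[int] | None = None,
) -> tuple[dict[str, list[Spectrum]], list[TruthSpectrum]]:
    """Redundant noisy fragment spectra for every sample.

    Each observed peptide of a species with nonzero abundance yields
    ``redundancy`` near-duplicate charge-2 spectra per sample; precursor
    intensity is proportional to the species abundance (lognormal
    biological scatter, sigma 0.3), retention times of duplicates fall
    within ``rt_jitter_minutes`` of a peptide-specific elution time, and
    the noise model applies peak dropout, fragment m/z jitter and
    intensity jitter per copy.
    """
    params = params or ParameterSet()
    fixed = _fixed_mod_map(params)
    # abundance columns are positional: species_order[i] is the taxon id of
    # the i-th abundance column
    species = list(species_order) if species_order is not None else sorted(observed_peptides)
    n_samples = abundances.shape[0]
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]

    # per-peptide properties fixed across samples/copies: elution time and
    # a fragment intensity pattern
    peptide_props: dict[str, tuple[float, np.ndarray, np.ndarray, float]] = {}
    for tid in species:
        for pep in observed_peptides[tid]:
            if pep in peptide_props:
                continue
            frag_mz = _fragment_mzs(pep, fixed, ())
            pattern = rng.uniform(0.2, 1.0, size=frag_mz.size)
            rt = float(rng.uniform(10.0, max(spec.gradient_minutes - 10.0, 11.0)))
            neutral = sum(_AA_MONO[a] + fixed.get(a, 0.0) for a in pep) + WATER_MASS
            peptide_props[pep] = (rt, frag_mz, pattern, neutral)

    spectra_by_sample: dict[str, list[Spectrum]] = {}
    truth: list[TruthSpectrum] = []
    for j, sid in enumerate(sample_ids):
        out: list[Spectrum] = []
        counter = 0
        for si, tid in enumerate(species):
            a = float(abundances[j, si])
            if a <= 0:
                continue
            for pep in observed_peptides[tid]:
                rt0, frag_mz, pattern, neutral = peptide_props[pep]
                base_int = a * spec.base_intensity * float(rng.lognormal(0.0, 0.3))
                precursor_mz = (neutral + 2 * PROTON_MASS) / 2.0
                for _ in range(spec.redundancy):
                    if spec.drop_prob > 0:
                        keep = rng.random(frag_mz.size) > spec.drop_prob
                        if keep.sum() < 3:
                            keep[:] = True
                    else:
                        keep = np.ones(frag_mz.size, dtype=bool)
                    mz = frag_mz[keep]
                    if spec.mz_jitter_sd > 0:
                        mz = mz + rng.normal(0.0, spec.mz_jitter_sd, size=mz.size)
                    inten = pattern[keep] * 1e4
                    if spec.intensity_cv > 0:
                        inten = inten * rng.lognormal(0.0, spec.intensity_cv, size=inten.size)
                    prec_int = base_int * (
                        float(rng.lognormal(0.0, spec.intensity_cv / 2))
                        if spec.intensity_cv > 0
                        else 1.0
                    )
                    sid_spec = f"{sid}.s{counter:05d}"
                    counter += 1
                    out.append(
                        Spectrum(
                            spectrum_id=sid_spec,
                            sample_id=sid,
                            precursor_mz=precursor_mz,
                            precursor_charge=2,
                            precursor_intensity=prec_int,
                            retention_time=rt0
                            + float(
                                rng.uniform(-spec.rt_jitter_minutes, spec.rt_jitter_minutes)
                            ),
                            mz=mz,
                            intensity=inten,
                        )
                    )
                    truth.append(TruthSpectrum(sid_spec, sid, pep, tid))
        spectra_by_sample[sid] = out
    return spectra_by_sample, truth


def make_community(spec: CommunitySpec, params: ParameterSet | None = None) -> SyntheticCommunity:
    """Generate a complete community from ``spec.seed`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    tree = make_taxonomy(spec)
    proteins, truth_index, observed = make_proteomes(tree, spec, rng)
    abundances = make_abundances(spec, rng)
    spectra, truth_spectra = simulate_spectra(
        observed, abundances, spec, rng, params,
        species_order=getattr(tree, "_species_order"),
    )
    return SyntheticCommunity(
        spec=spec,
        tree=tree,
        proteins=proteins,
        truth_index=truth_index,
        species_ids=list(getattr(tree, "_species_order")),
        observed_peptides=observed,
        abundances=abundances,
        spectra_by_sample=spectra,
        truth_spectra=truth_spectra,
    )
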