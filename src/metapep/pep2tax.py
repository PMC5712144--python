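"""In-silico tryptic digestion and the peptide-to-taxon index.

The index (``pep2tax``) is an exact-match map from every tryptic peptide
of a protein database to the sorted set of taxon ids of all proteins
producing it.  Peptides are generated by trypsin specificity (cleave
C-terminal to K/R, optionally suppressed before proline), allowing up to
two missed cleavages, and filtered to 6-35 residues.  The on-disk layout
is a sorted text key file behind a JSON header carrying the digestion
configuration fingerprint and a checksum of the source database, built
via external sort-merge so construction streams in bounded memory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import heapq
import json
import logging
import os
import tempfile
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

MAGIC = "#P2TX1"


@dataclass(frozen=True)
class DigestConfig:
    """Trypsin digestion settings.

    ``proline_rule`` suppresses cleavage when the residue after K/R is P
    (standard trypsin specificity).  ``equate_il`` folds isoleucine into
    leucine in index keys and lookups (as Unipept does); off by default,
    so I and L are distinct.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 35
    proline_rule: bool = True
    equate_il: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin digestion is supported")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cleavage_sites(sequence: str, config: DigestConfig) -> list[int]:
    """0-based positions *after* which trypsin cuts (excluding the C-terminus)."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if config.proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest_spans(sequence: str, config: DigestConfig) -> list[tuple[int, int]]:
    """All (start, end) digestion products passing the length filter.

    A product spanning ``m`` internal cleavage sites counts ``m`` missed
    cleavages; products with more than ``max_missed_cleavages`` are not
    emitted.
    """
    if not sequence:
        return []
    bounds = [0] + cleavage_sites(sequence, config) + [len(sequence)]
    spans = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + config.max_missed_cleavages, len(bounds))):
            length = bounds[b] - bounds[a]
            if config.min_length <= length <= config.max_length:
                spans.append((bounds[a], bounds[b]))
    return spans


def digest(sequence: str, config: DigestConfig | None = None) -> set[str]:
    """Tryptic peptide set of one sequence (duplicates collapsed)."""
    config = config or DigestConfig()
    return {sequence[a:b] for a, b in digest_spans(sequence, config)}


def _normalize_key(peptide: str, config: DigestConfig) -> str:
    return peptide.replace("I", "L") if config.equate_il else peptide


def _source_checksum(db: Sequence[ProteinRecord]) -> str:
    h = hashlib.sha256()
    for rec in db:
        h.update(rec.accession.encode())
        h.update(b"\x00")
        h.update(rec.sequence.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def _pair_stream(
    db: Iterable[ProteinRecord], taxonomy, config: DigestConfig
) -> Iterator[tuple[str, int]]:
    skipped = 0
    for rec in db:
        if rec.taxon_id is None:
            skipped += 1
            continue
        if rec.taxon_id not in taxonomy.nodes:
            raise KeyError(f"taxon id {rec.taxon_id} (protein {rec.accession}) not in taxonomy")
        for pep in digest(rec.sequence, config):
            if "X" in pep:
                continue  # unknown residue: mass/identity undefined
            yield _normalize_key(pep, config), rec.taxon_id
    if skipped:
        logger.info("pep2tax build: skipped %d proteins without taxon id", skipped)


def build_index(
    db: Sequence[ProteinRecord],
    taxonomy,
    config: DigestConfig | None = None,
    out_path: str | Path | None = None,
    chunk_size: int = 500_000,
) -> "Pep2TaxIndex":
    """Digest a database and build the peptide -> taxon-set index on disk.

    Proteins without a taxon id are skipped (count logged); a taxon id
    absent from the taxonomy tree is an error.  Construction spills
    sorted chunks to temporary files and merges them, so memory stays
    bounded by ``chunk_size`` pairs.
    """
    config = config or DigestConfig()
    if out_path is None:
        fd, tmp_name = tempfile.mkstemp(suffix=".p2t")
        os.close(fd)
        out_path = tmp_name
    out_path = Path(out_path)

    n_skipped = sum(1 for rec in db if rec.taxon_id is None)
    chunk_files: list = []
    chunk: list[tuple[str, int]] = []

    def spill() -> None:
        if not chunk:
            return
        chunk.sort()
        tf = tempfile.TemporaryFile(mode="w+t")
        for pep, tid in chunk:
            tf.write(f"{pep}\t{tid}\n")
        tf.seek(0)
        chunk_files.append(tf)
        chunk.clear()

    for pair in _pair_stream(db, taxonomy, config):
        chunk.append(pair)
        if len(chunk) >= chunk_size:
            spill()
    spill()

    def stream(tf) -> Iterator[tuple[str, int]]:
        for line in tf:
            pep, tid = line.rstrip("\n").split("\t")
            yield pep, int(tid)

    merged = heapq.merge(*(stream(tf) for tf in chunk_files))
    body = tempfile.TemporaryFile(mode="w+t")
    n_keys = 0
    current: str | None = None
    taxa: set[int] = set()

    def flush() -> None:
        nonlocal n_keys
        if current is not None:
            body.write(current + "\t" + ",".join(str(t) for t in sorted(taxa)) + "\n")
            n_keys += 1

    for pep, tid in merged:
        if pep != current:
            flush()
            current = pep
            taxa = set()
        taxa.add(tid)
    flush()
    for tf in chunk_files:
        tf.close()

    header = {
        "format": "pep2tax",
        "version": 1,
        "config": dataclasses.asdict(config),
        "fingerprint": config.fingerprint(),
        "source_checksum": _source_checksum(db),
        "n_keys": n_keys,
        "n_proteins_skipped": n_skipped,
    }
    body.seek(0)
    with open(out_path, "w") as fh:
        fh.write(MAGIC + "\t" + json.dumps(header, sort_keys=True) + "\n")
        for line in body:
            fh.write(line)
    body.close()
    return Pep2TaxIndex.open(out_path)


class Pep2TaxIndex:
    """Exact-match peptide -> sorted taxon-id-set map.

    The file stores sorted keys; :meth:`open` loads the key column and
    answers :meth:`lookup` by binary search.  Opening with
    ``expect_config`` refuses an index whose digestion fingerprint does
    not match, so stale indexes cannot silently answer queries digested
    under different rules.
    """

    def __init__(self, path: Path, header: dict, keys: list[str], values: list[tuple[int, ...]]):
        self.path = path
        self.header = header
        self.config = DigestConfig(**header["config"])
        self._keys: list[str] | None = keys
        self._values = values

    @classmethod
    def open(cls, path: str | Path, expect_config: DigestConfig | None = None) -> "Pep2TaxIndex":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if not first.startswith(MAGIC + "\t"):
                raise ValueError(f"{path} is not a pep2tax index (bad magic)")
            header = json.loads(first.split("\t", 1)[1])
            if expect_config is not None and header["fingerprint"] != expect_config.fingerprint():
                raise ValueError(
                    "pep2tax index digestion fingerprint mismatch: "
                    f"index={header['fingerprint']} requested={expect_config.fingerprint()}"
                )
            keys: list[str] = []
            values: list[tuple[int, ...]] = []
            for line in fh:
                pep, tids = line.rstrip("\n").split("\t")
                keys.append(pep)
                values.append(tuple(int(t) for t in tids.split(",")))
        if keys != sorted(keys) or len(keys) != header["n_keys"]:
            raise ValueError(f"{path}: corrupt pep2tax index body")
        return cls(path, header, keys, values)

    def lookup(self, peptide: str) -> set[int]:
        """Taxon ids of all source proteins of ``peptide`` (empty if unseen)."""
        if self._keys is None:
            raise ValueError("pep2tax index is closed")
        key = _normalize_key(peptide, self.config)
        i = bisect_left(self._keys, key)
        if i < len(self._keys) and self._keys[i] == key:
            return set(self._values[i])
        return set()

    def __contains__(self, peptide: str) -> bool:
        return bool(self.lookup(peptide))

    def __len__(self) -> int:
        if self._keys is None:
            raise ValueError("pep2tax index is closed")
        return len(self._keys)

    def items(self) -> Iterator[tuple[str, set[int]]]:
        if self._keys is None:
            raise ValueError("pep2tax index is closed")
        for k, v in zip(self._keys, self._values):
            yield k, set(v)

    def close(self) -> None:
        self._keys = None
        self._values = []
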