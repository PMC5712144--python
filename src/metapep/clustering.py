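"""MS/MS spectral clustering with delegate (consensus) spectra.

Redundant fragment spectra — the same peptide fragmented repeatedly within
or across runs — are collapsed into clusters, and one consensus spectrum
per cluster is carried forward to the database search.  Clustering is
gated by a wide precursor window (2 Da by default, wide enough to keep
the isotopic envelope together), a retention-time span limit (20 min) and
charge compatibility; within the gates, membership requires a normalized
dot-product similarity to the cluster consensus of at least 0.99.

The algorithm is a deterministic greedy single pass over spectra sorted
by precursor m/z: each spectrum joins the first eligible existing cluster
(lowest mean precursor m/z, then creation order) whose consensus it
matches, or seeds a new cluster.
"""
from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ParameterSet, Spectrum


@dataclass(frozen=True)
class ClusteringConfig:
    """Clustering gates and similarity settings.

    precursor_tolerance:
        Max precursor m/z spread inside a cluster, in Da (default 2.0,
        retaining the isotopic envelope).
    fragment_tolerance:
        Fragment bin width in Da (0.02 high-resolution; use 0.5 for
        high-low instrument mode).
    rt_gap_max:
        Max retention-time span of a cluster in minutes (default 20).
    similarity_threshold:
        Normalized dot-product threshold in [0, 1] (default 0.99).
    top_n_peaks:
        Peaks kept (by intensity) before binning (default 50).
    """

    precursor_tolerance: float = 2.0
    fragment_tolerance: float = 0.02
    rt_gap_max: float = 20.0
    similarity_threshold: float = 0.99
    top_n_peaks: int = 50

    def __post_init__(self) -> None:
        if self.precursor_tolerance <= 0 or self.fragment_tolerance <= 0 or self.rt_gap_max <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 <= self.similarity_threshold):
            raise ValueError("similarity_threshold must be >= 0")
        if self.top_n_peaks < 1:
            raise ValueError("top_n_peaks must be >= 1")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "ClusteringConfig":
        """Build from a :class:`ParameterSet`, honouring the instrument mode."""
        defaults = {"fragment_tolerance": 0.5 if params.instrument_mode == "high-low" else 0.02}
        defaults.update(params.clustering)
        return cls(**defaults)


@dataclass
class SpectrumCluster:
    """A set of similar spectra plus one delegate (consensus) spectrum."""

    cluster_id: str
    members: list[Spectrum]
    delegate: Spectrum

    @property
    def member_ids(self) -> list[str]:
        return [m.spectrum_id for m in self.members]

    @property
    def precursor_mz(self) -> float:
        return float(np.mean([m.precursor_mz for m in self.members]))

    @property
    def rt_span(self) -> tuple[float, float]:
        rts = [m.retention_time for m in self.members]
        return (min(rts), max(rts))


ReductionStats = namedtuple("ReductionStats", ["n_input", "n_clusters", "retained_fraction"])


def _bin_index(mz: np.ndarray, width: float) -> np.ndarray:
    return np.floor(mz / width).astype(np.int64)


def preprocess_spectrum(spectrum: Spectrum, config: ClusteringConfig) -> dict[int, float]:
    """Top-N peak filter, binning, sqrt transform, unit-norm scaling.

    Returns a sparse vector as ``{bin index: weight}`` with unit Euclidean
    norm; bins have width ``fragment_tolerance``.
    """
    if spectrum.n_peaks == 0:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r} has no peaks")
    # primary key: intensity descending; ties broken by m/z ascending
    order = np.lexsort((spectrum.mz, -spectrum.intensity))[: config.top_n_peaks]
    mz = spectrum.mz[order]
    inten = spectrum.intensity[order]
    bins = _bin_index(mz, config.fragment_tolerance)
    acc: dict[int, float] = {}
    for b, w in zip(bins.tolist(), np.sqrt(inten).tolist()):
        acc[b] = acc.get(b, 0.0) + w
    norm = math.sqrt(sum(w * w for w in acc.values()))
    if norm == 0.0:
        # all-zero intensities: fall back to flat weights over populated bins
        flat = 1.0 / math.sqrt(len(set(bins.tolist())))
        return {b: flat for b in set(bins.tolist())}
    return {b: w / norm for b, w in acc.items()}


def _dot(a: dict[int, float], b: dict[int, float]) -> float:
    if len(b) < len(a):
        a, b = b, a
    return sum(w * b.get(k, 0.0) for k, w in a.items())


def similarity(a: Spectrum, b: Spectrum, config: ClusteringConfig) -> float:
    """Normalized dot product of the preprocessed spectra, in [0, 1]."""
    return min(1.0, _dot(preprocess_spectrum(a, config), preprocess_spectrum(b, config)))


class _ClusterBuilder:
    """Mutable accumulator used during the greedy pass."""

    __slots__ = (
        "index",
        "members",
        "min_mz",
        "max_mz",
        "sum_mz",
        "rt_min",
        "rt_max",
        "charge",
        "bins",
        "_vec",
        "width",
    )

    def __init__(self, index: int, spectrum: Spectrum, config: ClusteringConfig):
        self.index = index
        self.width = config.fragment_tolerance
        self.members: list[Spectrum] = []
        self.min_mz = self.max_mz = self.sum_mz = 0.0
        self.rt_min = self.rt_max = 0.0
        self.charge = 0
        self.bins: dict[int, list[float]] = {}  # bin -> [intensity sum, intensity*mz sum]
        self._vec: dict[int, float] | None = None
        self.add(spectrum, config)

    def add(self, s: Spectrum, config: ClusteringConfig) -> None:
        if not self.members:
            self.min_mz = self.max_mz = s.precursor_mz
            self.sum_mz = 0.0
            self.rt_min = self.rt_max = s.retention_time
        self.members.append(s)
        self.min_mz = min(self.min_mz, s.precursor_mz)
        self.max_mz = max(self.max_mz, s.precursor_mz)
        self.sum_mz += s.precursor_mz
        self.rt_min = min(self.rt_min, s.retention_time)
        self.rt_max = max(self.rt_max, s.retention_time)
        if self.charge == 0:
            self.charge = s.precursor_charge
        for b, mz, inten in zip(
            _bin_index(s.mz, config.fragment_tolerance).tolist(),
            s.mz.tolist(),
            s.intensity.tolist(),
        ):
            cell = self.bins.setdefault(b, [0.0, 0.0])
            cell[0] += inten
            cell[1] += inten * mz
        self._vec = None

    @property
    def mean_mz(self) -> float:
        return self.sum_mz / len(self.members)

    def consensus_peaks(self) -> tuple[np.ndarray, np.ndarray]:
        items = sorted(self.bins.items())
        mz = np.array(
            [cell[1] / cell[0] if cell[0] > 0 else (b + 0.5) * self.width for b, cell in items],
            dtype=float,
        )
        inten = np.array([cell[0] for _, cell in items], dtype=float)
        order = np.argsort(mz, kind="stable")
        return mz[order], inten[order]

    def delegate_vector(self, config: ClusteringConfig) -> dict[int, float]:
        if self._vec is None:
            mz, inten = self.consensus_peaks()
            stub = Spectrum(
                spectrum_id="_consensus",
                sample_id=self.members[0].sample_id,
                precursor_mz=self.mean_mz,
                mz=mz,
                intensity=inten,
            )
            self._vec = preprocess_spectrum(stub, config)
        return self._vec


def consensus_spectrum(cluster: SpectrumCluster | Sequence[Spectrum], config: ClusteringConfig,
                       cluster_id: str | None = None) -> Spectrum:
    """Merge cluster members into one delegate spectrum.

    Singleton clusters pass through unchanged.  Otherwise peaks falling in
    the same fragment bin are merged (intensity sum, intensity-weighted
    mean m/z); the precursor m/z is the precursor-intensity-weighted mean,
    the retention time the member median, and the precursor intensity the
    member sum.
    """
    members = cluster.members if isinstance(cluster, SpectrumCluster) else list(cluster)
    if not members:
        raise ValueError("cannot build a consensus of an empty cluster")
    cid = cluster_id or (cluster.cluster_id if isinstance(cluster, SpectrumCluster) else "cluster")
    if len(members) == 1:
        return members[0]
    builder = _ClusterBuilder(0, members[0], config)
    for m in members[1:]:
        builder.add(m, config)
    mz, inten = builder.consensus_peaks()
    weights = np.array([m.precursor_intensity for m in members], dtype=float)
    prec_mzs = np.array([m.precursor_mz for m in members], dtype=float)
    if weights.sum() > 0:
        prec_mz = float(np.average(prec_mzs, weights=weights))
    else:
        prec_mz = float(prec_mzs.mean())
    charge = next((m.precursor_charge for m in members if m.precursor_charge > 0), 0)
    return Spectrum(
        spectrum_id=f"{cid}:consensus",
        sample_id=members[0].sample_id,
        precursor_mz=prec_mz,
        precursor_charge=charge,
        precursor_intensity=float(weights.sum()),
        retention_time=float(np.median([m.retention_time for m in members])),
        mz=mz,
        intensity=inten,
    )


def cluster_spectra(
    spectra: Sequence[Spectrum], config: ClusteringConfig | None = None
) -> list[SpectrumCluster]:
    """Partition spectra into clusters of near-identical scans.

    Two spectra may share a cluster only if the cluster precursor spread
    stays within ``precursor_tolerance``, charges are compatible (equal or
    one unknown), the cluster retention-time span stays within
    ``rt_gap_max``, and the joining spectrum's similarity to the cluster
    consensus is at least ``similarity_threshold``.  Deterministic for a
    given input order and configuration.
    """
    config = config or ClusteringConfig()
    if not spectra:
        return []
    order = sorted(range(len(spectra)), key=lambda i: (spectra[i].precursor_mz, i))
    builders: list[_ClusterBuilder] = []
    active_start = 0
    for idx in order:
        s = spectra[idx]
        vec = preprocess_spectrum(s, config) if s.n_peaks else {}
        # clusters whose minimum precursor fell out of the window can never
        # accept this (or any later) spectrum: precursors only increase.
        while (
            active_start < len(builders)
            and builders[active_start].min_mz < s.precursor_mz - config.precursor_tolerance
        ):
            active_start += 1
        candidates = sorted(
            builders[active_start:], key=lambda c: (c.mean_mz, c.index)
        )
        joined = False
        for c in candidates:
            if max(c.max_mz, s.precursor_mz) - min(c.min_mz, s.precursor_mz) > config.precursor_tolerance:
                continue
            if c.charge and s.precursor_charge and c.charge != s.precursor_charge:
                continue
            if (
                max(c.rt_max, s.retention_time) - min(c.rt_min, s.retention_time)
                > config.rt_gap_max
            ):
                continue
            if _dot(vec, c.delegate_vector(config)) >= config.similarity_threshold:
                c.add(s, config)
                joined = True
                break
        if not joined:
            builders.append(_ClusterBuilder(len(builders), s, config))
    clusters = []
    for k, b in enumerate(builders):
        cid = f"c{k:06d}"
        delegate = consensus_spectrum(b.members, config, cluster_id=cid)
        clusters.append(SpectrumCluster(cluster_id=cid, members=b.members, delegate=delegate))
    return clusters


def reduction_stats(
    spectra: Sequence[Spectrum], clusters: Sequence[SpectrumCluster]
) -> ReductionStats:
    """Summarize spectrum reduction: ``retained_fraction = n_clusters/n_input``.

    Raises if the clusters do not partition the input spectra.
    """
    input_ids = sorted(s.spectrum_id for s in spectra)
    member_ids = sorted(mid for c in clusters for mid in c.member_ids)
    if input_ids != member_ids:
        raise ValueError("clusters do not partition the input spectra")
    n = len(spectra)
    return ReductionStats(n, len(clusters), len(clusters) / n if n else 0.0)


def write_cluster_table(clusters: Iterable[SpectrumCluster], path) -> None:
    """TSV mapping spectrum_id -> cluster_id (one row per member)."""
    with open(path, "w") as fh:
        fh.write("spectrum_id\tcluster_id\n")
        for c in clusters:
            for mid in c.member_ids:
                fh.write(f"{mid}\t{c.cluster_id}\n")
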