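import numpy as np
import pytest

from metapep.io_formats import Spectrum
from metapep.synthetic import CommunitySpec, make_community
from metapep.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def small_community():
    """Low-noise 6-species, 2-sample community shared by read-only tests."""
    spec = CommunitySpec(
        n_species=6,
        n_samples=2,
        proteins_per_species=8,
        peptides_per_protein=5,
        peptides_observed_per_species=6,
        redundancy=3,
        seed=11,
    ).low_noise()
    return make_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spectrum(rng, spectrum_id="s0", sample_id="A", n_peaks=20, precursor_mz=None):
    mz = np.sort(rng.uniform(100, 1500, size=n_peaks))
    return Spectrum(
        spectrum_id=spectrum_id,
        sample_id=sample_id,
        precursor_mz=float(precursor_mz if precursor_mz is not None else rng.uniform(300, 1200)),
        precursor_charge=int(rng.integers(0, 4)),
        precursor_intensity=float(rng.uniform(0, 1e6)),
        retention_time=float(rng.uniform(0, 120)),
        mz=mz,
        intensity=rng.uniform(1, 1e4, size=n_peaks),
    )


def random_tree(rng, n_nodes=200):
    """Random tree: each node's parent is a uniformly chosen earlier node."""
    nodes = {1: TaxonNode(1, 1, "no rank", "root")}
    for tid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, tid))
        nodes[tid] = TaxonNode(tid, parent, "no rank", f"node {tid}")
    return TaxonomyTree(nodes)
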