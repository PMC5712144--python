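# metapep

Quantitative taxonomic profiling of microbial communities from
metaproteomics MS/MS data.

Shotgun metaproteomics measures the proteins a whole microbial community
expresses, but turning millions of fragment spectra plus a
multi-million-entry gene-catalog database into per-taxon abundances is
computationally awkward: the search space is enormous, most spectra are
redundant, and a peptide rarely points at a single organism.  `metapep`
implements the complete pipeline as a tested Python library with a thin
CLI:

1. **Spectral clustering** — near-identical MS/MS scans are grouped
   (precursor window 2 Da to keep the isotopic envelope together,
   retention-time span ≤ 20 min, charge-compatible, cosine similarity of
   binned √-intensity spectra ≥ 0.99) and one consensus *delegate*
   spectrum per cluster is carried forward, collapsing the redundancy
   before the expensive search.
2. **Sample-specific database reduction** — either the *iterative*
   two-round strategy (search every sample against the full catalog,
   extract the evidenced proteins, search again) or the *clustering*
   strategy (search only the delegates once and extract the proteins
   containing any FDR-accepted peptide).
3. **Peptide identification and quantification** — a minimal built-in
   engine matches spectra to tryptic candidates by precursor mass and
   scores matched b/y fragments (`score = n_matched / √n_theoretical`),
   with reversed-sequence decoys and acceptance at target–decoy
   FDR ≤ *q*:  accept the largest score cutoff *t* with
   `#{decoy ≥ t} / #{target ≥ t} ≤ q`.  Peptide records carry per-sample
   MS2 spectral counts and summed MS1 precursor intensities; tables from
   an external engine can be imported instead.
4. **Taxonomic profiling** — an exact-match *pep2tax* index maps every
   tryptic peptide (trypsin, ≤ 2 missed cleavages, 6–35 residues) of the
   catalog to the taxa of all proteins containing it; each identified
   peptide receives the lowest common ancestor (LCA) of that set, and its
   quantities are summed over the whole LCA lineage, so for every node
   and sample
   `value(node) = Σ value(children) + value(peptides with LCA = node)`.
   Node filtering is deliberately permissive by default (provisional
   species with digits in their names and "environmental samples"
   subtrees are retained); a `unipept-like` policy that removes them is
   available for comparison.
5. **Export and statistics** — BIOM 1.0 JSON (MS intensities in place of
   read counts, consumable by metagenomics tools), deterministic TSV
   tables, Firmicutes/Bacteroidetes ratios, a validity filter for
   high-confidence species (≥ 3 unique peptides in a sample, valid in
   more than 8 samples), nonzero-median normalization with log₁₀
   transform, and Pearson-correlation distance matrices.

A first-class synthetic module generates taxonomies, proteomes,
multi-sample communities and redundant noisy spectra with exact ground
truth, so every stage is testable without downloads.

## Worked example

```python
from metapep import ClusteringConfig, cluster_spectra, reduction_stats
from metapep.synthetic import CommunitySpec, make_community

spec = CommunitySpec(n_species=6, n_samples=2, proteins_per_species=8,
                     peptides_per_protein=5, peptides_observed_per_species=8,
                     redundancy=4, seed=8).low_noise()
community = make_community(spec)
spectra = community.all_spectra()
clusters = cluster_spectra(spectra, ClusteringConfig())
stats = reduction_stats(spectra, clusters)
print(stats.n_input, stats.n_clusters, f"{stats.retained_fraction:.1%}")
```

prints

```
384 48 12.5%
```

— 384 input spectra (48 peptides × 4-fold redundancy × 2 samples)
collapse to exactly 48 delegates: clustering removed precisely the
redundancy and nothing else.  Running the full pipeline on such a
community (`examples/04_full_pipeline.py`) reports each stage:

```
clustering: 432 spectra -> 47 delegates (retained 0.109)
reduce: 48 -> 33 proteins
search: 432 PSMs, 432 accepted at FDR 0.01
taxonomy: 47/47 peptides assigned an LCA
taxonomy: 20 taxa quantified
```

The `examples/` directory holds one short script per capability
(clustering, search + FDR, taxonomic profiling, full pipeline); each
prints the numbers it computes and what they mean.  The same operations
are available from the shell via `metapep simulate / cluster / search /
reduce / build-pep2tax / taxonomy / run`.

## Layout

```
src/metapep/
  io_formats.py     MGF/FASTA/TSV/JSON-parameter readers and writers
  clustering.py     spectral clustering and consensus spectra
  search_engine.py  minimal search engine, decoys, FDR, aggregation
  db_reduction.py   iterative and clustering database reduction
  pep2tax.py        tryptic digestion and the peptide->taxon index
  taxonomy.py       taxonomy trees, LCA, rank projection, quantification
  export_stats.py   BIOM/TSV export, F/B ratio, filters, distances
  synthetic.py      ground-truth community generator
  pipeline.py       three-stage orchestration
  cli.py            `metapep` command group
```

See `docs/methods.md` for the model, parameter and design documentation.
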