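# Methods

This note documents the models, parameters and design choices behind
`metapep`, and what the synthetic test bed does and does not show about
real data.

## Spectral clustering

Spectra are preprocessed into sparse unit vectors: the 50 most intense
peaks are kept, fragment m/z values are binned at the fragment tolerance
(0.02 Da in `high-high` mode, 0.5 Da in `high-low`), intensities are
square-root transformed (damping the dominance of base peaks) and the
vector is scaled to unit Euclidean norm.  Similarity is the dot product
of two such vectors — a cosine similarity in [0, 1].

Clustering is a greedy single pass over spectra sorted by precursor m/z.
A spectrum joins the first eligible cluster — candidates ordered by mean
precursor m/z, then creation order — whose gates it passes and whose
*consensus* spectrum it matches at or above the similarity threshold;
otherwise it seeds a new cluster.  Gates, applied to the cluster as a
whole:

| parameter | default | meaning |
|---|---|---|
| `precursor_tolerance` | 2.0 Da | max precursor spread per cluster; wide enough to keep an isotopic envelope together |
| `rt_gap_max` | 20 min | max retention-time span per cluster |
| `similarity_threshold` | 0.99 | cosine threshold against the cluster consensus |
| `top_n_peaks` | 50 | peak filter before binning |
| charge | — | equal charges only; unknown (0) matches anything |

The delegate is the consensus spectrum: peaks in the same fragment bin
are merged with summed intensity and intensity-weighted mean m/z; the
precursor m/z is the precursor-intensity-weighted member mean, the
retention time the member median.  Singleton clusters pass through
unchanged.  The pass is deterministic given input order and
configuration; sorting plus a sliding precursor window keeps it near
O(n log n) at the scales this package targets.

A note on the threshold scale: 0.99 on a cosine is *strict*.  Dropping a
single peak of 30 equal-weight peaks already pushes similarity to ~0.983,
and fragment m/z jitter comparable to the bin width moves peaks across
bin boundaries.  Clustering therefore collapses redundancy aggressively
only when replicate spectra are faithful (the regime the threshold is
meant for); under heavy noise it degrades conservatively toward
singletons rather than merging unrelated spectra.  Other implementations
score similarity on a probabilistic scale whose 0.99 is not directly
comparable to ours.

## Built-in search engine

The engine exists so the pipeline is runnable and testable end to end
without a licensed external engine; it is intentionally minimal, and
identifications from a production engine can be imported through the
peptide-table adapter (imported intensities take precedence during
aggregation).

Candidates are tryptic peptides (shared digestion rules below) of the
target database plus one reversed-sequence decoy per target (`REV_`
accessions).  For each spectrum and allowed charge (the annotated charge,
or 2 and 3 when unknown) the neutral mass window is
`precursor_tolerance` (default 0.01 Da, roughly 10 ppm at m/z 1000).
Modifications: fixed mods are always applied
(carbamidomethyl-C +57.02146 Da by default); each variable mod
(oxidation-M +15.99491, protein N-terminal acetyl +42.01057) is
enumerated present/absent up to `max_variable_mods` (2) per peptide, and
protein N-terminal mods apply only to protein-start peptides.  Scoring
counts singly charged b/y fragments matched within the fragment
tolerance, normalized by the square root of the number of theoretical
fragments; ties break toward fewer modifications, then the
lexicographically smaller sequence.  Spectra matching zero fragments
yield no PSM.

FDR control: PSMs are sorted by descending score (decoys first at equal
score, which is the conservative side) and the lowest score cutoff *t*
with `#{decoy ≥ t}/#{target ≥ t} ≤ q` is chosen, maximizing acceptances.
The accepted set is monotone in *q*.

Quantification fidelity gap: peptide intensity is the sum of precursor
(MS1) intensities of matched spectra, not a chromatographic XIC
integral.  On the synthetic data this preserves proportionality exactly;
on real data XIC-based values from an external engine should be imported.

## Database reduction

*Iterative*: round 1 searches each sample separately against the full
catalog and accepts target PSMs at a permissive score cut
(`round1_min_score`, default 0 — any fragment-matched PSM).  The strict
FDR belongs only to the final search: applying it twice would compound
the filters, and the intermediate database's only job is to be a
generous superset.  Round 2 searches all samples against the union of
round-1 proteins at FDR `fdr_threshold` (0.01); the reduced database is
the proteins identified in round 2.

*Clustering*: all samples are pooled and clustered jointly (cross-sample
redundancy is exactly what makes pooling profitable), the delegates are
searched once at FDR 0.01, and the reduced database is every protein
containing an accepted peptide as an exact substring.  Round-1 protein
"identification" is any protein carrying an accepted peptide — no
parsimony or protein grouping.  Duplicate protein sequences are kept
(and counted in the log), since distinct catalog entries may carry
distinct taxonomic annotations.

## pep2tax index and digestion

Trypsin cleaves C-terminal to K/R; cleavage before proline is suppressed
by default (`proline_rule`).  Products spanning at most
`max_missed_cleavages` (2) internal sites and 6–35 residues long are
kept.  Isoleucine and leucine are distinct by default; `equate_il` folds
I into L in both keys and lookups for compatibility with tools that
cannot distinguish them.  N-terminal methionine clipping is not applied.
Peptides containing X are dropped (undefined mass and identity).

The index maps each peptide to the sorted, deduplicated set of taxon ids
of all proteins producing it.  Construction streams protein-by-protein,
spilling sorted chunks to temporary files and merging them, so memory is
bounded by the chunk size regardless of database size.  The on-disk
format is a sorted text key file behind a one-line JSON header (magic
`#P2TX1`) carrying the digestion-configuration fingerprint and a source
checksum; opening with an expected configuration refuses a stale index.
`open()` loads the key column into memory and answers lookups by binary
search — appropriate at the scales this package targets, while the file
format itself stays streamable and mergeable.

## Taxonomy and quantification

Taxonomy trees load from NCBI taxdump (`nodes.dmp`/`names.dmp`,
scientific names) or a 4-column TSV; validation enforces a single root,
no cycles and no orphans.  Canonical ranks are superkingdom … species;
"no rank" nodes are kept in lineages and quantified but excluded from
rank projections.  Because a lineage may lack a canonical rank (e.g. a
species under an "environmental samples" node has no genus), per-rank
distinctive-peptide counts need not be monotone across ranks.

The LCA of a peptide's taxon set is the deepest node on every member's
root path.  Two node policies precede the LCA: `permissive` (default) keeps
every node; `unipept-like` removes species-or-below nodes whose name
contains a digit and any node below an ancestor named "environmental
samples".  The permissive default trades a shallower LCA on some shared
peptides for not discarding provisional organisms; by construction the
`permissive` LCA is never deeper than the `unipept-like` one for the same
peptide.

A peptide contributes its per-sample intensity, MS2 spectral count, and
a peptide count of 1 (in samples where it was observed) to **every node
on its LCA lineage** — the node a peptide uniquely resolves to, and all
ancestors, which are exactly the taxa it distinctively evidences.
Peptides shared beyond the lineage contribute nothing elsewhere, so the
table satisfies, exactly, per sample and mode:

    value(node) = Σ value(children present) + value(peptides with LCA = node)

and the root row equals the total of all assigned peptides.  Unassigned
peptides appear in the peptide table with an explicit `unassigned`
marker and never in the taxa table.

## Export and statistics

BIOM 1.0 JSON exports use type "OTU table" (maximal downstream-tool
compatibility), full-lineage taxonomy metadata per observation, sparse
coordinate encoding below 50% density, and a fixed header timestamp so
identical runs produce byte-identical files (override via `date=`).
TSVs are deterministic: sorted rows, `%.6g` floats in the human-readable
tables; the pipeline's intermediate peptide table keeps full precision so
staged runs reproduce one-shot runs bit for bit.

The validity filter keeps taxa with ≥ 3 unique peptides in a sample
("valid" there) in strictly more than 8 samples — both boundaries pinned
by tests.  Median normalization divides each sample column by its median
over *nonzero* entries (zeros are missing values in intensity data, and
including them would make the median reflect detection rate rather than
scale), then applies log₁₀ with zeros propagating as missing.  Sample
distances are `1 − Pearson r` with pairwise missing-value exclusion;
constant columns yield undefined (NaN) entries rather than errors.

## Synthetic communities

The generator emulates, from one seed (byte-identical outputs per seed):

- a seven-rank taxonomy with paired sister species per genus, a fraction
  of digit-bearing provisional species names, and an "environmental
  samples" subtree — the constructs the node policies disagree on;
- per-species proteomes concatenated from globally unique tryptic
  peptides (7–16 residues, no internal K/R/P), with a configurable
  fraction of peptides copied between sister species so their true LCA
  is the genus; the emitted truth map covers every digestion product,
  including missed-cleavage junction peptides;
- per-sample species abundances (lognormal, σ = 1, normalized — spanning
  roughly two decades, as microbial communities do) or explicit planted
  vectors;
- redundant spectra: each observed peptide yields `redundancy` (3)
  charge-2 copies per sample, precursor intensity proportional to
  abundance with σ = 0.3 lognormal biological scatter, retention times
  within ±2 min of a peptide-specific elution time on a 120-min
  gradient, and a noise model of 5% peak dropout, 3 mDa fragment m/z
  jitter and 20% intensity CV — typical of high-resolution instruments.

Deliberate circularity and its limits: spectrum simulation reuses the
search engine's b/y fragment model, so identification tests check the
matching and FDR machinery, not fragmentation chemistry.  Clustering
tests are insulated from that circularity by the independent noise
model.  Not emulated: chromatographic peak shapes, charge-state
envelopes, isotope patterns, chimeric spectra, and real cross-database
peptide homoplasy — so passing tests demonstrate the correctness of the
algorithms under the stated model, not instrument-level performance.

## Test and acceptance problem sizes

The suite and `scripts/acceptance.py` run desk-scale problems chosen to
exercise every code path with tight statistics: communities of 4–12
species (16 samples for the strategy comparison, ~3,000 spectra),
20 replicates for FDR calibration, 500 random sequences against the
digestion oracle and 1,000 subsets of a 200-node tree against the LCA
oracle.  The full suite completes in well under a minute.

## Known limitations

- The built-in engine has no PEP estimation, match-between-runs,
  labeling support or chromatographic quantification; it is a testing
  engine with an adapter for real ones.
- One LCA per peptide; no probabilistic or weighted taxon assignment,
  and shared-peptide quantity is never redistributed below the LCA.
- The clustering similarity scale is a plain cosine; thresholds from
  probabilistically scored implementations do not transfer numerically.
- mzML input is not implemented; MGF is the interchange format.
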