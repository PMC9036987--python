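# Methods

## Scope and model

`phycosignal` implements the inference chain used to ask how much of the
positive association between bacteria and eukaryotic phytoplankton in an
algal bioreactor community is attributable to indole-3-acetic-acid (IAA)
signaling.  The chain has five stages — reference construction, translated
read screening, RPKM quantification, LCA host taxonomy, and co-occurrence
network analysis — plus a synthetic-data generator that makes every stage
testable offline.  The unit of functional annotation is the *subtype*: one
of the three last-step IAA-synthesis enzymes (indoleacetamide hydrolase,
indoleacetaldehyde dehydrogenase, indoleacetonitrile nitrilase) or the algal
cyclin.  A genus whose reads carry a bacterial subtype is a *signaled
bacterium*; one reached through cyclin reads is a *signaled alga*.

## Reference construction

Curated proteins arrive as one FASTA per subtype; headers may carry
`genus=<name>`.  Redundancy is removed per subtype by greedy incremental
clustering in the cd-hit convention: sequences visited longest-first (ties
by id for determinism); a sequence joins the first cluster whose
representative matches it at identity ≥ 0.97, else founds a new cluster.
Identity is the number of identical positions on the optimal global-overlap
alignment divided by the shorter sequence's length.  With match 1, mismatch
0 and free gaps, the optimal match count equals the longest common
subsequence, which is how it is computed (and how the independent test
oracle recomputes it).  Subtypes are never merged: the subtype label is the
unit of downstream quantification.

## Screening

Reads are translated in all six frames, split at stop codons; fragments
shorter than 8 aa are discarded and N-containing codons become X.  Every
fragment is aligned to every reference by exact Smith–Waterman under
BLOSUM62 with affine gaps costing 11 + k for a gap of length k.  This is a
full dynamic-programming search rather than a seeded heuristic: at the read
counts this package targets, exhaustive alignment is affordable and removes
any dependence on an external aligner, while preserving the annotation rule
of a heuristic translated search.  Significance follows Karlin–Altschul,
E = K·m·n·e^(−λS), with m the fragment length, n the total residues in the
reference database, and the standard gapped-BLOSUM62 parameters λ = 0.267,
K = 0.041; bit score = (λS − ln K)/ln 2.  No effective-length correction is
applied, so E-values differ slightly from heuristic translated-search
output; the `evalue` function is exposed with K and λ as arguments.  A
score floor derived from the E-value cutoff skips traceback for hopeless
alignments.

Hits with E ≤ 10⁻⁵ are retained (best frame per reference); the best hit is
the highest bit score, ties broken by lower E then reference id.  The read
is annotated with the best hit's subtype only when identity > 0.50 **and**
alignment length > 25 aa — both strict, so a hit at exactly 50% identity or
exactly 25 columns is rejected.  Identity here counts identical positions
over all alignment columns including gaps (distinct from the clustering
identity above; both conventions are deliberate and documented).  Up to ten
passing hits per read are kept for taxonomy.

## Quantification

RPKM = c·10⁹ / (L·T) with c the reads assigned to a reference, L its
coding-nucleotide length (3 × amino-acid length, keeping magnitudes
comparable to nucleotide-gene RPKM) and T the sample's **total** clean read
count.  Using total rather than annotated reads as the per-million
denominator is a deliberate choice: the screened gene set is four genes, so
normalizing per annotated read would be degenerate.  Subtype abundance is
the sum of per-reference RPKM within the subtype.

## Host taxonomy

Per read, hits below 50 bits are dropped; of the survivors only those within
10% of the best bit score vote; votes are the `source_genus` tags of the hit
references (untagged references abstain); the read lands on the LCA of the
voting genera.  After all reads of a sample are placed, a node's support is
the fraction of the sample's placed reads at or below it; reads on nodes
with support strictly below 0.01 are promoted to the nearest ancestor with
sufficient support, in a single leaf-to-root pass (the root, support 1, is
the fallback).  Min support is interpreted as a fraction of assigned reads —
an absolute count of 0.01 would be meaningless.  Finally, only reads resting
on genus nodes are reported; everything else is UNCLASSIFIED, restricting
classification to the rank the method can support.  Mapping hits to taxa via
the curated references' genus tags (rather than a full accession→taxid
service) keeps the pipeline self-contained at the rank it reports.

## Network analysis

Genus abundance series across n samples are correlated with tie-corrected
Spearman rank correlation, restricted to bacteria–phytoplankton pairs
(intra-kingdom edges are excluded by design: the question is interkingdom).
Edges require |ρ| > 0.6 and p < 0.01, both strict; negative correlations are
kept with their sign.  Two-sided p-values use the exact permutation
distribution for n ≤ 9 — at the small sample counts typical of bioreactor
time series the t-approximation is unreliable — and the t-approximation
with n − 2 degrees of freedom otherwise.  The exact regime provably respects
the nominal false-edge bound (verified by full enumeration at n = 8); the
t-approximation is mildly anti-conservative, e.g. a measured per-pair
false-edge rate of ~1.3% at n = 12 against the nominal 1%.  Constant series
have undefined correlation and contribute no edge.

Graph metrics follow the Cytoscape NetworkAnalyzer definitions so that no
external tool is required: density 2E/(N(N−1)); heterogeneity
√(population variance of degree)/mean degree; centralization
(N/(N−2))·(max degree/(N−1) − density); closeness per node as reachable
count divided by summed shortest-path lengths, within components;
information centrality per component via Stephenson–Zelen with
C = (D − A + J)⁻¹ and Iᵢ = 1/(Cᵢᵢ + (tr C − 2·rowsumᵢ C)/N).  Node-level
metrics are reported as mean ± sd.

The signaled positive-edge fraction partitions positive edges by the
**bacterial** endpoint's signaled flag (phytoplankton flags do not enter)
and reports 100·n₊(signaled)/(n₊ total) to two decimals.  In the full
pipeline the signaled flags are themselves a result — the genera the
screening + taxonomy stages detected — not an input.  No multiple-testing
correction is applied to edge p-values, matching the thresholding procedure
the chain implements; this is a known limitation.

## Synthetic data

The generator emulates the targeted study design: a few bioreactor
metagenome samples (default 12) of 150-nt reads, with planted gene content
and planted interkingdom associations.  Everything is a pure function of
(config, seed); identical configurations yield byte-identical files.

* **Taxonomy** — root→superkingdom→…→genus lineages for all configured
  genera (defaults include Pseudomonas, Hydrogenophaga, Zoogloea, Serratia,
  Bradyrhizobium, Thauera, Streptomyces, Chlorella, Scenedesmus, with
  realistic family placements; Zoogloea and Thauera share a family to
  exercise the LCA fallback above genus).
* **References** — per subtype a hidden 300–500 aa template; each carrying
  genus gets a genus-tagged variant at `genus_divergence` (default 0.15,
  a realistic cross-genus homolog distance) from the template, so variants
  of two genera sit ~70–75% identical and the top-percent filter can
  separate them.  The template itself is not emitted: an untagged record
  ~2% from its variants would collapse with them at the 0.97 clustering
  threshold and leave reads mapping to a genus-less representative.  One
  near-duplicate (~1% divergence, same genus) per populated subtype
  exercises the clustering.
* **Reads** — each genus's *community* gene copy is its reference protein
  mutated at `gene_mutation_rate` (default 0.02; the strain-vs-database
  divergence), reverse-translated with uniformly sampled codons.  A fixed
  fraction of each sample's reads (default 0.4) is drawn as windows of these
  genes, allocated across genera proportional to their abundance series
  (largest-remainder rounding), on either strand, with per-base sequencing
  errors at 0.005.  The remainder is uniform-random background, which
  guarantees no accidental homology and makes screening precision exactly
  measurable.  A truth table records every read's source.
* **Abundance series** — log-normal latent-factor model: each anchored
  phytoplankton gets a factor Fₛ ~ N(0,1) per sample; its abundance is
  exp(F + ε) and each paired bacterium's exp(±loading·F + ε) with
  ε ~ N(0, 0.1); unpaired genera are independent log-normal noise.  Spearman
  detection is therefore a genuine statistical event, exercising the p-value
  path.  `planted_fraction_config` builds communities whose true signaled
  positive-edge fraction is a requested value, for recovery experiments.

What the generator does **not** emulate: real genome composition (GC,
codon bias, repeats), coverage and length heterogeneity, chimeras, or
community dynamics beyond monotone latent factors.  Passing tests therefore
demonstrate correctness of the inference chain under its stated model, not
performance on real metagenomes, where divergence structure and database
incompleteness are harsher.

## Numerical and design choices

* Alignment scores are integers; E-value ties are broken by reference id for
  determinism.  A read carries at most one subtype (its best hit's).
* Thresholds: E ≤ 10⁻⁵ inclusive; identity and alignment length strict;
  min-support boundary strict below (support exactly 0.01 is retained).
* Problem sizes in the tests and the acceptance script (6–12 samples,
  40–150 reads per sample, 50 replicates for recovery experiments) are
  chosen so the full suite runs in minutes on one CPU while keeping every
  statistical check comfortably powered.
* Centralization is undefined below 3 nodes and raises; information
  centrality of an isolated node is reported as 0.
* The pipeline's outputs carry a hash of the scientific parameters (not the
  working directory), so reruns are verifiably identical.

## Known limitations

* E-values lack effective-search-space corrections, so absolute values
  differ from heuristic translated-search tools (the ≤10⁻⁵ cutoff is far
  from the decision boundary for genuine hits, so annotations are robust to
  this).
* The t-approximation regime (n > 9) is mildly anti-conservative near the
  p = 0.01 threshold (see above).
* Single-pass min-support promotion; an iterative variant could differ on
  pathological support profiles.
* No multiple-testing correction on network edges, by design.
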