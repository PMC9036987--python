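# phycosignal

Metagenomic inference of quorum-sensing-mediated interactions between algae
and bacteria in engineered water-treatment communities (algal
photo-bioreactors), centred on the auxin indole-3-acetic acid (IAA) that
bacteria exchange with eukaryotic phytoplankton.

The package answers two questions from shotgun metagenomes of such
communities:

1. **Who carries the signaling machinery?**  Reads are screened by
   translated homology against a curated database of the last-step enzymes
   of the three bacterial IAA biosynthesis routes — indoleacetamide
   hydrolase (IAM pathway), indoleacetaldehyde dehydrogenase (IPA pathway),
   indoleacetonitrile nitrilase (IAOx/IAN pathway) — plus the algal cyclin
   that bacterial IAA regulates.  Annotated reads are quantified as RPKM and
   placed on genera by MEGAN-style lowest-common-ancestor (LCA) voting,
   yielding the "signaled" bacterial and algal community.
2. **Does signaling structure the interaction network?**  Genus abundance
   series are correlated across samples (Spearman, bacteria–phytoplankton
   pairs only; edges require |ρ| > 0.6 and p < 0.01), and the positive edges
   are partitioned by the signaled status of their bacterial endpoint.  The
   headline statistic is the **signaled positive-edge fraction**

   100 · n₊(signaled) / (n₊(signaled) + n₊(non-signaled)),

   the share of positive algal–bacterial associations attributable to IAA
   signaling.

## Method outline

* **Reference construction** (`phycosignal.refdb`) — curated protein FASTAs,
  one per gene subtype, made non-redundant by greedy incremental clustering
  at 97% identity (cd-hit convention: identity over the shorter sequence,
  longest-first greedy order).
* **Screening** (`phycosignal.screen`) — exact six-frame translated search:
  Smith–Waterman under BLOSUM62 with affine gaps (open 11, extend 1),
  Karlin–Altschul significance E = K·m·n·e^(−λS) (λ = 0.267, K = 0.041),
  hits kept at E ≤ 10⁻⁵; a read is annotated when its best hit exceeds 50%
  identity over more than 25 aligned amino acids (both strict).
* **Quantification** (`phycosignal.abundance`) — RPKM with coding-nucleotide
  reference length (3 × amino acids) and the sample's total clean reads as
  the per-million denominator.
* **Host taxonomy** (`phycosignal.taxonomy`) — per-read LCA over the top ten
  hits with min score 50, top percent 10.0 and min support 0.01 (fraction of
  the sample's assigned reads); genus-level placements only.
* **Network** (`phycosignal.network`) — thresholded Spearman co-occurrence
  graph with exact permutation p-values for n ≤ 9 samples, Cytoscape
  NetworkAnalyzer metric definitions (density, degree heterogeneity and
  centralization, closeness, Stephenson–Zelen information centrality), and
  the signaled positive-edge fraction.
* **Synthetic data** (`phycosignal.simulate`) — fully self-contained
  generator of taxonomies, reference proteins, reads with planted truth, and
  abundance series with latent-factor associations, so the whole chain is
  testable without downloads.

## Worked example

`examples/04_signaling_network.py` builds a 12-sample community with planted
associations and recovers them:

```text
detected edges (6):
  Bradyrhizobium - Chlorella: rho=-0.965 p=3.9e-07 NEGATIVE
  Hydrogenophaga - Chlorella: rho=+0.986 p=4.1e-09 POSITIVE
  Pseudomonas - Chlorella: rho=+0.965 p=3.9e-07 POSITIVE
  Serratia - Scenedesmus: rho=+0.965 p=3.9e-07 POSITIVE
  Thauera - Scenedesmus: rho=+0.965 p=3.9e-07 POSITIVE
  Zoogloea - Chlorella: rho=+0.979 p=3.1e-08 POSITIVE

signaled positive edges: 4, non-signaled: 1
signaled positive-edge fraction: 80.0%
```

All six planted associations (five positive, one negative) are detected with
the correct signs; four of the five positive correlations involve a
bacterium carrying an IAA-synthetase gene, so signaling accounts for 80% of
the positive algal–bacterial associations in this community.  The other
examples walk through reference construction, read screening with RPKM
output, and LCA taxonomy; `examples/05_full_pipeline.py` (or
`phycosignal run-all --workdir out --seed 1`) runs every stage on one
working directory with provenance-hashed outputs.

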