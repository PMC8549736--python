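# Methods

`bgcbiogeo` re-creates, at desk scale and with known ground truth, the
computational workflow used to map specialized-metabolite biosynthetic
gene clusters (BGCs) across human aerodigestive-tract (ADT)
microbiomes: quantify BGC abundance in shotgun metagenomes by
pseudoalignment, then ask how those abundances — and the underlying
bacterial communities — are structured by body site.

## The synthetic study

Real inputs to this kind of analysis are a genome-derived BGC catalog
(antiSMASH-style), ~10³ shotgun metagenomes, MetaPhlAn-style species
relative-abundance (RA) tables, and sample metadata. The generator
(`bgcbiogeo.synthetic_data`) emulates all four with a single seed.

**Catalog.** Each of `n_genomes` genomes (default 40, one species per
genome, genera drawn from common ADT colonizers) carries a
discrete-uniform number of BGCs (`bgc_per_genome_range`, default 1–6,
matching the observed per-genome range at reduced ceiling); each BGC
has 2–4 ORFs of 300–1,200 nt random sequence, a raw antiSMASH-style
type drawn with weights shaped like the observed category composition
(bacteriocins/RiPPs most common), a protein-domain string drawn from a
per-type vocabulary (so domain-based similarity recovers type
families), and an eHOMD-style habitat label. RiPP-class clusters carry
one short precursor ORF (Met leader ending in Gly-Gly, Cys/Ser/Thr-rich
core, reverse-translated with a trailing stop) so the peptide pipeline
has real substrate. About 8 % of ORFs are flagged nonbiosynthetic to
exercise the pre-index filter.

**Communities.** Species magnitudes are one shared log-normal(0, 1)
backbone multiplied by a per-site tilt drawn uniformly in ±0.8 log2
units and renormalized. The bound is deliberate: it caps natural
between-site species folds at ~3×, below the 4-fold enrichment
threshold, so the *planted* clusters are the only true ≥4-fold signals
and recovery can be scored against an exact truth set. Samples are
Dirichlet draws around the site profile (concentration 300, chosen so
within-site dispersion is clearly smaller than between-site tilt, as
in strongly site-structured body-site data). Each sample's draws come
from an RNG stream keyed by (seed, CRC32(sample id)), so samples are
reproducible independently.

**Planted enrichment.** By default three clusters per site (from
genomes in the upper half of the backbone magnitude, so the signal is
observable at 10⁴ reads/sample) get their read-sampling weight
multiplied by 8 in that site. Weights are global — species RA ×
within-genome length share × fold, renormalized over all ORFs — which
keeps the realized fold near the nominal one; renormalizing within the
genome instead would shrink the realized fold by 1/(1 + 7·share).

**Reads.** Each read is, with probability `background_fraction` (0.10),
a substring of genome-specific random background DNA (exercising the
unassigned path), otherwise a uniformly placed substring of an ORF;
strand is uniform; substitutions are applied per base at
`substitution_error_rate` (0.001). ORFs shorter than the read length
(some precursors) are skipped from sampling with a warning. What the
generator does *not* emulate: realistic error profiles and quality
scores, paired ends, host contamination, strain-level sequence
variation, shared sequence between genomes, and compositional coupling
between habitat label and community membership. Passing tests
therefore demonstrate correctness of the statistical machinery and
identifiability under clean conditions, not robustness to every
property of real ADT data.

## Quantification

A length-31 canonical k-mer index (lexicographic min of k-mer and its
reverse complement) is built over biosynthetic ORFs after replacing
non-ACGT characters with seeded pseudorandom bases. A read's
compatibility class is the intersection of the equivalence classes of
its in-index k-mers; k-mers absent from the index are ignored, which
tolerates isolated substitution errors (mirroring pseudoalignment
practice). Multi-mapping is resolved per sample by multinomial EM over
class counts with per-target probability proportional to the expected
read count (equivalently, abundance × effective length, effective
length L − k + 1); iteration stops when the largest count change is
below 1e-3 (max 200 iterations; desk-scale problems converge in well
under 50). ORF estimates are summed per BGC; clusters undetected in
every sample are dropped; estimates are rounded half away from zero,
one pseudocount is added, and samples are scaled by median-of-ratios
size factors. No fragment-length model is used — unnecessary for
single-end fixed-length reads at this scale.

## Statistics

* **Alpha diversity** — Shannon H′ in nats (vegan convention),
  richness S, equitability E_H = H′/ln S (undefined for S ≤ 1). BGC
  proportions are per-sample aligned-read fractions.
* **Group tests** — Kruskal–Wallis with tie correction; post hoc Dunn z
  tests (midranks, tie-corrected), BH-adjusted jointly across pairs;
  effect size ε² = H/(n−1); compact letter display assembled greedily
  over sites ordered by descending median. Sign test drops ties and is
  exact binomial to n = 1,000, then a continuity-corrected normal.
* **Ordination** — Bray–Curtis on species RA (after zeroing RA < 0.1 %,
  removing species ever at 100 % RA and species in < 25 samples) and on
  BGC proportions of normalized counts (clusters with < 100 total
  normalized reads removed). ANOSIM uses midranked distances,
  R = (r̄_between − r̄_within)/(n(n−1)/4), and a relabeling p with the
  +1 correction (exhaustive enumeration available for small n). NMDS
  minimizes Kruskal stress-1 by Guttman majorization against an
  isotonic regression of configuration distances on dissimilarity
  order; first start is classical scaling, then random restarts
  (relative stress tolerance 1e-7, 300 iterations, early stop after 10
  restarts without improvement), best configuration centered and
  principal-axis rotated. Above 250 samples the pipeline ordinates a
  random subsample of 250 for the reported stress.
* **Clustering** — Ward minimum variance (squared-Euclidean criterion)
  on log10 size-factor-normalized BGC counts; on the species side a
  Hellinger (square-root) transform is used instead, because RA tables
  are zero-heavy and a log transform with a pseudo-RA floor lets
  structural zeros dominate the distances. Trees are cut at K = number
  of distinct sites; cluster purity is the majority-site fraction;
  agreement between the two clusterings is pair-counting Jaccard
  n11/(n11+n10+n01).
* **Enrichment** — one site vs the rest on normalized counts. Effect is
  LFC = log2(μ_focal/μ_rest); the SE comes from the delta method with
  negative-binomial variance μ + αμ², α estimated by pooled
  within-group method of moments, floored at 1e-8. Wald p values are
  BH-adjusted within each site contrast; "enriched" means LFC ≥ 2
  (inclusive, enrichment direction only) and adjusted p < 1e-8.
  Dispersion shrinkage and outlier handling of full GLM machinery are
  deliberately not reproduced; the target is recovery of planted
  signals, and the simple estimator is transparent and testable.
* **ANCOM** — species RA × post-QC total reads, rounded; samples with
  < 10,000 estimated reads, taxa in < 10 samples or with < 1,000 total
  reads removed; zeros replaced by one. W_i counts BH-rejected
  two-sided Wilcoxon rank-sum tests of log(count_i/count_j) between the
  two sites over all j ≠ i. A taxon is differential when W reaches the
  empirical 90th percentile (inclusive) of the W distribution and the
  mean CLR difference exceeds 0.5 in absolute value.
* **Networks** — the BGC distance blends Jaccard of domain sets (0.2),
  Jaccard of adjacent ordered domain pairs (0.05), and a copy-number
  similarity (0.75; one minus the normalized L1 difference), a
  deliberately HMM-free analogue of domain-sequence-similarity
  metrics; families are connected components at distance ≤ 0.3
  (singletons kept). RiPP precursor candidates are ORFs ≤ 450 nt from
  RiPP/bacteriocin-class clusters, translated in frame 1; internal
  stops disqualify. The precursor classifier is a transparent
  rule-based stand-in (length in 20–120 aa, C-terminal Cys/Ser/Thr
  density, Gly-Gly motif; threshold 0.75) with an interface for
  externally computed scores. Leader cleavage is after the last
  Gly-Gly whose end lies in the first two-thirds, else the midpoint.
  Core identity is a global BLOSUM62 alignment (gap open 11, extend 1;
  global mode enforces full-length coverage), 100 × matches/alignment
  length; the edge threshold defaults to 75 with 80 available as the
  stricter display convention — the two conventions coexist in the
  source material, so the choice is surfaced as configuration.

## Problem sizes and defaults

The standard study is 4 sites × 250 samples × 10⁴ reads (100 nt) over
40 genomes (~130 BGCs, ~370 indexed ORFs) — sized so the full pipeline
(index, 10⁷ reads, both ordinations, enrichment, ANCOM, networks) runs
in roughly six minutes on one CPU while leaving every statistic in a
regime where its behavior is measurable (hundreds of samples per group,
tens of counts per cluster per sample). ANOSIM uses 999 permutations by
default in the pipeline (p resolution 0.001; R itself is
permutation-free); 10,000 remains the method default for small inputs.

## Degenerate inputs and tie-breaks

All-zero profiles, empty groups, constant vectors for τ_B, all-tied
sign tests, single-sample size factors (fixed at 1 with a warning),
K > n cluster cuts, and annotation id mismatches raise immediately with
named offenders. Rounding of estimated counts is half away from zero;
category percents round half-up to one decimal (matching printed
tabulations). Distance ranks use midranks throughout. NMDS stress can
legitimately approach zero on strongly clustered data (the classic
nonmetric degeneracy); stress is reported, not interpreted.

## Known limitations

Pseudoalignment here is not bit-compatible with kallisto (no de Bruijn
graph contigs, no bootstrap); the NB Wald test is not DESeq2 (no
shrinkage, no Cook's filtering); the BGC distance is not BiG-SCAPE
(no profile-HMM domain alignment, no affinity-propagation family
refinement); the precursor classifier is a rule table, not a learned
model. Each stands behind the same interface as the tool it emulates,
and each simplification is visible in exactly one module.
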