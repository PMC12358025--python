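# Methods

`melodiv` reimplements, as a reusable and testable pipeline, the classical
marker-based analysis applied to melon (*Cucumis melo*) germplasm surveys:
band-sharing similarity over a mixed dominant/codominant marker panel,
diversity statistics, UPGMA clustering and principal coordinate analysis,
Bayesian admixture clustering with ΔK model selection, chloroplast
(cytoplasm) typing from CAPS haplotypes, and seed/trait classification.
This note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Genotype coding

Dominant markers (RAPD bands) are scored present/absent and stored as the
pseudo-homozygotes `1/1` / `0/0`; heterozygotes are not representable and a
`0/1` token is rejected at load time.  Codominant markers (SSRs) carry
allele *size ranks* (1 = smallest fragment) as unordered pairs, stored
sorted, so `3/7` and `7/3` denote the same genotype.  All downstream
statistics consume this coding directly — in particular, no Hardy–Weinberg
back-estimation of dominant allele frequencies is attempted, because the
analyses this package mirrors operated on the raw band codes.

## Band-sharing similarity and distance

For accessions *i*, *j*:

    GS(i, j) = (N11 + N00) / n,   GD = 1 − GS

where `N11` accumulates positive shared-band scores, `N00` counts shared
dominant-band absences, and `n` is the number of mutually non-missing
markers (the full panel size under complete data).  A codominant marker
contributes the set-overlap score |A∩B| / max(|A|, |B|) over distinct-allele
sets: identical genotypes score 1, a homozygote against an overlapping
heterozygote (2/2 vs 2/3) scores 0.5, disjoint genotypes score 0.  This
generalization reproduces the conventional worked half-share case and fixes
the cases that convention leaves unstated (2/3 vs 2/4 → 0.5; 2/3 vs 4/5 →
0).  Under missing data the denominator is pairwise-deleted; cells marked
missing are likewise excluded from allele counts.

## Diversity statistics

* **PIC** — codominant markers use the Botstein form
  `1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`; dominant markers use the two-state form
  `2p(1−p)`, whose maximum 0.5 matches the upper bound reported for RAPD
  panels.  The two-state form is used because a dominant marker's PIC
  cannot exceed that of a biallelic locus scored by phenotype.
* **Gene diversity D** — per-locus `h = 1 − Σp_i²`, averaged over loci with
  data.  The uncorrected (biased) estimator is the default; the
  small-sample factor `2n/(2n−1)` is available behind `unbiased=True` but
  off by default since the surveys this mirrors report the plain form.
* **Nei's (1972) standard distance** between groups:
  `D = −ln(Jxy/√(JxJy))` with J's averaged over shared loci; identical
  profiles give 0 and fully disjoint allele sets give +∞ (returned as
  `inf`).
* **Seed-class geography** — Pearson's χ² of independence without
  continuity correction, as is standard for r×c tables of this size.

## UPGMA and ordination

UPGMA joins the closest pair of clusters, places the node at half the merge
distance, and updates distances by the size-weighted arithmetic average.
When several pairs tie at the minimum distance the pair whose
lexicographically smallest member labels sort first is merged, making the
tree a deterministic function of the matrix regardless of input order.
Trees serialize to Newick with branch lengths `parent height − child
height`.  Tree cutting for k groups undoes the last merges until exactly k
components remain (the lowest-height cut with that component count).

PCoA applies Gower double-centering to `−D²/2` and eigendecomposes.
Because band-sharing distances are not guaranteed Euclidean, negative
eigenvalues can occur: they are reported in `eigenvalues` but their axes
are dropped, and variance explained is normalized by the sum of *positive*
eigenvalues only.  Two axes are reported by default.  The 16-trait
morphology table is standardized column-wise ((x−mean)/sd, n−1 sd — without
this, fruit weight would dominate every distance), clustered by Euclidean
distance + UPGMA so the morphological and marker dendrograms share a
linkage, and summarized by PCA.  The Euclidean+UPGMA choice for morphology
is a documented assumption; the source analyses state only the
standardization.

## Admixture model

Each accession carries a membership vector Q_i on the K-simplex; each
cluster k has allele frequencies P_k per locus; every gene copy picks a
cluster from Q_i, then an allele from P_k.  Two priors on P are available:

* `independent`: P_k,l ~ Dirichlet(λ = 1);
* `correlated` (default): the F-model, P_k,l ~ Dirichlet(p_A,l(1−F_k)/F_k)
  around ancestral frequencies p_A,l, with per-cluster drift F_k.

Dominant markers enter the likelihood exactly as coded — two identical gene
copies — rather than through a dominance model; this mirrors the data entry
convention the package reimplements and slightly overweights those loci.

**Sampler.** One sweep comprises:

1. collapsed (Pólya-urn) resampling of every copy's cluster of origin —
   Q is integrated out, so copy *c* of accession *i* is drawn with
   probability ∝ (α + m_ik)·P_k,l,j given all other copies' counts m.
   The collapsed update is used because conditioning on a sampled Q mixes
   impractically slowly toward the near-vertex states that nearly pure
   accessions occupy;
2. conjugate Dirichlet update of P from the origin counts (plus the
   F-model prior where active);
3. Metropolis updates of each F_k (uniform prior on (0, 0.5), reflected
   normal proposal with sd 0.05) and of each p_A,l (Dirichlet proposal
   centred on the current value, concentration 50, with the proposal-ratio
   correction);
4. a reporting draw Q_i ~ Dirichlet(α + m_i);
5. Metropolis update of the single symmetric α on the log scale (uniform
   prior on (0, 10], log-normal random walk with sd 0.3 and Jacobian
   correction).  Inferring α matters: with α fixed at 1 the Q posterior for
   nearly pure material is pulled visibly toward 1/K and membership
   recovery degrades by a factor of ~2–4.  `infer_alpha=False` restores
   the fixed-α variant.

Chains warm-start from a k-means partition of one-hot allele dosages
(Q = 0.8 on the own cluster, origin indicators set to the cluster labels,
p_A at the pooled observed frequencies, and P drawn from its full
conditional given those labels): the posterior over labellings is sharply
multimodal, and short chains started flat spend their whole budget
climbing toward a mode — worse, replicate runs reach modes of different
quality, inflating the run-to-run lnP(D) spread that the ΔK denominator
divides by.  A flat start is available via `init="random"`.  Posterior
means of Q and P over the collected sweeps are reported.

**lnP(D) and ΔK.**  Per run, lnP(D) is estimated as
`mean(lnL) − var(lnL)/2` over collected sweeps (the harmonic-mean
estimator is avoided as notoriously unstable).  Across replicate runs per
K,

    ΔK(K) = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd L(K)

with the sample (n−1) standard deviation; ΔK is undefined at the endpoint
K values and flagged +∞ when the spread is zero.  Runs at one K are
aligned by choosing, run by run in decreasing lnP(D) order, the column
permutation minimizing the summed squared difference to the incrementally
built mean.  Because that objective decomposes per column, the Hungarian
assignment gives the exact optimum at any K (verified against exhaustive
K! search in the tests).  Accessions with consensus membership strictly
above 0.6 are assigned to that population; otherwise the two largest
components name an admixed class ("Pop1/2"), listed in descending
membership order.

**Defaults** mirror the standard survey protocol: K = 1–10, 20 runs per K,
5000 burn-in + 5000 collected sweeps, threshold 0.6.  The recovery studies
in the test suite run at a reduced scale — 100 accessions × 120 loci with
500/500 sweeps and 5 runs per K — chosen as the smallest design at which
membership recovery and ΔK selection are stable.

## Cytoplasm typing

A CAPS key maps each marker's observed fragment pattern to a haplotype
letter and each complete letter tuple to one of the maternal lineages Ia,
Ib, Ic, III.  Typing is a pure lookup: unknown patterns are hard errors (a
key/assay mismatch), while missing calls or tuples absent from the key
leave an accession `unclassified` with a recorded reason.  The concrete
key is assay-specific and therefore user-supplied configuration; the
packaged generator emits a synthetic three-marker key of the same shape.
Heteroplasmy is not modelled.  The geography × seed-class × type crosstab
conserves counts: every typed accession appears in exactly one cell or in
the excluded list.

## Synthetic data generator

The generator provides ground truth for every stage without any download.
It draws ancestral allele frequencies from a flat Dirichlet (dominant band
probabilities from Beta(1,1)), population frequencies from the F-model at
drift F, memberships either pure or Dirichlet(α), genotypes by Q-mixture
draws (one band draw per accession for dominant loci, recorded as 1/1 or
0/0; two independent allele draws for codominant loci), cytoplasm types
deterministically from the majority-ancestry population (an optional
mixing-rate knob reassigns a fraction at random, default 0), seed lengths
as a two-class Gaussian mixture straddling the 9.0 mm cut, and fruit
weight from the standardized seed length so the two reach a target
correlation.  Remaining traits are Gaussian around class-specific means;
flower type is an ordinal draw from {0, 1, 2}.

Defaults encode the emulated study conditions: two populations of 50
accessions, 100 dominant + 20 codominant loci, drift F = 0.05, 7–17
alleles per SSR (the allele-count range of the emulated panel), pure
ancestry, seed-length means 11.0/6.0 mm (sd 1.0) and a seed-length/fruit-
weight correlation of 0.823.  Everything is reproducible byte-for-byte
from one master seed, expanded per stage through `SeedSequence`.

What the generator does **not** emulate — and hence what passing tests do
not establish about real surveys: linkage between nuclear loci, genotyping
error and missingness patterns, marker ascertainment (real panels are
selected for polymorphism), independent maternal introgression
(cytoplasm follows nuclear ancestry exactly by default), and realistic
trait covariance beyond the seed-length/fruit-weight pair.

## Numerical choices and degenerate inputs

Dirichlet draws use gamma variates with a 1e-12 floor to avoid zero rows at
extreme concentrations.  PCoA's positive-eigenvalue threshold is relative
(1e-9 of the largest magnitude).  PHYLIP output truncates names to 10
characters and fails loudly on collisions; values round-trip to 1e-6.
Standardization refuses zero-variance traits by name.  χ² refuses tables
with a zero margin; `delta_k` refuses non-consecutive K or fewer than two
runs per K; membership thresholds outside (0.5, 1] are rejected, as two
populations could otherwise both exceed the threshold.

## Known limitations

* The sampler fixes one symmetric α rather than per-population α's, omits
  the linkage model and prior population information, and does not model
  dominance for RAPD loci.
* lnP(D) is an approximation; ΔK inherits its run-to-run noise and is
  undefined at the K range endpoints by construction.
* Band-sharing GD is not guaranteed Euclidean; PCoA axes after the first
  few can be distorted when negative eigenvalues are large.
* The morphological chain assumes Euclidean distance on standardized
  traits; ordinal traits (flower type, colour scores) are treated as
  quantitative.
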