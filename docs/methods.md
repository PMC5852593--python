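# Methods

This note records the models behind `tfssr`, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical conventions that make results reproducible.

## SSR detection

A microsatellite is a maximal perfect tandem tract of a primitive 2–6 bp
motif (a motif that is not itself a repetition of a shorter unit). The
scanner finds, for each unit size *k*, maximal runs of positions where
`s[t] == s[t+k]`, reports the leftmost alignment of full repeats, and never
counts partial trailing repeats or lets a tract span an N. Conventions:

- **Threshold.** A single total-tract-length rule (≥ 12 nt for every unit
  size) is the default; it coincides with the lower bound of the Class II
  length category. MISA-style per-unit minimum repeat counts (2×6, 3×5,
  4×4, 5×4, 6×4) are available as `min_repeats_by_unit` overrides.
- **Length classes.** Class I is ≥ 20 nt; Class II is 12–19 nt. The
  boundary tract of exactly 20 nt is Class I (the two conventional ranges
  overlap at 20; "≥ 20" is taken as authoritative).
- **Overlap resolution.** A region qualifying at two unit sizes is reported
  once at the smallest unit; remaining overlaps resolve to the leftmost
  start. Compound or interrupted repeats are not merged — each maximal
  perfect tract is its own locus. Mononucleotide runs are excluded by
  default.
- **Motif tallies** default to `as_is` (CCG and CGC counted separately);
  `rotation` and `rotation_revcomp` canonicalisations are provided for the
  standard 10-class trinucleotide grouping.
- The panel summary reports category percentages out of total loci to two
  decimals, and the screening-universe rate (SSR-containing sequences /
  sequences searched) when those totals are supplied.

## TF-candidate filtering

Homology hits (12-column tabular format) are filtered with inclusive
comparisons: E-value ≤ 10⁻¹⁰, query coverage ≥ 65 %, identity ≥ 40 %.
Coverage is `100·(q_end − q_start + 1)/query_length`, so the reader
requires a per-query length map computed from the query FASTA (the tabular
format does not carry query length). Each query takes the family of its
best passing hit, ranked by (E-value, −bit score, subject id) — a total
order, so assignment is invariant to input row order. The family vocabulary
is an input mapping, not a hard-coded list, because database versions
drift.

## Primer design

A native enumerator stands in for Primer3 at defaults: every candidate
window in either flank is screened against hard constraints
(length 18/20/27 min/opt/max, Tm 57/60/63 °C, GC 20–80 %, 3′-terminal
self-complementary run ≤ 3, product 100–300 bp, product spans the whole
tract, primers never overlap it), and surviving pairs are ranked by
`|Tm − Tm_opt| + |len − len_opt|` summed over the pair (weights 1 °C⁻¹ and
1 bp⁻¹), ties broken by forward then reverse start. Exact Primer3 output
parity is a non-goal; the testable contracts are tract containment and
constraint satisfaction, audited post hoc on every returned pair.

Melting temperatures use the unified nearest-neighbour ΔH/ΔS parameters
with the 0.368·N·ln[Na⁺] entropy correction at 50 mM monovalent salt and
50 nM total strand concentration (`Tm = 1000ΔH/(ΔS + R ln(C_T/4)) −
273.15`); the 2(A+T) + 4(G+C) rule is available as `wallace`. The default
product range 100–300 bp matches scoring on agarose gels against a 100 bp
ladder.

## Population-genetics battery

All statistics operate on diploid fragment-size calls with two missing-data
policies: per-locus deletion for frequency-based statistics, pairwise
deletion for distances; never imputation.

- **He** uses the plain (biased) 1 − Σp²; the 2n/(2n−1) correction is a
  flag (`unbiased=True`), matching common reporting defaults.
- **PIC** defaults to the PowerMarker/Botstein form
  1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²; the expected homozygosity Σpᵢ² is retained
  under the explicit name `homozygosity_sum` because some reports print
  that formula under the PIC label. PIC ≤ He always (property-tested over
  random simplex draws).
- **F_ST**: both Weir–Cockerham θ (1984 a/b/c variance components, summed
  over alleles and loci, loci skipped unless scored in every population)
  and Nei G_ST ((H_T − H_S)/H_T per locus averaged, H_T from unweighted
  mean frequencies, H_T = 0 loci skipped). θ is the default because it is
  the field's standard for unequal sample sizes; results are labelled with
  the estimator name.
- **AMOVA** is the two-level squared-distance partition on individual
  pairwise distances: SS_total = Σ_{i<j} d²/N decomposed into among/within
  strata, variance components via expected mean squares with the
  unequal-size coefficient n₀, σ²_among clamped at 0 (and flagged),
  Φ_PT = σ²_among/σ²_total. Populations of size 1 are excluded with a
  warning.
- **Distances**: the default individual metric is allele-sharing,
  d = 1 − (shared alleles)/2 averaged over co-scored loci — standard for
  codominant SSRs and a single matrix feeds both NJ and PCoA. A
  fragment-size-aware variant (1 − 2^−|Δ| under the minimal allele pairing)
  and Nei's 1972 population distance are also provided.
- **Neighbour joining** is the Saitou–Nei algorithm with deterministic
  tie-breaking (smallest index pair in node-creation order); negative
  branch lengths are clamped to zero with the deficit moved to the sibling
  edge; output is unrooted, serialised with a trifurcating root. NJ is
  exact on additive matrices, which the tests exploit.
- **PCoA**: Gower double-centering of −d²/2, symmetric eigendecomposition,
  axes by descending eigenvalue; percent variance divides by the sum of
  positive eigenvalues only, and negative eigenvalues are reported but
  yield no axis.

### Bayesian clustering and ΔK

The clustering model is the no-admixture, uncorrelated-allele-frequencies
finite mixture: each individual belongs to one of K clusters; cluster
allele frequencies have Dirichlet(1) priors. This is a deliberate
simplification of the admixture/correlated-frequencies model used by the
standard software — it keeps desk-scale runtimes while preserving the same
model-selection surface (ln P(D) per K, ΔK). The Gibbs sampler alternates
Dirichlet(1 + counts) draws of frequencies and mixture weights with
multinomial re-sampling of assignments; memberships are posterior means of
the per-sweep assignment probabilities (Rao–Blackwellised), and
ln P(D) ≈ mean(L) − var(L)/2 over post-burn-in mixture log-likelihood
samples.

Single-site Gibbs mixes poorly from a uniform random start when
differentiation is strong: chains can lock into merged/split partitions
whose likelihood is tens of log-units below the main mode, which corrupts
the ln P(D) curve and hence ΔK. Chains therefore initialise from a k-means
partition (8 restarts, best within-cluster sum of squares) of the leading
five principal coordinates of the allele-sharing distance; the restart
draws come from the chain's own generator, so independent seeds still
explore modes, and degenerate distance matrices fall back to a uniform
random start. All stochastic operations take explicit seeds (default
20180214).

ΔK(K) is the mean over runs of the per-run absolute second difference
|L(K+1) − 2L(K) + L(K−1)| divided by the across-run standard deviation of
L(K); it is undefined at the boundary K values, and a zero standard
deviation is reported as infinite with a warning.

## Expression tagging

Log₂ fold changes are computed against a baseline time point with a
pseudocount (default 1) to damp low-expression noise. UP/DOWN calls use
inclusive thresholds at ±1 log₂ units by default — the conventional
two-fold rule, configurable because no single cut-off is canonical.
Venn-style partitions count genes UP (or DOWN) in exactly each non-empty
subset of time points; the all-time-points cell is the intersection.
Hierarchical clustering runs on log₂(FPKM + 1) rows with
Pearson dissimilarity (1 − r) and average linkage by default,
approximating the uncentred-correlation/average-linkage defaults of the
classic clustering tool; zero-variance rows take the maximal dissimilarity
of 2. Merging is deterministic (smallest original index breaks ties), and
the heat-map export is a plain TSV in dendrogram leaf order — rendering is
left to the caller.

## Synthetic data

The generators are pure functions of seed and spec, and their truth tables
score every downstream module:

- **Transcriptomes** plant perfect tracts at known coordinates separated by
  ≥ 30 nt and rejection-sample the background until a scan finds exactly
  the planted set — no accidental SSRs, no junction extensions — so
  recovery tests are exact by construction.
- **Genotype panels** use the Balding–Nichols model: per locus, ancestral
  frequencies are Dirichlet(1) draws and population frequencies are
  Dirichlet(p·(1−F)/F) draws, giving E[F_ST] = F in closed form; genotypes
  are Hardy–Weinberg within populations. Defaults (3 populations ×
  50 diploids, 50 loci, 4 alleles, F = 0.30) are the study conditions used
  throughout the recovery tests. Optional uniform missingness is available.
- **FPKM matrices** give designated genes a log₂ fold change of ±2 (plus
  Gaussian noise on the log scale, default sd 0.1) at every non-baseline
  time point, constructed so the pseudocounted fold change is exactly
  effect + noise; baselines are uniform on [8, 64].

What these generators do **not** emulate: linkage between loci, stepwise
mutation of fragment sizes, null alleles and scoring artefacts, admixed
individuals, overdispersed or replicate-aware expression counts, and
homology search realism (hit tables are drawn around the thresholds, not
produced by alignment). Passing tests therefore demonstrate algorithmic
correctness and estimator calibration under the stated models, not
robustness to those real-data complications.

## Problem sizes and runtimes

The recovery experiments are sized for a laptop-class single core: F_ST
calibration uses 20 replicate panels at the default conditions (≈ 4 s);
ΔK recovery sweeps K = 1..5 with 3 runs × (80 burn-in + 120 kept sweeps)
on 45-individual, 50-locus panels, repeated over 5 panel seeds (≈ 25 s);
the detector-oracle comparison scans 200 repeat-enriched sequences up to
5 kb. The ΔK property is honestly stochastic: per-panel success is roughly
80 %, so the tests assert the documented ≥ 4-of-5 criterion rather than
universal success.

## Known limitations

- The clustering sampler is not the admixture model; membership
  coefficients are cluster posteriors, not admixture proportions, and
  ln P(D) values are not comparable to the standard software's numbers.
- AMOVA is two-level (among/within populations); the within-individual
  stratum of the three-level codominant design is not separated.
- Primer penalties are a simplified scalarisation; no thermodynamic duplex
  or hairpin scan beyond the 3′ self-complementarity run.
- NJ trees carry no bootstrap support values.
- Imperfect/compound SSRs are reported as separate perfect tracts.
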