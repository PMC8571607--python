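# Methods

This note records the models, estimators and design choices behind the
package, what the simulator does and does not emulate, and the numerical
conventions a user should know before trusting a number.

## Strain typing

Alleles follow the MLST convention: identity is **exact full-length string
match** — two sequences share an allele number iff they are identical, and a
novel clean sequence receives the next free number in its locus. No
similarity threshold is involved, so inputs must already be trimmed to locus
coordinates (trimming is out of scope). Any IUPAC ambiguity code or gap
anywhere in a locus marks that locus *missing* rather than guessing a base.
A sequence type (ST) is the five-allele tuple in scheme order
(gatB, coxA, hcpA, ftsZ, fbpA; lengths 369/402/444/435/429, concatenating to
2079 sites with coxA spanning positions 370–771, 1-based inclusive).
Profiles with a missing locus get manual-style labels `ST-N1`, `ST-N2`, ... in
sample-id order; novel complete tuples are numbered above the largest
reference ST id, ordered by first occurrence in canonical sample-id sort.
Partial allele labels of the form `near X` (a sequence close to, but not
confirmed as, allele X) are kept verbatim and count as distinct labels in
diversity summaries — collapsing them onto X would understate allele
diversity.

Supergroup assignment is distance-based: the query is assigned the label of
the reference group with the smallest **mean** corrected distance, at either
the concatenated or single-locus level. The margin (second-best minus best
group mean) must reach 0.005 substitutions/site, else the call is
`ambiguous`. The margin threshold is deliberately small: supergroups are deep
clades separated by an order of magnitude more than that, and the threshold
only guards against noise-level coin flips.

Percentages (screening incidence) are rounded **half-up to two decimals**
(47/390 → 12.05).

## Distances

p-distance uses **pairwise deletion**: per pair, sites where either sequence
is a gap or ambiguity are dropped; p = mismatches / remaining sites. The
one-parameter equal-rates correction d = −(3/4) ln(1 − 4p/3) is applied **per
pair, then averaged** — not applied to the averaged p. The alternative order
is numerically close at the divergences seen here (&lt;10%) but per-pair
correction is the standard estimator. The correction diverges at p = 3/4;
saturated pairs are flagged invalid and excluded from means with a warning
rather than capped. Corrected distances may violate the triangle inequality;
nothing downstream assumes it. The neighbor-joining utility (for quick
reports; no likelihood or Bayesian inference is attempted) is scikit-bio's.

## The similarity test

The test asks whether community strains are more similar among themselves
than a random, equally sized collection from a reference database. With m
community strain pairs, each of B = 10,000 iterations draws m pairwise
distances from the database's full pairwise pool **uniformly without
replacement within the iteration** and records the mean; the primary
inference is the empirical tail probability with the add-one rule,
p_lower = (1 + #{null means ≤ community mean}) / (1 + B), which can never be
exactly zero. Database strains whose sequence exactly matches a community
strain are removed from the pool first (the community must not be compared
against itself). A Wilcoxon rank-sum statistic comparing the m community
distances against the B null means — average ranks for ties, tie-corrected
variance, 0.5 continuity correction, two-sided normal p — is reported
alongside, since both framings are in circulation; the empirical tail is the
one to act on. Distance-level resampling (rather than strain-level) is the
primary reading of "randomly selected pairwise distances"; strain-level
resampling can be composed by the caller from `DistancePool.from_matrix` on
strain subsets.

Calibration caveat: the community's m pairwise distances are computed among
the *same* few strains and are therefore dependent, while each resampled set
of m distances is drawn freely from the whole pool. Under the exchangeable
null (community = random database subset) p_lower is consequently only
*approximately* uniform — slightly over-dispersed — and the package's tests
assert exactly that (Kolmogorov–Smirnov distance below 0.2 across 200 seeded
replicates, ≥95% indistinct verdicts at α = 0.05) rather than exact
uniformity, which no distance-level resampling scheme can deliver.

## Cophylogeny statistics

All three tests take two labelled distance matrices (host marker, symbiont)
plus a binary host×symbiont link matrix — one-to-one in this package's study
design (single infections only).

- **Mantel**: correlation of the strict upper triangles, Spearman by default
  (average ranks for ties), Pearson by flag; the permutation null relabels
  rows and columns of one matrix jointly; the default tail is one-sided upper
  (the directional hypothesis is positive association), two-sided by flag.
- **ParaFit**: hosts and symbionts are embedded by principal coordinates;
  the global statistic is the sum of squares of Bᵀ·HP·C. The permutation
  null shuffles each symbiont's host links (within each HP column). Per-link
  statistics: link1 = drop in the global statistic when the link is removed;
  link2 = link1 / (tracemax − global), tracemax being the larger of the two
  embeddings' summed squared eigenvalues. The implementation is verified
  against R's ape::parafit on a fixed instance (global and per-link values
  agree to printed precision).
- **Procrustes (PACo-style) m²ₓᵧ**: both embeddings are expanded to one row
  per link; the symbiont configuration is centred, rotated and scaled onto
  the host configuration by least squares (host-dependent orientation, not
  the symmetric variant); m²ₓᵧ is the residual sum of squares, verified
  against R's vegan::procrustes. Small residuals mean congruence, so the
  permutation p counts permuted residuals ≤ the observed one.

Principal coordinates use eigendecomposition of the Gower-centred matrix;
when the smallest eigenvalue is below −10⁻⁸ the Cailliez constant (largest
real eigenvalue of the standard 2n×2n companion problem) is added to all
off-diagonal distances first; axes with eigenvalues ≤ 10⁻⁸ are discarded.

The three statistics answer different questions and can disagree on real
data; the package reports all three and does not reconcile them.

A numerical fact worth knowing: on an **ultrametric** codivergent pair of
trees, every set of tip pairs sharing a most recent common ancestor has
exactly tied true distances. Rank-based (Spearman) Mantel correlation then
has a structural ceiling well below 1 — within-tie ranks are pure measurement
noise — with E[ρ] around 0.85 for balanced root splits regardless of sequence
length. The codivergence-recovery validation therefore uses the Pearson
variant (the estimated distances are on a common scale, so linear correlation
is the right recovery measure); Spearman remains the default for real-data
analysis where scales may differ.

## Recombination screens

- **Φ (pairwise homoplasy index)**: parsimony-informative sites (≥2 states
  each carried by ≥2 sequences, non-ACGT symbols ignored) are scored pairwise
  by the refined incompatibility score — the cycle count e − v + c of the
  bipartite graph of observed joint states, zero iff the two sites fit one
  tree without homoplasy. Φ is the mean score over informative-site pairs at
  most 100 apart **in informative-site order** (window size is the method's
  customary default; nothing in this package depends on it strongly). The
  null permutes informative-site order; recombination makes *nearby* sites
  more compatible than the permuted average, so p counts permuted means ≤
  observed (add-one). Fewer than two informative sites yields a flagged
  not-testable result, not an exception.
- **MaxChi-style scan**: per sequence pair, over the alignment's variable
  sites, a window of 100 sites either side of each candidate point is scored
  by the 2×2 chi-square of match/mismatch counts left vs right; the maximum
  over positions is compared against a permutation null built by shuffling
  site order and recomputing the maximum. Using the null of the maximum
  controls the family-wise error across candidate positions exactly, which
  is why no additional Bonferroni step appears. Pairs significant at
  α = 0.01 yield one event; the breakpoint is reported between the two
  adjacent variable sites flanking the best cut, in 1-based alignment
  coordinates, mapped to loci via the concatenation map. Alignments shorter
  than two half-windows shrink the window with a warning. On simulated
  chimeras between parents ≥5% divergent the scan recovers ≥80% of
  breakpoints to within one half-window, with events on recombination-free
  alignments in ≤5% of runs (both rates are exercised in the test suite and
  recomputed by `scripts/acceptance.py`).
- **Supergroup-conflict screen**: a strain is flagged when its concatenated-
  level supergroup assignment and some per-locus assignment disagree *and*
  both margins clear the threshold — ambiguous calls never create conflicts.
- **Shared-ST screen**: STs carried by ≥2 hosts whose taxonomies demonstrably
  differ at or above a chosen rank (class &gt; order &gt; family &gt; genus);
  unknown taxonomy fields are treated as incomparable rather than different.

Events supported by at least two of {Φ, MaxChi, conflict screen} can be
treated as confirmed; with only two sequence-level detectors implemented,
this is deliberately weaker than a three-of-seven rule over a larger program
suite, and is documented as such.

## Richness estimators

Classic (not bias-corrected) Chao1 — S + F₁²/(2F₂), falling back to
S + F₁(F₁−1)/2 when F₂ = 0 — with the bias-corrected variant left to the
caller; Chao2 analogously on incidence uniques/duplicates. ACE/ICE use the
conventional rare/infrequent cutoff of 10 and fall back to Chao1/Chao2 with a
warning when estimated coverage is zero. Jackknife orders 1 and 2; note the
second-order jackknife can legitimately fall below S_obs when duplicates
outnumber uniques, so "estimator ≥ S_obs" is only asserted for Chao2, ICE and
Jack1. Rarefaction is the analytic sample-based expectation
E[S_t] = S_obs − Σ_k C(m − m_k, t)/C(m, t), computed with log-gamma for
stability. Variance/SD estimators are out of scope; point estimates only.

## The community simulator

The generator emulates the study design the analyses target: an ultrametric
Yule host tree (pure birth, depth rescaled to 1); a host marker evolving on
it; a background "database" pool of symbiont strains structured into deep
labelled clades (supergroups A/B/F by default); one symbiont strain per host
(single infections, mirroring the exclusion of multiply infected hosts from
typing). Each host inherits the strain evolved along its own host-tree
lineage from an ancestral pool strain; then, independently per host, with
probability `h_within` the strain is replaced by the strain currently carried
by another community host, else with probability `g_global` by a random pool
strain. With probability `rho` an acquisition recombines: one contiguous
segment of one locus (uniform locus, uniform 1-based endpoints) is copied in
from the displaced resident strain. Every decision lands in `transfer_log` /
`recomb_log`, which tests use as ground truth.

Sequence evolution is the exact one-parameter equal-rates process per branch
(a site changes with probability (3/4)(1 − e^(−4bt/3)) and takes one of the
other three bases uniformly); no indels, no rate heterogeneity, no selection,
no loss/reinfection dynamics, no coalescent within hosts. Defaults: 25 hosts;
locus lengths 369/402/444/435/429; host marker 600 sites at rate 0.25
substitutions/site per unit depth (mitochondrial markers are several-fold
faster than bacterial housekeeping genes, and the marker's resolution is
what limits host-tree recovery); symbiont rate 0.05 (community strains then
average ~5–10% pairwise divergence, the scale such surveys report); pool of
60 strains in 3 clades, clade ancestors separated by twice the within-clade
depth. All randomness derives from one master seed; each stage (host tree,
marker, pool, vertical descent, transfer, recombination) draws from an
independent stream keyed by a fixed label, so stages are individually
reproducible and byte-identical under a repeated config.

What passing simulator-based tests shows — and does not. The simulations
demonstrate that each statistic recovers the signal it was designed for under
the generative model stated above (codivergence → high Mantel/ParaFit signal;
within-community transfer → depressed community divergence; planted chimeras
→ localized breakpoints). Real data add alignment error, rate heterogeneity,
multiple infections, indels and database ascertainment bias, none of which
the generator produces; rates measured here are upper bounds on real-data
performance.

One property is knowingly *not* asserted: that under pure global acquisition
(g_global = 0.6) the similarity test rejects at its nominal rate. Hosts that
retain vertically inherited strains all descend from one ancestral infection
and genuinely are more similar than random database draws, so the lower tail
fires above nominal (~20% at α = 0.05 in our conditions). That is the biology
the test is designed to detect, not an artefact; the suite asserts instead
that the global-acquisition scenario rejects strictly less often than the
within-community scenario, and that the exchangeable null (community = random
database subset) is calibrated.

## Problem sizes

Validation runs use 50 replicates for power/recovery rates in the test suite
(30 in the acceptance script), B = 400–1,000 resampling iterations in
replicated calibration runs versus 10,000 in single analyses, and permutation
counts of 99–499 inside replicated loops versus 999–9,999 defaults for
single analyses. These sizes give rate estimates with standard errors of a
few percentage points, comfortably inside the asserted margins.

## Known limitations

- Allele identity requires pre-trimmed, aligned, equal-length locus
  sequences; there is no trimming, alignment or chromatogram handling.
- The MaxChi scan reports pairwise breakpoints; it does not reconstruct
  donor/recipient roles or build recombination networks.
- The similarity test's database is user-supplied; results inherit whatever
  ascertainment bias the database carries.
- Richness SD/CI estimation and coverage-based extrapolation are not
  implemented.
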