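# Methods

`mycoverlap` quantifies how mycoheterotrophic (MH) plants — plants that take
carbon *from* their arbuscular-mycorrhizal fungi rather than supplying it —
partition and share their fungal hosts. The analysis has three layers: the
phylogenetic diversity of each plant's host set, pairwise and group host
overlap, and the joint behaviour of diversity and overlap across all
possible plant groups of a given size.

## Phylogenetic diversity and its exact scaling

The diversity of a host set `S` (a set of fungal OTU leaves on the fungal
phylogeny) is Faith's PD: the total branch length of the minimal subtree
spanning `S`. Two conventions exist; this package **excludes the stem edge
above the set's most recent common ancestor** and defines singleton PD = 0.
Under this convention the PD of the full leaf set equals the tree length
minus the root stem, and PD is exactly the unrooted (minimal spanning
subtree) form, which is what makes the extremal algorithms below exact.

Because PD grows mechanically with the number of hosts `k = |S|`, observed
values are min–max scaled within their own size class:

    PD' = (PD − PDmin(k)) / (PDmax(k) − PDmin(k)),

where PDmin(k)/PDmax(k) range over **all** k-subsets of the fungal pool.
Enumerating C(138, 42) subsets is impossible, but the extremes are
computable exactly:

* **PDmax(k)** — greedy leaf addition starting from the most distant leaf
  pair. For unrooted PD the greedy solutions are provably optimal and
  nested over k (Steel 2005; Pardi & Goldman 2005), so one greedy chain
  yields PDmax for every size at once. Ties break toward the
  lexicographically smallest label, making results deterministic.
* **PDmin(k)** — a knapsack-style dynamic programme over the tree:
  `f[v][j]` is the minimal branch length needed to connect `j` leaves of
  clade `v` to node `v`; children tables combine by min-plus convolution
  and the answer is `min_v f[v][k]` (taking the minimum over all candidate
  ancestors automatically discounts the MRCA stem). Complexity
  O(n_nodes · k²); a backtracking pass recovers an attaining subset.

Both algorithms are verified against exhaustive enumeration on hundreds of
random 8–12-leaf trees, for every feasible k, in the test suite. A
Monte-Carlo sampler (`sample_pd_range`) provides an independent bound
check; it is never used for the reported statistics. PD'=1 therefore means
"the most phylogenetically dispersed host set possible at this host
count", PD'=0 the tightest possible clade. When PDmax = PDmin (e.g. the
full leaf set) the scaled value is undefined and flagged rather than
forced.

Ultrametricity is not required — the sums are valid on any branch-length
tree — but a warning is emitted when leaf depths differ, because values
from non-clock trees are not on a common time scale.

## Overlap measures

With `d_i` the host count of plant `i` and `C_ij` the shared-host count:

* count dissimilarity `|d_i − d_j|`,
* Bray–Curtis (presence form) `1 − 2·C_ij/(d_i + d_j)`,
* min-overlap `C_ij / min(d_i, d_j)` — sharing relative to the maximum
  sharing that pair could show.

Group overlap is the **mean** of min-overlap over all unordered member
pairs. The statistic is sometimes written as the plain sum over pairs; the
pair count is constant within a group size, so min–max scaling within a
same-size ensemble is identical under either form (asserted as a test) and
the mean keeps raw values on [0, 1] across sizes. Group diversity is the
combined PD of the union of the members' host sets.

## Ensembles, scaling and location classes

For each group size n (2–5 by default) the package enumerates **all**
C(20, n) groups from the species pool and min–max scales combined PD and
group overlap within that same-size ensemble; observed field communities
are scaled against the generated ensemble of their size, so a community's
scaled value is directly comparable to the null of "any n species from
this survey". A group is *same-location* when at least one locality's
sampled species set contains every member (species may occur at several
localities; the classification is existential). Host sets are species-wide
unions — they are **not** restricted to the specimens of the shared
locality, since host detections are pooled at species level.

Covariates per group: total specimens, distinct OTUs in the union host
set, and the Herfindahl index of specimen shares (1/n for an even split,
→1 when one species dominates), used by the partial correlations.

## Statistics

* **Mantel tests** (phylogenetic signal): Pearson correlation of upper
  triangles of the plant patristic-distance matrix and each host
  dissimilarity matrix; significance by jointly permuting rows/columns of
  one matrix, one-sided "greater", `p = (count + 1)/(n_perm + 1)` with
  10⁴ permutations by default — the convention of vegan's `mantel`, which
  the in-package implementation is cross-checked against (scikit-bio) in
  the tests. Permutations are vectorised and take an explicit seed, so
  results are bit-reproducible. Run globally and within every locality
  that holds ≥3 sampled species.
* **Correlations**: scaled PD vs scaled overlap per size and pooled across
  sizes, as plain Pearson and as partial Pearson (residual method,
  df = n − 2 − #covariates) controlling for the three covariates above.
* **Location comparison**: Welch's unequal-variance t with the 95% CI of
  (same − different); Welch rather than Student because the two location
  classes have very different sizes and spreads.
* No multiple-testing correction is applied anywhere; each test is
  reported as-is.

Degenerate inputs (constant matrices, collapsed scaling ranges, all-equal
samples) produce flagged results, never crashes; p-values from permutation
tests are floored at 1/(n_perm+1).

## Synthetic data generator

The generator emulates the structure of a tropical MH survey so the whole
pipeline is testable without field data: 138 fungal OTUs on a random
ultrametric tree (Yule by default, Kingman coalescent optional), 20 plant
species, 15 localities of which 9 hold more than one species, host counts
log-uniform on 2–42 (log-uniform reproduces the heavy right skew of host
counts without asserting an empirical distribution), 1–10 specimens per
population, and observed communities of sizes {2:2, 3:3, 5:1} drawn inside
single localities. A plant phylogeny is generated alongside the fungal one
for the Mantel tests.

Location structure enters through fungal **locality pools**: each locality
holds a random pool of 20 OTUs (≈15 % of the regional pool — local
arbuscular-mycorrhizal communities are far smaller than the regional OTU
set, and pools this size keep chance overlap between two localities'
pools low enough for location structure to be visible). Each host draw
comes from the union of the plant's localities' pools with probability
`pool_sharing` (default 0.9), otherwise — and whenever the local pool is
exhausted — from the regional pool. At `pool_sharing = 0` locations are
inert and host sets are exchangeable. Species occupy one locality plus a
Poisson(0.3) number of extras; the 15-locality / 9-multi-species
constraint over 20 species forces some multi-locality species in any
case. One global seed drives every draw through a `SeedSequence`
splitting scheme.

Two emergent properties of this regime, checked by the tests: (i) scaled
combined PD and scaled overlap are positively correlated across generated
groups — host-count heterogeneity drives both, as groups containing
host-rich species have larger, more dispersed unions *and* higher expected
min-overlap; (ii) same-location groups have higher mean scaled overlap,
with the contrast (≈0.10–0.14) disappearing at `pool_sharing = 0`.

What the generator does **not** emulate: phylogenetic host specificity
(hosts are exchangeable within pools), spatial autocorrelation between
nearby localities, abundance structure, and sequencing noise. Two known
divergences from real surveys follow. Same-location groups show slightly
*lower* scaled PD here (sharing a pool shrinks the union host set, and no
counteracting biological mechanism is modelled), so tests assert the
location effect on overlap only. And the *partial* correlations are not
necessarily positive in synthetic data: the distinct-OTU covariate
absorbs nearly all of the PD signal because union size is the sole driver
of PD under exchangeable hosts. Passing tests therefore demonstrate the
machinery, not the field result.

## Problem sizes used in tests

The default analysis (20 plants, 138 fungi, all groups of sizes 2–5 =
21,679 groups, 10⁴ Mantel permutations) runs in a few seconds: group
metrics are evaluated as matrix products over the whole ensemble at once.
Oracle tests use 200 random 8–12-leaf trees (exhaustive enumeration stays
cheap at ≤ 4,096 subsets per tree); Mantel calibration uses 500 null
replicates at n = 10 with 999 permutations; synthetic-recovery tests
average three generator seeds.

## Numerical and design notes

* Greedy/DP tie-breaks are lexicographic; all stochastic operations take
  an explicit seed; reports are byte-identical under a fixed seed.
* The Mantel statistic uses the population (not sample) normalisation of
  the upper-triangle correlation, which cancels in both r and the
  permutation comparison.
* Incidence is binary at species level: an OTU is a host of a species if
  detected in ≥1 specimen. A long-format (specimen, species, family,
  locality, otu) table is accepted and collapsed on read.
* Branch lengths are mandatory on all non-root edges — PD is undefined
  without them; quoted Newick labels are accepted, comments stripped,
  underscores preserved verbatim.
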