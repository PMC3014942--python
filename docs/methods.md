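# Methods

## The model

`cnapath` asks whether a biologic pathway is hit by somatic copy-number
alterations (CNAs) more often than chance across a patient cohort. The
universe is the set of `G` genes quantifiable on the platform. In sample
`j`, `M_j` genes are altered (amplified or deleted). Under the null that
the altered genes are a uniform random `M_j`-subset of the universe, the
number `k_ij` of altered genes falling in a pathway of `N_i` genes is
hypergeometric:

    P(X = k) = C(N_i, k) C(G − N_i, M_j − k) / C(G, M_j)

The per-sample evidence that pathway `i` is targeted is the inclusive
upper tail `p_ij = P(X ≥ k_ij)`; an exclusive variant `P(X > k_ij)` is
available via `tail="exclusive"`. Because `M_j` is conditioned on per
sample and `N_i` enters the null, the metric self-adjusts for both the
sample's overall alteration burden and the pathway's size: a larger
pathway needs proportionally more hits to reach the same p.

Per-sample p-values are combined across the cohort of `n` samples with
Fisher's Omnibus, `X_i = −2 Σ_j ln p_ij`, referred to a chi-square upper
tail. The default degrees of freedom are `2n` (the standard Fisher
combination, under which `−2 ln p ~ χ²₂` exactly for continuous uniform
p); `df_mode="one_per_sample"` refers the statistic to `n` degrees of
freedom instead, for compatibility with analyses that use the sample
count directly. The family of pathway p-values is controlled with
Bonferroni: threshold `α/m`, adjusted p `min(1, m·p)`. With `α = 0.05`
and `m = 566` pathways the threshold is 8.834 × 10⁻⁵.

A "hit" defaults to any alteration (amplification or deletion both count
as targeting events); amplification-only and deletion-only definitions
are available. Genes altered in a sample but absent from every pathway
still count toward `M_j` — they are part of the universe. Duplicate gene
ids within a pathway are de-duplicated before counting `N_i`, and
pathway genes outside the universe are dropped with a logged count.

## Coordinate reconciliation

Array-CGH probes are BAC clones whose raw genomic mappings are often
incomplete. Two derived coordinate sets compensate:

* **Expanded** — each BAC whose raw span is under 100 kb and whose ends
  are not both anchored by mapped end sequences is grown to a 165 kb
  total span (the typical span of fully end-sequenced BACs; both values
  configurable). Growth is away from an anchored end, or symmetric when
  unanchored. Collisions between neighbours are resolved by a multi-pass
  procedure: growth proceeds in rounds of at most 1 kb per BAC, so two
  BACs expanding into the same gap split it essentially equally; when
  one direction is blocked the shortfall moves to the free end. The
  round-based algorithm is this package's design — the required outcome
  (equal assignment of intervening space, compensatory expansion) admits
  several implementations and this one is deterministic and order-free.
* **Extended** — the remaining gaps between expanded neighbours are
  split at the midpoint (odd gaps give the extra base to the left BAC, a
  deterministic tie-break), producing a pseudo-tiling of the arrayed
  span. The first and last BAC on a chromosome extend to the boundary of
  the arrayed region (minimum raw start / maximum raw end), not to the
  chromosome ends, since the tiling is over the region the array covers;
  a full-chromosome mode exists.

A BAC fully contained in a larger BAC is treated as a duplicate probe
and adopts the container's final coordinates. Partially overlapping ends
are left unchanged and take no part in expansion or extension.

Gene–BAC associations require a non-empty intersection, a BAC at least
one third the gene's length (guarding against insubstantial overlaps
with very broad gene mappings), and — in extended mode — at least 50% of
the gene inside the BAC, which together with the tiling makes the
assignment exclusive (residual exact-half ties break toward the
lower-start BAC). Per-sample altered segments are then overlaid on each
gene's effective interval (its BAC's extended interval in BAC-mediated
mode, its own span otherwise); a gene hit by both states in one sample
takes the state with the larger total overlap, with exact ties recorded
as 0 and warned about.

All coordinates are 0-based half-open; strand is ignored.

## Survival stratification

Per-pathway sample scores (externally computed activity/consistency
metrics; this package consumes, never computes them) are split into two
groups — by default 2-cluster k-means with 10 restarts on standardized
scores (seeded), with median-split and Ward-dendrogram-cut alternatives.
Group 1 is always the higher-scoring group. Kaplan–Meier curves and the
two-group log-rank test (1 df, asymptotic chi-square p) compare the
groups; censored subjects at a tied time remain at risk at that time.
The screen reports raw p-values flagged at `p < α` alongside
Bonferroni-adjusted significance, mirroring two-stage reporting where a
marginal screen precedes family-wise control. Separate endpoints
(overall survival, recurrence) are handled by running the screen once
per (time, event) column pair.

## Synthetic cohorts

The generator emulates the structure of a CGH breast-cancer cohort at
defaults of `G = 2000` genes, 100 pathways of 2–80 genes with
overlapping membership, 100 samples, and a background alteration rate of
0.05 (so `M_j ≈ 100`, matching the burden regime of a genome-wide
platform scaled to a desk-sized universe). Background alterations are
gene-wise independent Bernoulli draws; a segment mode instead plants
contiguous runs (geometric length, mean 5 genes) at the same expected
rate, emulating the segmental character of real CNAs. Driver pathways
are planted by adding hits at an excess probability (0.5 in the recovery
studies) in a random 60% of samples — different samples hit the pathway
through different member genes, as in real cohorts. Amplification vs
deletion is assigned per altered gene with probability 0.5; the default
statistic is state-agnostic, so this matters only for I/O round-trips.
Survival times are exponential with a hazard ratio (default 3) between
groups and independent exponential censoring calibrated to a 20%
censoring fraction. Everything is deterministic given the seed.

What the generator does **not** emulate: chromosome-arm-scale biology,
recurrent breakpoints, correlated co-amplification of neighbouring
pathways, or realistic pathway-gene clustering along the genome. Passing
recovery and calibration tests on these cohorts shows the statistic
behaves as designed under its own null, not that real cohorts satisfy
that null.

## Calibration and known limitations

**Discreteness makes the population p-value conservative.** The
hypergeometric per-sample p-value is discrete and, as an inclusive tail,
stochastically larger than uniform — for a 2-gene pathway at
`G = 2000, M ≈ 100` it takes essentially three values (1, ~0.1, ~0.003)
and `E[−2 ln p] ≈ 0.47`, far below the 2 expected of a continuous
uniform p. Fisher's combination inherits and amplifies this: across
sizes 2–80 at the default cohort, `E[−2 ln p]` ranges ~0.5–1.6, so the
omnibus statistic sits well below its χ²₂ₙ reference and the null
rejection fraction at 0.05 is near zero rather than 0.05. The method
therefore under-rejects, never over-rejects, under its own null; ranking
pathways (as in the planted-recovery studies) is unaffected, but
absolute population p-values are conservative, increasingly so for small
pathways. The test suite asserts the conservative direction; a
uniformity band around the nominal level is not attainable for this
statistic and the corresponding strict check is expected to fail.

**Asymptotic log-rank p at tiny n.** Against an exhaustive permutation
oracle at `n = 8` the asymptotic chi-square p typically differs by
~0.05 (the permutation distribution's granularity is 1/70); agreement
tighter than that is not achievable without an exact test, which is out
of scope. At the screen's realistic cohort sizes the approximation is
standard practice.

**Numerical choices.** p-values are computed through scipy's log-space
hypergeometric routines and clamped to `[1e-300, 1]` before logs in the
omnibus (a warning notes clamping). Tie-breaks: odd extension gaps go
left; equal-overlap gene assignment goes to the lower-start BAC;
equal-overlap amplification/deletion conflicts become 0. Degenerate
inputs (zero-length genes, empty chromosomes, constant score vectors,
empty groups) are rejected or skipped with diagnostics rather than
guessed at.

**Problem sizes.** The shipped studies use `G = 2000`, 100 pathways,
100 samples, with 100–200 replicates for calibration/recovery and 200
simulations for log-rank power — sizes at which every distributional
property under test has already stabilised, chosen to keep the whole
suite comfortably reproducible on a single CPU.
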