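# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices that were
genuinely open.

## Coordinates and the contact graph

All coordinates are 0-based, half-open.  A position `pos` belongs to bin
`pos // bin_size` (default 40,000 bp) and the midpoint of bin `v` is
`(v + 0.5) * bin_size`.  The contact graph stores a dense symmetric
matrix of non-negative frequencies; normalised matrices are consumed
as-is (no Hi-C correction is performed here).  Self-contacts `f(v, v)`
are retained and contribute once to the per-bin total
`t(v) = Σ_u f(u, v)`, so `Σ_v t(v) = 2 Σ_{u<v} f(u, v) + Σ_v f(v, v)`.
Bins with `t(v) = 0` (unmappable regions) are kept in the graph and
flagged; samplers place SNPs in them by default.  Asymmetric dense input
is symmetrised as `(A + Aᵀ)/2` with a warning rather than rejected,
because Hi-C text dumps vary in how they materialise the upper triangle.

## Distal filter and equivalence classes

A pair survives filtering when SNP and gene share a chromosome, the SNP
lies outside the gene body, and the distance from the SNP to the nearest
gene boundary is at least 50 kb (inclusive).  The filter distance is
measured SNP-position-to-gene-boundary; the class property *d* is
measured between bin midpoints.  These are deliberately distinct
quantities: the filter expresses "distal" in sequence coordinates, while
*d* lives at the resolution of the contact graph.  Gene names must map
to a unique interval; names with conflicting intervals are dropped
entirely (with a warning) rather than guessed.

The "closest gene fragment" is resolved by midpoint distance with ties
broken toward the lower bin index.  The SNP–gene interval is the closed
interval between the SNP-bin midpoint and that fragment's midpoint.  An
interval is *within-domain* when some domain `[s, e)` satisfies
`s ≤ a` and `b ≤ e` — an endpoint exactly on a boundary coordinate
counts as contained — *crossing* when it strictly overlaps a domain
without being contained, and otherwise lies in a non-domain gap.  For
multi-gene exclusivity, within-domain and gap classes are merged as
non-crossing.

## Random eQTL space

Random classes are built by resampling the observed empirical sequences:
gene length `l` and SNP-to-gene-boundary distance `d` are drawn with
replacement (independently by default; a `joint` flag resamples
`(l, d, orientation)` rows for sensitivity analysis), the SNP side is
Bernoulli with the observed downstream probability, and the SNP position
is uniform over the placements for which the implied gene fits on the
chromosome.  Draws that exactly reproduce an observed class (same SNP
bin and gene-fragment range) are discarded so matching can never pair an
observation with itself; duplicates within the random space are allowed.
A hard cap of 10 million draws guards against degenerate geometries.
The space multiplier `n_p` defaults to 100, balancing match quality
against memory; simulations in the test suite use `n_p = 20`, which
leaves the matched features correlated at ρ ≳ 0.95.

## Matching

Matching minimises the summed Euclidean distance between observed and
random feature vectors, each candidate used at most once, each observed
element receiving exactly `k` candidates.  It is solved by replicating
each observed element `k` times and running one rectangular min-cost
assignment (scipy's Jonker–Volgenant solver), so the `k` matches are
jointly optimal, not greedy rounds.  Features enter the distance
unscaled by default; a z-scaling option exists because bp-scale features
otherwise dominate frequency-scale features, but the default preserves
the plain-Euclidean contract.  Ranks within an element are ordered by
distance with candidate-index tie-breaks, making output deterministic
for fixed input order.

## Domain shuffling and the conditioned p-value

A shuffle decomposes the chromosome into its alternating domain /
non-domain tiling (leading and trailing uncovered segments count as
non-domain intervals), permutes the domain-length list and the
gap-length list independently, and reassembles along the original label
sequence.  This preserves exactly: the multiset of domain lengths, the
multiset of gap lengths, and the label pattern.

For the crossing test, `(N, N_G, N_S)` — crossing classes, distinct
crossing genes, distinct crossing SNP bins — are computed for each of
`n_d` shuffles (default 10,000; simulations use 200).  The `k_cond`
shuffles nearest the observed `(N_G, N_S)` in Euclidean distance are
selected — widened to include every shuffle tied with the k-th best
distance, so the result cannot depend on assignment-solver tie-breaking
— and the γ (genes) and σ (SNP fragments) ranges are the min/max over
that set, further widened to include the observed values.  The
conditioned space is every shuffle with both statistics in range, plus
the observed sequence; `p = #{members with N ≥ n} / |space|`.  Because
the observed sequence is a member and attains its own count, `p > 0`
and the space always holds at least `k_cond + 1` members.  `k_cond`
defaults to 100.  Distinctness is by gene name for `N_G` and by bin
index for `N_S`.

## Test statistics

The matched-pair comparison uses the two-sided Wilcoxon signed-rank test
on `p_obs − p_rand` with zero differences dropped and average ranks for
ties (exact null when scipy's exact path applies, normal approximation
otherwise).  Rank-sum comparisons use the Mann–Whitney U with an exact
null for tie-free groups of ≤ 50 and the tie-corrected normal
approximation otherwise.  Empirical p-values over shuffles use the
add-one estimator `(1 + #{extreme}) / (1 + n_d)`, so they lie in
`[1/(n_d+1), 1]`.  Per-chromosome crossing p-values are adjusted with
Benjamini–Hochberg.  Proximity bins for the direction display default to
`[0,1), [1,5), [5,10), [10,30), [30,∞)` with "high proximity" meaning
≥ 10; the edges are configurable.  Size-stratified boundary tests use a
20% size tolerance and 10 histogram bins by default, flag strata with
fewer than `5 × n_bins` SNPs as underpowered, and Bonferroni-multiply by
the number of size classes.

## Synthetic-data model

The generator emulates the structure the analysis targets, not the full
complexity of real data.  A chromosome (default 20 Mb, 500 bins) is
tiled by truncated-normal domains (mean 800 kb, sd 400 kb, minimum two
bins) separated by gaps occupying ~15% of the chromosome.  Contacts are
Poisson around `μ(u,v) = A (|u−v|+1)^{−α}`, multiplied by β when both
bins lie in one domain; defaults `A = 10`, `α = 1` (a standard
intra-chromosomal decay slope; a free parameter here, not an empirical
claim), `β = 5`.  A negative-binomial option adds overdispersion for
robustness checks.  Genes (default 60, mean 60 kb) are placed uniformly
without overlap; 200 eQTLs pick genes uniformly and SNPs uniformly over
the admissible distal region (50 kb – 1 Mb from the gene).

Three independent planting knobs create the effects the tests detect:
λ ≥ 0 re-weights candidate SNP positions by `(1 + f)^λ`; ρ ∈ [0,1]
re-draws the SNP uniformly within 250 kb of a domain boundary; κ ∈ [0,1]
forces the SNP–gene interval to cross a domain.  `λ = ρ = κ = 0` is the
global null, under which SNP placement is uniform over the admissible
set and independent of both contact and domain structure — this is what
makes the calibration simulations meaningful.

What the generator does **not** emulate: Hi-C coverage biases and
normalisation artifacts, overlapping/nested genes (available behind a
flag but off by default), inter-chromosomal contacts, linkage
disequilibrium between SNPs, and realistic eQTL effect-size
distributions.  Passing calibration and power checks on this model
therefore demonstrates the statistics are correct and sensitive under
controlled conditions, not that real data meet their assumptions.

## Simulation sizes

Calibration uses 200 null replicates of the default 500-bin chromosome
with 200 eQTLs; power uses 100 replicates at the strong planting levels
(λ = 5, ρ = 0.9, κ = 0.7) and 50 at null/moderate levels (λ = 1,
ρ = 0.3, κ = 0.2), with `n_p = 20`, `n_d = 200`, `k_cond = 100`
throughout.  These sizes were chosen so the whole suite completes in
minutes on one core while leaving the binomial noise on rejection rates
well inside the asserted bands.

## Degenerate inputs and tie handling

Empty pair lists yield empty graphs; a chromosome shorter than every
implied gene-plus-distance span raises immediately from the sampler; an
all-zero-difference matched test reports `p = 1` with no direction;
zero-variance matching features report an undefined (NaN) correlation
rather than raising; an empty domain sequence is an error for boundary
offsets.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning — the pipeline derives per-stage,
per-chromosome seeds from one master seed (chromosome names are hashed
with SHA-256, not Python's randomised `hash`), so reports are
reproducible bit-for-bit and stages can be re-run in isolation.

## Known limitations

Only intra-chromosomal analysis is supported; restriction-fragment-level
graphs are not modelled (all analysis is at bin resolution); domain
calling and Hi-C normalisation are out of scope — the package consumes
their outputs.  The conditioned p-value's γ/σ ranges follow the min/max
construction described above; other conditioning-window definitions are
conceivable and would trade conservativeness against power.
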