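# Methods

## The fingerprint model

A protein of length *n* is compared against itself under a substitution
matrix *M* (BLOSUM62 by default). The grey value of cell (i, j) is the
windowed score

    grey(i, j) = clamp( Σ_{k=−h..h} M(s[i+k], s[j+k]), 0, 255 ),   h = (W−1)/2

with window length W = 25 (odd; the classic dot-plot scoring window for
proteins). Windows truncate at the sequence ends: offsets that would index
outside the chain simply contribute nothing. This avoids inventing padding
residues and keeps the matrix defined everywhere, at the cost that cells
near the termini and the matrix corners see fewer than W terms. The
neutral characters X (unknown residue) and "−" (gap/padding) score zero
against everything, so they neither create nor destroy signal — this is
what makes terminal gap padding in the consensus pipeline work.

Cells of the strict upper triangle with grey ≥ 31 (the *black point*) are
the **pixels** of the fingerprint; the self-identity diagonal is a trivial
perfect match and is never stored. Raising the black point can only remove
pixels (monotone binarization). On this raw-sum scale a pixel requires
roughly 35–40% identity across the window, which is the regime in which
sibling repeat units in natural proteins recognize each other.

The grey scale here is the raw clamped window sum. The original dot-plot
programs map window scores onto a 0–255 greyramp through their own
internal scaling, which is not part of this package; the black point is
therefore exposed as a parameter so the scale can be recalibrated against
any external pixel source if bit-compatibility is ever needed. All
qualitative behaviour (repeat lines, density separation of repeat vs
non-repeat chains, decay kinetics) is reproduced on the raw-sum scale.

## Sliding Jaccard comparison

Two fingerprints A and B are compared by translating the smaller plot's
pixels along the larger plot's self-identity diagonal. At offset o every
pixel (i, j) moves to (i+o, j+o); the Jaccard index is

    J_X(o) = |A_o ∩ B| / |A ∪ B|,

where the union counts *all* pixels of both plots, including those outside
the overlap window — size mismatch is penalized, which is what makes the
maximal J_X a meaningful similarity. The maximum over all offsets with at
least one residue of overlap is the reported J_X; J_D = 1 − J_X is the
distance. Ties are broken toward the smallest |offset|, negative before
positive, so a plot compared with itself reports offset 0. When both plots
are empty, J_X = 0 by convention: two information-free plots are not
evidence of relatedness.

The implementation exploits that a translated pixel can only match a
pixel on the same off-diagonal d = j − i; per diagonal, intersection
counts for every offset are the cross-correlation of the two plots'
i-coordinate lists. This gives all offsets in one pass and is checked in
the test suite against an exhaustive per-offset set-translation oracle.

## Repeat detection and deconvolution

A chain is classified repeat-containing iff it has at least `min_length`
residues (default 121, the census setting; the curated-set experiments in
the literature used a floor of ~101) **and** its fingerprint has at least
0.42 upper-triangle pixels per residue. Deconvolution reads the pixel
indices back out of the plot:

- the **residue profile** counts, per residue, occurrences in any pixel's
  row or column (sums to twice the pixel count);
- **segments** are maximal runs of residues whose profile meets a cutoff,
  with internal gaps of ≤ 2 residues closed and runs shorter than 3
  residues discarded (the small tolerances suppress salt-and-pepper
  segmentation caused by window blurring);
- **periods** are the dominant off-diagonal pixel distances d = j − i,
  with adjacent distances (±1) merged into one support-weighted peak,
  because windowed scoring blurs repeat lines by about one residue.

For consensus matrices the deconvolution rule operates on the averaged
grey scores rather than pixel counts: a residue is a repeat member at
cutoff c (multiples of 10 up to 50 are conventional) iff any cell in its
row/column of the averaged matrix scores ≥ c. `consensus_score_profile`
produces exactly the profile that `repeat_segments` needs for this.

## Sequence evolution experiments

**Substitution model.** "Mutate according to BLOSUM62" is made concrete as
the Boltzmann-like back-transform of the half-bit log-odds scores: a
mutating residue a is replaced by b ≠ a with probability ∝ 2^(M(a,b)/2).
Self-substitution is excluded so every round changes a residue; repeated
rounds can hit the same site (with replacement), so sequence identity is
*measured* positionwise against the original rather than inferred from the
round count. The tests check the measured identity against the exact
20-state per-site Markov-chain expectation, which includes reversions.

**Decay experiment.** Each replicate applies single-site mutations
cumulatively for `rounds` rounds (default: the chain length); after each
measured round the mutant is fingerprinted and slide-compared against the
original. Curves average J_X and percent identity across replicates
(default 1001, matching the published protocol; the desk-scale experiments
below use 24). A `measure_every` parameter thins the measured rounds —
the fitted relationship is J_X against identity loss, not against round
index, so thinning does not bias the fit. Curves are fitted by nonlinear
least squares to

    J_X = exp(−b·z),    z = 100 − mean identity (percent),

giving the decay constant b, the half-life z50 = ln 2 / b (percent
identity loss at which J_X halves), and R². A fit is *clean* when
R² ≥ 0.98 and b > 0; a non-decaying curve is returned flagged with
undefined half-life.

**Insertion experiment.** Residues drawn from the original chain's
composition (uniform-over-20 available) are inserted one at a time at
uniform positions, up to 20% of the original length by default; after each
insertion the grown chain is fingerprinted and slide-compared to the
original. The **half-loss rate** is the first insertion rate (percent of
original length) at which mean J_X ≤ 0.5, linearly interpolated between
bracketing measurements. A single insertion splits the pixel pattern into
two diagonal-consistent blocks, of which sliding can recover only one, so
insertions cost far more J_X per percent sequence change than
substitutions — the experiments below measure half-loss rates around
0.5% of length versus substitution half-lives around 8% identity.

**Alphabet shuffling.** A bijection over the 20 letters is optimized by
Monte Carlo (propose a swap of two keys' images; accept decreases of the
per-residue BLOSUM similarity of the remapped chain always, increases with
probability exp(−Δ/kT), kT = 0.04; 10000 steps, best of 10 restarts). The
score is normalized per residue — kT = 0.04 is only meaningful on an O(1)
scale — and depends only on residue composition, so each evaluation is
O(20) after a one-time composition count. Because a bijection preserves
self-identity structure exactly and much of the near-match structure, the
remapped chain keeps a recognizable fingerprint (J_X well above 0.1) while
sharing essentially no sequence identity with the original.

## Consensus fingerprints

Given an externally computed multiple sequence alignment of homologs
(alignments are inputs, not products, of this package): columns in which
≥ 20% of members have a gap are trimmed; 25 gap symbols (one full scoring
window) are padded onto both termini to push window-truncation edge
effects off the residues of interest; each member's grey matrix is
computed on its edited sequence; the matrices are averaged cell-wise; and
the average is binarized at the standard black point. Averaging raw grey
matrices (rather than binary plots) lets sub-threshold agreement
accumulate: a cell every member supports survives, a cell only one member
supports is washed out.

Coherent family groups are discovered by hierarchical clustering of the
pairwise J_D matrix under five linkages (McQuitty/WPGMA, average,
complete, single, Ward), cutting each dendrogram at 50 evenly spaced
heights, and scoring each (linkage, height) by the number of *coherent*
clusters — clusters of ≥ 2 members whose median pairwise J_D ≤ 0.875
(mean and max aggregators are available). Ties are broken toward the cut
whose coherent clusters cover more chains, then toward the earlier linkage
and lower height; without the coverage tie-break a cut that strands one
family member can tie with the complete grouping.

## Clustering

Curated-scale sets use the dense J_D matrix and scipy's agglomerative
clustering; McQuitty is WPGMA ("weighted" in scipy), in which a merged
cluster's distance to any third cluster is the unweighted mean of the two
merged clusters' distances. Large sets are sparsified by keeping each
node's k strongest similarities (k = 1400 at census scale) with union
symmetrization — an edge survives if either endpoint kept it, so strong
one-sided neighbours are not lost. Markov clustering is re-implemented at
desk scale: unit self-loops, column normalization, then alternating
expansion (matrix squaring) and inflation (element-wise power, default
2.0, the conventional setting) with entries below 1e−12 pruned, iterated
until the matrix changes by < 1e−6 (capped at 100 iterations, returning a
flagged best-effort result on non-convergence); clusters are the connected
components of the limit matrix's support. Clusters of ≤ 4 members are
flagged singletons. Every cluster reports its medoid — the member with
the smallest summed J_D to the rest, ties broken lexicographically for
determinism.

## Synthetic data

The generators emulate the three kinds of input the analyses consume.

- **Tandem-repeat proteins**: a random ancestor unit (length 20–40 typical)
  drawn from the BLOSUM62 background composition is copied 3–8 times; each
  copy is independently diverged under the substitution model, optionally
  with single-residue insertions, and flanked by random sequence. Ground
  truth (unit intervals, period, ancestor) is returned with each chain.
  `unit_divergence` may be a single rate or a (low, high) range sampled
  per copy; the range form models natural repeat arrays, where some units
  are recent duplicates and others ancient.
- **Non-repeat controls**: i.i.d. chains from a given composition, and
  composition-matched shuffles of specific chains.
- **Star-phylogeny families**: members independently diverged from a
  common ancestor by substitutions only, so the columnwise alignment is
  trivially correct — used for the consensus experiments without needing
  an external aligner.

**The synthetic standard set** (`make_standard_set`) emulates a curated
benchmark of natural repeat chains of known structure: 20 chains of unit
length 20–40, 4–8 copies, length 150–450, per-copy divergence drawn from
U(0.40, 0.60), keeping only chains with ≥ 0.42 pixels/residue. The
divergence range was fixed by matching the generated fingerprint densities
(≈ 0.8 px/residue after filtering) to the band reported for natural
repeat proteins in curated structural databases (mean ≈ 0.66), rather
than the several-fold higher densities of designed repeat proteins.
This matters: with near-identical units, repeat pixels sit far above the
black point and the decay curve develops a shoulder (several hits are
needed before any pixel disappears), visibly departing from a single
exponential. Natural-like marginal pixels produce the clean exponential
decay the method is known for.

What the generators do **not** model: domain architecture, indel length
distributions beyond single residues, compositional biases of specific
families, low-complexity regions, and any structural constraint. Passing
benchmarks on this data shows the pipeline's operations behave correctly
and that the published kinetics emerge under realistic divergence; it does
not certify performance on any particular natural proteome.

## Problem sizes and numerical choices

Desk-scale experiment defaults (used by the test suite and the acceptance
script): 20 standard-set chains; decay with 24 replicates measuring every
4th round; insertion with 20 replicates up to 8% of length (the half-loss
point lies near 0.5%, so 8% brackets it many times over); shuffling with
2000 steps and 3 restarts (the score landscape over 20! permutations is
shallow; longer runs change the optimum by < 1%); classification benchmark
with 50 repeat chains (unit 20–40, 3–8 copies, homogeneous divergence up
to 30%) against 50 matched shuffles; planted-family clustering with 3
families × 5 members. Library defaults keep the published protocol sizes
(1001 decay replicates, 100 insertion replicates, 10000 MC steps × 10
restarts, k = 1400).

Other numerical choices: grey values clamp to [0, 255]; the exponential
fit starts from b = 0.1 and flags rather than fails on non-decaying
curves; half-loss points interpolate linearly between bracketing
measurements; degenerate inputs (empty plots, single-residue chains,
single-member clusters) are defined explicitly rather than rejected where
a sensible convention exists (J_X = 0 for two empty plots, a singleton's
medoid is itself).

## Known limitations

- The grey scale is the raw window sum, not any particular legacy
  greyramp; absolute densities are only comparable within this package.
- Sliding searches diagonal-parallel shifts only; a large internal
  insertion that splits a pattern in two is scored by its larger half
  (sub-plot partial matching is out of scope).
- Unit-boundary segmentation inside a repeat region is provided via
  periods + segments, not as an exact per-unit annotation.
- MCL here is a dense-matrix desk-scale implementation; it is not meant
  for millions of chains.
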