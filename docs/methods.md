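# Methods

This note documents the models, parameters and numerical choices
behind `omicmatch`, and what the synthetic-data evaluation does and
does not establish.

## Profile similarity as an intrinsic barcode

Two omics layers measured on the same individual are coupled at
*cis*-associated feature pairs: SNP–transcript, methylation
probe–transcript, CNV segment–transcript, miRNA–host gene,
protein–mRNA.  Across N such pairs, the vector of one sample's Type A
values and the vector of the same individual's Type B values are
positively correlated after two normalizations:

- **Normal rank transform.** Each feature is mapped to
  Φ⁻¹((rank − ½)/n) with average ranks for ties, over all samples of
  its matrix.  This removes platform-specific dynamic ranges and
  marginal distributions; the (rank − ½)/n offset (rather than
  rank/(n+1)) keeps the extremes finite and symmetric.  The transform
  is taken over *all* samples, not only the currently matched ones, so
  that unmatched extra samples remain scoreable in every round.
- **Orientation.** Each significant pair's B-side feature is
  multiplied by the sign of its estimated cis Spearman correlation.
  Cis-associations are mixed-sign in real data (promoter methylation
  is anti-correlated with expression; eQTL effect alleles are
  arbitrary), and an unoriented Pearson over mixed-sign pairs cancels
  toward zero.  Orientation makes every significant pair contribute
  |ρ| of signal.  For an association set that is all-positive
  (miRNA–host, protein–mRNA) orientation is the identity.

The similarity S(Aᵢ, Bⱼ) is the Pearson correlation of the two
transformed length-N vectors over pairwise-complete features; entries
with fewer than `min_overlap` complete features
(default max(10, ⌈N/2⌉), a guard against platforms with heavy
non-random missingness) are undefined and never aligned.

Matched samples score around the mean |ρ| of the significant cis set
(≈ 0.3–0.5 under the defaults here); unrelated samples score
0 ± 1/√N.  The separation therefore improves with N and the
difficulty of the problem is governed by N and by the number of
samples competing for each match.

## Decision procedures

**Rank matcher (baseline).**  A candidate self pair (same annotated
ID) is confirmed iff its score ranks within the top 5% of both its row
and its column (⌈0.05·n⌉, replaced by a flat top-20 when the dimension
exceeds 400 — the historical rule this matcher reproduces); leftovers
are cross-aligned by unique reciprocal best score.  Ties occupy the
best tied rank, which favors self-alignment; a tied reciprocal maximum
is not aligned.  As n grows at fixed N the top-k bar tightens while
score noise stays 1/√N, which is why this rule degrades for small N
and large M.

**Probabilistic matcher.**  Every pair (i, j) is judged against a
2-D reference cloud {(S(Aᵢ, Bₘ), S(Aₘ, Bⱼ))} over currently matched
pairs m (excluding pairs involving row i or column j), augmented with
`n_permuted` = 1000 pseudo-profile pairs built by drawing, for each
cis feature independently, the value of a uniformly random sample —
this destroys the cis structure while preserving the marginals, and
sampling with replacement is used because 1000 pseudo-profiles can
exceed the sample count.  The cloud is fitted with a bivariate normal
(population covariance; ridge 10⁻⁶·I when near-singular) and the
chance-match p-value of the observed score s is

    p(i, j) = p₀·exp(−r²/2)   (same annotated ID)
              exp(−r²/2)       (otherwise)

with r the Mahalanobis distance of (s, s) from the cloud and
p₀ = 1/N_s the self-alignment prior (N_s = number of candidate self
pairs).  Under the fitted normal, r has CDF 1 − exp(−r²/2), so p is a
genuine tail probability.  All comparisons are carried out on
log p = log p₀ − r²/2: for confident matches r² reaches the hundreds
and exp(−r²/2) underflows to zero, which would create spurious ties
under the strict-minimality rules below.

Per round: (1) self-align (i, i) iff S(Aᵢ, Bᵢ) exceeds the self floor
and p(i, i) is strictly minimal over row i and column i; (2) among
profiles still free, cross-align (i, j) iff S(Aᵢ, Bⱼ) exceeds the
cross floor and p(i, j) is strictly minimal over its full row and
column (a tie aligns nothing); (3) rescue remaining self pairs whose
score clears the self floor and whose p is within the `rescue_rank`
= 5 smallest of both their row and their column, ties inclusive.  The
score floors come from the self-self score distribution:
mean − 2.576·sd (central 99% lower bound) for self and mean − 1·sd
(central 68%) for cross.  The z-multipliers follow the
central-interval reading; the one-sided alternative (2.326) would
admit marginally more self pairs.  The cross floor acts as a
similarity *floor*: a cross-alignment must still look like a genuine
match, only less stringently than a self confirmation.

Because the floor is an extreme-tail quantile of the self-score
distribution itself, on clean data roughly the lowest ~0.5% of true
self pairs fall below it and remain unaligned.  This is the designed
trade-off — the procedure optimizes specificity over sensitivity (no
false alignment is worth a few abstentions) — and it is why the
headline accuracy is ">99%" rather than 100%.

Per-pair model fitting is exact but vectorized: the cloud mean and
covariance for all N_A × N_B contexts are assembled from shared
sufficient-statistic matrix products with closed-form exclusion
corrections, and the unit tests verify the vectorized path against the
naive per-context fit to 10⁻⁸ on shared permutation draws.

**Iteration.**  Matched pairs (initially the shared IDs) drive the cis
test; aligned pairs from each round become the matched set of the
next.  The loop stops when the full decision set repeats the previous
round's (converged) or after `max_iter` = 20 rounds (flagged
non-converged).  Correcting even a few percent of labels visibly
raises the number of significant cis-associations between rounds, and
convergence takes 2–4 rounds in practice.

## Error-source verdicts and correction

Pairwise alignments from ≥ 2 data-type comparisons are merged into a
graph with nodes (patient, data type) and edges labeled self / cross /
unaligned.  The verdict rules formalize the patient-centric reasoning
used to localize errors:

- **Swap in data type T** between patients i and j: reciprocal cross
  edges (i,T)↔(j,T′) and (j,T)↔(i,T′) for at least `min_support`
  (default 1) other data types T′; neither T profile carries any self
  edge (a profile corroborated by another layer is not the swapped
  one); and for both patients every observed edge among their non-T
  profiles is self, with at least one such corroborating self edge
  present.
- **Mislabeled profile**: cross-aligned away with no reciprocal
  pattern and no self edge, while the patient's remaining profiles
  agree among themselves.  The relabel target is the partner patient
  when all cross edges point to a single one.
- Everything else is **unresolved** and is never auto-corrected.

Corrections are applied per data type, all-or-nothing: swap verdicts
exchange the two sample columns; unambiguous mislabels are relabeled
(collisions abort), ambiguous ones are dropped; every action is
logged.  The correction-gain utility compares per-cis-pair Spearman
correlations on the aligned pairs against the mean over 100 equal-size
random subsets of the initially matched pairs, removing the
sample-size confound.

## Synthetic data: what it emulates and what it does not

The generator draws Type A cis features as iid standard normals over
samples and builds the paired Type B features as
Y = (r/√(1−r²))·X + ε with ε standard normal, so that corr(X, Y) = r
exactly.  Effect sizes:

- planted pairs (`n_cis`, 75–1000): |r| from a half-normal with scale
  `r_scale` = 0.3, truncated below at the correlation whose two-sided
  t-approximation p-value equals the BH boundary
  α·n_true/(n_true + n_null) — i.e. the threshold at which a pair is
  *just* significant assuming the planted pairs occupy the top ranks —
  and truncated above at 0.99; a random sign is then attached
  (handled by the orientation step above).  The fixed-threshold
  construction keeps the generator deterministic given its seed; an
  exact data-adaptive BH cutoff would make the truncation point itself
  random.
- null pairs (`n_null` = 2000): r from a centered normal with scale
  `r_null_scale` = 0.03.  This scale is deliberately small: the study
  conditions sweep "N significant cis-associations", so the null
  background must contribute essentially no significant pairs (at
  M = 1000 about 3 of 2000 pass q < 0.05), leaving the planted count
  as the realized barcode size.  A null scale comparable to the
  planted scale would flood the barcode with ~1000 extra significant
  pairs and decouple the realized difficulty from N entirely.

Ten percent extra unmatched samples are appended to each type
(unbalanced sample lists), and label errors are planted by permuting
`round(rate·M)` Type B core labels with a uniform random derangement —
no selected sample keeps its label, so the realized error rate equals
the nominal one — or with disjoint 2-cycles when reciprocal swaps
specifically are wanted.  All randomness flows from one master seed
through named substreams.

Alignments are scored against the known pairing: sensitivity = truly
aligned / simulated core pairs, precision = truly aligned / aligned,
FPR = 1 − precision, F = 2·precision·recall/(precision + recall)
(0 when undefined); a pair is truly aligned iff its partner matches
the truth, whether self or cross.

What passing these evaluations does *not* show about real data: the
generator has no missing values, no batch or platform effects, no
non-normal marginals, no correlated features (each cis pair is
independent), no population structure among samples, and every
candidate pair is a genuine biological hypothesis.  Real applications
face heavy non-random missingness (protein arrays especially),
probe-to-gene mapping ambiguity, and cohort substructure that can
inflate off-diagonal similarity; the `min_overlap` guard and the
missingness/MAF filters address the first two only coarsely.

## Problem sizes and determinism

The bundled evaluations run the full procedure at N ∈ {200, 500, 1000}
× M ∈ {100, 300} with 4% and 6% error rates and three replicate seeds
(36 runs, about a minute), plus a rank-matcher sweep up to M = 1000
and a swap-correction round trip at N = 500, M = 200.  Larger grids
scale linearly in cells; a single match at M = 1000 with ~2000
candidate pairs takes a few seconds.  Every run is bit-reproducible
given its seed; per-cell seeds in grid sweeps derive from the master
seed by seed-sequence spawning.

## Known limitations

- The probability model evaluates one data-type pair at a time; no
  joint model over more than two profile types is attempted, and the
  patient-view verdicts are rule-based rather than probabilistic.
- The self/cross floors assume the self-score distribution is roughly
  normal; heavy contamination (error rates well above ~10%) distorts
  the floor estimates.
- Step-2/step-3 comparisons treat per-context p-values as commensurate
  across contexts; this is the procedure's definition rather than a
  calibrated joint test.
- The exact-permutation Spearman path is used only for tie-free
  vectors with n < 10; tied small-n inputs fall back to the
  t-approximation.
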