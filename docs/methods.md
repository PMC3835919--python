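# Methods

## Model and assumptions

`bifanr` treats a multiple sequence alignment as S independent draws of
an L-dimensional categorical vector and looks for groups of columns
("protein sectors") whose states covary through shared latent causes,
against a background of columns that evolve (statistically) on their
own. Two assumptions shape everything downstream:

1. Sites inside one sector are pairwise strongly coupled, so a sector
   appears as a dense block of the position-coupling matrix W.
2. Distinct sectors are mutually independent, so after an orthogonal
   rotation each significant factor of W should load on exactly one
   sector — the rationale for varimax rotation rather than, say,
   interpreting raw eigenvectors.

The method is alignment-statistical: sequences are exchangeable and no
phylogeny is modeled. Phylogenetic relatedness in real families
violates exchangeability and can inflate couplings; the column-shuffle
null controls the pure-sampling component of that, not shared ancestry.

## Coupling statistic

With amino acids encoded 1–20 (alphabetical one-letter order) and gap
0, the frequencies use the full sequence count S as denominator (gaps
count toward no amino acid), so Σ_a f_i^a ≤ 1 with equality only at
gap-free columns; `denominator="nongap"` switches both the single and
the pairwise counts to non-gap denominators. Background frequencies q^a
are the pooled residue counts of the input alignment (an external
20-vector can be supplied).

The coupling of sites i, j is

    C_ij^ab = f_ij^ab − f_i^a f_j^b
    φ_i^a   = ln[ f_i^a (1 − q^a) / ((1 − f_i^a) q^a) ]
    W_ij    = sqrt( Σ_ab (φ_i^a φ_j^b C_ij^ab)² ),  W_ii = 0.

The log-odds conservation weight up-weights covariation at conserved
positions, the convention of statistical coupling analysis; both the
weight and the Frobenius reduction are single functions
(`conservation_weights`, the reduction inside `weight_and_reduce`) so
alternates can be swapped in.

Numerical choices: frequencies entering the weight are clamped to
[ε, 1−ε] with ε = 1/(2S) — half a pseudo-count — so fully conserved or
absent residues give large finite weights instead of infinities; the
same clamp is applied to q (an amino acid absent from the whole
alignment would otherwise make the weight undefined). The diagonal of W
is zeroed: self-coupling is not a coevolution signal.

## Noise reduction

Rmax(i) is the mean of the k = ceil(0.05·(L−1)) largest off-diagonal
couplings of site i (k ≥ 1), `plus` the mean of Rmax over all sites,
and sites with Rmax(i) ≤ 0.8·plus are removed. The boundary tie is
removed ("no larger than"). Both constants (5 %, 0.8) are parameters.
If every site falls at or below the threshold the run aborts with an
explicit no-signal error rather than an empty matrix.

## Factor retention against a column-shuffle null

Each null replicate permutes every kept column independently across
sequences — destroying inter-column dependence while preserving every
column's composition exactly — and recomputes the full pipeline on the
kept sites. Single-site frequencies and the background are invariant
under within-column permutation, so the conservation weights are
computed once and reused (an equivalence test checks this against full
recomputation). All n eigenvalues of each of the 100 shuffles are
pooled into E (|E| = 100·n), and with N(i) the number of elements of E
strictly greater than λ_i, the retained count t is the largest index
with N(t) < 100.

A property of this rule worth knowing: for the *top* eigenvalue it is a
lenient test. On a completely uncoupled alignment the real λ1 is
exchangeable with the 100 null λ1's, and because the top (Perron) mode
of a nonnegative coupling matrix sits well above the bulk, N(1) < 100
essentially whenever the real λ1 is not the minimum of those 101
exchangeable draws — so pure noise yields t = 1 far more often than
t = 0. Retained factors whose rotated loadings clear no site threshold
produce no sector, which is what happens to such borderline top modes
in practice; a stricter alternative (retain only λ > max E) would make
t itself conservative but is not this method's rule.

## Rotation and site selection

Eigenvector signs are fixed (largest-magnitude entry positive) before
rotation so the bidirectional selection is reproducible. Varimax
maximizes Σ_k [mean_i b_ik⁴ − (mean_i b_ik²)²] by the standard
SVD-ascent iteration; the loop stops when the criterion gain drops
below `tol` (default 1e-6). Raw varimax is the default; Kaiser row
normalization is available (`kaiser=True`) and the rotation is always
applied to the unnormalized loadings, so per-site communalities are
preserved to numerical precision in either mode. A single retained
factor is returned unrotated (the criterion is rotation-free up to
sign).

Site selection runs per factor and per sign: p(i) = s·b_ik, w = mean of
the top ceil(n/2) values of p, and site i is selected when
(p(i)/w ≥ r0 and p(i) > p0) or p(i) ≥ p1. A sign pass whose w is not
positive yields no sector (degenerate direction), and candidates with
fewer than 2 sites are discarded — a one-site "sector" carries no
coevolution meaning. The defaults r0 = 0.8, p0 = 0.1, p1 = 0.4 are
calibrated so that strongly coupled planted sectors are recovered
exactly under the default synthetic conditions below; all three are
exposed in the API and CLI because appropriate values depend on how
sharply the rotated loadings separate in a given family.

Overlapping candidate sectors (a by-product of bidirectional selection)
are merged: the intersection is grown greedily by the
symmetric-difference site with the largest summed coupling to the
current intersection, until the merged sector reaches the size of the
smaller parent. Ties break toward the lowest column index, making the
merge deterministic.

## Evaluation suite

* **Internal correlation** — the sector's mean off-diagonal coupling
  against 1000 equal-size site sets drawn from the analyzed (kept)
  sites; reported with the resample mean, SD and the empirical p-value
  (fraction of draws at least as large).
* **MDI entropy** — the KL divergence (nats) between the empirical
  joint distribution of a site group and the maximum-entropy model
  with the same single-site marginals, fitted by generalized iterative
  scaling. Because the constraints are single-site marginals, the
  maxent model factorizes over columns and the scaling updates act on
  per-column factors at full strength (the per-column state indicators
  are mutually exclusive features), so no joint state space is ever
  enumerated and groups of any size are exact. Gaps count as a state.
  Fitted marginals are asserted against the empirical ones at
  convergence. An earlier variant restricted the model support to
  observed sequence patterns for large groups; that approximation
  collapses the joint MDI when patterns are nearly unique and was
  abandoned for the factor-form fit.
* **Independence test** — for disjoint sectors A, B: MDI(A) + MDI(B)
  versus MDI(A∪B), plus a random expectation: the mean of
  MDI(A′) + MDI(B′) over 100 random re-splits of A∪B into groups of
  the original sizes. For truly independent sectors the true split's
  sum equals the joint value while random splits hide cross-group
  structure inside the groups, so a joint MDI above the random
  expectation supports independence. Note the plug-in estimator is
  support-limited: with S sequences the empirical joint entropy cannot
  exceed ln S, which biases MDI of large groups upward and opens an
  additivity gap of a few percent even for independent sectors at
  realistic S; the clean additivity regime (deterministic sector
  columns) is used where exact additivity is asserted.
* **Evolutionary rates** — Rate4Site output is parsed (never
  re-implemented); per-sector mean normalized rate and fraction of
  negative-rate (slower-than-average) sites, with sector columns mapped
  through the template numbering when present.
* **Evolutionary independence** — the S×S matrix of pairwise sequence
  identity over the sector's columns (gaps always mismatch) is
  column-centered and the sequences split by the sign of their first
  principal component coordinate; a constant or spectrum-tied matrix is
  flagged degenerate with a warning.
* **Sensitivity/PPV** — each reference sector is matched to the single
  predicted sector containing most of its sites; sensitivity and PPV
  are percentages of the reference and of the matched prediction
  respectively, with unrecovered reference sites listed as lost.

## Synthetic study conditions

The default generator (`default_spec`) draws 300 sequences × 80
columns with two 12-site sectors at fixed interleaved positions,
ρ = 0.9 and independent binary latent traits: each sequence draws one
state per sector, and each sector column shows its state-specific
consensus residue with probability ρ, otherwise a uniformly random
residue. Noise columns each have a random consensus residue shown with
a per-column conservation drawn from U(0.05, 0.5) — a weakly conserved,
high-entropy background typical of surface positions — and gaps are
injected uniformly at rate 0.01. Everything is reproducible from the
spec seed.

What passing on this generator shows: the pipeline separates genuinely
coupled blocks from independent background at realistic conservation
levels and sample sizes. What it does not show: robustness to
phylogenetic correlation (no tree), to alignment errors, or to the
graded couplings of real families, where sector boundaries are soft and
the selection thresholds matter more.

## Problem sizes and defaults

The shipped tests and the acceptance script run the default conditions
above (and 20 uncoupled replicates for the null-calibration check);
one full fit — including the 100-shuffle null — takes about 1.5 s on a
single CPU at these sizes, and the coupling pipeline scales as
O(S·(20L)²) per (shuffled) alignment via a sparse one-hot cross-product.
Alignments the size of the classic serine-protease family (a few
hundred sequences, ~223 template-mapped columns) run in minutes.

## Known limitations

* The exact printed forms of the weighting equations in the source
  method are not recoverable from the available text; the SCA-style
  log-odds weight plus Frobenius reduction implemented here is a
  reconstruction (isolated behind single functions) validated against
  its own brute-force oracle and the method's downstream behavior, not
  against the original typography.
* The selection thresholds r0/p0/p1 have no published values; the
  defaults here are the package's own calibration.
* The factor-retention rule is lenient for the top eigenvalue (see
  above); users wanting a conservative factor count should compare
  λ_i against max(E) themselves — both the spectrum and E are on the
  results object.
* MDI plug-in estimates of large site groups are support-limited at
  small S (joint entropy capped near ln S); compare against the random
  re-split expectation rather than reading the additivity gap as exact.
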