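# Methods

## Statistical model

Expression is modelled per dataset as ordinary least squares with an
intercept on additive allele dosages,

    y_i = β₀ + Σ_v β_v g_iv + ε_i,  ε_i ~ N(0, σ²),  g_iv ∈ {0, 1, 2}.

Each probe is standardized (mean 0, standard deviation 1, with the n−1
denominator) before any modelling, so coefficients are on the
standardized-expression scale and datasets are comparable.  Inference per
fit: two-sided t tests per term, an F test against the intercept-only
model, adjusted r² = 1 − (1−r²)(n−1)/(n−p−1), and the Gaussian profile
log-likelihood ℓ = −(n/2)(ln(2π·RSS/n)+1), which makes the nested
likelihood-ratio statistic equal to n·ln(RSS_small/RSS_large).

Numerics: coefficients come from `numpy.linalg.lstsq` (SVD) and the
parameter covariance from an economic QR factorisation; the cross-product
matrix is never inverted explicitly.  Exact rank deficiency is detected
(incremental column ranks) and reported with the offending columns rather
than silently regularised.  Fits are complete-case; the retained sample ids
are recorded on the fit and every model comparison refuses mismatched
sample sets.

## Model comparison

* **Nested**: LRT with χ²(Δp) reference.  The χ² calibration is the
  default; an F-change calibration (`lrt_f_change`) is available for
  small-sample work.  For a single added column the LRT statistic is
  asymptotically the squared t statistic of that column, which the test
  suite checks.
* **Non-nested**: Davidson–MacKinnon J-test.  To test model A's adequacy
  against rival B, B is fitted, its fitted values ŷ_B join A's design as
  one proxy regressor, and the proxy coefficient's two-sided t P value is
  reported.  Both directions are always computed and never averaged; the
  test is asymmetric by construction.  If the proxy lies in the span of the
  base design the comparison is degenerate and reported as such.
* **Verdict labels**: n.s. / * / ** / *** / **** at P thresholds
  0.05 / 0.01 / 0.001 / 0.0001.

No multiple-testing correction is applied anywhere; all P values are raw.

## Forward-entry selection

Candidates are the LD-pruned panel (genotypic r², squared Pearson
correlation of dosage columns, threshold 0.90; greedy keep-rule prefers
declared-functional variants, then higher minor-allele frequency, then
smaller genomic position, so of a high-LD pair the more informative variant
survives, and a functional variant is never silently pruned).  Selection
starts from the intercept-only model; each step adds the candidate with the
smallest nested-LRT improvement P (ties: larger |t| of the entering term,
then position, then id) while that P < α_entry.  After each entry the model
is refitted; if any term's P ≥ α_stay the entry is rolled back and
selection stops (`term_lost_significance`).  A continue-without-candidate
mode exists behind `on_term_loss="continue"` for exploration; the stop rule
is the default analysis behaviour.  Defaults α_entry = α_stay = 0.05, both
configurable.

Unadjusted stepwise entry at α = 0.05 over m null candidates admits a
spurious term with probability ≈ 1−0.95^m per dataset — a property of the
procedure, not of this implementation.  The bundled four-study fixture
configuration therefore runs its selection at α = 0.001, chosen a priori so
that the familywise spurious-entry probability across its four datasets and
~10 effectively independent null candidates stays below ~5% and the
fixture's architecture-recovery patterns are attributable to signal, not to
stepwise overfitting.  The library default remains 0.05.

An exhaustive best-subset search (`_exhaustive_best_subset`) exists purely
as a validation oracle: order-free enumeration of all subsets up to size 4,
admissible when every term P < α_stay, terminal when no admissible
one-variant extension improves the fit at α_entry, ranked by model F P.
Greedy forward entry can disagree with it when the greedy path grows past
the oracle's size cap; the validation battery measures the agreement rate
(≥ 90% required) rather than assuming identity.

## Probe handling

Pairwise probe r² is the squared Pearson correlation over shared samples
(invariant to affine transforms of the raw values).  The representative
group is found by greedy agglomeration: from every seed pair with
r² ≥ `min_mean_r2` (default 0.5), repeatedly add the probe with the highest
mean r² to the group as long as both that candidate's mean r² to the group
and the group's mean pairwise r² stay above the threshold; the maximal
group wins (size, then mean r²).  Requiring the candidate itself to be
group-coherent keeps weakly related probes from diluting a large group —
without it, a tight 8-probe group would absorb uncorrelated probes until
the group mean decayed to the threshold.  Composites are arithmetic means
of standardized members; cross-study composites use the intersection of
sample ids and refuse partial overlap unless `allow_partial` is set.
Display coordinates use classical (Torgerson) MDS on d = √(1−r²) — a
deliberate display-only approximation to nonparametric MDS; perfectly
correlated probes coincide.

## EM haplotype phasing

Haplotype frequencies over ≤ 12 tag variants are estimated by
Excoffier–Slatkin expectation–maximisation under Hardy–Weinberg: each
sample's unphased genotype is a mixture over its 2^(h−1) compatible
haplotype pairs (h = heterozygous sites), the E-step computes pair
posteriors from current frequencies, the M-step re-estimates frequencies
from expected counts.  Uniform initial frequencies over
observed-compatible haplotypes; convergence when the log-likelihood
improves by < 1e-8; hard cap 10,000 iterations (non-convergence raises,
reporting the last delta); the log-likelihood is checked to be
non-decreasing every iteration.  Per-sample output: the most probable
diplotype with its posterior, and posterior-expected dosages (which sum to
2 per sample).  Haplotype-trait regression uses hard (most-probable)
0/1/2 counts by default, with expected dosage as a labelled alternative;
the sum-to-2 identity makes joint regression on all haplotype dosages rank
deficient, which the package detects and refuses with an explanation.
Coalescent-prior phasing is out of scope; for desk-scale tag sets the EM
maximum-likelihood point is verified against a grid search.

## Association

Haplotype and single-variant associations are univariate OLS on 0/1/2
dosage; 95% CIs use the t distribution with n−2 df.  Single variants are
oriented to minor-allele counts measured in the analysed samples, recorded
on the result.  Figure-style panels rescale coefficients per dataset by the
maximum absolute coefficient (CI endpoints scale identically, preserving
sign and zero-crossing); rescaled values are display-only.

## Synthetic data

`simulate_genotypes` draws two independent haplotypes per sample from a
frequency-weighted pool (Hardy–Weinberg random mating, no inbreeding,
recombination or mutation) and records the true diplotypes.
`simulate_expression` builds a latent signal Σβ·dosage + N(0, σ) and gives
each probe independent Gaussian probe noise; expression is generated
directly on the standardized scale since the analysis standardizes anyway.
Noise is calibrated analytically: the genetic variance of an effect vector
is 2·Var_hap(Σβ·allele) under the pool frequencies, so a target
genotype-explained variance h² fixes σ.

The default pool has six haplotypes (H1–H6; frequencies .28/.05/.21/.17/
.13/.16) over eight tag variants, each rarer haplotype carrying a private
tag so that phase is essentially unambiguous, plus 22 extended variants: 18
exact copies or allele flips of tags (r² = 1 pairs that pruning must
collapse, emulating a dense cis block) and four distinct-pattern survivors,
one of them an indel.  Pruning at 0.90 collapses 30 variants to 12.

The four-study fixture emulates the shape of published
lymphoblastoid-cell-line experiments: three studies (57/60/58 samples,
17/2/1 probes) observe prefixes of one simulated 60-sample collection — the
same cell lines with per-study dropout — and a fourth (181 samples, 3
probes) observes an independent collection.  The shared-collection causal
architecture is {t6: +1.0, t3: −0.6}; the independent collection replaces
t3 with the functional promoter indel (−0.7) while keeping the lead variant
t6, which is carried only by the risk haplotype H6.  Haplotype H2 is
deliberately decoupled from the shared-collection causal variants (it
carries neither and is rare), giving a known low model–haplotype r² regime.
Per-study latent h² targets are 0.31/0.80/0.55/0.28.  The 17-probe study
has 8 signal probes whose probe noise is set by the attenuation law
r²_pair = (Var(latent)/(Var(latent)+σ_p²))² to a pairwise r² of 0.79, 7
uncorrelated exonic probes and 2 intron-targeting probes (exercising the
intron filter); the single-signal studies use probe noise at 15% of the
latent standard deviation.

What the fixture does **not** emulate: a shared non-genetic cell-line
component across studies.  Studies share only the genetic signal, so the
expected cross-study probe r² is the product of the two studies' h²
(≈ 0.25 for the S-vs-K pair), lower than real same-cell-line experiments
show; the fixture configuration accordingly accepts cross-study
representative probes at r² ≥ 0.15.  Passing tests on this fixture
demonstrate recovery of haplotype-borne additive architecture under
Gaussian noise — not robustness to batch effects, non-normal expression,
population structure or genotyping error.

## Validation battery and problem sizes

The acceptance script and the acceptance test suite recompute, at a given
seed: OLS vs normal-equation agreement (100 instances, n ≤ 50, p ≤ 5,
tolerance 1e-8); forward-entry vs exhaustive-subset agreement (50 panels,
n = 200, 15 independent variants, ≤ 3 causal effects from 1.0/0.7/0.4);
type-I error of the 1-df LRT and of the J-test (2,000 replicates each,
n = 200, band [0.03, 0.07]); J-test power under model A at h² = 0.3,
n = 200 (500 replicates, ≥ 95% rejection of the false rival at P < 0.01,
reverse direction at nominal rate); heritability recovery at n = 10⁴
(targets 0.30 and 0.80, ± 0.05); EM-vs-grid-search frequency agreement
(≤ 1e-3; the grid refines to step 2e-4) and 8-tag frequency recovery within
3 SE at n = 200; 95% CI coverage over 2,000 null replicates ([0.93, 0.97]);
and the fixture patterns above.  These sizes keep the full battery around
one minute while leaving each band's Monte-Carlo error well inside its
tolerance.

## Known limitations

* Stepwise selection is not a consistent model-selection procedure;
  reported per-term P values are conditional on the selected model and
  optimistically biased.  The package reports them raw, as is conventional
  for this analysis style, and documents the caveat here.
* The LRT uses the asymptotic χ² reference; at n ≈ 60 it is mildly
  liberal (the type-I band check covers n = 200).
* EM phasing assumes Hardy–Weinberg and unrelated samples; it has no
  recombination model and is restricted to ≤ 12 tags by pair enumeration.
* Multi-allelic sites, sex chromosomes and genotype imputation are out of
  scope; missing dosages are handled pairwise-complete for LD and
  complete-case per fit.
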