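# Methods

## Substitution model

All fitted models are time-reversible Markov codon models on the 61
sense codons of the standard nuclear code.  For codons *i* and *j*
differing at exactly one nucleotide position,

    q_ij = (1/C) · π_j · κ^[transition] · α^[synonymous] · β^[nonsynonymous]

and `q_ij = 0` for multi-nucleotide changes.  κ is the
transition/transversion rate ratio (single, shared by all mixture
categories and estimated by ML); α and β are the synonymous (dS) and
nonsynonymous (dN) rate factors, with ω = β/α.  The global scale `C`
is chosen so that the process at the **reference rates α = β = 1**
(with the current κ and π) has unit expected substitution rate per
codon site; branch lengths are therefore expected substitutions per
codon site at the neutral reference.  This convention makes the
mean-one constraint on the DUAL model's dS distribution (below) the
exact resolution of the scale confound between site rates and branch
lengths.

Stationary frequencies π default to **F3×4** (products of
position-specific nucleotide frequencies, renormalized over sense
codons) computed empirically from the alignment with a pseudocount of
0.5 per nucleotide per codon position, which keeps every sense-codon
frequency strictly positive on small alignments.  Empirical per-codon
(F61) and uniform frequencies are available.

Transition matrices are computed by eigendecomposition of the
symmetrized generator `diag(√π) Q diag(1/√π)`; the simulator uses the
same code path, so simulator and likelihood engine agree by
construction.  Eigendecompositions and the resulting
`P(t) = exp(Qt)` are batched across mixture categories and branches.

## Likelihood

Felsenstein pruning over compressed site patterns with per-internal-node
rescaling (log scale factors accumulated per pattern and category).
Mixture likelihoods combine per-category pattern log-likelihoods by
log-sum-exp with the category weights.  Gap and `N` characters — and
codons mixing gaps with bases — are treated as fully missing
(marginalized); an all-gap site contributes exactly zero
log-likelihood.  A pattern with zero likelihood under every category
raises a degenerate-input error rather than returning −inf.

The pruning implementation is checked against brute-force summation
over all internal-node codon assignments on trees of up to 5 taxa
(agreement to 1e−8) and against `scipy.linalg.expm` for single
transition matrices.

## Model fitting

Optimization is bounded quasi-Newton (L-BFGS-B) on log-transformed
rates and logit/softmax-transformed proportions, with multi-start
support: restart *r* > 0 adds uniform jitter of half-width 0.5 to every
free coordinate (≈ ×exp(U(−0.5, 0.5)) on rates), and the restart with
the highest log-likelihood wins; identical seeds give bit-identical
results.  Default 3 restarts in the pipeline, with convergence and
restart logs recorded on every fit; non-converged fits are flagged,
never silently dropped.

* **M0** jointly estimates κ, ω and branch lengths: a global tree
  scale first, then one sweep of per-branch Brent refinement, then a
  κ/ω re-polish.  M0's branch lengths are **fixed** for all site-model
  fits (the configurable alternative — using them as starting values —
  is deliberately not the default, for speed and stability).
* **M3(k=3)** free ω classes and proportions; `k=1` reduces exactly
  to M0.  Near-equal categories are reported with a `category-collapse`
  flag, not treated as errors.
* **M7/M8** discretize Beta(p, q) into 10 equal-probability categories
  at quantile midpoints; M8 adds a class at ω_s ≥ 1 with proportion
  p1.  p1 estimates under 1e−3 carry a `boundary-p1` flag (the
  chi-square reference for the M7-vs-M8 LRT is then conservative).
* **DUAL(3×3)** draws each site's (dS, dN) pair from the product grid
  of an independent 3-category dS distribution (constrained to mean
  one) and a 3-category dN distribution with absolute rates.  Fits are
  seeded from the M3 solution (dN side) with a mild dS spread, then a
  two-stage optimization: dS block first, full joint polish second.
  `k_syn=1` reduces exactly to M3.  κ may be held fixed at a previous
  estimate (`kappa=...`): κ is well identified already under M3, and
  profiling it preserves the LRT's nesting property because the M3
  optimum remains feasible for DUAL.

## Decision rules

* LRTs use `statistic = max(0, 2ΔlnL)` against chi-square upper tails
  with df 4 (M0 vs M3, k=3), 2 (M7 vs M8) and 4 (M3 vs DUAL: two free
  dS rates after the mean-one constraint plus two free weights).  No
  boundary/mixture corrections are applied (standard practice for
  these tests); boundary situations are flagged instead.  An
  alternative lnL below the null by more than 1e−6 triggers a warning
  and clamping — an optimizer-failure signal.
* **SRV+** ⟺ p(M3 vs DUAL) < α and CV(dS) > 1e−6.  The CV condition
  excludes ML artifacts in which the LRT prefers the richer model
  while the fitted dS distribution is degenerate; the strictly-positive
  condition is operationalized with a numeric tolerance because exact
  zeros are float artifacts.  Extreme-SRV flags are recorded at
  CV ≥ 0.8 and CV ≥ 1.0 regardless of the call.
* **PS+** ⟺ (1) p(M0 vs M3) < α, p(M7 vs M8) < α and ω_s(M8) > 1;
  (2) p1 · n_sites ≥ 1 (the positive-selection class covers at least
  one site); (3) the DUAL fit contains at least one grid cell with
  dN_i/dS_j > 1 whose prior weight times n_sites is ≥ 1.  Condition
  (3) is this package's operationalization of "the SRV-aware model
  also supports PS"; it is deliberately symmetric with condition (2).
* α = 0.05 by default, 0.01 available.
* The divergence filter removes families whose amino-acid tree length
  divided by (2T−3) **strictly exceeds** 2 expected substitutions per
  site per branch; exactly 2 is kept.  When no amino-acid tree is
  supplied the pipeline applies the filter to the input (codon) tree
  and records that provenance.

## Codon-usage indices

* **GC/GC3**: G+C fraction over non-gap bases / third codon positions.
* **ENC** (Wright): per synonymous family, homozygosity
  `F̂ = (nΣp² − 1)/(n − 1)` in counts mode or `F = Σp²` in frequencies
  mode; `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` with degeneracy-class
  means.  Families observed fewer than twice are imputed by their
  class mean; an absent 3-fold class by the average of the 2- and
  4-fold means; any other absent class by the mean of available class
  means.  Results clipped to [20, 61].
* **CBI**: `(N_opt − N_rand)/(N_tot − N_rand)` over codons of
  degenerate families with at least one declared optimal codon,
  `N_rand` the expectation under uniform synonymous choice.  The
  optimal set is user-supplied; a deterministic toy set (first codon
  of each family) is bundled for tests and examples — absolute CBI
  values are only comparable within one optimal-set choice.
* **TPI**: per amino acid, the observed number of isoacceptor-tRNA
  switches along the codon occurrence order is normalized linearly
  between the exact minimum (`#distinct labels − 1`) and maximum
  (`min(2(n − m_max), n − 1)` for largest multiplicity `m_max`)
  achievable for that label multiset, giving +1 for perfectly blocked
  (autocorrelated) and −1 for perfectly alternating usage; the index
  is the occurrence-weighted mean over amino acids whose bounds
  differ.  Both bounds are verified by exhaustive enumeration in the
  tests.  The default codon→tRNA mapping groups same-amino-acid codons
  sharing their first two bases when the third is a pyrimidine (T/C
  wobble) and gives third-position A and G their own tRNAs; any
  mapping can be supplied as a TSV.

## Association analyses

Genes belong to all ancestors of their directly annotated categories
(closure over a validated DAG; diamond paths counted once).
Enrichment uses one-sided Fisher exact tests in both directions, with
Benjamini–Hochberg FDR applied within each direction family
separately.  Group comparisons use a percentile bootstrap of the
difference in means (both groups resampled with replacement;
significant when the central 95% interval excludes zero).  The
separation ratio is weighted between-group variance over pooled
within-group variance; zero within-group variance returns an
infinite-F flag.  Spearman correlations use midranks with the
large-sample p-value.  Category dissimilarity over SRV+ gene sets is
the Jaccard form `d_AB = 1 − N(A∩B)/N(A∪B)` — the minimal formula
satisfying both anchored endpoints (0 for identical SRV+ sets, 1 for
disjoint ones); this choice is recorded here because other forms
(e.g. overlap coefficient) satisfy the endpoints too.  Clustering is
average-linkage agglomeration with categories sorted lexicographically
beforehand so tied merges resolve deterministically.

## Synthetic data

The generator emulates small curated protein-family alignments: 4–30
taxa, 50–500 codons, random-join (coalescent-shaped) topologies with
i.i.d. exponential branch lengths (default mean 0.15 expected
substitutions per codon site per branch), uniform root codon
frequencies, κ = 2, and a purifying-dominated default ω distribution
(0.05/0.3/1.0 at weights 0.5/0.35/0.15).  Planted SRV uses a
symmetric three-point mean-one dS distribution (1−d, 1, 1+d at
weights ¼, ½, ¼, CV = d/√2); for CV ≥ 1/√2 an asymmetric three-point
form with a zero-rate category is solved numerically for the exact
requested CV.  Annotation DAGs, planted enrichments (log-odds shift
inside one category) and attribute tables (class mean + Gaussian
noise) cover the downstream machinery.  All randomness flows through
one seeded generator per call; identical specs give identical outputs.

What the simulator does **not** emulate: indels and alignment error,
among-site nucleotide-level rate variation below the codon model,
non-reversible or non-stationary composition, selection on codon
usage (the usage indices of simulated data are uninformative noise),
and correlated rates along the sequence.  Passing tests therefore
demonstrate correctness and calibration of the machinery under the
model, not robustness to real-data violations of it.

## Validation experiments and problem sizes

The statistical suite uses these designs (all seeded, fixed in
advance):

* SRV LRT null calibration: 100 constant-dS families (8 taxa,
  200 codons); rejection rate of M3-vs-DUAL at α = 0.05 must stay
  within [0, 0.10] (conservative behaviour is acceptable; the mixture
  boundary makes the χ²₄ reference conservative).
* CV recovery: 10 families at true dS CV = 0.6 (8 taxa, 500 codons).
  Note: the ML estimate of CV from a 3-category general discrete
  distribution is heavy-right-tailed at this information level — the
  global optimum often contains a near-zero-weight extreme-rate
  category.  The mean estimate over these conditions runs above the
  generating CV (see the test suite for measured values); the LRT
  calls are unaffected because such categories carry negligible
  likelihood mass.
* Neutral recovery: M0 on a β = α simulation (6 taxa, 300 codons);
  the acceptance script averages 12 replicates (single-replicate SD
  of ω̂ ≈ 0.17) to reduce Monte Carlo error.
* Power and identifiability checks run at reduced replicate counts
  (3–6 per condition, 200–250 codons) chosen to keep the default
  serial test run practical; they assert orderings (more SRV ⇒ more
  rejections; true model beats M0 on its own output), not rates.
* Enrichment: planted odds-ratio-5 category among 50 (500 genes)
  recovered after BH in ≥ 95/100 seeds; bootstrap significance rate
  for equal distributions within the exact binomial band around 5%
  over 200 runs.

## Numerical choices and edge cases

* Optimizer bounds: κ ∈ [0.05, 50], ω and dN rates ∈ [1e−8, 60],
  dS raw rates ∈ [1e−4, 50] (before mean-one normalization), weight
  logits ∈ ±12, L-BFGS-B ftol 1e−11 on the negative log-likelihood.
* Transition-matrix entries are clipped at 0 (eigendecomposition can
  produce −1e−15-scale negatives); rows re-normalized only in the
  simulator, where exact stochasticity matters for sampling.
* Alignments with fewer than two distinct rows are fitted but flagged
  `uninformative`.
* The pipeline isolates per-family failures, excludes
  convergence-failed families from downstream tables, and counts both
  in the run manifest; reruns with the same config and seed are
  byte-identical, and `--resume` reuses cached per-family fit payloads.

## Known limitations

* Absolute log-likelihoods depend on the frequency parameterization
  (F3×4 vs F61) and the κ treatment and are not comparable across
  conventions; only differences within one convention are meaningful.
* CV point estimates from 3-category discrete fits are noisy and
  upward-skewed on small families (see above); the SRV call couples
  the CV to the LRT precisely to avoid over-reading them.
* No per-site empirical-Bayes identification of selected or
  rate-shifted sites; calls are family-level.
* No multiple-testing correction across families (classification at
  fixed α; only enrichment p-values are FDR-adjusted), matching the
  pipeline's decision-rule design.
* Branch lengths are fixed at M0 estimates for all site models; under
  strong SRV the M0 lengths are mildly misspecified, which the DUAL
  dS mean-one constraint absorbs only on average.
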