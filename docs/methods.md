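# Methods

## Abundance model

The pipeline treats a dereplicated MAG's gene content as fixed and its
abundance as sample-specific. Hit counts `N_ij` (MAG × family) are computed
once, from hmmsearch per-target tables filtered at full-sequence
E ≤ 10⁻⁵ (inclusive), counting each distinct protein once per family so a
multi-domain protein does not inflate its family (a `per_domain` mode is
available). Sample specificity enters only through the coverage matrix
`A_ik`. The per-sample family abundance is

    T_jk = Σ_i A_ik · N_ij / (L_j · G_i)

with `L_j` in kilo-match-states and `G_i` in megabases. These units are the
model's convention; no additional per-sample read-depth rescaling is applied
— sequencing-depth normalization is regarded as carried by the mean-coverage
estimates themselves (CoverM mean mode), and an optional total-coverage
rescaling would simply multiply each sample's column by a constant, which
Bray–Curtis, PLS-DA and the t-test are either invariant to or monotone in.

Contribution fractions come in two flavours: count-based
`N_ij / Σ_i N_ij` (optionally restricted, per sample, to MAGs with
`A_ik > 0`) and coverage-weighted `H_ijk / T_jk`. Group-level source
summaries use the coverage-weighted form, because "which genera supply this
enzyme in this cohort" is a question about realized abundance, not genome
counts. Undefined cells (zero denominator) are flagged and reported as 0,
never NaN.

## Screening

Retention requires total abundance strictly greater than 16 and presence in
strictly more than 5 subjects; both thresholds are configurable and the
strict inequality is deliberate. The two-group screen then combines:

* **PLS-DA.** NIPALS PLS1 on column-centered `T`ᵀ against the {0,1}-encoded
  group (case = 1), 5 components, stratified 10-fold CV with a fixed seed,
  hard decision at 0.5. With a single response NIPALS needs no inner
  iteration; the first weight vector is exactly the normalized covariance
  `X'(y − ȳ)`, which the tests exploit as an oracle, and component scores
  are mutually orthogonal by construction. Per-feature significance uses the
  VIP score with a label-permutation null and the add-one estimator
  `P = (1 + #{VIPπ ≥ VIPobs}) / (1 + nπ)`. This test is exact (exchangeable
  null) but deliberately conservative on raw abundance data: families whose
  variance is inflated — as planted case-enriched families are — also reach
  high VIP under permuted labels, so the VIP gate passes only the strongest
  distinguishers. The t-test/FDR gate, not the VIP gate, carries the
  sensitivity guarantees.
* **t-test + BH.** Two-sided unpaired pooled-variance t per family (Welch by
  flag), Benjamini–Hochberg step-up q-values (statsmodels), differential
  flag at q < 10⁻⁴ by default. Zero-variance rows with equal means take the
  degenerate limit t = 0, p = 1 and are flagged. No abundance transform is
  applied by default; log/CLR preprocessing can be applied upstream by the
  caller.
* **Candidates** pass both gates, ranked by total abundance; "outliers" are
  candidates above Q3 + 1.5·IQR of the candidate abundances (Tukey fence),
  the rule used to single out standout enzymes for validation.

## Ordination statistics

Bray–Curtis dissimilarity (all-zero pairs → 0 by convention), centered-SVD
PCA with a deterministic sign rule (largest-magnitude loading positive),
PCoA via scikit-bio with negative eigenvalues discarded. PERMANOVA
partitions squared distances (`SS_T = Σ_{k<l} d²/n`, within-group analogue
per group) into a pseudo-F with a free label-permutation P; note that for
semimetric distances such as Bray–Curtis, `SS_among` can be marginally
negative on unstructured data, so R² is bounded in [0, 1] only for metric
inputs. The Procrustes test is symmetric: both configurations centered and
scaled to unit Frobenius norm, optimal rotation via SVD,
`m² = 1 − (Σσ)²`, `r = √(1 − m²)`, P by permuting sample rows of one
configuration. Defaults pair the PCoA (Bray–Curtis) of the community
coverage profiles with the PCA of the family abundances, first two axes;
a narrower configuration is padded with zero axes. All permutation
procedures are bit-reproducible given a seed, with add-one P-values whose
floor is `1/(nπ + 1)`.

## Library preparation

Length QC keeps 300–3000 aa inclusive (the conventional reading of a
"between" range). Pairwise identity is computed from a global alignment with
match 1 / mismatch 0 / gap −1 scoring, identities divided by alignment
length; CD-HIT's shorter-sequence denominator is available via an option,
and the alignment-length default is a documented deviation that is
negligible at the 80% threshold for similar-length proteins. Greedy
clustering processes sequences longest-first (ties by id) and joins the
first representative matched at ≥ threshold — the CD-HIT strategy — and is
deterministic for a given input set. MAFFT and hmmbuild are invoked, not
reimplemented; their exact commands are recorded in a provenance JSON.

## Simulator

The generator emulates a two-group cohort after assembly/binning:
genome lengths ~ U(1, 8) Mb, profile lengths ~ U(300, 1500) match states,
background hit presence ~ Bernoulli(0.05) with geometric counts (p = 0.7),
per-MAG characteristic log-depth μᵢ ~ N(0.5, 1), coverage
`A_ik = Bernoulli(0.8) · LogNormal(μᵢ, 0.5)`, genus labels drawn from a
front-loaded pool of common gut genera. Defaults use 80 case / 86 control
subjects, 300 families, 30 planted. Planted families get dedicated producer
MAGs (3 each) whose coverage is multiplied by the effect size in case
samples only; dedicated producers carry hits only for their family and
background MAGs carry none on planted families, so the planted effect
cannot leak into null families and sensitivity/FDR are well-defined. The
zero-inflation (0.2) and lognormal dispersion (0.5) were fixed once as
moderate values for prevalent, dereplicated species representatives — small
enough that a two-fold planted effect is recoverable at n = 40 + 40, which
is the regime the recovery guarantees are stated for.

Ground-truth genus fractions are analytic expectations
(`E[A_ik] = (1 − zi) · exp(μᵢ + σ²/2)`, boosted for producers in cases)
rather than recomputations from the realized matrices, so the source-
tracking comparison is an estimation check with genuine sampling error.

What the simulator does *not* emulate: compositional coupling between MAGs,
read-level noise in coverage estimation, chimeric or incomplete bins,
correlated families sharing producer genomes, and batch structure. Passing
the planted-recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to assembly
artifacts or confounding in real cohorts.

## Numerical choices

Rank-deficient PLS truncates components with a warning at a relative
tolerance of 1e-12 on the residual covariance. The E-value filter is
inclusive (≤). Ties in candidate ranking and genus summaries break
alphabetically; sorts are stable (mergesort). Matrices are written at
`%.17g` so TSV round-trips are bitwise. Problem sizes in the test-suite
(hundreds of families, tens-to-hundreds of samples, ≤ 999 permutations)
were chosen as the smallest at which the asymptotic claims (calibration
CIs, KS uniformity, recovery rates) are statistically meaningful.

## Known limitations

The VIP permutation gate is conservative under variance heterogeneity (see
above). PERMANOVA assumes free exchangeability (no strata). Identity from
the first optimal alignment can differ between co-optimal alignments in
rare ties. The pipeline consumes, and does not verify, upstream MAG quality
and taxonomy calls.
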