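# Methods

This document records the statistical model, the numerical choices and the
known limitations of the `csannot` workflow.

## 1. Synthetic data model

### Compound universe and network

`generate_network(n_compounds, n_pathways, seed, ...)` builds:

- **Pathways** as linear reaction chains over contiguous compound blocks
  (equal sizes up to rounding), plus occasional single-reaction cross-links
  between pathways (`cross_link_prob`, default 0.15 per pathway).
- **Masses** rejection-sampled in 100–850 Da so that all H⁺/Na⁺/K⁺ adduct m/z
  values of non-decoy compounds are separated by > 0.02 Da and stay clear of
  the internal standard.
- **Decoys** (`decoy_fraction`): database-only compounds that emit no peaks
  but are placed within the search tolerance of another pathway's compound's
  adduct m/z, so real peaks acquire ambiguous candidate sets. Decoy/target
  pathway membership always differs, making context the only disambiguator.
- **Xenobiotics** (`xenobiotic_fraction`, default 5%) flagged for exclusion at
  the annotation stage.

### Concentrations

Per subject, log-concentration of compound *i* in pathway *p* is

    log c_i = base_i + σ·(√ρ · a_p + √(1−ρ) · ε_i)

with pathway activity `a_p` and residual `ε_i` standard normal, so ρ is the
within-pathway correlation of log-concentrations (default 0.6; ρ = 0 gives
fully independent compounds for null calibration). Disease effects multiply
affected-set concentrations by a constant (default 0.5) in case groups.

### Spectra

Each compound emits its chosen adducts with per-(compound, adduct) response
factors; a fraction of H⁺ parents (10%) also emit a fragment peak at exactly
0.5× the parent intensity. Peaks get multiplicative log-normal measurement
noise (σ = 0.2), Gaussian m/z jitter (1 mDa), and a detection limit.

The chemical background is **reproducible across injections**: background m/z
positions and base intensities are drawn once per cohort (rejected within
0.02 Da of any theoretical signal) and only intensity-jittered per sample.
This mirrors real spectra, where the background is a stable population of
low-abundance ions — the property that makes a rank-statistic window divisor
a usable intensity reference. The default density (9 000 background peaks per
spectrum) puts a few hundred peaks in every 50 Da window, so the rank-150
normalization divisor is a mid-order statistic rather than a window minimum;
at sparse densities the divisor degenerates to an extreme order statistic and
destroys cross-sample correlation structure after normalization.

## 2. Preprocessing

1. **Recalibration**: single-point multiplicative m/z correction to the
   internal standard at m/z 423.169 (closest peak within ±0.05 Da; intensity
   breaks ties).
2. **Normalization**: each peak is divided by the 150th most intense peak in
   the 50 Da window centred on it; windows with fewer than 150 peaks use
   their minimum. All divisors are computed before any division, making the
   result exactly invariant to global per-spectrum intensity scaling.
3. **Alignment**: pooled peaks sorted by m/z and cut at gaps > 5 mDa (single
   linkage); consensus m/z is the intensity-weighted mean; same-sample
   duplicates within a feature are summed.
4. **Filtering**: features detected (nonzero) in strictly more than 9 samples
   are kept.

## 3. Candidate search

Each feature's consensus m/z is matched against protonated, sodiated and
potassiated theoretical ions within an absolute tolerance (default 5 mDa),
sorted by |mass error|. Isotopologues, multimers and neutral losses are out
of scope.

## 4. Context-support annotation

### Correlation

Pearson correlation over **jointly nonzero** samples only (zeros are
non-detections, not measurements); entries with fewer than `min_pairs` (9)
complete pairs, or zero variance on them, are missing. Only the
candidate-bearing rows of the matrix are computed (rectangular block), since
the full matrix is quadratic in feature count.

### Context selection and the one-vote rule

Members are the top-k (30) candidate-bearing features by |r|, after removing
derivative peaks (|r| ≥ 0.85) — and, by default, after skipping any feature
whose candidate compound set duplicates an already selected member's
(`dedup_context`). The rationale: the Na⁺ and K⁺ ions of one compound
correlate near-perfectly with each other and enter the top-30 together, then
cast several identical context votes. A random same-size context cannot mimic
that coupling, so without de-duplication the observed score is over-dispersed
relative to its null (mean preserved, variance inflated) and the calibration
becomes anti-conservative. In measured null cohorts the de-duplication rule
cuts the false acceptance rate roughly in half. `dedup_context=False`
restores the plain sort-and-cut selection.

### Scoring

For candidate compound *c* of the tested feature, each CS member contributes
its minimum network distance from *c* to any of the member's candidates.
S_N counts members with distance in [1, N], N = 1..4 (cumulative; `exact`
mode counts distance == N). Distance 0 — the member's candidates include *c*
itself — is identity evidence (a derivative ion), not pathway context, and is
excluded; counting it would let a compound's own adduct peaks certify its
annotation circularly.

### Null calibration

300 random contexts of the same size are drawn per feature. Under the default
one-vote rule the null mirrors it exactly: features are scanned in a
uniformly random order with the same skip-duplicates rule, which under
exchangeability is the distribution of the observed scan applied to an
uninformative ranking (implemented via per-group minima of i.i.d. keys).
A generalized extreme value distribution is fitted to each N's null scores by
maximum likelihood (custom Nelder–Mead fitter; no SciPy distribution
machinery in the hot loop) and

    q_N = GEV-CDF(S_N − 0.5)

— the half-integer offset keeps the continuous CDF consistent with the
"random context scores *strictly lower*" semantics of the discrete empirical
fallback, which is used whenever the null has fewer than 6 distinct values
(a 3-parameter continuous fit is not meaningful on sparser support).

### Iteration and decision

Candidates with max_N q_N > 0.95 are provisionally accepted; before each next
iteration the candidate sets of provisionally accepted features are
restricted to their accepted compounds, CS membership (and the de-duplication
partition) is recomputed from the refined map, and scoring repeats — six
iterations in total, the context growing more competent each round. Finally
Z = −Φ⁻¹(max_N q_N); candidates with Z < −1.64 that are not xenobiotics form
the annotation set. Xenobiotic hits remain visible in the diagnostics table.

## 5. Group analysis

Per-feature two-sided Wilcoxon rank-sum tests compare the control group with
each case group, overall and within each sex stratum. The null distribution
is exact (full rank-sum distribution) when both groups have ≤ 10 samples and
the pooled values are tie-free, and a tie-corrected normal approximation
otherwise. Features significant at α (default 0.01) map to their accepted
compounds, which are tested for metabolite set over-representation with the
hypergeometric tail P(X ≥ k) against the population of all accepted
compounds; adjusted p-values are Benjamini–Hochberg (or Holm).

## 6. Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives
independent per-stage seeds (< 2³¹) from the master seed via
`numpy.random.SeedSequence`. Identical configuration and seed reproduce
byte-identical outputs. `scripts/acceptance.py --seed N --out f.json`
recomputes the headline metrics for any master seed.

## 7. Known limitations

- **Union over N levels**: acceptance fires when *any* of q_1..q_4 exceeds
  0.95. The four levels are dependent but not identical, so the per-candidate
  false acceptance rate under the null is above the nominal 5% (measured
  ≈ 6% with de-duplication on 100-sample null cohorts). Raising `accept_q`
  trades sensitivity for stringency.
- **Discreteness**: S_N takes few values when candidate sets are sparse; the
  GEV is a continuous surrogate whose tail behavior between attainable scores
  is interpolated. The strictly-lower convention plus the 6-distinct-value
  guard keep this conservative.
- **Correlation ≠ causation**: context support assumes biologically related
  metabolites co-vary. Strong technical covariation (batch effects) would
  inflate context for co-processed features; no batch correction is included.
- **Search scope**: only H⁺/Na⁺/K⁺ singly charged ions; isotopologues,
  multimers, in-source water losses etc. are not modelled, so the derivative
  flag at |r| ≥ 0.85 is the only guard against them.
- **ORA granularity**: enrichment uses the accepted-compound population, so
  pathways poorly covered by annotation are hard to detect regardless of
  effect size.
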