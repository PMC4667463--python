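# Methods

## Model

For one transcript, the normalized log-intensities `y` (one entry per
one-color measurement, or per two-color array after taking the log-ratio
`M = log R − log G`) follow the linear mixed model

```
y = X β + Z₁ u₁ + Z₂ u₂ + e
u₁ ~ N(0, G₁ σ₁²)      biological sample effects
u₂ ~ N(0, G₂ σ₂²)      blending effects, one per physical mixture
e  ~ N(0, I σe²)       residual technical error
```

so `V(y) = Z₁G₁Z₁'σ₁² + Z₂G₂Z₂'σ₂² + Iσe²`. The blending component
captures the technical imprecision of dividing RNA into aliquots: for a
pool of γ individuals whose aliquot weights have variance of order
σz²(γ−1)/γ³ around 1/γ, the marginal variance of the pooled log-signal is
approximately `σ₁²/γ + σ₂²(γ−1)/γ² + σe²` with `σ₁² = e^{σb²} − 1` and
`σ₂² = (e^{σb²} − 1)·σz²`, where σb² is the biological variance of
individual log-expressions. `G₂` is diagonal with entries (γ−1)/γ²; pools
blended once share one `u₂` entry across technical replicates, and γ = 1
samples carry none.

Two parameterizations of the biological term are interchangeable (equal
`Z₁G₁Z₁'`): *composition*, one effect per distinct member set with
`G₁[i,j] = |overlap|/(γᵢγⱼ)`, and *individual*, which resolves pools into
per-individual effects wherever the membership structure allows and
otherwise assigns a composite pool effect with prior variance 1/γ. The
fitting pipeline uses the individual parameterization internally because
its `G₁` is always diagonal and invertible (the composition `G₁` is
singular whenever a pool is exactly the average of individually measured
samples, which breaks the mixed-model-equation form of EM).

Fixed effects use reference-level dummy coding (first declared level is
the baseline); two-color rows are red-minus-green covariate rows with an
all-ones intercept absorbing the dye effect. Confounded treatment columns
raise an explicit rank error naming the aliased coefficients.

## Estimation: EM-REML

Variance components are estimated by EM-REML through Henderson's mixed
model equations with `λⱼ = σe²/σⱼ²`. Updates are the classical ones,

```
σⱼ² ← (ûⱼ'Gⱼ⁻¹ûⱼ + σe²·tr(Gⱼ⁻¹Cʲʲ)) / qⱼ        j = 1, 2
σe² ← y'(y − Xβ̂ − Σⱼ Zⱼûⱼ) / (n − p),
```

with `Cʲʲ` the corresponding block of the inverse MME coefficient matrix.
Convergence is declared when `‖B_prev − B‖ / ‖B‖ < ε` for the estimate
vector `B = (σ̂₁², σ̂₂², σ̂e²)` (the 2-vector for m1), with ε = 1e-8 and an
iteration cap of 1000. Defaults that matter:

* **Initialization**: σ̂e² starts at the OLS residual variance, both random
  components at half of it (scale-aware, strictly positive).
* **Boundary floor**: variances are floored at `1e-10·var(y)`; estimates
  that end on the floor are reported as exact zeros.
* **Boundary detection**: EM approaches a zero variance only polynomially
  (σ_{k+1} = σ_k + c·σ_k², c < 0), so a collapsing component would never
  meet the criterion. When a component falls below 0.01·‖B‖, its REML
  score at exactly zero (holding the others) is evaluated; a non-positive
  score means the restricted likelihood is maximized on the boundary, and
  the component is frozen at the floor. Frozen components are re-checked
  at convergence and released (at most twice) if the score turned
  positive.
* **Acceleration**: the EM map is wrapped in SQUAREM-type vector
  extrapolation — two EM steps, an extrapolated candidate, one stabilizing
  EM step, accepted only if the restricted likelihood does not decrease.
  Fixed points and the convergence criterion are unchanged; plain EM
  (`FitConfig(accelerate=False)`) is retained for diagnostics such as the
  monotonicity property test. Without acceleration the slowest geometric
  rates on the pooled design exceed 0.999 and fits need 10³–10⁴
  iterations.
* **Nested-likelihood repair**: on rare transcripts (~0.4 % under strong
  blending) the m2 EM converges at a local maximum below the m1 optimum,
  which would produce a negative likelihood-ratio statistic. The pipeline
  re-fits such transcripts warm-started from the m1 solution plus a small
  blending variance and keeps the better solution; EM ascent guarantees
  weak dominance of the nested optimum.

The per-transcript reference implementation (`em_reml_fit`) and the
batched fitter (`fit_transcripts`) perform the same iteration; the batched
path works on residual contrasts `w = K'y` (K an orthonormal null-space
basis of X'), eigendecomposes the biological covariance once per design
and handles the rank-q₂ blending term through the Woodbury identity, so
one EM sweep over all transcripts is O(m·n·q₂²) vectorized work. Batched
linear algebra introduces last-ulp differences when transcripts are
re-ordered; identical inputs give bit-identical outputs.

The restricted log-likelihood is normalized as
`ℓ = −½[log|V| + log|X'V⁻¹X| + y'Py] − (n−p)/2·log 2π`, making m1 and m2
values directly comparable.

## Tests

**RLRT.** `T = max(0, 2(ℓ_m2 − ℓ_m1))`; the null parameter lies on the
boundary, so T is referred to `½δ₀ + ½χ²₁`: p = 1 when T = 0 (including
blending estimates at the floor and T below 1e-8, which finite convergence
tolerance can produce) and `p = ½P(χ²₁ ≥ T)` otherwise.

**Kenward–Roger F-tests.** Treatment contrasts are tested by Wald F
statistics with the KR small-sample adjustment: the covariance of β̂ is
inflated by the curvature terms `Q_ij − P_iΦP_j` weighted by the
covariance `W` of the variance-component estimates, and the denominator
degrees of freedom are matched to the first two moments of the adjusted
statistic. `W` is the inverse *expected* REML information
`½tr(PVᵢPVⱼ)` at the estimate. Components estimated as zero are treated
as known zeros (dropped from the adjustment); components whose covariance
contribution is numerically proportional to another are merged, which
makes the classical limits exact — the all-singles design reproduces the
two-sample ANOVA F with n−2 df, and balanced technical duplicates
reproduce the subject-means ANOVA with between-subject df. The
denominator df is capped at n − rank(X); if the moment match is
infeasible the test falls back to the residual df and is flagged.
Simulated-null KR p-values on the pooled design are uniform (KS p ≈ 0.2
at 2000 transcripts) with exact 5 % size.

**FDR.** Each p-value family (RLRT, F under m1, F under m2) is controlled
separately. π₀ is estimated on the grid λ = 0.05, …, 0.95 by the
bootstrap criterion (100 resamples, MSE against the minimal plug-in
estimate); q-values are the monotone step-up transform `π̂₀·m·p₍ᵢ₎/i`,
reducing exactly to Benjamini–Hochberg at π̂₀ = 1. RLRT p-values equal to
1 enter unmodified; the null law is uniform-dominated, so the estimator
stays conservative in expectation.

## Synthetic data

The generator reproduces the pooled-experiment mechanism, not the fitted
Gaussian model: per transcript, a mean `μ ~ U[8, 14]` (log2 scale); one
third of transcripts differentially expressed with effects `U[0.5, 1.5]`
of random sign applied to the second group; individual expressions
`x ~ N(μ(+effect), σb²)`; aliquot weights `w ~ Dirichlet(a)` with
`aᵢ = 1/σz² − 1/γ` (mean 1/γ, component variance exactly
`(γ−1)/γ³·σz²`; uniform when the transcript is unaffected by blending);
pooled signals `log(w'exp(x))` computed by log-sum-exp; independent
`N(0, σt²)` technical errors per measurement. Individuals re-used between
single and pooled samples keep one expression draw, and technical
replicates share the pooled value. The ground truth records, exactly,
`observation = μ(+effect) + u₁ + log-bias + u₂ + technical error`, where
`u₂ = log(w'exp(x)) − log(mean exp(x))` and the log-bias is the Jensen
gap `log(mean exp(x)) − mean(x)`.

The default design is the canonical two-line mouse layout (60 animals, 44
arrays); scenarios s1/s2/s3 set the blending-affected fraction to 0, 1/3
and 1. The default calibration σb² = 0.103, σt² = 0.017, σz² = 2.7 matches
the mean variance components estimated from the mouse ovary data on the
model scale (σ₁² = 0.109, σ₂² = 0.295, σe² = 0.017); a nearby variant with
σb² = 0.094 is also shipped. Weights are redrawn per transcript by
default — matching the per-transcript random-effect model being
validated — with a per-mixture shared-draw mode available (physically, one
blending happens per pool). Randomness splits into one child stream per
transcript, so output is bit-reproducible and independent of evaluation
order. Simulated values are not clipped to [8, 14]; at these parameters
negative expressions cannot occur.

What the generator does **not** emulate: probe-level effects,
normalization artifacts, intensity-dependent variance, heavy-tailed or
correlated technical noise, and missing values. Passing tests therefore
validate the estimator and test calibration under the stated mechanism,
not robustness to real-array pathologies.

One consequence of the mechanistic generation is worth knowing: even with
perfectly uniform weights, the per-pool log-bias fluctuates across
transcripts and pools, which is a real (if tiny, order σb⁴) pool-level
variance absent from the fitted model. At low technical noise this makes
the "no blending" scenario an imperfect model null: the RLRT point mass
stays near one half, but the continuous p-value part runs slightly
sub-uniform and the estimated non-null fraction is a few percent rather
than zero. Under an exact Gaussian model null the same test machinery is
cleanly calibrated.

## Study sizes used by the shipped checks

The repeated model-comparison study is averaged over 20 repetitions in the
acceptance tests and 12 in `scripts/acceptance.py` (both with the full
9000-transcript experiment; averages are stable to a few counts at these
scales, with Monte-Carlo standard errors reported by `replicate_study`).
The estimator-consistency check uses 500 transcripts per σz² grid point
over {0.9, 1.35, 1.8, 2.25, 2.7}, excluding smaller values whose REML
estimates carry the known upward boundary bias; the regression slope of
median σ̂₂² on `(e^{σb²}−1)σz²` comes out ≈ 0.88 (medians sit slightly
below the mean of the right-skewed sampling distribution, whose own mean
is within 5 % of the target).

## Known limitations

* EM-REML is locally convergent; the boundary detection and nesting
  repair above handle the failure modes we observed, but pathological
  multimodal likelihoods could still defeat them.
* The KR adjustment uses the expected rather than observed information;
  in tiny designs with near-singular information the test falls back to
  residual df (flagged per transcript).
* The expression filter ("mean log-expression below threshold in every
  group") is defined for one-color designs; two-color log-ratio inputs
  skip it unless the caller supplies group labels on another scale.
* Experimental data enter only as normalized TSV matrices plus a design
  file; no raw-array preprocessing or normalization is provided.
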