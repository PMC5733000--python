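# Methods

This note records the statistical models implemented in `hetconn`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Rank-one covariance regression

Centered p-vectors y_i with design rows x_i (intercept first, then a 0/1
group contrast) follow y_i = γ_i·Bx_i + ε_i. The generating assumptions are
moment conditions — E γ = 0, Var γ = 1, E ε = 0, Cov ε diagonal, γ ⟂ ε —
and we take both γ_i and ε_i Gaussian, which is the assumption under which
the marginal likelihood is tractable: y_i is then mean-zero normal with
covariance Σ_{x_i} = (Bx_i)(Bx_i)ᵀ + diag(σ²). γ_i is integrated out
analytically rather than sampled; with the matrix determinant lemma and
Sherman–Morrison the per-observation density costs O(p), and because the
likelihood depends on data only through per-group second moments, the
stacked observations are compressed to sufficient statistics (per distinct
design row: count, column sums of squares, scatter) before sampling, making
MCMC cost independent of the number of time points.

The noise covariance is per-parcel diagonal, diag(σ²) with p free scales,
not a single scalar σ²I_p; the scalar form is the special case in which all
σ_j coincide and the per-parcel form is what lets the model scale to large
parcellations while absorbing heterogeneous parcel variances.

Priors are flat and improper by default — uniform on each B entry over the
real line, uniform on each σ_j over (0, ∞), realized by sampling log σ with
the exact Jacobian. Improper priors are safe here because the likelihood of
any non-degenerate dataset is integrable in these parameters; a
weakly-informative alternative (Normal(0, 10²) on B, lognormal(0, 2) on σ)
is available via `SamplerConfig(prior="weak")` for stress cases.

### Sign identifiability and alignment

Σ_x is invariant under B → −B. With a two-group 0/1 design the identified
objects are the directions v_g = B x_g per group, each up to its own sign,
so the posterior has several mirror-image modes. Two measures keep
inference coherent:

- every chain is initialized at the same canonically signed moment estimate
  (leading eigenvector of each group covariance, scaled, with the
  largest-magnitude entry made positive; B recovered by least squares
  against the distinct design rows), so chains start — and, with modes well
  separated by the likelihood, remain — in one orientation;
- `align_signs` applies the per-column Frobenius-optimal sign flip of each
  chain's draws toward a reference chain (sign of the chain-mean inner
  product, ties to +1) as a safety net, and summaries refuse to run on
  unaligned posteriors.

Reported coefficient signs remain arbitrary as a whole: only the
same-side/opposite-side structure of the credible intervals is
interpretable, and the parcel-set metrics below are invariant to label
swaps.

### Summaries

Credible intervals for a design column use quantile endpoints α/m and
1 − α/m with m defaulting to the number of parcels (Bonferroni correction
for the m simultaneous intervals displayed). Intervals entirely below zero
assign the parcel to set 1, entirely above to set 2, and intervals covering
zero leave it undecided.

## Full Wishart covariance regression

Subject scatter matrices S_k = Y_kᵀY_k (column-centered Y_k, raw scatter,
not divided by N) are modeled as S_k ~ Wishart(x_k⁽¹⁾Σ⁽¹⁾ + x_k⁽²⁾Σ⁽²⁾, ν)
in the scale parameterization, E[S] = νΣ. Because the 0/1 contrast makes
the scale a sum of positive-definite matrices, positive definiteness is
automatic; designs with other contrast codings are rejected with an
explanatory error. Intercept-only designs (single group) drop the Σ⁽²⁾ term
entirely rather than leaving it likelihood-free under a flat prior.

Priors: Σ⁽ᵐ⁾ = diag(σ⁽ᵐ⁾)Ω⁽ᵐ⁾diag(σ⁽ᵐ⁾) with LKJ(η) on each correlation
matrix (η = 1 default, uniform over valid correlation matrices), flat on
each σ⁽ᵐ⁾_j > 0, and ν uniform on (p − 1, N − 1) with N the minimum subject
run length (conservative under unequal lengths; overridable). ν estimated
below N is the model's account of temporal dependence: the scatter of
autocorrelated rows fluctuates like that of fewer independent rows.

### Parameterization and sampling

The LKJ prior is realized through the C-vine construction: canonical
partial correlations z at tree level k are independent 2·Beta(a_k, a_k) − 1
with a_k = η + (p − 1 − k)/2, and the assembled matrix is exactly
LKJ(η)-distributed. MCMC runs on unconstrained y with z = tanh(y); the
target needs only the Beta log densities plus the tanh Jacobian, never a
correlation-matrix Jacobian, and every draw reconstructs to a valid
correlation matrix by construction.

The sampler works in (νΣ, ν) rather than (Σ, ν) coordinates: the likelihood
pins the product νΣ tightly while leaving the (Σ, ν) ridge stiff, which
stalled ensemble chains in early experiments. The flat prior on σ is
transported to the new coordinates with its exact Jacobian (an extra
−(total scale count)/2 · log ν term), so the posterior is unchanged. ν is
initialized at the Wishart moment estimator 2·E[S_ii]²/Var(S_ii) (median
over parcels) and the scales/correlations at the mean scatter of the
reference group.

### Differential connectivity and FDR

P_ij = |2·Prob(Ω⁽²⁾_ij > 0) − 1| estimates the posterior evidence that the
correlation difference between groups has a definite sign (strict
inequality; draws exactly zero count as not positive; the diagonal is
ignored). The selection threshold λ is found by scanning a grid of step
0.001 from 0 upward and keeping the smallest λ whose nonempty selection has
posterior expected FDR ≤ the target — the smallest qualifying λ maximizes
discoveries. An empty qualifying set yields an empty report with λ* = 1,
and the FDR of an empty selection is reported as "no selection" (None), not
a number. By construction FDR_λ < 1 − λ whenever the selection is nonempty.

## Effective sample size and thinning

Per parcel, ESS_j = N / (1 + 2 Σ_t ρ_j(t)) with FFT-based sample
autocorrelations; the infinite sum is truncated by Geyer's
initial-positive-sequence rule (accumulate consecutive lag-pair sums while
positive), which the MCMC literature leaves as the standard choice when no
truncation is fixed. The series ESS is the minimum over parcels (floored,
clamped to [1, N]); the study-wide thinning count extends the same
conservatism as the minimum over subjects. Constant parcels have undefined
autocorrelation and force ESS = 1; negative-autocorrelation series can
exceed N and are clamped to N, since thinning cannot add rows. Thinning
keeps n evenly spaced rows starting at the first time point
(row ⌊iN/n⌋), preserving temporal order and run coverage.

One bound worth recording: thinning an AR(1) series exactly to its ESS
leaves lag-1 autocorrelation ≈ φ^((1+φ)/(1−φ)), which peaks near
e⁻² ≈ 0.135 for moderate-to-large φ. Thinned series are therefore *nearly*
but not perfectly decorrelated; the property test asserts the achievable
bound (< 0.15), not zero.

## Synthetic data

`simulate_lowdim` draws exactly from the rank-one model; `simulate_scatter`
draws rows from the stated normal model so each scatter is exactly Wishart
with df = N when rows are iid. Temporal dependence is introduced by
AR(1)-filtering the latent γ sequence and each noise component (or each row
process) with coefficient φ, scaled by √(1−φ²) so marginal variances — and
hence the implied covariances — are unchanged. This is a testing
construction to exercise ESS estimation and the ν posterior; the models
themselves treat time points as exchangeable. All randomness flows from one
seed through `SeedSequence` spawning, so individual subjects are
independently reproducible.

Default experiment conditions used by the test suite and the acceptance
script: rank-one recovery at p = 5, J = 2 with 400 observations per group,
contrast column (−1.5, 1.6, 0, 1.2, −1.2) against unit noise; Wishart
recovery at p = 5, K = 100 subjects, N = 200; power analysis on a
135-subject population (2:1 group ratio, mirroring a two-thirds/one-third
sleep-group split), N = 120 time points with φ = 0.3, subsample sizes
20/40/80 and 10 replicates at reduced sampler settings. These sizes were
chosen once as desk-scale analogues of a large neuroimaging cohort: large
enough for the posteriors to be informative, small enough that the whole
suite runs in minutes on one CPU.

What the passing tests show: the samplers recover their own generating
processes, the analytic shortcuts (marginalized likelihood, CPC/LKJ
pushforward, FDR bound) are correct, and the power metrics behave
monotonically. What they do not show: robustness to real fMRI artifacts —
drift, motion, physiological confounds, non-Gaussian tails, inter-subject
heterogeneity — none of which the generators emulate.

## Power analysis

Subsamples preserve the population group ratio via stratified sampling
without replacement (non-reference count rounded to nearest). For each
(size, replicate) the pipeline re-runs end to end — ESS on the subsample,
thinning, fitting, alignment, classification — and one fit is scored at
every α level, since α only moves the summary quantiles. Ground truth on
synthetic populations is the sign partition of the generating contrast
column; for real populations the recommended convention is the parcel-set
assignment of a full-population fit. True positives take the maximum over
the two set matchings and false positives the minimum, each optimized
independently; TPR divides by the number of truly assigned parcels, FDR by
all predicted parcels (0 when nothing is predicted).

## Numerical choices

- Ensemble sampler: affine-invariant stretch moves, walkers ≥ 2·ndim + 2
  (minimum 32), 4 chains × (500 burn-in + 500 retained) by default; each
  chain's post-burn-in walker cloud is condensed to the requested number of
  draws by striding over steps and walkers simultaneously. Split-R̂ is
  computed per parameter (on sign-aligned draws for B) and low acceptance
  fractions are surfaced as warnings in the fit metadata.
- Tie-breaks: sign alignment maps a zero inner product to +1; the canonical
  orientation makes the largest-|entry| coordinate positive.
- Degenerate inputs: constant parcels (ESS), singular scatters (rejected by
  the Wishart density requirement), empty FDR selections, and single-group
  Wishart designs all have defined behavior with explicit errors or
  sentinels rather than silent NaNs.
- Scatter matrices are symmetrized against float round-off and validated
  PSD with tolerance 1e-8 relative to the largest eigenvalue.

## Known limitations

- The rank-one model captures one covariance direction per design column;
  connectivity structure orthogonal to it lands in the diagonal noise term.
- The Wishart model requires N > p per subject and a 0/1 two-column design;
  more general designs would need explicit positive-definiteness handling.
- Ensemble MCMC mixes more slowly than gradient-based samplers on the ν
  posterior; split-R̂ for ν around 1.1–1.2 at default settings is typical
  and can be reduced by raising burn-in or chains.
- The per-column sign alignment is exact for the symmetries of orthogonal
  design contrasts; for 0/1 contrasts the canonical initialization is what
  keeps chains in a common mode, and alignment is a safety net.
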