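# Methods

`neurotau` estimates the multi-timescale structure of single-neuron
spiking and tests two population-level hypotheses about it: that slow
timescales follow a power law, and that recurrent-network dynamics at the
edge of instability (linear networks) or in the chaotic regime with
heavy-tailed connectivity (nonlinear networks) can generate such a law.
This note records the models, the estimation choices, and the places
where the design was genuinely open.

## Intrinsic timescales from spike counts

Spikes are counted in Δt = 5 ms bins over the recording (default duration
600 s, a 10-minute spontaneous period). The autocorrelation at lag
t_j = jΔt is estimated with lag-dependent windowed means μ̂₁(j), μ̂₂(j)
for the leading and trailing windows and a single global sample variance
σ̂²:

    AC(t_j) = [ Σ_{i=1}^{N−j} (A_i − μ̂₁(j)) (A_{i+j} − μ̂₂(j)) ] / (σ̂² (N−j)).

At j = 0 this equals (N−1)/N identically, so lag 0 is never fitted: the
drop between lag 0 and lag 1 reflects spiking irregularity, not dynamics.
Units with refractory-like dips at early lags are handled by starting the
fit at the lag where the autocorrelation begins to decay,
operationalized as the argmax of AC over lags 1..20 (100 ms horizon,
configurable) — a deliberately simple rule; any monotone variant would
do as well for clean autocorrelations. No bias correction is
applied — at 600 s the estimator bias is negligible relative to its
variance.

The autocorrelation up to 5 s lag is fitted with mixtures of M = 1..4
exponential decays, AC(t) = Σ c_i exp(−t/τ_i), by unweighted nonlinear
least squares in linear AC space (log-space fitting is impossible because
AC is routinely ≤ 0 at long lags; the fit is unweighted, since the
estimator variance is approximately lag-independent over the fitted
range). Fits use 10 seeded
multi-start initializations (τ log-uniform in [Δt, 5 s], coefficients
Dirichlet on the simplex), with analytic Jacobians and a deterministic
early stop when repeated starts cease to improve the residual. Bounds:
τ ∈ [Δt, duration], c ≥ 0. Model order is selected by the least-squares
BIC, n·ln(RSS/n) + k·ln n with k = 2M over the n fitted lags, among
converged fits whose components each contribute at least 1% of the total
mixing weight (a violating model is demoted to the smaller admissible
one, even when the BIC prefers it); BIC ties break toward fewer
timescales. A selected fit passes quality control when R² > 0.5; a
single-exponential pathway (M fixed at 1, no QC) reproduces the
conventional estimator for robustness checks.

The effective timescale τ_eff = Σc_iτ_i / Σc_i is the mixing-weighted
mean; it matches the area under the mixture autocorrelation to a single
exponential and is invariant to rescaling all coefficients.

## Power-law tails

The continuous power law p(x) = (γ−1)/θ (x/θ)^{−γ}, x ≥ θ, is fitted by
maximum likelihood with the lower cutoff chosen to minimize the KS
distance between the empirical tail and the fitted distribution, scanning
the observed order statistics (optionally decimated every k-th value — a
documented speed approximation) with at least 25 tail samples above every
candidate. No upper cutoff is imposed. Goodness of fit uses a parametric
bootstrap (default 10,000 synthetic datasets of N_θ tail samples each,
independently refitted; the power-law hypothesis is retained above the
conservative p = 0.1 threshold). Alternatives (exponential, log-normal)
are fitted by maximum likelihood restricted to x ≥ θ (the log-normal by
numerically maximizing the truncated likelihood) and compared through the
normalized log-likelihood ratio R = R₀/(√N σ_R0), with the standard
two-sided normal significance test at 0.05. When pooling groups with different cutoffs,
the maximum group cutoff is used so the pooled tail is power-law
consistent in every group. The timescale fits use the continuous (not
discrete) formulation throughout, since timescales are continuous.

A control simulation draws many datasets from a true power law (γ = 2,
N_θ = 1,000), refits each, and compares against the log-normal: the
normalized LLR is expected to be slightly negative in most datasets
(the truncated log-normal family contains the power law in a limit) and
statistically significant only in rare cases — this calibrates how often
"statistically comparable to log-normal" is expected even for genuine
power-law data.

## Task-variable selectivity

Selectivity of a unit to stimulus side, choice direction, or reward is
the condition-combined Mann-Whitney statistic: within each stratum of
held-fixed other variables, spike counts in an event-aligned window
([0, 100] ms from stimulus onset; [−100, 0] ms from first movement;
[0, 200] ms from feedback — the movement-aligned [0, 150] ms reward
variant is exposed as configuration) are ranked with average ranks for
ties, U_j = min of the two one-sided forms, and P = ΣU_j / Σ n1_j n2_j.
Contrast is not a conditioning variable.

One structural fact forces a deviation from the verbal recipe "hold the
other two variables fixed": in this task reward is exactly determined by
stimulus and choice, so each variable is a function of the other two and
full conditioning leaves no stratum containing both values of the tested
variable — the statistic would be undefined for every unit. The model
therefore uses the largest usable conditioning set: both held variables
when any usable stratum exists, otherwise the single held variable whose
usable strata carry the largest Σ n1_j n2_j, otherwise no conditioning.
Degenerate strata (one group empty) are always dropped from both sums.

The null distribution permutes the tested variable's labels only within
cells formed by block identity crossed with the conditioning strata,
preserving each block's label counts exactly. This block restriction
exists because the side-prior blocks (20/80% or 80/20% right, 20–100
trials each) make labels serially dependent at the block timescale; an
unrestricted shuffle would convert any slow rate drift into spurious
selectivity. The p-value is the plain fraction of permutations whose
combined statistic is at most the observed one (small P = strong
separation; no add-one smoothing; a strict-inequality variant is
available), and selectivity means p < 0.05 over 3,000 permutations by
default. Downstream, effective timescales of selective versus
non-selective units are compared per group by two-sided Wilcoxon rank-sum
with Benjamini-Hochberg correction at FDR 0.01.

## Anatomical-feature regression

Neurons are assigned to 200 µm voxels; all neurons in a voxel share its
feature row (e.g. principal components of gene-expression density
retaining 95% cumulative variance). Ridge regression predicts
log10(τ_eff) — the log transform reflects the heavy tail and keeps the
squared-error loss from being dominated by the slowest neurons; the raw
scale is available — with the penalty chosen by 5-fold cross-validation over a
log grid. The reported R² is cross-validated by default; the in-sample R² is
also carried on the results.
The baseline model uses one-hot brain-region indicators, reproducing
per-region means at negligible penalty.

Spatial-confound control: surrogate feature fields are built by a 3-D
Fourier transform of each raw feature (randomization is applied to raw
features, not components), replacing phases with those of an independent
real white-noise field — which enforces Hermitian symmetry, so the
surrogate is exactly real — while amplitudes (hence the power spectrum
and spatial autocovariance) are preserved to machine precision and the
DC term is copied (mean preservation). The surrogate p is the fraction
of (default 500) surrogate fits whose R² reaches the observed one. The
unique explained variance of a feature, ΔR², refits after permuting that
feature's values across voxels.

## Linear networks at the edge of instability

For τ_syn dx/dt = −Mx + η with M = I − gW and isotropic white noise D,
the stationary lagged correlation matrix is the double eigen-sum

    C(t) = D Σ_{p,q} (u_qᵀu_p)/(λ_p+λ_q) v_p v_qᵀ e^{−λ_p t},  t ≥ 0,

validated against Euler-Maruyama simulation. Unit autocorrelations are
mixtures of modes with timescales τ_syn/λ_p; the population timescale
density follows f(λ) by g(τ) = f(1/τ)/τ², and a density f ∝ λ^ζ near
zero yields a power-law tail with exponent γ = 2 + ζ above the cutoff
1/λ_cutoff (uniform: ζ=0 over the whole range; semicircle radius R:
ζ=1/2, λ_cutoff=2R; gamma shape α, unit scale: ζ=α−1, λ_cutoff=ln 2).
The edge of instability is implemented as a support shift placing the
minimum eigenvalue at ε (default 10⁻⁴): tuning the gain g is the
physical control, and the shift is the equivalent one-parameter version
since λ_min = 1 − gλ_w,max; a spectrum-scaling variant is exposed as an
option.
Raising ε caps the longest timescale at τ_syn/ε (power-law collapse);
τ_syn rescales all timescales without changing the exponent. Timescale
distributions are computed from inverse eigenvalues by default, with the
stochastic simulation used for validation.

One caveat discovered in validation and worth recording: the
inverse-eigenvalue surrogate for *fitted single-unit* timescales holds
when eigenmodes are localized (each unit expresses a few modes). With a
dense Haar-random eigenbasis, every unit receives weight on every mode
and mode variance scales as 1/λ, so all units' autocorrelations are
dominated by the slowest modes and single-exponential fits concentrate
near the longest timescales instead of sampling the spectrum.
`network_from_eigenvalues` therefore defaults to a locally mixed
(Givens-rotation) basis, with the dense basis available for contrast.

## Nonlinear networks with heavy-tailed connectivity

The rate network τ_syn dx_i/dt = −x_i + g Σ_j J_ij tanh(x_j) has i.i.d.
symmetric α-stable connectivity (Chambers-Mallows-Stuck sampling; tail
exponent 1+α for α<2; α=2 is the Gaussian control). The connectivity
scale defaults to the reference convention c = N^{−1/α}, which keeps the
recurrent input O(1) as N grows and the dynamics robustly chaotic at
the gains studied (g = 1.5–2.1); the literal convention c = 1/N is also
implemented. At fixed N the two differ only by an effective-gain
rescaling, but the difference matters at reduced size: under c = 1/N at
N = 300 the α = 1.2 network sits near the edge of chaos (a third of
repetitions decay to the fixed point) while the α = 2 Gaussian network
is fully subcritical — which makes c = 1/N the natural setting for the
"Gaussian connectivity produces no heavy tail" control, and c = N^{−1/α}
the natural setting for the chaotic heavy-tail experiments. Chaos is
verified empirically (post-burn-in activity variance bounded away from
zero); quiescent repetitions are counted, not silently included. A
caveat from validation: a Gaussian network pushed deep into chaos
(c = N^{−1/2}, g·√2 ≈ 2.5) also develops a broad, slower-than-exponential
timescale distribution, so the Gaussian control discriminates
connectivity tails only near or below criticality.

Integration uses Euler steps of dt = 0.1 τ_syn for 14,400 steps with the
first 10% discarded as burn-in (dt and the burn-in fraction are package
choices; the step count is counted at this dt). Per-unit
timescales come from single-exponential least-squares fits to the
normalized autocorrelation over lags up to 500 steps; near-constant
units, fits with no amplitude (white-noise-like), and fits pinned at
either τ bound are excluded with counts reported. Pooled timescales over
(default 100, reduced-scale 20) repetitions with fresh connectivity and
initial conditions feed the standard power-law tail fit.

## Synthetic data

The spike-train generator is doubly stochastic: rate(t) = max(0, r₀ +
Σ a_i y_i(t)) with independent stationary unit-variance OU processes y_i
of time constant τ_i, and spikes drawn as an inhomogeneous Poisson
process on a 1 ms grid. With this convention the binned-count
autocovariance beyond lag 0 is Σ a_i² Δt² e^{−t/τ_i} (weights ∝ a_i²;
under the alternative fixed-diffusion OU convention the weights would be
∝ a_i²τ_i), so the planted signal-to-noise is set directly by the
amplitudes. Defaults — r₀ = 50 Hz with two components (50 ms and 500 ms)
at 12.5 Hz each — keep Σa_i at the 0.5·r₀ bound, which bounds rate
rectification below ~1% of time (the rectified fraction is reported and
a warning is attached above 20%) while giving the mixture fit a
realistic, resolvable two-timescale target; the zero-lag drop induced by
binning is absorbed by the fit-start rule. These generator settings are
validation conditions: passing recovery tests shows the estimator chain
is correct at this SNR, not that every real neuron is as well behaved —
real spiking adds refractoriness, oscillations, nonstationarity and
rate-timescale correlations that the generator deliberately omits.

The trial-table generator reproduces the task statistics (alternating
side-prior blocks of 20–100 trials at 20/80%/80/20%, contrasts
{100, 25, 12.5, 6, 0}%, choice matching the stimulus at a configurable
accuracy, reward deterministic given correctness) plus planted
multiplicative rate effects in the per-variable count windows and an
optional multiplicative log-OU rate drift for calibration studies. The
voxel-world generator synthesises smooth Gaussian random fields
(spectral amplitude ∝ |k|^{−smoothness}), plants a linear map from
features to log10 timescales with Gaussian noise, and reports the
planted signal fraction. All generators are bit-reproducible given their
seeds.

## Numerical choices and problem sizes

Acceptance-level simulations run at sizes chosen to make each check
statistically decisive while staying desk-scale: 1,000 eigenvalues and
10 seed repetitions for the linear-network exponents; 1,000 datasets of
1,000 samples for the LLR control (with a 4-fold decimated cutoff grid);
N = 300 units and 20 repetitions for the nonlinear-network properties;
300-neuron populations at 600 s for end-to-end recovery; 500 repetitions
for permutation calibration. Bootstrap sizes in tests (100–200) are far
below the 10,000 default, which only sharpens the p-value resolution,
not its calibration.

## Known limitations

* The nonlinear experiments have a measurement ceiling: units with true
  timescales comparable to the simulated duration (1,440 τ_syn at the
  default step count) are censored, and the KS-selected cutoff can sit
  either in the chaotic bulk or in the censored far tail. At N = 300 the
  pooled fitted exponent for α = 1.2 comes out near 1.9 — below the
  theoretical 1 + α = 2.2 — while at N = 1000 with 100 repetitions the
  empirical distribution in the scaling band (3–30 τ_syn) is consistent
  with 2.2. Reduced-size runs of this experiment should therefore be
  read as qualitative (heavy tail present, gain-independent, τ_syn
  scaling) rather than as unbiased exponent estimates.
* The selectivity conditioning fallback (above) means "stimulus
  selectivity" is assessed holding choice fixed while reward covaries
  with the tested label inside strata; with reward a deterministic
  function of the other variables, no test can do better.
* The anatomy regression treats voxel features as fixed; measurement
  error in the features and neuron-to-voxel assignment error are not
  modelled.
* No oscillatory (complex-eigenvalue) spectra in the linear theory, no
  dynamic mean-field theory for the nonlinear networks, and no discrete
  power-law support.
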