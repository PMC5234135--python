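# Methods

This note documents the models implemented in `tspoquant`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Input function

The kinetic model is driven by cp(t), the parent (unmetabolized)
radioligand concentration in arterial plasma. It is assembled from
two data streams: a continuous withdrawal record covering roughly the
first 22.5 min, and timed manual samples (defaults at 2.5, 7, 12, 15,
30, 45, 60, 90, 120 min) with plasma and parent-fraction assays.

**Dispersion.** The withdrawal line smears the true blood curve by
convolution with a monoexponential kernel of time constant τ
(default 16 s, the value measured for this sampler class).
`dispersion_correct` inverts it by Richardson–Lucy multiplicative
deconvolution, with two departures from the textbook scheme that
matter in practice:

- iterations are seeded from the closed-form inverse
  g = m + τ·m′ (exact for the continuous operator), so the default 50
  iterations refine an already-near solution instead of crawling from
  the measured curve; the analytic route is also exposed separately
  and doubles as an independent cross-check in the tests;
- the correction factor is normalized by the window sensitivity
  K^T·1, without which the estimate collapses over the last kernel
  length of the record;
- the measured curve is Gaussian-smoothed (default FWHM 5 s) *before*
  deconvolution to limit noise amplification. Set
  `smoothing_fwhm_s=0` for noise-free data; the smoothing slightly
  biases genuinely sharp structure (a step edge loses ~1–2% locally).

**Merging.** The corrected sampler curve is adaptively rebinned (bin
width ≈ t/8, between 2 s and 30 s, bin centroids retained) — counting
noise averages down where the curve carries no fast structure, while
the bolus peak keeps its native resolution. Manual samples take over
beyond the sampler window, bridged log-linearly; a single exponential
fitted to the last three manual samples extrapolates past the final
draw. If a manual sample falls inside the sampler window, the sampler
curve is rescaled to agree with it at the first such time — a crude
but standard cross-calibration; disable with `scale_to_manual=False`.

**Blood-to-plasma ratio.** A bi-exponential r(t) is fitted to the
manual blood/plasma ratios, and plasma = blood / r(t) (the package
reads the ratio as blood-to-plasma; `inverse=True` flips the
convention). Rates are bounded to ≤ 1/min and amplitudes to twice the
data scale: with the earliest ratio sample at 2.5 min, faster
components are invisible to the data and, left unbounded, blow up
when the model is extrapolated into the bolus window. Partitioning
kinetics are slow, so the bound costs nothing physiologically.

**Parent fraction.** fp(t) = 1 − a·t^b/(c + t^b) with a ∈ [0, 1],
b > 0, c > 0 — the standard Hill form with fp(0) = 1 and a monotone
non-increasing course; c is fitted on a log scale with multi-start
over b.

The final input is cp(t) = blood(t)/r(t)·fp(t), clipped at zero, on a
uniform grid (default 1 s over 0–125 min; the forward model is exact
for piecewise-linear cp, so a 2 s grid is used where speed matters
and changes frame averages by < 0.1%).

## Tissue model

The reversible two-tissue compartment model with vascular signal:

    dC1/dt = K1·cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    C(t)   = (1 − vb)(C1 + C2) + vb·C_blood(t),   vb fixed at 0.05

vb multiplies whole blood (not plasma) and tissue is scaled by
(1 − vb), the standard convention. The solution is evaluated by
eigendecomposition of the 2×2 rate matrix into two exponential
convolutions, each computed by an exact recursive update for
piecewise-linear cp (no ODE solver error, ~0.5 ms per evaluation);
an adaptive LSODA route exists solely as a cross-check and agrees to
< 0.05%. Frame values are duration-averages of the continuous curve
(trapezoid on the dense grid), because mid-point evaluation is biased
for the early 30 s frames.

**Fitting.** Trust-region least squares over (K1, k2, k3, k4) with
bounds K1 ∈ (0, 2], k2, k3, k4 ∈ (0, 1], vb fixed, uniform weights
(frame-duration weights optional), from three deterministic start
points; best residual wins, ties broken toward lower K1. The
covariance is σ²(JᵀJ)⁻¹ with σ² = RSS/(n − 4); VT = K1/k2(1 + k3/k4)
and its standard error follows by the delta method with gradient
[(1 + k3/k4)/k2, −VT/k2, K1/(k2·k4), −K1·k3/(k2·k4²)]. Fit quality is
%COV = 100·SE(VT)/VT; singular covariances yield %COV = ∞ with a
warning rather than an error. The quality filter retains fits with
%COV ≤ 20 (inclusive boundary) and applies to VT only by default; a
per-parameter switch exists because the convention is ambiguous in
the field.

## Logan graphical analysis

Y(t) = ∫₀ᵗC/C(t) against X(t) = ∫₀ᵗcp/C(t), integrals by trapezoid on
frame mid-times anchored at (0, 0), OLS over frames with mid-time
≥ t* and positive activity. The slope estimates VT, asymptotically
unbiased for reversible kinetics and biased low before equilibration
— hence t* defaults to 30 min, or `choose_t_star` picks the earliest
mid-time from which all later points stay within a 10% relative band
of the line through the final third of the plot. For slow
dissociation (k4 ≈ 0.01/min) the 30 min default can still carry a few
percent of residual negative bias; noise-free agreement with the
compartmental VT is typically 1–4%, worst-case ~6% at the slowest
corner of the parameter priors. Voxel-wise `parametric_logan` is the
ROI computation applied per voxel (exactly equal when pre-smoothing
is off); optional Gaussian pre-smoothing of the dynamic series stands
in for heavier voxel-noise machinery and trades resolution for
stability. No vascular correction is applied at the voxel level.

## Partial-volume correction

Müller-Gärtner with a separable Gaussian PSF (default FWHM
4.4/4.4/4.5 mm, the reconstructed resolution of the scanner class
emulated):

    GM_corr = [PET − C_wm·smooth(WM) − C_csf·smooth(CSF)] / smooth(GM)

evaluated where smooth(GM) > 0.3 (conventional range 0.25–0.5,
configurable), NaN elsewhere. CSF activity is fixed at zero. C_wm is
estimated per frame from deep white matter (probability > 0.95,
eroded one voxel) unless supplied. Both paths the ambiguity allows —
correcting frames then extracting ROI TACs, or correcting a single
frame — are available; ROI extraction is NaN-aware.

## Cohort statistics

Per region: a Type-III factorial ANCOVA of VT on disease × genotype
with effects-coded contrasts (matching the common SPSS configuration)
and injected amount as nuisance covariate, via statsmodels OLS;
Levene's test (ANOVA on absolute deviations from the group mean)
gates the region's significance level — α = 0.01 instead of 0.05
where error variances differ (p < 0.05). Second level: pooled-variance
two-sided t tests of genotype within each disease stratum (Welch by
flag), and Pearson correlations of VT against clinical measures in
the PD group. Genotype contrasts are reported as
100·(HAB − MAB)/((HAB + MAB)/2), the unique simple form consistent
with the published regional tables; report output rounds to one
decimal. No multiple-comparison correction across regions is applied,
reproducing the analysis convention of the study design emulated.

## Synthetic data

The generator provides ground truth for every stage. It emulates: the
34-frame / ~125 min schedule (leading variable frame configurable,
default 30 s; remaining durations sum to 7335 s); a plasma bolus with
linear rise to a 0.6 min peak (120 kBq/mL) and tri-exponential
washout (rates 4, 0.35, 0.015 /min); metabolite loss with Hill
parameters a = 0.9, b = 2, c = 400 min²; a slowly drifting
blood-to-plasma ratio near 0.8; sampler dispersion at τ = 16 s with
1% noise on the 1 s record (a device-averaged output level) and 1%
proportional noise on manual assays; subject-level VT drawn from
per-(region, genotype) normal distributions calibrated to published
FEPPA group means — HABs 30–45% above MABs — pooled across disease so
the disease effect is exactly null by default (an additive
`disease_effect` and fully cell-level means are available); injected
amounts of 4.8 ± 0.22 (HC) vs 5.0 ± 0.27 mCi (PD).

Micro-parameters are randomized at fixed VT (k2 ∈ [0.05, 0.3],
k3/k4 ∈ [0.5, 4], k4 ∈ [0.01, 0.06] /min, K1 solved from VT and
rejected above 0.6 mL/cm³/min), so the fit surface is exercised
without changing the quantity under study. TAC noise is zero-mean
Gaussian, proportional to activity and to 1/√(frame duration)
(normalized to 300 s frames), scaled per subject by a lognormal
quality factor (σ = 0.6): fit quality in real cohorts is dominated by
subject-level factors (plasma assay quality, dose, motion), which
makes QC failures co-occur across a subject's regions. The noise
level itself can be calibrated to a target %COV-pass fraction by a
pilot: one fit per pilot draw at a reference noise gives the pass
curve through the %COV quantiles (%COV is near-linear in the noise
level), followed by one direct-evaluation bias correction.

Three cohort modes trade realism for cost: `fit` renders and fits
every TAC (used for QC and recovery checks at one cohort — 520 fits,
~40 s); `onetcm` is a closed-form single-compartment mode independent
of the 2-TCM fitter; `direct` draws the subject-level VT that the
statistics consume and attaches a lognormal %COV spread, fast enough
for 200-cohort power/level studies in ~30 s. Repeated-simulation
studies therefore use `direct`; nothing in the statistics layer can
tell the difference, because VT is the only quantity it reads.

What the generator does **not** emulate: reconstruction and
attenuation artefacts, head motion, anatomically realistic tissue
geometry (phantoms are concentric spheres), region-specific noise
differences, and any real between-region covariance of VT within
subject. Passing tests therefore demonstrate correctness of the
estimators under the stated models, not robustness to every
real-data failure mode.

## Numerical notes and limitations

- Exponential convolution uses series expansions below θ·Δt = 10⁻⁶;
  the degenerate equal-eigenvalue 2-TCM case is split by a 10⁻⁹
  relative nudge.
- The tail exponential of the merged blood curve is clamped to
  non-negative decay rates; non-positive tail samples fall back to a
  flat tail.
- `fit_2tcm` reports `converged=False` instead of raising when the
  optimizer exhausts its budget; downstream QC treats such fits like
  any other through their %COV.
- The per-subject %COV in `direct` cohort mode is drawn, not
  propagated from a fit; use `fit` mode when the %COV mechanism
  itself is under study.
- Problem sizes in the test suite and acceptance script (50 recovery
  draws, 200 power cohorts, 32³ phantoms, one full `fit`-mode cohort)
  were chosen to exercise each claim at useful statistical precision
  while keeping a full run to a few minutes.
- Levene's test uses deviations from the mean (not the
  Brown–Forsythe median variant), matching the gating rule emulated.
- The dispersion deconvolution assumes a time-invariant
  monoexponential kernel; real catheter dispersion can be flow- and
  time-dependent.
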