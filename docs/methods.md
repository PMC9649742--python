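# Methods

## Physical model and assumptions

The assay anchors a microbead (radius r ≈ 1100 nm) to a coverslip through a
dsDNA tether (end-to-end length l under force). Flow drag stretches the
tether; because vertical bead motion is negligible compared with the
in-plane excursion d, the lever geometry satisfies (l+r)² ≈ d² + r², and the
transverse fluctuation of the bead center is that of an inverted pendulum of
stiffness κ = F/(l+r). The equipartition theorem then fixes the equilibrium
transverse variance at ⟨δy²⟩ = k_BT(l+r)/F, which is inverted to estimate F.
This holds independently of the drag model; hydrodynamics only set the
relaxation time τ = γ/κ with γ = 6πηr, which governs how long a record must
be for a converged variance estimate and how fast it must be sampled
(corner frequency f_c = κ/2πγ; the simulator warns below 2·f_c, and
calibration-grade records should resolve ~10·f_c).

Bond rupture under a linear force ramp follows the single-barrier
Bell–Evans picture: the force-dependent off-rate k(F) = k_off·e^{FΔX/k_BT}
gives the rupture density p(F) = a1·e^{a2F}·exp[(a1/a2)(1−e^{a2F})] with
a1 = k_off/Ḟ and a2 = ΔX/k_BT, whose mode is
F* = (k_BT/ΔX)·ln[ḞΔX/(N·k_BT·k_off)]. N identical bonds loaded in series
fail N-fold faster, lowering F* by (k_BT/ΔX)·ln N; N is a property of the
construct declared by the user (3 for a tether anchored by biotin at both
ends through tetravalent streptavidin, 1 otherwise), never inferred from
data. Rebinding, near-equilibrium corrections and richer barrier shapes
(Dudko–Hummer–Szabo) are out of scope; when the log argument of F* drops
below 1 the value is returned flagged with a warning rather than raised,
because CDF optimisation can traverse that region transiently.

## Numerical choices

**Exact vs series CDF.** The density integrates in closed form to
P(F) = 1 − exp[(a1/a2)(1 − e^{a2F})], which is the default everywhere. The
truncated-series form Σ_{n=1}^{N} a1ⁿ/(n!a2ⁿ)·e^{na2F} × exp[...] (N = 50
by default) is also provided because it is what practitioners commonly fit;
its infinite-N limit exceeds the exact CDF by the constant e^{a1/a2} − 1
(the missing n = 0 term), below 0.5% at typical parameters. The series is
evaluated by log-sum-exp over n·ln(a1/a2) + n·a2F − ln n!, since the naive
terms overflow beyond ~40 pN. Fitting with either form changes ΔX by < 2%.

**Sampling.** Rupture forces are drawn by exact inversion of the
closed-form CDF, F = (1/a2)·ln[1 − (a2/a1)·ln(1−u)], using `log1p` to keep
the tails accurate.

**CDF fitting.** Nonlinear least squares over (log10 k_off, ΔX) with bounds
k_off ∈ [1e-12, 1e3] s⁻¹ and ΔX ∈ [0.01, 100] nm; residuals are taken
against the empirical CDF at the sorted sample points with plotting
positions i/n (ties share the last-of-ties position) — no binning, so no
binning loss; a fixed-bin variant is not needed for any supported analysis
but exact (force, probability) pairs can be fitted directly through
`fit_cdf_points`. Initialisation: ΔX₀ = k_BT/SD(F) (the density's width is
≈ k_BT/ΔX) and k_off₀ by inverting the F* relation at a histogram mode
estimate. Solutions pinned at a bound raise a warning.

**Global regression.** Unweighted OLS of F* on ln Ḟ (slope → ΔX, intercept
→ k_off), with delta-method uncertainties from the regression covariance. A
weighted fit is deliberately not the default: per-rate subgroup SDs are
themselves noisy at three subgroups. Censored beads (no rupture by ramp
end) are excluded from CDF fits with a logged count.

**Subgroup statistics.** Each rupture population is split by random
permutation into three disjoint subgroups with sizes differing by at most
one; the mean ± SD of the three subgroup F* values is reported alongside
the full-sample fit.

**WLC.** Marko–Siggia interpolation; the inverse (extension at force) is
the unique root of the cubic in l/Lc, solved by Brent's method. Fitting
minimises extension residuals — force is the controlled variable in this
assay — with bounds P ∈ [1, 500] nm, Lc ∈ [1.001·max l, 10·max l]. The
averaged-curve reading (fit the mean of the replicate curves) is the
primary path; per-curve fits are possible by calling `fit_wlc` per curve.

**Calibration fit.** Through-origin least squares c = ΣFV/ΣV² by default
(zero force at zero flow); a free-intercept variant reports the intercept
as a diagnostic. The calibration object carries the bead radius, tether
length and channel height it is valid for and refuses application to a
mismatched geometry unless explicitly overridden.

**Registration.** Integer-pixel peak of the FFT cross-correlation (windows
mean-subtracted), refined by a matrix-multiply DFT of the cross-power
evaluated only on a ±1.5 px neighbourhood of the peak at 1/upsample
resolution. The default upsample factor is ceil(pixel_size/10 nm),
targeting ~10 nm displacement resolution. The localized refinement is
exactly equivalent to upsampling the full correlation grid (asserted
against a brute-force oracle in the tests) at a small fraction of the cost.

**Rupture detection.** The detector triggers on the first frame whose
in-window pixel area falls below 50% of the initial median area rather than
exactly zero — rendered and real beads rarely hit zero in the frame they
detach — and maps that frame time to the ramp flow rate. Tie rule for
tether selection: the flow-parallel excursion must *strictly* exceed the
2.0 µm threshold in both flow directions.

**Survival kinetics.** Censored-exponential MLE k = events/Σt with the
exact chi-square interval; the strand-displacement rate is the difference
k(with invader) − k(background) at matched force, justified by the
independence of anchor dissociation and displacement (rates of independent
competing exponentials add). Negative differences are clipped to zero with
a warning; single-exponential kinetics are assumed per condition.

## Environment defaults

Temperature is taken as room temperature with k_BT = 4.114 pN·nm; the
`Environment` type enforces k_BT = k_B·T to 1e-6 relative, so the default
is constructed from the thermal energy with T derived (≈ 298 K). Water
viscosity 1.0e-3 Pa·s is used by the simulator only. Flow rates are mm³/s
internally (1 µL/min = 1/60 mm³/s); velocities mm/s; the calibration slope
pN·s·mm⁻¹. Every config key carries a unit suffix.

## What the simulators emulate — and what they do not

* `simulate_tethered_bead`: exact-discretisation Ornstein–Uhlenbeck
  process; its equilibrium variance equals the equipartition value for any
  time step, so calibration tests probe the estimator, not the integrator.
  Free-space Stokes drag, no Faxén wall correction, no vertical or axial
  fluctuations — these affect only the correlation time in reality, not the
  equilibrium statistics the analysis uses.
* `render_bead_movie`: beads as sub-pixel-positioned disks with a 1 px
  Gaussian edge (a reasonable stand-in for bright DIC blobs as seen by an
  area-threshold detector); ruptured beads vanish from their rupture frame.
  No optics model, no illumination gradients, no drift.
* `simulate_rupture_experiment`: per-channel loading rates Ḟᵢ = c·β/(wᵢh)
  from the shared volumetric ramp; forces drawn from the exact rupture
  density and converted to rupture flow rates; right-censoring at the ramp
  end. Lift forces and bead–wall hydrodynamics are not modelled (no
  quantitative parameters exist for them; the calibration is empirical).
* `simulate_survival`: i.i.d. competing exponentials with right-censoring.

Passing round-trip tests therefore demonstrates correctness of the
estimators under the model's own assumptions — not robustness to drift,
heterogeneous bead populations, tether polydispersity or detection
artifacts in real movies.

## Problem sizes

The acceptance computations use the experiment-scale sizes of the study
design: 2000 rupture forces per loading rate (three rates, three replicate
seeds) for the antibody-bond round trip; 500 beads per channel per ramp
(four channels, three ramp settings whose twelve loading rates span
0.01–10 pN/s) for the multiplexed unzipping round trip; nine
force–extension curves of twenty log-spaced forces (0.05–5 pN, 10 nm
extension noise); and twenty beads per velocity at four velocities
(0.1–0.7 mm/s, 2000 samples per record at ten times the corner frequency)
for the calibration round trip. The movie-based end-to-end test uses a
smaller rendered field (20 beads, 80 frames), which is ample to exercise
every image-path branch.

## Known limitations

* The empirical-CDF least-squares fit is not maximum likelihood; at small n
  it inherits the usual mild bias of CDF fitting.
* Censored beads are excluded from CDF fits rather than handled by a
  censored likelihood; with ramps run to completion this loses nothing.
* The tracker assumes beads stay within their fixed analysis window;
  large-excursion selection movies should use a window covering the full
  excursion (`window_half` is configurable).
* Loading rate is treated as constant per channel (linear ramp through a
  linear calibration); nonlinear protocols are out of scope.
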