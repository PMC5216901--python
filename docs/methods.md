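# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `psitrap`, in the order the pipeline uses them.

## Kinetic model and the IRF convolution

The fluorescence decay of a pigment–protein complex recorded on a streak
camera is modelled as a sum of `n` exponential components convolved with a
Gaussian instrument response function (IRF), identical at every wavelength:

    I(t, λ) = Σₙ Aₙ(λ) · C(t; τₙ, μ, σ),
    C(t; τ, μ, σ) = exp(−t/τ) ⊗ G(t; μ, σ)
                  = ½ exp(σ²/2τ² − (t−μ)/τ) erfc[(σ/τ − (t−μ)/σ)/√2].

Assumptions: the IRF is a single Gaussian per image (no wavelength-dependent
dispersion of its center), annihilation is absent, and open reaction centers
dominate so the components have clean exponential character.

Numerics: the leading exponential in the closed form overflows when σ/τ is
large. Writing the erfc argument as z, the identity
`exp(a)·erfc(z) = erfcx(z)·exp(a − z²)` with `a − z² = −(t−μ)²/2σ²` gives a
bounded expression used whenever `z ≥ 0`; the plain formula is used for
`z < 0`, where its exponent is itself negative. The kernel is verified
against adaptive quadrature of the defining integral to 1e−6 relative across
lifetimes 0.5–1700 ps and IRF widths 0.1–50 ps, and is finite up to
σ/τ ≈ 10³. The σ → 0 limit is the sharp exponential with a unit step at μ.

Lifetimes are the canonical user-facing parameterisation everywhere; rate
constants appear only inside the cascade algebra.

## Sequential scheme and DAS ↔ EAS

The sequential (unbranched cascade) scheme 1 → 2 → … → n with unit transfer
efficiency has the Bateman solution: compartment populations are linear
combinations of the same IRF-convolved exponentials, with a lower-triangular
coefficient matrix **B** built from the rates. Evolution-associated spectra
(EAS, per compartment) therefore map to decay-associated spectra (DAS, per
exponential) by `DAS = Bᵀ·EAS`, and back by a triangular solve; the
reconstruction of the total signal is identical in both bases to 1e−10.
Coincident lifetimes make the cascade degenerate; they are rejected (within
1e−9 relative) with advice to perturb, rather than silently switching to the
`t·exp` confluent solution.

## Global fitting by variable projection

Lifetimes are shared across all wavelengths and all images (the three streak
time ranges); amplitudes are conditionally linear. The fit exploits this
separability: for each candidate lifetime vector the per-wavelength
amplitudes of every image are solved exactly by linear least squares, and
only the lifetimes are iterated (Levenberg–Marquardt on the projected
residual). Free lifetimes are optimised in log-space, which enforces
positivity without constraints; fixed lifetimes (e.g. a 6 ns free-chlorophyll
component) are excluded from the parameter vector and never move.

Initialisation defaults to log-spaced values between twice the time
resolution and the longest time window. Five seeded log-normal restarts
(spread 0.4 in log-lifetime) guard against local minima; the best-cost
solution is returned, deterministically for a given seed. The reported
lifetimes are sorted ascending, so the result is invariant to the ordering
of the initial guesses and of the input images.

During lifetime optimisation each image receives its own unconstrained
amplitude matrix — this keeps the inner problem linear and exact. The single
reported DAS set is then formed by aligning each image's amplitude matrix to
the first image's by a least-squares scale factor and averaging; the scale
factors absorb the different acquisition gains of the time ranges. A
DAS-reporting convention scaling the total t = 0 amplitude to one is
available (`KineticFitResult.normalized_das`). Relative amplitudes use the
signed trapezoidal area of each DAS over the detected range (a switch
selects absolute-value areas), and the average time to charge separation is
their amplitude-weighted mean lifetime over the connected components only.

Model-order selection fits increasing n and stops at the smallest n for
which adding a component improves the rms residual by less than 2%
(relative) or produces two lifetimes within 10% of each other — both
signatures of over-parameterisation; ties favour the smaller model.
Components are classified as disconnected when τ ≥ 1 ns (default): detached
antenna complexes decay near their intrinsic ~1.7 ns lifetime and free
chlorophyll a near 6 ns, far slower than trapping in a connected
supercomplex.

## Steady-state spectra

Band positions in congested chlorophyll Qy regions are read from minima of
the second derivative, computed by a single Savitzky–Golay pass (default
window 11 points, polynomial order 3, suited to ~0.5–1 nm grids). Minima
shallower than 5% of the deepest are discarded as noise wiggles; positions
are refined by a parabola through the three points around each minimum,
which makes them invariant under amplitude rescaling and equivariant under
wavelength shifts. Non-uniform grids are resampled linearly before
differentiation. Normalisation modes: global maximum, Qy maximum (620–720
nm), and red-tail (integral beyond a threshold, default 705 nm, scaled to
one — the convention for comparing spectra per red-form content). All modes
are idempotent. Emission maxima are parabolically interpolated argmaxima
within a search window; a boundary maximum (monotone spectrum) is returned
with a warning.

## Fraction analysis

Because each sucrose-gradient band has a fundamentally different protein
composition, search-engine normalisation is not applicable; per-fraction
factors are computed from the summed non-normalized intensities, anchored to
the mean fraction total. The anchor is a convention — it cancels exactly in
the per-protein distribution, which is the only quantity interpreted.
Missing intensities are treated as zeros (absence in the run); all-zero
proteins are excluded from the distribution and reported. Enrichment in a
target fraction uses a ≥75% share threshold by default.

## Pigments

Peak areas convert to mol per 100 Chl a through response factors (area per
mol): `molᵢ = 100·(areaᵢ/rfᵢ)/(area_Chl/rf_Chl)`. The vaucheriaxanthin
response factor is derived from violaxanthin's with a 10% correction for the
different absorption spectrum; the correction is applied as an increase by
default, with the sign configurable since the direction is an empirical
calibration choice. The Chl:Car ratio is 100 over the summed carotenoid
content. Contents known only as upper bounds ("< 1") are carried as censored
values, and a ratio involving them is returned as a (low, high) interval
instead of a point.

## Synthetic data: what it emulates and what it does not

The generator defaults encode the measured PSI–LHC system:

- **Kinetics** (`KineticGroundTruth.alpha_dm` / `.beta_dm`): four components
  with lifetimes 10.5 / 45.5 / 1700 / 6000 ps (α) and 13.0 / 45.1 / 1600 /
  6000 ps (β); Gaussian DAS whose signed areas equal the observed relative
  amplitudes (33.1 / 48.9 / 11 / 7% for α). The fast components peak at
  685–688 nm; the slow, disconnected components are blue-shifted — 680 nm
  for the detached antenna and 675 nm for free chlorophyll a, matching its
  675–680 nm steady-state emission. Giving the two slow components distinct
  spectra is essential: it is what makes a fourth component resolvable, as
  it was in the measurement.
- **Time ranges**: 0–155, 0–400 and 0–1500 ps with Gaussian IRFs of FWHM
  4.5, 6.5 and 20 ps (the midpoints of the instrument's quoted temporal
  responses). Whether such figures denote FWHM or σ is instrument
  convention; FWHM is the default, configurable via `irf_width_is_sigma`.
  The IRF center sits at 10 ps so the rising edge is recorded.
- **Noise**: Gaussian with variance proportional to the local signal plus a
  1e−3 floor (photon statistics after camera gain). The default
  `noise_scale = 0.005` corresponds to a peak signal-to-noise ratio of 200,
  typical of sweep-averaged streak images and consistent with a dataset in
  which all four components, including the 7%-amplitude 6 ns one, are
  statistically resolvable.
- **77 K absorption**: four Gaussian Qy sub-bands at 669, 679.5, 685 and
  697.5 nm with FWHM 6–9 nm and unequal amplitudes; **emission**: a dominant
  722 nm red-form band plus a configurable free-chlorophyll band at 678 nm.
- **Fraction tables**: archetypes covering every gradient band (PSI core,
  PSI antenna, LHC monomers/trimers, PSII core, and a mixed class),
  log-normal per-protein totals and mean-one log-normal per-cell dispersion
  (default 0.1). Covering all bands matters because the per-fraction
  normalisation divides by column totals; a gradient carrying protein in
  only one band would distort every share.
- **Pigment areas**: exact inversion of the quantification formula, so the
  round trip recovers the configured contents (α defaults: 14.5 / 2.3 / 2.1 /
  2.5 / 10.2 mol per 100 Chl) to 1e−9.

Not emulated: detector saturation and singlet–singlet annihilation, IRF
dispersion across wavelength, baseline drifts and scattering artifacts,
peptide-level identification noise (missing values beyond simple absence),
and chromatogram peak integration. Passing tests therefore demonstrate the
correctness of the analysis chain under the stated statistical model, not
robustness to every artifact of real instruments.

## Problem sizes

The standard synthetic experiment uses 256 time points per image, a 5 nm
wavelength step (55 channels) and three time ranges; lifetime-recovery
statistics use ten seeded replicates. These sizes give sub-second individual
fits and stable replicate means while exercising the full joint-fit code
path.

## Known limitations

- The joint fit assumes all images share one wavelength grid.
- No branched/target kinetic schemes and no per-component error bars from
  the nonlinear fit's covariance.
- The sequential scheme assumes unit transfer efficiency between successive
  compartments (the standard unbranched cascade).
- Model-order selection compares nested fits by rms only; no information
  criteria.
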