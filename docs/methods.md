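# Methods

`endorkit` models the spectroscopic chain by which pulsed EPR observables on
a tyrosyl radical (Y•) at a protein subunit interface are turned into
structural statements: electron–nucleus distances from ¹⁹F hyperfine
couplings, a stacked/flipped conformer population from orientation-selective
ENDOR spectra, and the radical-pair distance distribution from PELDOR/DEER
traces. This note records the models, the assumptions behind them, the
defaults, and the numerical choices.

## Spin Hamiltonian and frames

The electron Zeeman interaction is parameterized by principal g values
(default g = (2.0062, 2.0044, 2.0022), characteristic of an
electrostatically perturbed tyrosyl radical at W band). The g frame is the
molecular reference: x along the C–O• bond, y in-plane perpendicular, z
normal to the ring. Hyperfine tensors are given as principal values in kHz
plus **active z-y-z Euler angles** (degrees): the columns of
`Rz(α)·Ry(β)·Rz(γ)` are the A principal axes in g-frame coordinates. For an
axial tensor built from `(T, a_iso)` the principal values are
`(a−T, a−T, a+2T)` and `(α, β)` are the azimuth/polar angles of the unique
axis. Units are kHz for hyperfine couplings (matching how such parameters
are tabulated), MHz for spectral axes and Larmor frequencies, tesla for
fields.

Nuclear data (¹H, ²H, ¹⁹F, ¹⁷O) are embedded as g factors derived from
tabulated nuclear moments; no external data source is needed. With these,
γ(¹⁹F)/2π = 40.078 MHz/T and γ(¹⁹F)/γ(¹⁷O) = 6.94.

## Point-dipole distances

For an electron spin idealized as a point at the ring centroid (the
unweighted mean of the O, C1, C3, C5 atoms — the approximate center of
gravity of the spin density on a tyrosyl radical), a nucleus at distance R
has a purely dipolar axial coupling `T = C/R³` with
`C = (μ0/4π)·g_e·μB·g_n·μN/h ≈ 7.44·10⁴ kHz·Å³` for ¹⁹F. The free-electron
g value is used in C (the radical's g anisotropy would change it by <0.2%;
configurable). The inversion `R = (C/T)^{1/3}` warns, but does not fail,
below 5 Å, where spin delocalization makes the point-dipole picture
unreliable; couplings at such distances must come from quantum chemistry and
are accepted as explicit tensor inputs throughout.

## Pake patterns and reading splittings

The powder pattern of an axial tensor is computed analytically in
cos θ (the powder measure), deposited onto the frequency axis with linear
(triangular) weight sharing, and convolved with a Gaussian of the stated
FWHM. The singularities are integrable, so this is deterministic and
converges with the cos θ grid (default 20001 points). Annotations carry the
analytic separations: perpendicular singularities split by `|a_iso − T|`,
parallel shoulders by `|a_iso + 2T|`.

Reading a splitting back off a spectrum takes the strongest local maximum
on each side of zero offset (ties toward smaller |offset|) with parabolic
refinement. One bias matters: the maximum of a Gaussian-convolved
inverse-square-root powder edge sits **0.765 σ inside** the true
singularity (the maximizer of `∫ w^{−1/2} exp(−(u+w)²/2σ²) dw`). When the
reader is told the applied linewidth it corrects each peak outward by this
amount, so the returned separation estimates the underlying `|a_iso − T|`
rather than the smoothed-maximum separation. At 250 kHz FWHM the raw
maxima of the (T = 1.0 MHz, a_iso = −0.8 MHz) pattern are 1.63 MHz apart;
the corrected read-off returns 1.79 MHz against the analytic 1.80 MHz.

## Mims ENDOR simulation

First-order (high-field) ENDOR frequencies only:
`ν(mS=±½) = |ν_n·l ∓ ½·A·l|` as a vector norm (the pseudo-secular nuclear
field is kept; no electron-nuclear state mixing). This is accurate at W
band where ν_n(¹⁹F) ≈ 134 MHz dwarfs the ≤2 MHz couplings of interest.
The powder is a deterministic Fibonacci hemisphere grid (no RNG anywhere in
the simulator); weights are uniform by the lattice's equal-area property.

Each orientation is weighted by three factors:

* **solid angle** (uniform grid weight);
* **orientation selection**: a Gaussian excitation window of width σ_B
  (default 0.3 mT — the pulse bandwidth is not an explicitly reported
  quantity, so this is a configurable package default) around the observer
  field, averaged over the m_I branches of "selection-only" nuclei. The
  strongly coupled β-methylene proton (~55 MHz) is carried this way: it
  shapes the EPR envelope but contributes no peaks near the ¹⁹F window;
* **Mims efficiency** `½·sin²(π·a·τ)` evaluated at the
  orientation-dependent splitting a(θ), which reproduces the blind-spot
  physics exploited experimentally (τ ≈ 236/266 ns for ~1.6 MHz couplings,
  τ ≈ 620 ns for ≤250 kHz couplings, with a blind spot at a = 0 in all
  cases).

Sticks are deposited with linear weight sharing and convolved per nucleus
with the conventional linewidth rule: 25 kHz FWHM for couplings below
0.5 MHz, 250 kHz above. Peaks are placed relative to the Larmor frequency
of the reference isotope (¹⁹F), so ring protons — included only at long τ,
as is conventional — appear at their true offsets and form a broad
background in the ¹⁹F window. Observer positions named gx/gy/gz resolve to
fields through the electron resonance condition at the configured microwave
frequency (94 GHz default).

Multi-observer spectra are combined with weights proportional to the
simulated EPR envelope amplitude at each observer field; two-τ acquisitions
are combined as a scan-normalized average, which fills the blind spots of
one τ with the other.

## Two-conformer ratio fit

The data model is a superposition of two conformers — "stacked" (distal
fluorines only, weak couplings) and "flipped" (one proximal fluorine with
mixed isotropic/dipolar coupling, one distal fluorine with its unique axis
along g_x) — with a single mixing fraction f shared by **all** spectra
(three observers × two τ regimes; one global parameter set). Components are
max-normalized before mixing (area normalization is available and recorded
in metadata); the fit scans f on a 0.01 grid, sums the rmsd over all
spectra, and refines the minimum parabolically. The quoted uncertainty is
the half-width of the f interval where the summed rmsd stays within 5% of
its minimum. The fit is invariant to rescaling the experimental spectra.

Background handling: a contaminant reference spectrum is removed by
least-squares scaling over a mask. The scale should be fitted where the
window is signal-free; in the bundled analysis this is the outer region of
the wide short-τ window (ring protons are absent at short τ), and the same
scale is applied to the co-acquired narrow window.

## PELDOR/DEER inversion

Orientation averaging is assumed complete, so the kernel is the standard
`K(t,r) = ∫₀¹ cos[2π·ν_dip·(1−3x²)·t] dx` with `ν_dip = 52.04 MHz/(r/nm)³`,
evaluated in its Fresnel-integral closed form (matches numerical quadrature
to better than 10⁻⁹). The trace model is
`V(t) = [1−λ+λ·∫P(r)K(t,r)dr]·e^{−kt}` — a homogeneous-3D (exponential)
intermolecular background, standard for frozen solutions. Background
correction fits a log-linear tail (default start: half the trace window)
and returns the isolated dipolar signal S(t) plus the modulation-depth
estimate; with the narrow default distribution the oscillation has not
fully damped by 2.5 µs, so λ̂ carries a few percent of systematic error
(harmless for the peak position; a 4 µs window recovers λ and k within 2%).

P(r) is recovered on a 1.5–8 nm grid (0.02 nm step, bracketing the ~3 nm
feature) by Tikhonov regularization with a second-difference penalty and a
nonnegativity constraint enforced inside the bounded least-squares solve
(not by post-hoc clipping); the result is unit-area normalized. The
regularization weight is chosen at the maximum curvature of the
(log residual, log seminorm) L-curve over 40 log-spaced α values
(10⁻⁴–10²). Two robustness measures matter in the constrained setting,
where the L-curve is shallow and slightly jagged: the curve is lightly
Savitzky–Golay smoothed before differentiating, and a 3-point margin at
each end of the α scan is excluded from the corner search (raw
finite-difference curvature otherwise occasionally locks onto a boundary
artifact). For noiseless data the corner settles at small α, as expected
for a residual-dominated curve.

Peak and width of the recovered distribution are reported as the
parabolically refined argmax and the linearly interpolated full width at
half maximum; secondary local maxima reaching 90% of the global maximum
set a multimodality flag while the primary peak is still reported.

## Synthetic data: what it emulates, and what it does not

The generator stands in for the experimental samples with known ground
truth. Defaults encode the study conditions: flipped fraction 0.25;
stacked-conformer fluorine couplings T = 159/83 kHz (nominal distances
8.4/10.0 Å); flipped-conformer proximal fluorine with principal values
(580, −1668, −1952) kHz (a_iso ≈ −1.013 MHz) and distal T = 246 kHz with
its unique axis along g_x; three observer positions × τ ∈ {236, 620} ns;
additive i.i.d. Gaussian noise with σ = 5% of the spectrum maximum; a DEER
truth of mean 3.03 nm and FWHM 0.12 nm with λ = 0.3 and background
k = 0.2 µs⁻¹ over 2.5 µs. The Euler angles of the ¹⁹F tensors other than
F_b (and of the ring protons) are not published quantities; they are fixed
representative choices, recorded in one place in the source.

The contaminant background is a synthetic construct: smooth humps several
MHz wide in fixed physical units, emulating a fluorinated contaminant
radical whose structure is much broader than the small-coupling window. It
is not a simulation of that species. Instrument artifacts (resonator
profile, RF power droop, acquisition ordering), temperature effects, and
conformer-dependent relaxation are not emulated; passing closed-loop tests
therefore demonstrates the *inference machinery* (identifiability of f at
the stated noise, invertibility of the trace) and not robustness to those
experimental nuisances. Noise on the ENDOR spectra is i.i.d. per point,
which is optimistic relative to stochastic-acquisition noise with drifts.

## Problem sizes and determinism

Defaults are sized so the full test suite and the acceptance run complete
in seconds–minutes on one core: powder grids of 3000 orientations for the
multi-setting fit (convergence checks run at 10⁴–2×10⁴, where doubling the
grid changes max-normalized spectra by <1%), 20001-point cos θ grids for
Pake patterns, 251-point traces and 326-point r grids for DEER, a 40-point
α scan. All stochastic operations take explicit seeds and are reproducible
bit-for-bit; dataset manifests record every truth parameter and the seed.

## Known limitations

* First-order ENDOR only: no exact diagonalization, no quadrupole terms
  (¹⁷O is present in the nuclear data table for Larmor arithmetic only).
* Point-dipole tensors ignore spin-density delocalization; the default
  conformer parameterization therefore uses explicit tabulated-style
  couplings, and geometry-derived tensors are an opt-in alternative.
* The DEER kernel is orientation-averaged; orientation-selective PELDOR
  would need a correlated kernel.
* The edge-bias correction in the splitting reader assumes a
  one-sided inverse-square-root singularity; for heavily rhombic tensors
  the mid-principal-value peak is log-divergent and the correction slightly
  overshoots (the read-off is then conservative by a few tens of kHz).
* The background-fit window start is the user's responsibility; starting
  inside a strong residual oscillation biases λ̂ by up to ~6%.
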