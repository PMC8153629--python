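# Methods

This note documents the models implemented in `nemri`, the defaults and
units, what the synthetic phantoms do and do not emulate, and the design
choices made where the methodology was genuinely open.

## Units

Echo and repetition times are stored in milliseconds and converted to
seconds wherever they multiply a relaxation rate (s⁻¹) or relaxivity
(mM⁻¹·s⁻¹). The dynamic time axis is in minutes with the injection at
t = 0 (pre-injection frames negative), so the accumulation rate τ is in
min⁻¹ and half-lives are in minutes. ESR field axes are in mT, spin
content in mol per gram of tissue, hemolysis in percent of red cells
lysed.

## Forward signal model and phantom

The spoiled-GRE magnitude signal is modeled as
`S = M0·sin α·exp(−TE·R2*)` with `R2* = R2*(0) + r2*·C`. The full
steady-state expression including the `(1−E1)/(1−cos α·E1)` saturation
factor is implemented in the phantom only, to bound the error of ignoring
the longitudinal term: at the agent's r1 upper bound (0.1 mM⁻¹·s⁻¹ —
defaults use 0.05) and TR 30 ms the normalized-signal error stays below
~3%, and it vanishes at r1 = 0 (`test_full_steady_state_reduces_to_simplified_model`).

Default protocol: flip 30°, TE 3.4 ms, TR 30 ms, 60 s per dynamic frame
(the per-frame time is a free parameter of the acquisition — total scan
time divided by the number of images — and 60 s is used throughout).
Default agent: r2\* = 45 mM⁻¹·s⁻¹ (upper end of the measured 42–45
range), iron dose 3 mg/kg. Tissue states are plausible 4.7 T values
(liver T2\* 25 ms, renal cortex 40 ms, plaque 9 ms, near-zero-M0 air
background); they set the scene but no conclusion depends on their exact
values because every comparison is against the phantom's own ground
truth.

Magnitude noise is **Rician**: independent Gaussian noise of standard
deviation σ on two complex channels before the modulus. SNR statements
refer to (noiseless first-frame liver signal)/σ. At SNR ≥ 10 the
magnitude bias is ≈ σ²/2S, which is what the noise property test checks.

**Motion** is a respiratory surrogate: a sinusoidal-in-time bulk
displacement (default period 4 min across frames, random phase) shaped by
a broad Gaussian spatial envelope, applied as a backward warp. Gradients
of the displacement stay ≪ 1 voxel/voxel for the default 3-voxel
amplitude, so the deformation is smooth and invertible. It emulates
slowly varying organ drift, not intra-frame blur, cardiac pulsation,
through-plane motion, or signal dropouts — passing the tracking tests
therefore shows robustness to smooth in-plane deformation only.

## Motion estimation and ROI tracking

`estimate_motion` is a single-channel Horn–Schunck optical flow:
quadratic data + quadratic smoothness penalty, solved by Jacobi fixed
point iterations (cap 200/warp, tolerance 1e−3) inside a 3-level
coarse-to-fine pyramid with 3 warps per level. The regularization weight
is the classic α² in squared-intensity units; `track_organ` uses 2000 by
default — high enough that the flow stays smooth inside homogeneous
organs (which keeps the push-forward ROI voxel count within a few percent
of the reference), low enough to recover multi-voxel displacements.

The flow convention is `mov(p + d(p)) ≈ ref(p)`, so the reference-frame
ROI is propagated by pushing each voxel to `p + d(p)`, rounding to the
nearest voxel, and morphologically closing the result; a nearest-voxel
fallback guarantees a nonempty ROI and a frame whose ROI leaves the grid
entirely is an error. The reference ROI is eroded by 2 voxels first —
analysts draw ROIs inside the organ, away from partial-volume edges.

`align_echoes` reuses the same flow between echoes of a multi-echo train
after histogram-matching each echo to the first (T2\* decay is a monotone
intensity change on a piecewise-homogeneous object, which otherwise
violates brightness constancy). Because an echo train spans only tens of
milliseconds, the estimated field is reduced to its median translation
over high-signal voxels; echoes too noise-dominated to correlate with the
first echo (r < 0.75) are left untouched. Very low-SNR late echoes can
still pick up sub-voxel spurious shifts; the T2\* pipeline does not
depend on alignment unless shifts are actually present.

## Pharmacokinetics

Normalization uses the pre-injection baseline; both the first-frame
convention and the pre-injection mean are implemented, and the recovery
studies use the mean (it is less sensitive to single-frame noise; with a
baseline error ε every concentration shifts by ≈ ε/(TE·r2\*), which a
two-parameter accumulation fit cannot absorb). Concentrations from
S_norm > 1 (noise) are retained — clamping at zero would bias τ upward.

`fit_accumulation` fits `C(t) = Cmax(1 − e^(−τt))` over post-injection
samples only, by Levenberg–Marquardt (lmfit/MINPACK; xtol = ftol = 1e−12,
≤ 500 evaluations) with bounds Cmax ∈ (0, 10·max C], τ ∈ [1e−6, 10]
min⁻¹ and initialization Cmax₀ = max C, τ₀ = initial slope / Cmax₀.
Degenerate inputs (no positive concentrations) return a failed result
with a flag; a parameter pinned at a bound clears the success flag.

The recovery study uses a 96×96 grid (the liver ROI then holds ~1500
voxels, matching the noise floor of the original acquisition's much finer
matrix better than a 64×64 scale-down would), 8 pre- and 48
post-injection frames (≈ 50 min of uptake), Cmax 2 mM, SNR 30, motion
amplitude 3 voxels, injection gap 2 min. These sizes keep the full study
around two minutes on one CPU.

## T2* relaxometry

The SNR gate keeps voxels whose first-echo signal is ≥ 4× the noise
level; when no noise estimate is supplied it comes from corner background
patches via the Rayleigh relation (mean = σ√(π/2)).

A through-slice field gradient G_z modulates echo k by
`|sinc(γ·G_z·Δz·TE_k/2)|` (sinc(x) = sin x/x, γ the proton gyromagnetic
ratio in rad·s⁻¹·T⁻¹; the magnitude is used since images are magnitude).
The correction divides each echo by that factor; where the factor is
< 0.1 the echo is dropped from the fit rather than amplified, and the
noise amplification 1/factor of the remaining echoes is propagated into
the fit weights — without that weighting the corrected map is *worse*
than the uncorrected one at low SNR, because near-null echoes contribute
mostly amplified noise. The gradient map is supplied (known truth from
the phantom, or finite differences of a user field map); estimating ΔB0z
from multi-echo phase is out of scope.

Per-voxel fitting is mono-exponential `S = S0·e^(−TE/T2*)` without a
noise-floor term (the analysis relies on the SNR gate instead of floor
modeling): a weighted log-linear closed form (weights S², divided by the
squared noise amplification where applicable) initializes a
Levenberg–Marquardt refinement. Voxels need ≥ 3 usable positive echoes;
constant signals run to the 500 ms internal bound and are flagged
fit-fail. Validity filtering excludes T2\* strictly greater than 30 ms
(a voxel at exactly 30 ms is kept), and every voxel lands in exactly one
accounting bin — kept, low-SNR, outlier, or fit-fail — so the counts
always sum to the grid size. Slice means are arithmetic means of valid
segmented voxels; an empty slice is reported as empty, never as zero.
Slice correspondence across sessions is a user-supplied offset, not
inferred.

## ESR quantification

Spectra are first-derivative absorption lines; the default generator
lineshape is a Gaussian derivative (an 80 mT peak-to-peak width then
means σ = 40 mT; a Lorentzian with p-p width 2Γ/√3 is selectable).
Processing: linear baseline fit to the outer 10% of the sweep on each
side (centered-field design for conditioning), trapezoidal cumulative
integration to the absorption, **re-anchoring of the absorption** by a
second edge-fitted line, and a final trapezoid. The anchoring step
matters: white point noise integrates into a random walk whose drift
dominates the double-integral variance; anchoring the absorption
endpoints cuts the error at 5% spectral noise roughly threefold while
leaving lines that decay within the sweep unbiased (the analytic Gaussian
area is recovered to 0.1% at 0.7 mT/pt).

Calibration regresses mass-normalized double integrals on concentration
through the origin (zero spins ⇒ zero intensity); a fitted line over all
references is used, with a single-reference path available through the
same arithmetic. Quantification divides by the slope; the reported
uncertainty is an expanded (k = 2, ≈95% coverage) combination of the
slope standard error and the sample's double-integral noise, the latter
propagated exactly through the linear processing chain from the
line-free-edge noise estimate. Resonance arithmetic uses
g = hν/(μ_B·B) with CODATA constants; the printed pairing of "about
320 mT" with g = 2.12 at 9.54 GHz is self-consistent only to ~0.5%, so
the field is always treated as an input rather than reconciled.

## KRL reduction

Hemolysis kinetics are logistic in time (default steepness 0.08 min⁻¹,
i.e. a rise spanning ~1 h around T50); the generator refuses grids that
never reach the 50% crossing. T50 is the linear interpolation at the
first upward 50% crossing; if noise creates several crossings a 3-point
median filter is applied first and the result flagged. The antioxidant
effect is 100·(sample − control)/control — scale-invariant, and *not*
antisymmetric under swapping roles (a property test documents this).
Trolox equivalents invert a user-supplied monotone calibration by linear
interpolation and divide by the emulsion mass tested; shifts outside the
calibrated range are rejected. The synthetic studies use a control T50 of
100 min, effect sizes of +104.63% and −10.95%, and a linear calibration
of 2 min per mg over 0–60 mg with a true loading of 44.62 mg/g — the
magnitudes the assay must resolve. Per-run controls are assumed; no
dose–response modeling is attempted.

## Pipeline and provenance

`RunConfig` (pydantic) carries every stage parameter with the defaults
above; physical constants live in `nemri.constants`. Reports carry the
config digest, seed and package version, and rerunning a config + seed
reproduces byte-identical headline numbers. The full default synthetic
experiment runs in well under a minute; the 20-series recovery study in
about two minutes.

## Known limitations

* The phantoms are piecewise-homogeneous 2D objects; partial volume,
  perfusion heterogeneity, B1 inhomogeneity and k-space artifacts are not
  modeled, so the measured accuracies are upper bounds on real-data
  performance.
* The single-compartment accumulation model ignores spleen/bone-marrow
  clearance; τ is an apparent liver-uptake rate.
* Echo alignment corrects bulk shifts only and can be perturbed by
  noise-dominated late echoes.
* No R2\*↔iron calibration in tissue is attempted, and ESR lineshape
  physics (superparamagnetic ensembles, temperature, saturation) is out
  of scope.
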