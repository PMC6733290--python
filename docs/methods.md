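# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, and what the synthetic generators do and do not
emulate.

## Terahertz optical constants

Model: transmission through a homogeneous slab of thickness *d* between
identical empty-cell reference measurements.  The transfer function is the
complex ratio of the sample and reference spectra; the inversion assumes

* two-interface Fresnel amplitude transmission 4n/(n+1)²,
* Beer–Lambert attenuation exp(−αd/2) in amplitude,
* propagation phase −ω(n−1)d/c,
* **no Fabry–Pérot etalon terms**, in either the forward model or the
  inversion.  Pellets of a few hundred micrometres make the first echo
  separable in time, and the glass-transition analysis uses only the
  relative temperature dependence of α(1 THz), for which a constant
  etalon bias cancels.  The quartz-window sandwich of a cryostat cell is
  treated as common mode (the reference is measured through the same
  windows) and not modelled separately.

Numerics.  Waveforms are transformed with a real FFT; frequencies are in
THz (1/ps), lengths in cm, so c = 0.0299792458 cm/ps.  Phase is unwrapped
and anchored by fitting a line to the 0.2–0.8 THz phase and removing the
zero-frequency intercept rounded to the nearest multiple of 2π — the
standard remedy for the 2π branch ambiguity of unwrapping.  Bins where the
reference magnitude falls below 10⁻³ of its peak are masked; bins where
|H| exceeds the Fresnel factor (which would give α < 0) are flagged in the
mask rather than raised, since they occur routinely at band edges.  The
probe-frequency absorption is the mean of α over 1 ± 0.05 THz (window
configurable; single nearest bin when fewer than 3 bins fall inside),
which evaluates a locally linear α(f) exactly at the probe frequency.

The synthetic slab generator shares this physics exactly, which makes the
forward→inverse round trip an identity test (observed agreement is at
machine precision over 0.3–2.0 THz; the suite asserts 1 %).  It therefore
does **not** test sensitivity to etalon echoes, detector response, delay
jitter or water-vapour lines — on real data those effects enter the
extraction as structured noise that this package does not remove.

## Three-region glass-transition analysis

The absorption–temperature series is segmented into three contiguous
regions by exhaustive search over all ordered breakpoint-index pairs with
at least `min_pts = 3` points per region (O(n²) pairs, closed-form OLS per
segment via prefix sums).  Lines are fitted independently — no continuity
constraint — and the transitions are the line intersections, so they need
not coincide with grid points.  When replicate standard errors are
present, segments are fitted by weighted OLS (weights 1/SD²) and slope
standard errors come from the unscaled (XᵀWX)⁻¹; otherwise the residual
variance scales the covariance.  SSE ties (ubiquitous on noiseless data)
are broken toward the most balanced segmentation, then the smallest
breakpoint pair, making the fit fully deterministic.  A degenerate series
whose regions fit parallel lines yields NaN transition temperatures rather
than an error; the explicit `intersect` helper raises on slope differences
below max(10⁻⁸, 10⁻⁶·|m|).

Confinement classification: *confined* requires the region-3 slope to sit
below the region-2 slope **and** the decrease to exceed
`confinement_z = 5` combined standard errors.  The threshold is
deliberately conservative: region-3 slopes come from the shortest, hottest
segment and are often poorly determined, and a slope decrease of only a
few combined SEs is routinely a noise artefact rather than a genuine
absorption plateau.  With this default, published slope/SE tables for the
formulation set studied here classify exactly as their authors describe
(plateaus for the three BSA/sucrose-or-trehalose formulations and the
polysorbate-containing antibody formulation; monotonic growth for the
rest).  Both the ratio threshold and z are configuration keys.

Cycle comparison reports the region-3 slope change with propagated SE and
flags hysteresis when the mobility classes differ or |Δm₃| exceeds
2 combined SEs.

The piecewise generator is continuous at its breakpoints — real fits of
independent lines need not be — which is what makes intersection-recovery
round trips exact.  Its default grid uses 10 K increments over 100–380 K
(the typical cryostat heating protocol); the validation suite uses a 2 K
grid so that segment point counts do not limit breakpoint precision.

## FTIR amide-I deconvolution

Chain: excipient subtraction → area normalisation → Savitzky–Golay second
derivative → ten-Gaussian fit → class assignment → area fractions.

* **Excipient subtraction** scales the excipient spectrum by the ratio of
  baseline-corrected peak heights within ±5 cm⁻¹ of the isolated
  851 cm⁻¹ excipient band; an excipient spectrum without a local maximum
  there is an error.
* **Amide-I window**: 1600–1700 cm⁻¹, the conventional definition,
  exposed as configuration and logged at WARN once per run.
* **Second derivative**: Savitzky–Golay, window spanning 14 cm⁻¹ (15
  points at 1 cm⁻¹ resolution), cubic polynomial; edges where the filter
  support is incomplete are truncated.
* **Band fit**: the model is a sum of ten Gaussian absorbance components
  pushed through the *same* Savitzky–Golay second-derivative operator as
  the data, so data and model see an identical transform and the
  noiseless optimum is the generating parameter set.  (Fitting analytic
  second-derivative profiles against the smoothed trace was tried first;
  the operator mismatch combined with band overlap left the class
  fractions unidentifiable.)  Initial centres are the deepest negative
  local minima of the trace, padded from a canonical amide-I component
  position list when smoothing has merged neighbours; initial widths come
  from the zero-crossing span of each minimum's lobe.  Identifiability
  constraints: centres may move at most ±3 cm⁻¹ from their start, widths
  are bounded to σ ∈ [2, 6] cm⁻¹, amplitudes are non-negative.  Without
  these bounds the ten-Gaussian decomposition admits near-zero residuals
  with arbitrary area splits.  The best of four jittered trust-region
  starts is kept; convergence is judged by the residual share of the
  trace because overlapped components leave near-flat directions that can
  exhaust the iteration budget after the fit has effectively converged.
* **Assignment**: half-open centre intervals — β-sheet [1600, 1640) and
  [1680, 1695); random coil [1640, 1646); α-helix [1646, 1665); turn
  [1665, 1680).  The anchors (helix ≈1658, sheet ≈1640 with 1670/1690
  shoulders) are standard; the exact boundaries are a configuration table
  because no canonical partition exists.  Bands outside every interval
  are excluded from the denominator and logged.  Areas are those of the
  underlying absorbance Gaussians (amplitude·σ·√(2π)).

The synthetic amide generator places same-class components close together
(smoothing may merge them — harmless, the area stays in the class) and
separates adjacent classes by ≥ 8 cm⁻¹ with σ = 3.2 cm⁻¹ components.
Validation recovers class fractions within ~1 point noiseless and within
5 points at SNR 100.  Real amide-I envelopes are less favourable — broader
components, classes meeting without gaps — which is why published
fractions of this kind carry ±8–13 % uncertainties; passing the synthetic
suite shows the chain is correct and stable, not that real-data accuracy
is 1 %.

## CD

Mean residue ellipticity implements [θ] = θ_obs/(l·c·n) literally with the
path length in **millimetres** — this embeds the conventional factor of 10
relative to cm-based definitions, and the result object records the
convention to prevent silent misuse.  Accumulation averaging is a plain
pointwise mean with SD; no outlier rejection.

Classification is deliberately qualitative: helix-rich needs negative
local minima within ±3 nm of both 208 and 222 nm plus a positive value at
193 ± 2 nm; sheet-rich needs all negative minima concentrated within
218 ± 4 nm and neither helix minimum; everything else — including flat
spectra and balanced helix/sheet mixtures, whose merged minimum falls
between the sheet and helix anchors — is *indeterminate*.  No quantitative
basis-set deconvolution (CONTIN/SELCON-style) is attempted.  The synthetic
bases are parameterised Gaussian band sets reproducing the textbook
signatures, not measured reference spectra.

## ssNMR relaxation

Inversion recovery is fitted as M(t) = M₀(1 − 2A·e^(−t/T₁)) with the
correction factor A free within (0, 1.2] (published protocols rarely state
whether A was fixed; floating it absorbs imperfect inversion), initialised
at M₀ = M(longest delay), A = 0.9 and T₁ = t₀/ln 2 from the zero-crossing
delay.  The spin-lock decay M(t_SL) = M₀·e^(−t_SL/T₁ρ) is initialised from
a log-linear regression when all points are positive.  Standard errors are
the lmfit covariance estimates; fits restart with jittered initial values
on failure.  Default delay grids are the standard 8-point sets
(0.01–5 s and 0.1–50 ms).

Phase homogeneity: ΔT = T_protein − T_sugar with combined SE
√(SE_p² + SE_s²); *homogeneous* iff |ΔT| ≤ 2·SE, labelled with the
spin-diffusion length scale (T₁ → 20–50 nm, T₁ρ → 2–5 nm).  Heating
comparisons use the same 2-SE rule per component.  Inputs are integrated
magnetisation tables; a thin trapezoidal integrator over the 165–185 ppm
(protein carbonyl) and 67–102 ppm (sugar) windows is provided for users
starting from full spectra, but spectral deconvolution is out of scope.

## Pipeline

`run_formulation` applies the residual-moisture QC gate (strict < 2.5 %
w/w; missing values warn and pass through as *unknown*), then runs every
stage with available inputs, catching per-stage exceptions so one corrupt
file cannot abort a study run.  Reports serialise losslessly to JSON and
carry provenance (config hash, seed, input paths); two runs with identical
config and seed produce byte-identical reports.  All analysis constants
above are fields of a validated YAML-loadable configuration with the
defaults stated here.

## Problem sizes used in validation

Temperature series: 141 points (2 K steps, 100–380 K) for exact round
trips, 29 points (10 K steps) for Monte-Carlo breakpoint studies (50
seeds, noise SD 0.05 cm⁻¹).  THz: 2048 samples at 0.05 ps, 3×3 (n, α)
inversion grid.  FTIR: 1 cm⁻¹ grid over 1580–1720 cm⁻¹, SNR-100 noise
realisations.  Relaxation: 200 seeds at 2 % noise per estimator.  These
sizes keep the full suite around a minute on one CPU while leaving every
statistical assertion comfortably powered.

## Known limitations

* No Fabry–Pérot/etalon handling or window-correction terms in the THz
  inversion; absolute α on real pellets carries the corresponding bias.
* Exactly three temperature regions; no VFT/Arrhenius mobility models.
* The FTIR chain estimates fractions only as well as centre-based
  assignment allows; components straddling a class boundary are assigned
  wholly to the class containing their centre.
* CD analysis is qualitative by design.
* Heteroscedastic noise models, baseline drift and detector response are
  not simulated.
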