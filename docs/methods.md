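# Methods

This note records the models, conventions, numerical choices and known
limitations behind `chemholo`.  Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Units and conventions

All lengths are micrometres; spectra may be tagged in wavenumbers with
ν̄[cm⁻¹] = 10⁴/λ[µm].  The free-space wavevector is k = 2π/λ and the time
convention e^{−iωt}, so a medium with extinction coefficient κ ≥ 0 attenuates
e^{iknz}.  Image grids are row-major with physical coordinates centred on the
grid.  Reciprocal-space coordinates are ordinary frequencies (cycles/µm).

## Coupled-wave layer solver

Layers 0..L−1 are separated by L−1 strictly increasing internal boundaries;
the outer two layers are unbounded and the incident wave is specified at a
coordinate z₀ inside layer 0.  Each layer carries one up-going and one
down-going amplitude, *anchored at its entry boundary*, so every propagation
factor appearing in the continuity equations decays for absorbing layers and
the boundary system stays well conditioned.  Rather than assembling
continuity equations for all three Cartesian field components, the solver
works per polarization (s or p, selected after rotating the transverse
wavevector onto the x-axis) with scalar amplitudes and reconstructs the
3-vector amplitudes from polarization unit vectors orthogonal to the
propagation vector — Gauss's law s·P = 0 then holds exactly by construction.
Correctness rests on closed-form oracles rather than transcription: the
solver is required (in the test suite) to match the Fresnel coefficients,
the thin-film reflectance formula, Brewster's angle, Beer–Lambert
attenuation through an index-matched absorbing layer, and R + T = 1 for
random lossless stacks, all to 1e-10.  Power bookkeeping (R, T) is defined
only for lossless outer layers; the longitudinal flux per unit |E|² is
proportional to Re(s_z) for both polarizations in that case.

The branch of s_z = √(n² − s_x² − s_y²) is chosen with Im(s_z) ≥ 0 (decaying
evanescent/absorbed waves), ties broken toward Re(s_z) ≥ 0.

## Scalar Mie model and the 1-D representation

The sphere model is scalar: the incident plane wave e^{ikz} is expanded in
spherical waves and continuity of the field and its radial derivative at
r = a gives the series coefficient B_t per order (the closed form is checked
per order against a small numerical continuity solve in the tests).  The
series is truncated at the Wiscombe-style cap N = ⌈ka + 4(ka)^{1/3} + 2⌉,
then trimmed where |B_t| < 1e-14 of the peak.  Spherical Bessel/Hankel
functions come from scipy (complex arguments included).

In the radiation zone the scattered field factorises into e^{ikr}/(ikr)
times the angular amplitude S(θ) = Σ_t B_t e^{−itπ/2} P_t(cosθ).  The
reciprocal-domain representation samples S at radial spatial frequencies
v = sinθ/λ; frequencies beyond the light cone 1/λ are evanescent and carry
zero amplitude.  The image-plane (spatial) representation is the order-0
inverse Hankel transform of that spectrum, with the incident plane wave
contributing a unit constant that is retained by default.

S(θ) has a square-root kink at the light-cone edge.  That kink is physical,
and it sets the agreement floor between different discretisations of the
same transform: the 2-D FFT route (Cartesian frequency grid) and the 1-D
discrete Hankel route (Bessel-zero radial grid) of the same sphere agree to
a few parts in 10³ of the field peak at a 32 µm / 256-pixel configuration,
limited by how each grid samples the kink, not by either transform's
internal accuracy.  The test suite asserts this discretisation-limited bound
(2e-2 with margin) and separately documents the idealised 1e-4 equivalence
as an open gap.  Smoothing the edge with an apodisation factor would close
the gap but has no physical justification, so the spectrum is kept exact.

### Quasi-discrete Hankel transform

Both domains are sampled at scaled zeros j_n of J₀: with spatial extent R
and j_{N+1} the (N+1)-th zero, r_n = j_n R/j_{N+1} and v_m = j_m/(2πR).
The transform matrix follows from the Fourier–Bessel quadrature for
band-limited functions and is its own inverse up to conditioning; round
trips on band-limited profiles are exact to better than 1e-8 and the
Gaussian closed form is reproduced to 1e-10 (tested).

### Aperture band-limiting

An annular collection aperture keeps frequencies f_l = NA_in/λ ≤ v ≤
f_u = NA_out/λ.  In 2-D the mask acts on the FFT of the image; in 1-D it
multiplies the radial spectrum before the inverse Hankel transform.  An
aperture too small to retain any radial sample is an error, except in the
NA sweep where it is clamped to the first sample (the sweep's smallest
apertures would otherwise be undefined on the discrete grid).

### Two-sphere superposition

The two-sphere field is single-scattering superposition: each sphere
contributes its own image-plane radial profile centred at its position,
plus one incident wave.  Multiple scattering is deliberately excluded — the
structured perturbation of interest is the interference between the two
single-sphere fields.  The perturbing sphere's contribution decays only
algebraically (band-limited spectra transform to ~r^{−3/2} tails), so even
at eight times the field of view it perturbs the extraction at the 1e-2
level; tests assert the vanishing trend rather than an unattainably small
bound.

## Phase-stepped holography

Frames are I_m = |E_S + E_R e^{ikΔ_m}|² at uniform reference offsets
Δ_{m+1} − Δ_m = δ, starting at Δ₁ = 0.  The default step convention is
δ = Δ_total/M (32 frames over 2 µm give δ = 0.0625 µm); Δ_total/(M−1) is
available via `uniform_deltas(..., convention="total/(M-1)")`.  Differencing
consecutive frames cancels the DC terms exactly and leaves, per pixel, a
linear system in the two conjugate cross-terms, solved by `lstsq`
simultaneously for all pixels; E_S follows from the first cross-term, while
the second provides a per-pixel consistency metric (`conjugate_mismatch`).
Three frames (two difference rows, two unknowns) are the minimum; k·δ ≡ 0
(mod π) makes the two columns degenerate and raises a dedicated error.  An
optional per-pixel sinusoid fit at the known wavelength cross-checks the
canonical pseudo-inverse path.  Reconstruction error for noiseless synthetic
data sits at the float64 floor (~1e-15, asserted); with additive Gaussian
intensity noise the error grows linearly in σ (slope and R² asserted).

Experimental stacks load from multi-page TIFF with caller-supplied step and
wavelength metadata; whether the reference amplitude is a measured frame or
an assumed constant is left to the caller (both scalar and per-pixel E_R are
accepted).

## Layered inversion

Candidates m_i = m_min + iε with d_i = P/m_i (half-open grid, default
ε = 1e-3 over m ∈ [1.1, 2.0]) are scored by the wrapped phase difference
between the simulated and measured detector fields; κ is then fitted on
κ ∈ [0, 0.1] (same ε) by amplitude mismatch.  Two refinements beyond the
plain two-stage search:

* a coordinate-descent pass re-runs the phase stage with the fitted κ in
  the candidate forward models.  κ's phase footprint through interface
  reflections is small but, at ε = 1e-3, large enough to shift the argmin by
  one grid step; one refinement pass restores exact on-grid recovery.
* the measurement is the pixel average over a flat detector image (default
  128² pixels), which is what makes m and d robust to noise: the averaged
  phase noise stays below the inter-candidate phase spacing, while the
  κ amplitude fit — κ being an order of magnitude smaller — degrades first.
  Noise σ is quoted relative to the unit incident amplitude.

Geometry defaults for the reference experiment: λ = 1 µm, the sample's
lower boundary at z = 0, detector 2 µm beyond the upper boundary.  With the
default m-range at this wavelength, the wrapped-phase aliases d_true ± λ
fall outside the candidate thickness range, so the noiseless argmin is
unique.

## Inverse-Mie networks

The training corpus is a full factorial grid: 30 levels each of
a ∈ [1, 2] µm, m ∈ [1.1, 2.0], κ ∈ [0.01, 0.05] → 27 000 spheres at
λ = 1 µm.  Each sample's input is the spatial-domain total field on the
near-uniform Bessel-zero grid of 320 radii over an 8 µm half-field,
separated into real and imaginary channels (640 inputs).  The intensity
corpus replaces the channels with (√(re² + im²), 0) — a representation
blind to global phase, which is exactly the information holography adds
(asserted as a property test).  The corpus is shuffled and split 9:1 into
training-pool and test, with 20 % of the pool held out for validation:
19 440 / 4 860 / 2 700 samples.

The network is a single tanh hidden layer of 5 units with a linear 3-unit
output, Glorot-normal initialisation with σ = √(2/(N_in + N_out)) from each
layer's actual fan-in/out, trained 400 epochs at batch 200 with Adam at
1e-3 on the MSE.  The κ label is min–max scaled to [−1, 1] on the training
labels (its raw magnitude is 30–60× smaller than a and m) and the scaling
is inverted before any error metric.  Inputs are z-score standardised per
feature (fitted on the training inputs): raw-field training is seed-unstable
— some seeds never learn the refractive index — while standardisation
stabilises every seed without changing the information content.

The error metric is the per-label relative RMSE in percent.  Its printed
formula admits two readings, √(mean(Δ²/y)) and the conventional
√(mean((Δ/y)²)); both are computed and reported (`EvalReport.eps_printed`
and `.eps_ratio`), with the conventional ratio form used for headline
reporting because only it gives a scale-consistent error across labels of
very different magnitude.  A deeper preset (3 × 64 tanh units) is provided
for the capacity comparison; its exact reference architecture is not
specified, so deep-network numbers are treated as directional only.

### Robustness sweeps

Three paired experiments retrain both representations with a fourth input
feature and evaluate per sweep point:

* **Noise** — per channel, zero-mean Gaussian noise with σ = fraction ×
  RMS(clean sample), fractions spanning [0.01, 1.00]; intensity inputs are
  computed from the *noisy* complex fields; the fraction is the fourth
  feature.
* **Aperture** — NA_out ∈ [0.02, 1.01] masks the radial spectrum before the
  inverse Hankel transform (clamped to the first frequency sample when the
  passband would be empty); NA is the fourth feature.
* **Two spheres** — both spheres share the (a, m, κ) label; the perturber
  approaches from 8 µm down to 2 µm (combinations closer than contact, 2a,
  are skipped); inputs are right-half line extractions through the central
  sphere (320 uniform samples over (0, 8 µm]); separation is the fourth
  feature.

The sweep deliverable is the ordering — complex-trained error at or below
intensity-trained error — on the mean relative RMSE over the three labels
at every sweep point.  These orderings are only resolvable when both
networks actually learn, which requires corpora near the full sweep scale
(10³ label grid × ~10² sweep values); at small scaled-down sizes both
networks sit at the predict-the-mean floor and the comparison is dominated
by noise.  The test suite therefore runs the noise sweep at 30 levels and
the aperture and two-sphere sweeps at the full 100 sweep values.  For the
two-sphere sweep the every-separation ordering does not hold under this
package's single-scattering model and separation range: the ordering is
clear on the sweep average and at weak perturbation, but crosses at a
minority of separations where the interfering sphere dominates the
extraction; the strict test records that gap while companion tests assert
the attainable mean ordering and the interference-driven fluctuation of
error with distance.

## Problem sizes used by the default test run

Chosen as the package's standard verification settings: the full 27 000
corpus with 3 training trials per representation for the clean-data
ordering; 100 epochs for the deep-network ordering; sweeps as configured in
the acceptance tests; 8 random recovery problems for the layered-inversion
property.  `scripts/acceptance.py` uses 10 trials per representation.

## Known limitations

* The Mie treatment is scalar: no vector spherical harmonics, no
  polarization-resolved scattering, no interior field, no coated spheres.
* The two-sphere model neglects multiple scattering.
* The coupled-wave solver handles planar, laterally uniform stacks only.
* The 5-hidden-unit network under this training protocol does not reach the
  lowest published shallow-network errors; the same corpus supports much
  lower errors with the deeper preset, indicating a representation-adequate
  corpus and an optimisation-limited shallow fit (see the acceptance tests
  for measured values).
* The synthetic corpora are noiseless, perfectly calibrated and perfectly
  registered; passing tests demonstrate algorithmic correctness and the
  information advantage of complex data, not instrument-level performance
  on real holograms (vibration, drift, source fluctuations are out of
  scope).
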