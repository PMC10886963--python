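# Methods

`sesorsmc` simulates how light launched onto skin interacts with an
implant-sized SERS-active target and where the Raman-shifted photons come
back out of the surface — the physics underlying spatially offset Raman
detection (SORS/SESORS) of subcutaneous biosensors.  It also implements the
matching measurement-side preprocessing chain for Raman spectra.  This note
records the model, its assumptions, the defaults and why, and what the
synthetic inputs do and do not capture.

## Photon transport model

The engine is a weighted-packet multi-layer Monte Carlo of the classic
hop/drop/spin form:

* **Hop.** Free paths are sampled from the exponential law
  `s = −ln(u)/µt`, `µt = µa + µs`, with the coefficients of the region the
  packet is currently traversing (determined by probing 1 nm ahead of the
  packet, which makes behavior on boundaries unambiguous).
* **Drop.** At each interaction the fraction `µa/µt` of the packet weight is
  absorbed.  Packets below a weight of 1e-4 play Russian roulette: they
  survive with probability 0.1 and have their weight multiplied by 10,
  which keeps the estimator unbiased.  Both numbers are the long-standing
  defaults for this class of engine and are configurable; setting the
  threshold to 0 disables roulette, in which case weight is conserved to
  round-off (every packet eventually leaves the open-boundary volume).
* **Spin.** Deflection cosines are drawn from the Henyey–Greenstein phase
  function with anisotropy `g` (inverse-CDF sampling; `g = 0` reduces to
  isotropic) and the azimuth uniformly.
* **Boundaries.** The tissue–air top surface applies unpolarized Fresnel
  reflectance with whole-packet probabilistic reflect/transmit; packets
  transmitted through the top are tallied as surface exits.  Internal
  interfaces are index-matched (all tissues share one refractive index, air
  above is n = 1.0), and the lateral and bottom faces are open: packets
  reaching them leave the problem and are logged separately.  After any
  boundary stop the remaining step is discarded and resampled — valid
  because the exponential distribution is memoryless.

### The inelastic (Raman) extension

At every scattering event **inside the inclusion**, a packet that has not
yet shifted undergoes a Stokes shift with probability `p_raman = 1e-2`.
This probability is orders of magnitude above the physical cross-section —
a standard variance trick that makes the weak process observable — so
absolute exit counts are meaningful only relative to each other, never as
predicted fluence.  On a shift:

* the emission channel is drawn from the branch probabilities of the
  four-peak MBA set (1072, 1430, 1582, 1702 cm⁻¹ at pH 7; weights
  proportional to the areas under the reference spectrum at those peaks,
  0.3747 / 0.1070 / 0.4649 / 0.0534);
* the new wavelength follows `λ' = 1/(1/λ − Δν̃)`;
* all subsequent optical-property lookups use the shifted wavelength index
  (unless the control mode `property_update=False` is set, in which case
  the index changes for tallying only);
* only one shift is allowed per photon.  Later scattering events inside the
  inclusion by an already-shifted packet increment an "additional criteria"
  counter (configurable to count p-draw successes instead).

Restricting Raman draws to the inclusion reflects that the modeled peaks
belong to the implanted SERS reporter, not to tissue.

### Geometry

A 2 × 2 × 2 cm box, z positive downward, beam entry at the origin of the
top face.  Default stack: 0.1 mm epidermis over dermis to full depth, with a
6 mm diameter, 1 mm thick SERS disc spanning 2–3 mm depth, laterally
centered under the beam.  All containment is half-open `[lo, hi)` so each
point belongs to exactly one region.  The source is an ideal point/pencil
beam entering at 45° from the vertical (no convolution over a beam
profile).  The default tilt azimuth is 180°, i.e. away from the +x axis
along which detection offsets are measured: tilting *into* the detection
columns moves the exit maximum to the 1 mm bin and destroys the monotone
zero-offset-maximum profile the model is meant to exhibit, so the default
keeps the tilt on the far side.  Azimuth, angle, layer stack and disc are
all configurable.

### Optical properties

Properties are precomputed at startup for every (tissue, wavelength-index)
pair — index 0 the excitation (785 nm by default, typical for MBA SERS),
indices 1–4 the Stokes wavelengths (857.1, 884.3, 896.3, 906.1 nm) — and
looked up in O(1); there is no runtime interpolation.  The shipped table:

| tissue    | µa @ exc (cm⁻¹) | µs @ exc (cm⁻¹) | g    | n    |
|-----------|-----------------|-----------------|------|------|
| epidermis | 3.50            | 220             | 0.90 | 1.40 |
| dermis    | 1.20            | 200             | 0.90 | 1.40 |
| inclusion | = dermis        | = dermis        | 0.90 | 1.40 |
| base      | 1.00            | 90              | 0.90 | 1.40 |

Dermis µs is anchored to decrease by exactly 14.68 % at the 1072 cm⁻¹
shift and 15.40 % at the 1582 cm⁻¹ shift relative to the excitation — the
two calibration anchors the package ships with — and other wavelengths and
tissues follow piecewise-linear monotone interpolations in wavelength (a
single power law cannot satisfy both anchors).  The base values are NIR
skin values from the tissue-optics literature; dermis µs ≈ 200 cm⁻¹ is
also consistent with the reference run's statistics (≈21 inclusion
scatters per photon through a 1 mm disc implies a scattering length of
about 50 µm).  The hydrogel inclusion is assumed optically matched to
dermis for lack of data on the implant's own turbidity.  µa declines
mildly with wavelength (water-window trend).  All of it can be replaced
via config or CSV.

### Random numbers and paired runs

Every deviate is a pure function of (seed, substream, photon id, draw
counter) through a SplitMix64-style hash.  Substreams are named per purpose
(step, Raman trigger, peak choice, roulette, spin, Fresnel), so a
conditional draw never shifts deviates used elsewhere.  Consequences:

* the scalar reference engine and the vectorized production engine consume
  identical deviate sequences and produce bit-identical tallies (asserted
  in the test suite — the per-photon scalar loop is the oracle);
* with/without-property-update pairs share random numbers draw-for-draw
  (common random numbers), which removes all pre-shift variance from
  percent-change estimates;
* runs are exactly reproducible across machines for a fixed seed.

Float ledgers (absorbed weight, exit weights) are accumulated per photon
and summed once in photon order so the two engines agree to the last bit
despite visiting photons in different orders.

### Tallies

Top-surface exits are binned on a 10 × 10 grid of 1 mm squares.  The tally
frame maps the beam entry to (x = 0.05, y = 0.5) cm: the center of column 1,
on the row 5/6 boundary.  Bins are half-open; exits outside the window are
counted per wavelength so binned + off-window always equals total top
exits.  Each in-window exit also feeds a per-bin histogram of the photon's
maximum visited depth (1 mm bins to 2 cm, deeper excursions clamped into
the last bin).  Offset profiles average the two rows bounded by y = 4–6 mm
at each column offset; percent changes and the 0→5 mm decline are simple
ratios on those profiles, with zero baselines marked NaN rather than
raising.  Heatmaps hold both raw packet counts (the default reported
quantity) and weight sums; the `weighted` tally flag switches profiles to
the fluence-like weight measure.

A consequence worth knowing: with open lateral/bottom boundaries, *packet
counts* respond only weakly to the post-shift µs decrease — the longer mean
free path raises top-exit probability and side/bottom losses almost equally
— while *weight* tallies respond strongly (total exit weight of shifted
photons rises by roughly 19 % for the 1072 cm⁻¹ channel and 38 % for
1582 cm⁻¹ when the update is enabled).  Count-based per-offset percent
changes therefore sit near zero for this geometry, which is the main known
divergence from the behavior the model family is reported to show; the
weighted mode is provided for the physically meaningful comparison.

"Steps" count every hop, boundary stops included; scattering interactions
dominate the statistic by three orders of magnitude.

### Problem sizes

The default headline run uses 1e5 photons (about half a minute vectorized),
which resolves the Raman-event fraction to ±0.4 % absolute and the offset
profiles to a few percent per column; paired percent-change estimates at
single-column granularity remain noisy at this size (±4–10 points), so the
reproduction script averages three seed-pairs.  Unit and invariant tests
use 10²–2·10⁴ photons.

## Spectrum preprocessing

The measurement chain mirrors how SERS spectra are acquired (one dark
spectrum and fifteen raw spectra per detector offset) and runs in fixed
order: dark subtraction (identical axes enforced) → cosmic-ray removal →
asymmetric least-squares baseline correction → peak-intensity extraction
(windowed maximum, ±10 cm⁻¹ — intensities are reported as single heights,
not areas) → replicate summaries (mean/min/max).

Cosmic rays are defined by two thresholds — breadth ≤ 2 wavenumbers and
amplitude ≥ 15 % of the (max − min) intensity range of the dark-subtracted
spectrum — and the breadth limit is what separates them from genuine MBA
peaks (~20 wavenumbers wide).  The detector behind those thresholds is this
package's choice: points whose positive residual from a 5-point running
median exceeds the amplitude threshold, grouped into contiguous runs,
excised and bridged by linear interpolation.  The operation is idempotent.

The ALS baseline is the standard Whittaker-smoother iteration: minimize
`Σ wᵢ(yᵢ − zᵢ)² + λ Σ(Δ²z)²` with weights `p` above the fit and `1 − p`
below, defaults λ = 1e5, p = 0.01, 10 iterations (early exit on weight
convergence).  These are conventional values for Raman baselines; λ trades
baseline stiffness against peak erosion and is the parameter worth touching
first.  The sparse solve is cross-checked against an independently
assembled dense solver in the tests.

### Synthetic spectra

`synth_spectrum` emulates an acquisition: four Gaussian MBA-like peaks
(20 cm⁻¹ FWHM, heights 1000/300/1250/150 a.u. in the reference-peak-heavy
pattern of MBA at pH 7) on a smooth quadratic baseline over a 100-count
dark level, white noise (σ = 5 a.u.), and optional 1–2-point spikes of
20–50 % of the signal range, placed ≥ 30 cm⁻¹ from any peak so that
recovery assertions are meaningful.  A truth record carries every injected
component.  What it does not emulate: detector nonlinearity and etaloning,
wavelength-calibration drift, baseline shapes with sharp curvature,
shot-noise scaling with intensity, and spikes landing on peaks — so passing
tests demonstrate the chain's correctness on well-behaved instrument-like
input, not robustness to every pathology of real spectrometers.

## Known limitations

* Internal refractive-index mismatches (e.g. a stratified barrier) are not
  modeled; only the tissue–air surface refracts.
* Raw packet counts are kept as the default tally for comparability, with
  the caveat about their insensitivity to the property update described
  above.
* The property table is a calibrated reconstruction, not a measured
  dataset; absolute event counts inherit its uncertainty.
* Anti-Stokes lines, continuous emission, fluorescence, polarization and
  time-gated detection are out of scope.
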