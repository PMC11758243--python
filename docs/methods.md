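# Methods

This note documents the models implemented in `scos`, the choices made where
the design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Processing model

**Raw contrast (per frame).** Each camera frame `I` is reduced to one squared
spatial speckle contrast `K_raw² = σ²(I)/μ²(I)`, computed with the population
variance (divide by N) over the whole frame or the analysis mask. Whole-frame
statistics, not spatially windowed contrast maps, are the point of this kind
of instrument: one channel yields one K per frame at the camera frame rate.
At ≥10⁴ pixels per frame the population/sample variance distinction is
far below every other uncertainty. Saturated pixels (`DN == 2^bit_depth − 1`)
are excluded from the mask by default and the excluded fraction is logged,
since clipped values bias the variance downward.

**Noise correction.** The measured variance contains sensor contributions
that are subtracted in squared-contrast units:

    K_adj² = K_raw² − K_shot² − K_quant² − K_cam²

with the standard camera-calibration forms, everything in digital numbers
(DN): `K_shot² = 1/(g·μ)` for conversion gain `g` [e⁻/DN], `K_quant² =
(1/12)/μ²` for a 1-DN quantization step, and `K_cam² = σ_r²/μ²` for read +
dark noise of `σ_r` DN. Camera parameters come from a `CameraModel`
(per-session calibration-frame ingestion is possible by constructing the
model from measured `g` and `σ_r`, but is not a separate input path).
Frames where the subtraction is non-positive — possible at very low light
where the noise terms dominate — are **flagged invalid and excluded**, never
clamped: `1/K²` of a clamped value would be arbitrary and explosive. Invalid
counts are logged and recorded in the run log.

**Flow index.** `CBFI = 1/K_adj²` on valid frames. For comparability across
channels and subjects the normalized trace divides by the mean CBFI over a
baseline window; the default window is the first 5 seconds (clipped to the
recording if shorter). The same window defines the blood-volume baseline.

**Volume indices.** From the per-frame spatial mean intensity `μ(t)` (DN) and
its baseline mean `I₀`:

    CBVI_linear(t) = 2 − μ(t)/I₀        (baseline value 1)
    CBVI_log(t)    = log10(I₀/μ(t))     (baseline value 0)

Both are first-class outputs. The linear form is the default output column
for continuity with the linear convention; the logarithmic form is exact
under exponential attenuation and preferable for large excursions (the linear
form is its first-order expansion: `CBVI_linear − 1 = ln(10)·CBVI_log +
O(δ²)` for fractional excursion δ). No Beer–Lambert pathlength model is
implied; these are indices, not absolute hemoglobin quantities.

**Cross-channel analysis.** The pairwise statistic is the plain Pearson
coefficient on the normalized CBFI traces over the full recording, with **no
detrending or band-pass filtering** — none is part of the definition, and
adding one silently would change what ρ measures; callers can pre-filter
traces explicitly if they want. Samples invalid in either channel of a pair
are dropped pairwise (complete-case; counts logged). "Distinct channel
groups" are operationalized as connected components of the graph whose edges
join pairs with ρ ≥ threshold; the default threshold of 0.6 sits between
the within-group and cross-group correlation levels observed in practice and
is exposed as a parameter.

## Synthetic-data generator

The simulator exists so every processing stage can be verified against known
ground truth without instrument data. It emulates, per channel:

1. **Spatial statistics.** A circular complex Gaussian field generated by
   low-pass filtering white complex noise with a circular pupil in the FFT
   plane. The pupil radius is calibrated so the 1-D speckle/pixel length
   ratio is `sp_ratio` (default 0.5, i.e. ~4 speckles per pixel area). The
   field lives on a fine grid oversampled by `ceil(1/sp_ratio)` relative to
   the sensor; sensor pixels are block averages of fine-grid intensity, which
   is what physical pixel-area integration does. The speckle is marginally
   sampled on the fine grid; the resulting effective contrast ceiling
   `β̂ ≈ 0.27` at `sp_ratio = 0.5` is *measured* (see `estimate_beta`), not
   asserted, and every oracle comparison is expressed relative to it.
2. **Temporal statistics.** Field autocorrelation `g1(τ) = exp(−τ/τ_c)`
   (single-scattering Lorentzian form); every Fourier mode evolves as an
   AR(1) process, which reproduces `g1` exactly, and the Siegert relation for
   Gaussian fields then fixes the intensity statistics. The expected frame
   contrast is the standard visibility curve
   `K²(x) = β(e^(−2x) − 1 + 2x)/(2x²)`, `x = T/τ_c`, provided in closed form
   by `theoretical_contrast` as the independent oracle.
3. **Exposure integration.** Trapezoidal quadrature over `M+1` snapshots with
   `M = max(10, ceil(20·T/τ_eff))` (sub-frame spacing ≤ τ_eff/20). Trapezoid
   weights matter: plain snapshot averaging at the same M biases the expected
   contrast by up to +0.4% relative (worst near x ≈ 0.5), while the
   trapezoidal rule keeps the residual bias below 0.1% — small compared with
   the 3-standard-error bands used in the oracle tests.
4. **Time-varying flow.** `relative_flow(t)` scales the decorrelation rate,
   `τ_eff = τ_c/relative_flow`, held constant within one exposure: cardiac
   flow variation is ~1 Hz, three orders of magnitude slower than a 6-ms
   exposure.
5. **Sensor stage.** Scale to electrons by the gain → Poisson shot noise →
   additive Gaussian read+dark noise → back to DN → round to integer DN →
   clip at saturation. The three steps map one-to-one onto the three
   subtracted noise terms.
6. **Cardiac waveform.** Each beat is a unit baseline plus two positive
   bumps: an asymmetric (fast-rise, slow-fall) systolic peak and a smaller
   dicrotic bump, periodic in beat phase and normalized to unit mean over the
   whole beats actually sampled (so the sampled mean is 1 to float
   precision). The functional form is a modelling choice — what matters
   downstream is a strictly positive, periodic waveform with a dominant
   fundamental and a secondary intra-beat feature. Optional beat-to-beat
   amplitude jitter (`variability`) is off by default.
7. **Scenes.** Multi-channel recordings share one frame grid and timing;
   channels share the baseline waveform unless listed as "altered", in which
   case they follow an independent waveform (different rate and pulse shape,
   emulating a region decoupled from systemic dynamics). Per-channel
   transmission scales multiply the mean level; volume coupling modulates the
   mean level by a scaled copy of the waveform (`volume_modulation`, default
   0.2) so the volume index carries the cardiac fundamental — a plumbing
   device, not an absorption model.

### Default operating point

| parameter | default | why |
|---|---|---|
| exposure `T` | 6 ms | instrument operating point |
| frame rate | 40 Hz | instrument operating point |
| bit depth | 8 | instrument operating point |
| `sp_ratio` | 0.5 | ~4 speckles/pixel operating point |
| `τ_c` | 3 ms (x = 2) | mid-curve: contrast sensitive to flow in both directions |
| `β` (source) | 1.0 | effective ceiling is measured, not assumed |
| mean level | 100 DN | ~40% of 8-bit range: headroom for speckle tail + noise |
| gain | 2 e⁻/DN | typical CMOS board-camera scale |
| read noise | 2 DN | typical CMOS board-camera scale |
| frames | 256×256 (desk scale) | statistics scale with pixel count; the full 3840×2160 sensor only shrinks error bars |
| heart rate | 60 bpm (altered: 75) | whole beats fit a 12-s recording for both rates, keeping periodic leakage out of cross-group correlations |

What the simulator does **not** emulate: rolling-shutter readout (frames are
treated as globally shuttered; no correction is applied on the processing
side either, so the comparison is consistent), photon-transport depth
sensitivity and scalp-vs-brain partial volumes, motion artifacts,
physiological variability beyond the cardiac waveform (no respiration, no
Mayer waves), and spatial heterogeneity within a frame. Passing tests
therefore demonstrate the correctness of the *processing chain* under the
stated speckle model — not the instrument's in-vivo sensitivity.

## Numerical choices and degenerate inputs

- Contrast estimates use float64 throughout; field evolution uses complex64
  (the per-substep FFT dominates runtime; contrast error from single
  precision is orders of magnitude below speckle sampling noise).
- `theoretical_contrast` switches to a 2nd-order series below `x = 1e-4` to
  avoid catastrophic cancellation, evaluates `x = 0` as β and `x = ∞` as 0,
  and rejects negative x.
- Pearson ρ is clipped into [−1, 1] after evaluation; constant traces raise
  an explicit undefined-correlation error rather than returning NaN silently.
- Baseline windows are closed intervals in time. `compute_baseline_intensity`
  is strict (a window extending past the recording is an error); the pipeline
  wrappers clip the default window to short recordings.
- Recordings longer than the configured cap (default 180 s) are truncated
  with a warning, mirroring the capped-recording operator workflow.
- Simulated-scene statistics in the test suite run at reduced scale
  (64×64 to 256×256 sensor crops, 64 to 480 frames); contrast statistics
  depend on the number of independent speckle cells, so smaller crops only
  widen Monte-Carlo error bars, and every tolerance in the tests is tied to
  a measured standard error rather than a fixed percentage where that
  matters.

## Known limitations

- The effective contrast ceiling β̂ is a property of the simulator's sampling
  chain, reported and used consistently, but not matched to any particular
  hardware.
- The connected-components grouping is deliberately simple; it answers "which
  channels move together at this threshold", not "what is the statistically
  optimal partition". No significance testing on ρ is performed.
- CBVI from the simulator inherits whatever `volume_modulation` injects; the
  simulator validates the volume *arithmetic*, not vascular physiology.
- Raw-frame persistence is always offered by the I/O layer; deleting raw data
  to save disk is left to the user.
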