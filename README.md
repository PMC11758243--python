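# scos

Processing chain for **speckle contrast optical spectroscopy (SCOS)** — the
technique behind wearable multi-channel monitors of cerebral blood flow and
blood volume. Coherent near-infrared light transmitted through scalp, skull
and cortex forms a speckle pattern on a board camera; moving red blood cells
decorrelate the optical field, blurring the speckle within the exposure. The
spatial contrast of each frame therefore encodes flow, and the transmitted
mean intensity encodes blood volume. This package implements the full
frame-to-index chain for such instruments, plus a physics-based
dynamic-speckle simulator so every stage can be verified against known ground
truth without instrument data.

It is aimed at researchers building or analyzing camera-based blood-flow
monitors (SCOS / speckle visibility spectroscopy) who need a tested,
scriptable reference implementation of the standard processing steps.

## Model

Per frame, the squared speckle contrast and its sensor-noise correction:

    K_raw²(t) = σ²(I(t)) / μ²(I(t))
    K_adj²(t) = K_raw²(t) − K_shot²(t) − K_quant²(t) − K_cam²(t)

with `K_shot² = 1/(g·μ)`, `K_quant² = (1/12)/μ²`, `K_cam² = σ_r²/μ²`
(conversion gain `g` in e⁻/DN, read+dark noise `σ_r` in DN). The blood flow
index is `CBFI(t) = 1/K_adj²(t)`, normalized to its mean over a baseline
window. Blood volume indices come from the mean transmitted intensity
relative to its baseline `I₀`:

    CBVI(t) = 2 − μ(I(t))/I₀      and      ΔCBVI(t) = log10(I₀/μ(I(t)))

Multi-channel recordings are compared through the Pearson correlation
`ρ(i,j)` of the normalized CBFI traces for every unordered channel pair
(15 pairs for six channels), and channels are partitioned into groups as
connected components of the ρ ≥ threshold graph.

The simulator generates pupil-filtered complex Gaussian fields with
`g1(τ) = exp(−τ/τ_c)` dynamics, integrates them over the exposure, and
applies a full sensor stage (shot noise, read noise, quantization). Its
independent oracle is the closed-form visibility curve

    K²(x) = β · (e^(−2x) − 1 + 2x) / (2x²),    x = T/τ_c.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a six-channel recording in which channels 1–2 follow an independent
"injured-region" waveform, then process and correlate:

```bash
scos simulate --out raw/ --channels 6 --duration 12 --frame-size 64 \
              --injured 1,2 --seed 7
scos process  --in raw/ --out results/
scos correlate --in results/ --threshold 0.6
scos check-safety --power 67 --spot 5.5
```

The last two commands print:

```
15 pairs; groups at rho>=0.6: [['ch1', 'ch2'], ['ch3', 'ch4', 'ch5', 'ch6']]
irradiance 2.820 mW/mm^2 (limit 3.28 mW/mm^2): PASS
```

meaning: the six channels yield 6-choose-2 = 15 pairwise correlation factors;
at a grouping threshold of ρ = 0.6 the two altered channels form their own
connected component — the signature of a region whose perfusion dynamics have
decoupled from the rest of the head — and a 67 mW beam spread over a 5.5 mm
spot averages 2.82 mW/mm² on the skin, below the 3.28 mW/mm² maximum
permissible exposure for this wavelength. `results/` contains per-channel
CSV traces (contrast terms, CBFI, CBVI, validity flags), the labeled
correlation matrix, the per-pair summary (two-channel mean intensity vs ρ)
and a provenance run log.

The same pipeline is scriptable from Python:

```python
from scos import (SceneSpec, SpeckleParams, CameraModel, simulate_scene,
                  ChannelSet, correlation_matrix, group_channels)

params = SpeckleParams(tau_c=3e-3, frame_shape=(64, 64))
camera = CameraModel(gain_e_per_dn=2.0, read_noise_dn=2.0, bit_depth=8)
rec = simulate_scene(SceneSpec(n_channels=6, n_frames=480,
                               altered_channels=(0, 1), seed=12),
                     params, camera)
cset = ChannelSet.from_stacks(rec.stacks, baseline_window=(0, 5))
result = correlation_matrix(cset)
print(group_channels(result, threshold=0.6))
# [['ch1', 'ch2'], ['ch3', 'ch4', 'ch5', 'ch6']]
```

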