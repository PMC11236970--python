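# cortexshape

Quantitative analysis of actomyosin-cortex mechanics and membrane shape
in giant unilamellar vesicles (GUVs, "liposomes") from two-channel
timelapse microscopy.

When myosin is activated inside a liposome carrying a reconstituted
F-actin cortex, the architecture of that cortex — branched (Arp2/3),
linear (mDia1/formin), or a mixture — controls whether contractile
forces deform the membrane. `cortexshape` implements the full
measurement chain used to characterize this system, together with a
synthetic-scene generator that provides ground truth for every stage:

| stage | quantity | definition |
|---|---|---|
| PIV / strain | compressive strain ε(t) | −∫₀ᵗdt′ ∫dA min(∇·**u**, 0) / ∫dA over the liposome interior |
| cortex texture | nematic order ⟨S⟩ | S = ⟨cos 2θ⟩ of structure-tensor directors relative to the local reference director |
| contour shape | membrane strain ε_memb | 1 − C with circularity C = 4πA/L² |
| contour shape | actin polarity P_act | \|**r**_act − **r**_c\| / R, offset of the intensity-weighted actin centroid |
| spectra | scaling exponent α | ⟨\|u(q)\|²⟩_t ∼ q^(−α); (κq⁴+γq²)⁻¹ Helfrich form fit |
| correlation | deformation size θ_c | smallest first zero of ⟨u(θ+Δθ)u(θ)⟩_θ over frames |
| linescans | cortex thickness h | h = Δ + √(Δ² − 2σ² ln r), the exact solution of h = 2(Δ−δ), δ = (σ²/h) ln r |
| model | cortex tension γ_c | h·σ_act via the energy route (W ∼ hσ_act ξ_c²δ/R) and the flow-friction route (σ_act = ζv_act, ζ = η_m N_link / 4πR²) |

Audience: biophysicists analyzing reconstituted-cortex or cell-cortex
imaging who need these metrics end to end, with tested sub-pixel
estimators and a fully controlled synthetic benchmark.

## Worked example

Synthesize one mixed-architecture liposome timelapse (11 frames,
0.25 µm/pixel), run the full analysis, and evaluate the mechanical
model:

```python
from cortexshape import pipeline as pl
from cortexshape import mechanics_model as mm

cohort = pl.synthesize_cohort(["mixed"], 1, seed=0,
                              pixel_size_um=0.25, n_frames=11)
cfg = pl.AnalysisConfig(pixel_size_um=0.25, spectrum_frames=11)
summary = pl.run_timelapse_analysis(cfg, cohort)
row = summary.per_liposome.iloc[0]
print(f"eps_memb_max = {row.eps_memb_max:.4f}")
print(f"P_act_max    = {row.P_act_max:.3f}")
print(f"theta_c      = {row.theta_c_deg:.1f} deg")
print(f"h            = {row.h_um:.3f} um")

rep = mm.full_report(F_stretch_override_J=8.4e-17)
print(f"F_bend       = {rep.F_bend_J:.2e} J")
print(f"gamma_c      = {rep.gamma_c_N_per_m:.2e} N/m (energy), "
      f"{rep.gamma_c_flow_N_per_m:.2e} N/m (flow)")
```

prints

```
eps_memb_max = 0.0187
P_act_max    = 0.242
theta_c      = 24.5 deg
h            = 0.323 um
F_bend       = 1.24e-18 J
gamma_c      = 1.63e-05 N/m (energy), 6.39e-05 N/m (flow)
```

The generator built this liposome with a maximum membrane strain of
0.0180, actin polarity 0.240, deformation size 24.5° and cortex
thickness 0.29 µm, so the pipeline recovers the shape metrics to a few
percent (thickness carries ~10% error at this coarse pixel size). The
two independent cortex-tension estimates agree within a factor of four
— the level of agreement expected from order-of-magnitude scaling
relations with unit prefactors.

## Command line

```bash
cortex-shape simulate --preset mixed --n 2 --seed 1 --out scenes/
cortex-shape run      --scene-dir scenes/ --config cfg.yaml --out results/
cortex-shape strain   --input actin.tif --windows 100,60,48
cortex-shape shape    --membrane ch0.tif --actin ch1.tif
cortex-shape spectrum --membrane ch0.tif --frames 20
cortex-shape nematic  --input surface.tif --sigma 2
cortex-shape thickness --membrane ch0.tif --actin ch1.tif --psf-sigma 0.119
cortex-shape mechanics --out mechanics.json
```

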