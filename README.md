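# bleachmap

Photobleaching-kinetics modelling and **time-integrated emission (TiEm)**
mapping for fluorescence microscopy bleach stacks.

## The problem

Quantifying where a fluorescent probe sits in a living cell from raw
intensity is unreliable: illumination is never perfectly flat across the
field of view, fluorescence quantum yield and lifetime vary with the local
environment, and cellular autofluorescence adds a position-dependent offset.
The *time-integrated emission* — the total fluorescence a pixel emits until
its probe is completely photobleached — removes the first two artefacts by
construction, and pixel-wise decay fitting removes the third.

For the photocycle S₀ ⇌ S₁ (excitation rate k₁ = σ_ex·I_ex, relaxation rate
k₋₁ = 1/τ_f) with irreversible bleaching k₂ from S₁, the rapid-equilibrium
approximation gives a mono-exponential bleach curve

    S₁(t) = M·q/(1+q) · exp(−k_b t),    k_b = k₂·q/(1+q),    q = k₁/k₋₁,

and the TiEm

    TiEm = ∫₀^∞ S₁ dt = M/k₂,

independent of q, i.e. of illumination intensity and fluorescence lifetime.
Fitting A·e^(−t/τ) + B to each pixel of a bleach stack and forming **A·τ**
therefore yields a probe-distribution map that cancels both illumination
shading and the autofluorescence background B. The package implements this
chain end to end, together with the triplet-state extension
(TiEm = M/(k₂ + k₄k₃/k₅)), multi-exponential bleaching (TiEm = Σ Aᵢτᵢ), and
a time-dependent rate-coefficient model k₂(t) = k₂′·t^(−b) for restricted
environments such as lipid droplets, whose TiEm involves the Euler gamma
function. See `docs/methods.md` for the full model account.

Modules:

- `bleachmap.photokinetics` — forward models, closed-form TiEm expressions,
  stiff/exact photocycle ODE solutions, photon-unit conversions;
- `bleachmap.pixelfit` — pixel-wise bounded least-squares fitting
  (mono-exponential, bi-exponential, stretched exponential, all with a
  background offset), parameter maps, three TiEm image variants, AICc model
  selection;
- `bleachmap.synthgen` — synthetic bleach-stack generator with a line-wise
  illumination ramp, a two-compartment cell phantom and Box–Muller-perturbed
  per-pixel bleach rate constants, returning exact ground truth;
- `bleachmap.io` / `bleachmap.cli` — multipage-TIFF I/O and the
  `bleachmap synth | fit | tiem | report` command-line pipeline.

## Worked example

Render the synthetic validation scene (nucleus: M = 7000 molecules on
background 100; cytoplasm: M = 5000 on background 600; illumination constant
q ramping 8.0 → 2.0 photons/molecule bottom → top; k₂ = 0.1 s⁻¹ perturbed
per pixel by 0.01·N(0,1); 100 frames at 1 s), fit it pixel-wise and compare
compartment statistics:

```python
import numpy as np
from bleachmap import SynthSpec, render_stack, fit_stack, tiem_maps

spec = SynthSpec(shape=(64, 64), seed=1)
stack, truth = render_stack(spec)
maps = fit_stack(stack, "monoexp")
tiem = tiem_maps(maps, stack, "formula")          # A * tau per pixel

lab = truth["labels"]                             # 0 outside, 1 cyto, 2 nucleus
for name, l in (("nucleus", 2), ("cytoplasm", 1)):
    sel = lab == l
    print(f"{name}: B = {np.nanmean(maps['background'][sel]):.1f}, "
          f"TiEm = {np.nanmean(tiem[sel]):.0f} ± {np.nanstd(tiem[sel]):.0f}")
```

prints

```
nucleus: B = 100.0, TiEm = 70882 ± 7241
cytoplasm: B = 600.0, TiEm = 50538 ± 5176
```

The fitted background recovers the generated autofluorescence level of each
compartment exactly, and the TiEm map reports M/k₂ (≈ 7000/0.1 and 5000/0.1,
spread by the per-pixel k₂ noise). The illumination ramp is visible in the
amplitude map but cancelled in the TiEm: on the same run the mean amplitude
in the cytoplasm differs between the dimly and brightly illuminated half of
the field (3937 vs 4300 intensity units) while the TiEm does not
(50590 vs 50485).

The same pipeline from a shell:

```sh
bleachmap synth --preset shading-phantom --seed 1 --out stack.tif
bleachmap fit stack.tif --model monoexp --out run/ \
    --tiem formula,sum_minus_background,sum_plus_background
bleachmap report run/ stack.labels.tif
```

which writes 32-bit float TIFFs for the amplitude, time-constant, background
and RMSE maps, the three TiEm variants, a per-region CSV and a JSON sidecar
with the full run configuration.

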