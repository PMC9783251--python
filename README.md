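# perfcolor

Pseudo-coloring and quality assessment of myocardial perfusion SPECT images.

Reconstructed perfusion SPECT slices are grayscale, low-contrast, and noisy;
the human eye resolves far fewer gray levels than colors, so assigning an
RGB color to each gray level can make perfusion defects easier to see.
`perfcolor` implements a complete evaluation pipeline for this idea:

1. **Denoise** — a locally adaptive Wiener filter (5×5 neighborhood by
   default) with gain `max(σ² − ν², 0)/σ²`, where `μ, σ²` are the local mean
   and variance and `ν²` is the noise power (estimated as the mean of all
   local variances when not supplied).
2. **Colorize** — five analytic transfer functions `t ↦ (R(t), G(t), B(t))`
   applied pixel-wise to the normalized intensity `t`:
   * **WCM** (warm): an orthonormal rotation of a chroma vector around the
     gray axis of the RGB cube, `(R,G,B)ᵀ = B·(r(t)sin(ωt+φ), r(t)cos(ωt+φ),
     √3·t)ᵀ`, so the channel mean equals `t` exactly and equal intensity
     steps give equal color steps;
   * **HCM** (hot): clamped ramps black → red → yellow → white;
   * **SCM** (sine): half-period sinusoids, blue background to red targets;
   * **ZCM**: piecewise-linear blue → turquoise → green → yellow → red → white;
   * **JCM** (jet): the triangular jet profile on a signed `[−1, 1]` domain.
3. **Assess** — full-reference indices between the channel-replicated gray
   image `G` and its colored version `X`: MSE `= Σ(G−X)²/(3MN)`, PSNR
   `= 10·log₁₀(I²max/MSE)` dB, normalized color difference in CIELAB, and
   windowed SSIM `= (2μxμy+c₁)(2σxy+c₂) / ((μx²+μy²+c₁)(σx²+σy²+c₂))`;
   plus a one-way ANOVA comparing maps across an image corpus.

Because no clinical images ship with the package, a **phantom** module
generates synthetic short-axis slices — a blurred myocardial annulus with an
optional perfusion-defect sector and Poisson counting noise at SPECT-like
count levels — so every stage runs and is tested end to end.

## Worked example

```python
import numpy as np
from perfcolor import (PhantomParams, generate_clean_phantom, add_poisson_noise,
                       wiener_filter, metric_report)

params = PhantomParams(defect_severity=0.6, seed=7)   # 64x64, ~100 peak counts
clean = generate_clean_phantom(params)
noisy = add_poisson_noise(clean, params.counts_scale, seed=params.seed)
denoised = wiener_filter(noisy, kernel_size=5)
for row in metric_report(denoised):
    print(f"{row.map_name}  mse={row.mse:.4f}  psnr={row.psnr_db:.4f} dB  "
          f"ncd={row.ncd:.4f}  ssim={row.ssim:.4f}")
```

prints

```
wcm  mse=0.0039  psnr=24.0621 dB  ncd=0.2970  ssim=0.9326
hcm  mse=0.0236  psnr=16.2688 dB  ncd=0.5298  ssim=0.7235
scm  mse=0.3064  psnr=5.1368 dB  ncd=0.9512  ssim=0.4172
zcm  mse=0.3083  psnr=5.1103 dB  ncd=0.9480  ssim=0.3419
jcm  mse=0.3238  psnr=4.8967 dB  ncd=0.9658  ssim=0.3799
```

Lower MSE/NCD and higher PSNR/SSIM mean the colored image stays closer to
the gray original.  The warm map hugs the gray axis by construction, so it
scores best on MSE, PSNR and SSIM — the same ordering direction reported for
clinical perfusion images.  Absolute values depend on the image content: a
synthetic phantom is not a patient study.

The same pipeline is available from the shell:

```sh
perfcolor phantom --n 30 --seed 7 --out-dir corpus/
perfcolor colorize --map wcm --in corpus/phantom000.png --out warm.png
perfcolor compare --in corpus/phantom000.png --out report.csv
perfcolor run --n 30 --seed 7 --out-dir report/     # corpus + ANOVA tables
```

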