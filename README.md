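# syrdose

Syringe drug-dosage recognition from still images, for medication-safety
imaging in hospital pharmacy dispensing. Given a photograph of a syringe
after drug extraction and the syringe's nominal capacity, `syrdose`
reports the drawn volume in ml — without ever reading the printed scale,
so it keeps working when the graduations face away from the camera, are
washed out by lighting, or are occluded, and when the piston sits between
two marks.

## Method

The pipeline is classical image processing end to end:

1. grayscale conversion (Rec.601 luma);
2. binarization at the Otsu threshold — the gray level `k` maximizing the
   between-class variance `σ²(k) = ω₀ω₁(μ₁−μ₀)²`;
3. binary morphology: opening, closing, hole filling (flat 3×3 element);
4. Gaussian smoothing (`σ = 1` px, 5×5 kernel), re-binarized at 0.5;
5. Harris corner detection on the silhouette:
   `CRF = det(M) − k·tr(M)²` over the Gaussian-windowed structure tensor
   `M`, thresholded and non-max-suppressed;
6. landmark selection: the barrel's tip vertex `(x₁,y₁)`, the piston
   position `(x₂,y₂)` and the opposite barrel vertex `(x₃,y₃)`, assigned
   from the corner set via the silhouette's barrel axis.

The recognized dose is the distance ratio scaled by the capacity `R`:

    L = √((x₂−x₁)² + (y₂−y₁)²) / √((x₃−x₁)² + (y₃−y₁)²) × R

A deterministic synthetic scene renderer (`syrdose.synthgen`) with exact
ground truth — liquid column, piston band, graduation ticks, rotation,
Gaussian noise, occluding erasures — stands in for laboratory
photographs and drives the validation suite. See `docs/methods.md` for
the full account.

## Worked example

Render a 5 ml syringe filled to 60% and measure it:

```sh
$ syrdose synth --capacity 5 --fill 0.6 --seed 42 --out scene.png
$ syrdose measure scene.png --capacity 5
{
  "dose_ml": 3.0,
  "raw_dose_ml": 3.0008502196571434,
  "fill_fraction": 0.6001700439314287,
  "capacity_ml": 5.0,
  "landmarks": {
    "tip_vertex": [109.5, 288.0],
    "piston_point": [361.5, 282.0],
    "end_vertex": [529.5, 288.0]
  }
}
```

The piston's air-side face was found 252 px from the tip vertex along a
420 px barrel (the slight excess over 3.00 ml comes from the 6 px
perpendicular offset between the piston/wall junction and the outer
barrel corners): 252/420 × 5 ml ≈ 3.00 ml drawn. The same call works on any
PNG/TIFF/JPEG photograph meeting the assumptions in `docs/methods.md`.

Library use mirrors the CLI exactly:

```python
from syrdose import SynthScene, render, measure_dose

img, truth = render(SynthScene(capacity_ml=5, fill_fraction=0.6, seed=42))
result = measure_dose(img, capacity_ml=5)
print(result.dose_ml)   # 3.0
```

Other commands: `syrdose batch DIR --out report.csv` (one row per image,
errors isolated per row), `syrdose scenarios --out DIR` (materializes the
full 60-scene validation grid with truth sidecars), `--config cfg.yaml`
to override any pipeline parameter, and `--debug-dir` to dump the
intermediate stages (gray, binary, morphology, silhouette) as PNGs.

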