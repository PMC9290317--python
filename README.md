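# retimorph

Automated retinal vascular morphometry from color fundus photographs.

Retinal vessel geometry carries systemic signal — arteriolar narrowing
tracks hypertension, venular dilation tracks diabetic retinopathy,
tortuosity tracks hypercholesterolemia — but extracting it by hand is
slow and poorly reproducible. `retimorph` is the measurement half of
an automated pipeline for ophthalmologists and oculomics researchers:
it preprocesses fundus photographs, gates image quality with an
ensemble-confidence rule, converts segmentation-model probability maps
into anatomy masks, and measures a standard catalog of vascular and
optic-disc features, with the agreement statistics used to validate
such measurements. Segmentation networks themselves are *pluggable
inputs* (any model that writes probability maps or masks); a synthetic
scene generator with exact ground truth makes the whole pipeline
testable without photographs or trained weights.

## Features measured

Per image, per region (whole image, Zone B = annulus 0.5–1.0 disc
diameters from the disc margin, Zone C = 0.5–2.0):

* **Tortuosity**, three ways: distance tortuosity (arc/chord),
  squared-curvature tortuosity (∫κ² ds along the centerline), and
  tortuosity density (inflection-partitioned arc/chord excess,
  ((n−1)/n)·(1/L)·Σ(Lᵢ/chordᵢ − 1));
* **Fractal dimension** (Minkowski–Bouligand box counting);
* **Vessel density** and **average caliber** (2× distance transform
  at the skeleton);
* **CRAE / CRVE / AVR** from the six widest arteries and veins, by
  both the revised Knudtson pairing Ŵ = k√(Wa²+Wb²)
  (k = 0.88 / 0.95) and the Parr–Hubbard formulas;
* **Optic disc/cup** height, width, and vertical/horizontal
  cup-to-disc ratio.

Calibers are reported in pixels (image resolution is rarely known);
scale by µm/px where available. The quality gate collapses
good/usable/reject ensemble grades to gradable/ungradable and
rectifies low-confidence gradable calls (mean probability < 0.75 or
between-model SD > 0.1) to ungradable before anything is measured.

## Worked example

Generate three synthetic scenes (the third drawn with a deliberately
low-confidence quality grade), run the full pipeline, and read the
feature table:

```sh
retimorph demo-data demo/data --n-scenes 3 --ungradable-every 3
retimorph run demo/data demo/out
# processed=2 gated_out=1 failed=0 -> demo/out/features.csv
```

```python
import pandas as pd
df = pd.read_csv("demo/out/features.csv")
print(df[["source_id", "fractal_dimension_whole", "vessel_density_whole",
          "average_width_whole", "CRAE_knudtson_zoneB",
          "CRVE_knudtson_zoneB", "AVR_knudtson_zoneB", "vertical_CDR"]])
```

```
source_id  fractal_dimension_whole  vessel_density_whole  average_width_whole  CRAE_knudtson_zoneB  CRVE_knudtson_zoneB  AVR_knudtson_zoneB  vertical_CDR
scene_000                 1.384852              0.048945             9.088159            18.546244            22.652597            0.818725           0.5
scene_001                 1.379846              0.048952             9.106238            18.595377            22.445763            0.828458           0.5
```

Reading: each scene's 14 vessels (widths 3–15 px, mean 9) cover ~4.9%
of the frame and branch with a fractal dimension of ~1.38; the six
widest arteries in Zone B summarize to a CRAE of ~18.5 px against a
CRVE of ~22.5 px (AVR ≈ 0.82 — the generator draws arteries and veins
from the same width ladder, and equal-width pools land at the pairing
ratio 0.88/0.95 per round, not at the clinical ~0.7); the cup is half
the disc's height by construction. `scene_002` was gated out as
ungradable and has no feature row. Library use mirrors the CLI:
`measure_image(bundle)` returns one `FeatureRecord`, `grade_image`
one quality decision.

See `docs/methods.md` for definitions, numerical choices, and the
limits of what synthetic validation shows.

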