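# rnflgray

Peripapillary RNFL grayscale-value measurement on circular SD-OCT
B-scans: synthetic phantom generation, retinal layer segmentation,
sectoral quantification, and normative/determinants statistics.

## What this is for

The reflectivity of the peripapillary retinal nerve fiber layer (pRNFL)
— summarised as its **grayscale value**, the mean 8-bit pixel intensity
(0 black … 255 white) of the layer on a circular SD-OCT B-scan — is a
candidate imaging marker for glaucoma that may change before the layer
thins. Using it clinically requires a normative account: what is the
sectoral pattern in healthy eyes, and which subject- and scan-level
factors shift it?

`rnflgray` implements that measurement chain end to end for
researchers working on OCT reflectivity markers:

* **synthdata** — generate cohorts of healthy eyes with known
  ("ground-truth") covariates, grayscale and thickness structure, and
  render each eye as a 1024-column circular B-scan with speckle and a
  calibrated scan-quality degradation;
* **segmentation** — trace the ILM, the pRNFL posterior boundary and
  the RPE band with smooth minimum-cost paths on gradient images, plus
  an automated boundary-misidentification screen;
* **quantify** — average and six-sector grayscale values and
  thicknesses (temporal and nasal sectors span 90°, the four oblique
  sectors 45°), RPE grayscale reference, and a scan-quality proxy;
* **cohortstats** — age-group normative tables, Bonferroni-corrected
  within-eye sector comparisons, a univariable screen with
  carry-forward into a multivariable OLS (axial length forced), and a
  two-observer ICC(2,1);
* **pipeline / CLI** — a deterministic synthesize → segment → measure →
  analyze run with explicit exclusion accounting.

The core determinant model is ordinary least squares on the per-eye
average grayscale G:

```
G_i = β₀ + β_age·age_i + β_AL·AL_i + β_RPE·RPE_i + β_Q·ImageQ_i + ε_i
```

with the generator's default effects β_age = −0.053, β_AL = −0.664,
β_RPE = 0.372, β_Q = 0.658 gray levels per unit — older age, longer
eyes, a darker RPE reference and lower scan quality all lower the
measured pRNFL grayscale value. Because every synthetic eye carries
exact truth, the package can test that the *entire* image pipeline
(render → degrade → segment → measure → regress) returns these effects
and the normative sectoral pattern, not merely that each piece runs.

## Worked example

```python
from rnflgray.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_eyes=100, seed=42)
manifest = run_pipeline(cfg)
cohort = manifest["cohort"]
analyzed = cohort[cohort["excluded"] == ""]
print(f"analyzed {manifest['n_analyzed']} / {manifest['n_recruited']} eyes")
print(f"average pRNFL grayscale : {analyzed['gray_mean'].mean():6.2f}")
print(f"average pRNFL thickness : {analyzed['thick_mean'].mean():6.2f} um")
print(f"nasal sector grayscale  : {analyzed['gray_N'].mean():6.2f}")
print(manifest["tables"]["multivariable"].dropna(subset=["beta"])
      [["covariate", "beta", "se", "p_value"]].to_string(index=False))
```

prints

```
analyzed 100 / 100 eyes
average pRNFL grayscale : 163.90
average pRNFL thickness : 106.19 um
nasal sector grayscale  : 162.18
covariate      beta       se      p_value
       al -0.863620 0.331211 1.057741e-02
 rpe_gray  0.383753 0.041854 9.080463e-15
   imageq  0.557250 0.102663 4.277687e-07
```

One hundred eyes were rendered, degraded to their sampled quality,
segmented and measured; none fell below the quality gate or failed QC.
The cohort means sit near the generator's normative targets (164.82
gray levels, 106.68 µm), the nasal sector reads lowest, and the
multivariable fit recovers effect sizes near the generative values
(axial length −0.66, RPE 0.372, ImageQ 0.658) within their standard
errors — at n = 100 the univariable screen does not always carry age
forward, which is expected behaviour for a weak marginal effect.

The same run from a shell, with images and tables written to disk:

```bash
rnflgray run --n 100 --seed 42 --out out/
rnflgray synth --n 10 --seed 7 --out phantoms/          # cohort + PNGs
rnflgray segment --in phantoms/images/eye_0001.png --out bounds.csv --qc qc.json
rnflgray measure --img phantoms/images/eye_0001.png --bounds bounds.csv \
                 --eye OD --out row.csv
rnflgray stats --cohort out/cohort.csv --out tables/
```

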