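# lysoquant

Quantitative pipelines for studying oxidative-stress-induced perinuclear
lysosomal clustering and its signalling readouts, with matched
synthetic-data generators that plant recoverable ground truth.

Oxidative stimuli can drive lysosomes along microtubules towards the
microtubule-organising centre (MTOC), activating autophagy; the pathway is
read out with fluorescence microscopy (lysosome clustering), ratiometric
Ca²⁺ imaging (TRPML1-dependent spikes), targeted mass spectrometry
(phosphosite stoichiometry) and grouped scalar assays. `lysoquant`
implements the four corresponding analyses for cell biologists who need
them reproducible and testable:

* **Imaging** — per-cell lysosomal clustering ratio: thresholded
  lysosome-marker intensity inside a 2 µm circular ROI centred on the
  detected MTOC spot, divided by whole-cell intensity; group *clustering
  values* are ratios relative to the control-group mean, so control
  averages to 1:

      ratio_i = Σ I(ROI ∩ cell_i) / Σ I(cell_i),   value_i = ratio_i / mean(ratio_control)

* **Calcium** — F340/F380 ratio traces sampled every 5 s; spikes are local
  maxima of (ratio − running-median baseline) exceeding 0.05 ratio units,
  counted over 40 min per cell, summarised as a percentage-of-cells
  histogram by spike count.
* **Phospho** — SWATH peak areas normalised per sample by the summed areas
  of the protein's three most intense unmodified peptides (cancelling
  loading/injection factors exactly), then condition fold-changes with
  per-peptide Tukey–Kramer tests.
* **Stats** — Wilcoxon rank-sum (exact or tie-corrected asymptotic),
  Dunnett many-to-one (Monte-Carlo multivariate-t), Tukey–Kramer
  (studentized range), Steel many-to-one (permutation), plus LDH
  cytotoxicity % and the LC3-II autophagic-flux index.

Each analysis is paired with a generator (`lysoquant.simulate`) producing
synthetic fields / traces / peptide tables / grouped scalars with known
ground truth, so every estimator has a parameter-recovery test surface.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
import lysoquant as lq

# simulate two treatment groups of fields with different planted clustering
ratios = {}
for base, (label, frac) in enumerate([("control", 0.2), ("treated", 0.7)]):
    means = []
    for j in range(6):
        p = lq.ImageSimParams(perinuclear_fraction=frac, seed=100 * base + j,
                              background_level=2.0, noise_model="gaussian", noise_sd=1.0)
        field = lq.generate_field(p)
        fi = lq.FieldImage(channels=field.channels, pixel_size_um=field.pixel_size_um)
        masks = {t.cell_id: t.cell_mask(field.channels["lysosome"].shape) for t in field.truth}
        cells = lq.quantify_field(fi, masks, lq.QuantConfig()).cells
        means.append(np.mean([c.ratio for c in cells]))
    ratios[label] = means

values = lq.clustering_values(ratios, "control")
print({k: round(float(np.mean(v)), 3) for k, v in values.items()})
result = lq.dunnett(values, "control", seed=0)
print(result.test_name, round(result.comparisons[0].p_adjusted, 6))
```

prints

```
{'control': 1.0, 'treated': 2.122}
dunnett 1e-05
```

— the control group's clustering values average to 1 by construction, the
group with 70% of lysosomes planted perinuclearly scores ~2.1× the control,
and the Dunnett-adjusted p-value (10⁵ Monte-Carlo draws, so 1e-05 is the
smallest reportable value) flags the shift as significant.

The same workflows run from the shell:

```bash
lysoquant simulate --config sim.yaml --out run/
lysoquant quantify-images run/*.tiff --labels labels.csv --control control --out quant/
lysoquant analyze-calcium --traces run/traces.csv --out ca/
lysoquant quantify-phospho --table run/peptides.csv --control control --out ph/
lysoquant compare --data groups.csv --test steel --control c --out steel.json
```

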