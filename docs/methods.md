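# Methods

This note documents the models, estimators and numerical choices behind
`lysoquant`, and what the synthetic-data generators do and do not emulate.

## 1. Lysosomal clustering quantification (`lysoquant.imaging`)

### Measurement model

Fixed cells are imaged in three channels: a lysosome marker (LAMP2-like
puncta), an MTOC marker (a single bright γ-tubulin-like spot per cell) and a
nuclear stain. The per-cell **clustering ratio** is

    ratio = Σ I_lyso(ROI ∩ cell) / Σ I_lyso(cell)

where `I_lyso` is the lysosome channel after z-projection and background
thresholding, and the ROI is a circle of radius 2 µm centred on the MTOC
spot. Because the ROI is intersected with the cell mask and both sums use
the same thresholded image, the ratio always lies in [0, 1], is monotone in
the ROI radius, and is invariant to rescaling the channel intensity.
**Clustering values** divide every observation's ratio by the control-group
mean ratio, so the control group averages to 1 by construction (to floating
precision, < 1e-12).

### Pipeline steps and defaults

* **Projection** — z-stacks are flattened by maximum-intensity projection
  (default), the standard choice for punctate signal; sum projection is
  available. Single planes pass through unchanged.
* **Thresholding** — Otsu's criterion on the histogram of *nonzero*
  intensities (256 bins, exhaustive between-class-variance scan), or a fixed
  value. A constant image has no background/foreground split: all pixels are
  kept and a warning logged. Caveat: with a faint, sparse foreground the
  256-bin histogram is dominated by background, and the selected threshold
  can jump between "inside the background noise band" and "above it"
  depending on the brightest pixels (which set the bin width). This shifts
  the absolute scale of ratios but preserves their ordering; fixed
  thresholds avoid it entirely.
* **MTOC detection** — global maximum of the Gaussian-smoothed (0.2 µm)
  MTOC channel inside the cell mask; ties resolved to the smallest
  (row, col). An all-zero channel inside the mask is an error.
* **ROI geometry** — a pixel belongs to the ROI iff its centre is within
  the radius: `((r−r0)² + (c−c0)²) · pixel_size² ≤ radius²`, evaluated in
  µm² and clipped at image borders. The centre-in rule matters at small
  radii, where boundary pixels change counts.
* **Aggregation** — per-cell ratios by default; a per-field aggregate
  (Σ ROI / Σ cell over all cells) equals the intensity-weighted mean of the
  per-cell ratios and is available as a config option. Fields with fewer
  than 10 usable cells are flagged but still reported.
* **Segmentation is out of scope** — cell masks come from the simulator's
  ground truth or from a user-supplied label image.

## 2. Synthetic fields (`lysoquant.simulate.images`)

Cells are non-overlapping ellipses (area-preserving random stretch up to
1.25×, uniform orientation); the nucleus is a concentric co-oriented ellipse
at 0.45 of the cell axes; one MTOC sits 0.5 µm outside the nuclear envelope
along a random direction. Each of the 80 lysosomes per cell is perinuclear
with probability `perinuclear_fraction` — drawn from an isotropic Gaussian
(σ = 0.8 µm) around the MTOC, resampled until it lies in the cytoplasm —
and otherwise uniform over the cytoplasm. Puncta are rendered as
unit-integral Gaussians (σ = 0.15 µm, the confocal-PSF convention),
normalised over their 4σ support so interior puncta conserve intensity
exactly (border truncation is logged). Defaults: 1024×1024 px at
0.1 µm/px, 10 cells of 8 µm radius per field (magnification is not dictated
by the application, so these are exposed in config). Noise is applied last:
additive Gaussian (clipped at 0) or Poisson counts at a configurable photon
scale applied to signal plus background.

The per-cell **planted truth** records the MTOC position, all punctum
centres, and the fraction of punctum centres within 2 µm of the MTOC. The
recorded fraction is a centre-count on the noiseless, pre-blur positions;
the measured intensity ratio differs from it by PSF mass straddling the ROI
boundary (≈0.5% at the defaults) plus any threshold effects.

Not emulated: photobleaching, cell movement, z-drift, spectral
bleed-through, irregular cell shapes, clumped or touching cells, intensity
heterogeneity between lysosomes. Passing recovery tests therefore shows the
estimator tracks planted geometry under idealised optics, not that it is
robust to segmentation error or marker heterogeneity in real images.

## 3. Ca²⁺ ratio traces and spike detection (`lysoquant.calcium`)

The Fura-2 readout is the ratio F340/F380 sampled every 5 s. Points with
F380 at or below a floor are treated as missing, bridged by linear
interpolation for baseline estimation, and never counted as peaks.

* **Baseline** — running median over a centred 180 s window (truncated at
  the trace edges). The window must be long enough that one transient's
  decaying tail cannot claim a majority of the window: with the default
  pulse decay (τ = 10 s) a transient occupies ~14 samples, so a 37-sample
  window keeps clean samples in the majority and the median sits exactly on
  the baseline for isolated events; a 60 s window would not.
* **Spike rule** — a spike is a local maximum of (ratio − baseline)
  strictly exceeding 0.05 ratio units within the 40 min analysis window;
  maxima closer than 10 s are merged keeping the larger. Amplitude is
  baseline-relative, measured at the peak. Raising the threshold can only
  remove spikes (monotonicity).
* **Histogram** — percentage of cells with each spike count; bin 0 is
  cells with no detected spikes; percentages sum to 100.

### Synthetic traces (`lysoquant.simulate.traces`)

ratio(t) = baseline + Σᵢ aᵢ·exp(−(t−tᵢ)/τ)·1[t ≥ tᵢ] + Gaussian noise, with
constant F380 and F340 = ratio × F380 so the computed ratio equals the
planted trace identically. Three generator choices keep planted truth
exactly recoverable on noiseless traces: onsets snap to the sampling grid
(events are unobservable between samples anyway); the pulse is truncated
where it falls below 10⁻³ of its amplitude, so baselines see exact zeros
beyond ~7τ; and a 20 s minimum inter-spike interval (above the detector's
10 s merge window) emulates the refractoriness of store-release transients
and keeps planted events distinct. Defaults: 40 min at 5 s sampling,
baseline ratio 1.0, rate 0.5 events/min, amplitude 0.1, τ = 10 s, noise
SD 0.01. Explicit spike times can be supplied for deterministic planting.

## 4. Phosphopeptide quantification (`lysoquant.phospho`)

Peak areas of one protein's peptides are normalised per sample by the
summed areas of the protein's **three most intense unmodified peptides**
(top-3 reference normalisation), which cancels any per-sample multiplicative
factor (loading, injection) exactly. "Most intense" is resolved as the
highest mean area across all samples — one global reference set, because a
per-sample set would break cross-sample comparability. Eligibility requires
presence (area > 0) in every sample; ties break lexicographically.
Condition fold-changes are ratios of condition means of the normalised
abundances, tested per peptide with Tukey–Kramer across conditions.

With three replicates and per-measurement lognormal noise of σ = 0.1 the
fold estimator's log-scale standard error is ≈ 0.09 (σ·√(4/3) per value,
averaged over 3 replicates, doubled across two conditions), so individual
runs scatter roughly ±20% around the planted fold even though the estimator
is unbiased and its median converges on the planted value. Precision
claims for single runs should be read against that noise floor.

The generator (`lysoquant.simulate.peptides`) plants 5 phosphopeptides and
8 unmodified peptides across control / oxidant / oxidant+kinase-inhibitor
conditions, 3 replicates each: area = base(peptide) × fold(peptide,
condition) × scale(sample) × lognormal noise. The default planted effect —
a 3-fold rise of the T217-site phosphopeptide under oxidant treatment,
abolished by the inhibitor — mirrors the biology the pipeline is meant to
resolve. Missing fold entries default to 1.

## 5. Group comparisons (`lysoquant.stats`)

All tests are two-sided; nonparametric tests use midranks throughout.

* **Wilcoxon rank-sum** — exact p by enumeration of all C(n, n_x) rank
  assignments when n ≤ 10 (valid with ties, since midranks are enumerated);
  otherwise a normal approximation with tie-corrected variance and
  continuity correction.
* **Dunnett (many-to-one, parametric)** — statistics
  dᵢ = (mᵢ − m_c)/(s_p·√(1/nᵢ + 1/n_c)); adjusted p-values are tail
  probabilities of max|t| under the equicorrelated multivariate t,
  realised by seeded Monte Carlo (10⁵ draws by default) with a shared
  control variate and a common χ² scale — this handles unbalanced designs
  exactly as defined, with no table lookup. p = (1 + #{M ≥ |d|})/(reps + 1).
* **Tukey–Kramer (all pairs)** — qᵢⱼ = |mᵢ − mⱼ|/√(s_p²/2·(1/nᵢ + 1/nⱼ)),
  p from the studentized-range distribution with k groups and pooled df.
  For family-wise calibration studies the rejection event min p ≤ α is
  evaluated as max q ≥ the 1−α studentized-range quantile (computed once);
  the two are identical because the p-map is monotone, and this avoids
  thousands of slow distribution-function evaluations.
* **Steel (many-to-one, nonparametric)** — per-treatment rank sums against
  the control computed on each pair alone, standardised by exact
  finite-population moments (tie-exact); the family-wise adjusted p is the
  permutation tail probability of max|z| under seeded permutations of the
  pooled observations (10⁴ by default), with the +1 correction. The
  discreteness of rank statistics makes this mildly conservative (null
  family-wise error ≈ 0.045 at α = 0.05 in our calibrations).
* **Determinism and label invariance** — Monte-Carlo and permutation
  procedures are pure functions of (data, seed). Treatments are ordered
  canonically by their data content (size, then sorted values) before the
  random stream is consumed, so renaming or reordering groups changes no
  p-value bit-for-bit.
* **Assay arithmetic** — LDH cytotoxicity % =
  100·(sample − background)/(total − background), clipped at 0 with a
  warning; the LC3-II flux index offers a `level` mode (LC3-II with
  lysosomal-inhibitor treatment over loading control, the default) and a
  `difference` mode (± inhibitor difference over loading), because the
  conventional verbal definition is ambiguous between the two; the mode is
  echoed in every output.

## 6. Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 50 compact noiseless
fields (300×300 px, 3 cells) for oracle equivalence; 20 full-size fields
per planted fraction in {0.1, 0.3, 0.5, 0.7, 0.9} for recovery; 200 noisy
traces for detection sensitivity/precision; 100 seeded peptide tables for
fold recovery; and 5,000 (Dunnett, Tukey–Kramer) / 2,000 (Steel) null
simulations for family-wise error. These sizes give binomial standard
errors of ~0.003–0.005 on calibration rates while keeping a full run around
one minute on a single core.

## 7. Known limitations

* Otsu threshold instability for sparse bright foregrounds (see §1) —
  monotone comparisons survive it, absolute ratio scales do not.
* The baseline median biases amplitudes low when inter-spike intervals are
  shorter than half the baseline window; at the default rate this is a
  sub-threshold effect but it grows with spike rate.
* Fold-change precision is noise-floor-limited at n = 3 (see §4).
* The simulators are idealised (see §2); none of the pipelines is validated
  here against manually annotated real microscopy or MS data.
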