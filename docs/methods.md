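# Methods

This note records the statistical model, the numerical choices and the known
limitations of the `beanprint` pipeline, in the spirit of a package methods
appendix. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## Data model

A dataset is a strictly increasing wavelength grid (nm), an
`n_spectra × n_wavelengths` absorbance matrix, and per-spectrum metadata.
Spectra group into physical samples via `sample_id`; the acquisition protocol
modelled here scans each sample 4 times, and 4-replicates-per-sample is
validated but configurable. The grid is *not* assumed uniform in nm: FT
instruments are uniform in wavenumber, and all grid-dependent computation
(derivative scaling) uses local spacing. Wavelength windows are inclusive on
both ends.

## Preprocessing chain

Order is fixed: trim → baseline → SNV → second derivative. All stages are
per-spectrum maps, so preprocessing cannot leak information from held-out
spectra into training statistics.

* **Baseline**: "baseline correction" is ambiguous in chemometrics software;
  the default here is the offset variant (subtract the spectrum's minimum,
  so min(output) = 0). A least-squares linear detrend is available behind
  `PreprocessConfig(baseline_mode="detrend")` but is not the default.
* **SNV**: centre and scale each spectrum to unit sample sd (n−1). A
  zero-variance spectrum raises a `DegenerateSpectrumError` naming the
  spectrum, never a silent NaN.
* **Savitzky–Golay second derivative**: degree-2 local polynomial (the
  polynomial order is configurable ≥ 2). A "smoothing points" count of 24 is
  even and incompatible with a symmetric window, so it widens to 25; the
  effective window is recorded in the run log. The filter is evaluated in
  index space and rescaled by the squared local mean step
  ((λ[i+h] − λ[i−h])/(w−1))², which is exact on uniform grids and a
  controlled approximation on mildly non-uniform ones. Edge points without a
  full window are dropped (no extrapolation), shrinking all spectra to a
  common interior grid — downstream matrices stay rectangular. On the
  949-point instrument grid the 900–2400 nm window leaves 829 derivative
  points.

## NIPALS PCA

Components are extracted sequentially from the mean-centred matrix:
`p ← Rᵀt/(tᵀt)`, normalise, `t ← Rp`, iterate; deflate `R ← R − t pᵀ`.
The starting score is the column of largest sum of squares. Sign convention:
the largest-magnitude loading coefficient is positive, which stabilises
score/loading signs across runs. Explained variance per component is
`tᵀt / ‖X_c‖²F · 100`; centering always uses the training mean, and held-out
spectra are projected with the stored centre vector.

**Convergence.** The primary criterion is a relative score-vector change
below `tol = 1e-10`. Plain power iteration converges at rate λ₂/λ₁, which is
hopeless inside the near-degenerate noise floor that a second-derivative
spectrum always has; two additional criteria make the algorithm usable there
without sacrificing accuracy where it matters:

1. the component's explained sum of squares (its Rayleigh quotient) changing
   by less than `eigen_tol = 1e-12` relative — the quotient converges
   quadratically and is accurate even while the score vector still rotates
   inside a numerically degenerate eigen-subspace;
2. at the iteration cap (`max_iter = 10000`), the component is accepted if
   its variance motion is below 1e-9 of total variance per iteration
   (< 1e-7 explained-percentage points); otherwise a `ConvergenceError`
   names the component.

Deflation with the final `t = Rp` makes subsequent loadings exactly
orthogonal to the accepted one regardless of where the iteration stopped, so
orthonormality of loadings is structural, not tolerance-dependent. Agreement
with a full eigendecomposition on random matrices is below 1e-8 percentage
points of explained variance (measured in the test suite and the acceptance
script).

**Hotelling's T².** For a score vector s, `T² = Σ_j s_j²/var(t_j)` over the
retained components (training score variances, n−1). The 95 % control limit
uses the classical small-sample F approximation
`k(n−1)/(n−k) · F₀.₉₅(k, n−k)`. An optional leave-random-segments-out
residual-variance diagnostic exists for exploratory use; it is not on the
modelling path.

## PCA-LDA

Classification happens in the k-dimensional training score space. Each class
contributes its centroid; the pooled within-class covariance uses the
`n − n_classes` denominator. Priors are uniform (training classes are
balanced by construction, so prior terms would cancel anyway). If the pooled
covariance's condition number exceeds 1e10, a ridge of `1e-8·trace/k` is
added; a covariance still singular after that raises. Prediction minimises
the squared Mahalanobis distance; ties (equal within 1e-9 relative) break
deterministically toward the earlier class in the declared order and are
flagged in the `classify` output.

**Top-down component selection.** Candidates run from the smallest k whose
cumulative explained variance reaches 95 % to the smallest k reaching
99.9 %, thinned evenly to at most 10 models; each candidate is scored by
cross-validation accuracy and the best wins, smaller k on ties. NIPALS
components are nested, so the PCA is fitted once to the largest candidate
and truncated — each candidate model is bit-identical to an independent fit.
Two boundary rules: if 99.9 % is unreachable within the available rank the
candidate list truncates with a warning, and a hard cap of
`max_components = 30` applies because a flat noise tail can push the 99.9 %
bound hundreds of components deep, where discrimination dimensions are pure
noise and fitting them is both slow and pointless.

## Balanced resampling ("interactions")

Per interaction: (1) the requested number of whole samples per class moves to
the test set with all replicate spectra — a sample never straddles the test
boundary, so test performance reflects unseen bean lots; (2) from the
remaining spectra, the per-class minimum count is drawn for every class and
split 80/20 by nearest integer on the training share (e.g. 352 remaining
spectra → 282 training + 70 cross-validation). Training and cross-validation
are therefore exactly balanced across classes; test sets are intentionally
not. Replicates of a non-test sample *may* split between training and
cross-validation — that is the protocol being modelled, and its consequence
(optimism in cv estimates when sample-specific signal survives
preprocessing) is discussed under Limitations. All drawing uses
`numpy.random.Generator` seeded through `SeedSequence.spawn`, so plans are
reproducible per (seed, interaction).

## Metrics

Multi-class one-vs-rest convention per class c: TP = diagonal entry,
FN = off-diagonal row sum, FP = off-diagonal column sum,
TN = total − TP − FN − FP; Se = TP/(TP+FN)·100, Sp = TN/(TN+FP)·100,
accuracy = trace/total·100. For a two-class task with a designated positive
class these reduce exactly to the binary definitions, so the summary row
quotes the positive class. A class with no true spectra has undefined
sensitivity: reported as NaN with a warning and excluded from macro means.
Across interactions, each metric is aggregated as arithmetic mean ± sample
sd (n−1), rendered to one decimal.

## Synthetic generator

The generator is the package's stand-in for unreleased instrument data and
defines the study conditions under which the pipeline is validated:

| parameter | default | rationale |
|---|---|---|
| grid | 866–2532 nm, 949 points | instrument grid of the modelled protocol |
| replicates/sample | 4 | acquisition protocol |
| band centres (nm) | 920, 1000, 1200, 1470, 1700, 1760, 1900, 2130, 2400 | canonical green-coffee absorbance peaks |
| band widths / amplitudes | 28–60 nm / 0.12–0.52 AU | broad overlapping NIR bands on a rising continuum (0.25–0.45 AU) |
| class multipliers | +10 % (2-class) or 1.00/1.04/1.08/1.12/1.16 (5-class) on bands ≥ 1400 nm | origin effect confined to the combination-band region, with the continent ordering Africa > S. America > Asia > C. America > Yemen |
| sample effect | 3 Gaussians, width 150–400 nm, amplitude sd 0.01 AU | smooth within-origin biological variation |
| replicate noise | white, sd 5e-5 AU | high-end FT-NIR with 128-scan averaging; also reproduces the realistic regime where 95–99.9 % cumulative variance spans ~7–14 post-derivative PCs |
| scatter | U(0.95, 1.05) multiplicative | packing/path-length variation between scans |
| baseline | offset U(−0.02, 0.02) AU + slope U(−2e-5, 2e-5) AU/nm | drift between scans |

Band shapes are Gaussian in nm; true NIR bands live in the wavenumber domain
and are asymmetric in nm — acceptable for a statistical stand-in, not for
spectroscopic simulation. An optional `band_jitter_sd` adds per-sample
compositional variation of band amplitudes (default 0): it is off because it
makes replicates sample-identifiable after preprocessing, which deliberately
violates the null-calibration property below; turning it on is the easy way
to study that leakage.

`inject_adulteration` relabels a random fraction of donor-class samples as a
victim class (whole samples, ground truth returned separately), emulating
origin fraud for screening studies; mislabelled samples show strongly
elevated Mahalanobis distance to the victim centroid.

**What passing tests show — and what they don't.** The generator's smooth
sample effect is essentially annihilated by the second derivative, so under
the null (no class effect) held-out test accuracy sits at chance (~50 %,
measured). Real bean lots differ compositionally, i.e. in band amplitudes,
which the derivative preserves — so on real data, replicate spectra of one
sample stay mutually recognisable and cross-validation estimates are more
optimistic than test estimates, as the gap between cv and test numbers in
real studies of this design shows. Recovery results on the synthetic default
(100 % at a 10 % class amplitude step) demonstrate correctness of the
machinery, not expected field performance.

A related caveat: the cv accuracy of the *selected* model is the maximum of
~10 candidate accuracies measured on the same cv split, which is upward
biased (≈ 60 % under the null for a 64-spectrum cv set). The held-out test
set is the only unbiased performance estimate the pipeline produces; the
null-sanity check in the acceptance materials therefore uses test accuracy.

## Problem sizes

Validation experiments use 50 samples/class × 4 replicates (400 spectra ×
949 wavelengths) for the two-class recovery and null runs, 3 interactions ×
5 seeds; oracle comparisons use 50 random matrices up to 30×15. One full
experiment takes ~1 s on a single core; the complete acceptance computation
~45 s.

## Known limitations

* Gaussian-in-nm bands and white noise are statistical conveniences; no
  wavenumber-domain band physics, no water-vapour or temperature effects.
* The baseline "offset" reading of baseline correction is one of several
  conventions in commercial software; results with the detrend variant may
  differ slightly.
* The 80/20 split is nearest-integer on the training share; other rounding
  conventions change per-class counts by ±1.
* `max_components = 30` bounds the selection sweep; data whose genuine
  structure needs more components would need the cap raised.
* Region-level (within-country) designs are supported by the data model and
  splitter but exercised in tests only through the country-level path plus
  the region-set scheme constructor.
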