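# Methods

`wheatlnc` estimates wheat leaf nitrogen content (LNC, % of leaf dry mass)
from near-ground hyperspectral canopy imagery by fusing three feature
families — vegetation indices (VIs), spectral position features (PFs), and
CNN deep features (DFs) — and comparing three regressors (PLSR, SVR, GBDT)
on each family and on the fused set. This note documents the models, the
numerical choices, and what the synthetic experiments do and do not show.

## Data model

The sensor emulated by the package delivers reflectance cubes of 520 bands
evenly spanning 360–1025 nm (a ~1.281 nm sampling step; the nominal 2.8 nm
resolution is treated as the optical FWHM, not the sampling step). Each
sample (plot) contributes a canopy ROI-mean reflectance spectrum — the
per-band arithmetic mean over canopy-labelled pixels — restricted to a
400–1000 nm analysis window, plus a false-colour image rendering of the
cube for the CNN. LNC is the regression target; samples carry a
calibration/validation tag emulating a by-season split: all fitting and all
feature selection use calibration samples only, and validation data are
transformed with calibration statistics (standardisation uses calibration
mean/variance), so no validation information can leak into the fit.

## Spectral features

**Vegetation indices (26).** Fixed algebraic combinations of reflectance at
single wavelengths (R_λ, obtained by linear interpolation on the band grid;
nearest-band lookup is a config option) and four broadband roles that
default to NIR = 800, R = 670, G = 550, B = 450 nm. Three catalogued
formula strings are typographically garbled in common printings (EVI's
division bar, MTVI2's square roots, ARVI); the standard forms are used and
the definitions' docstrings record the discrepancy. Two quirks are
implemented exactly as catalogued: PRI's asymmetric 531/530 nm numerator/
denominator pair and MSR without the customary square root; GNDVI as
catalogued duplicates NDVI II (a broadband green variant is available as
`gndvi_green` but is not part of the 26-index census).

**Continuum removal (12 parameters).** Each of two absorption regions
(557–754 and 900–1000 nm) and two reflection regions (500–721 and
753–959 nm) is normalised by its continuum: for absorption, the upper
convex hull of the region (computed by monotone chain, so hull ≥ spectrum
with equality at the endpoints), removed curve R/hull ∈ (0, 1]; for
reflection, the mirrored construction with the lower convex chord and
removed curve hull/R. Per region: Depth = 1 − removed at its extremum,
Area = trapezoidal integral of |spectrum − hull| on the native band grid
(nm·reflectance), ND = Depth/Area (NaN, reported explicitly, when
Area = 0). The second absorption region is nominally 900–1030 nm in the
literature this feature set comes from, which exceeds the 400–1000 nm
extraction window; the default clips it to 1000 nm. Degenerate (all-equal)
regions remove to 1 everywhere. Feature names use the conventional field
spellings, including `A_Aear`/`R_Aear` for the areas.

**Band positions (13).** First derivative of reflectance per nm, by a
Savitzky–Golay filter (window 7, order 2) by default — raw differences are
noise-sensitive at 1.28 nm sampling — with plain central differences as an
option (and as the automatic fallback on short or non-uniform grids). Edge
amplitudes/positions are the maximum derivative and its wavelength within
blue (490–530), yellow (560–640) and red (680–760) edges; Rg/λg and Ro/λo
are the green-peak maximum (510–560) and red-valley minimum (650–690);
SDb/SDy/SDr are the derivative sums within the edge windows. Together with
the continuum parameters these are the 25 position features.

## Deep features

A five-conv/three-pool AlexNet-shaped trunk with a two-layer fully
connected head whose second layer (FC2) is 256 units wide supplies the
per-sample deep feature vector (DF_000…DF_255). The canonical AlexNet head
(three FC layers, 4096-wide penultimate activations) is replaced by this
256-out head; FC1 width 1024 is a package choice. Input is a 3-channel
224 × 224 image: cube planes at 800/670/550 nm (configurable triplet),
each min–max normalised per channel (a zero-range channel maps to zeros)
and bilinearly resized; a cube already at the target size is passed through
unresampled. The forward pass is pure numpy (im2col convolutions, 3×3
stride-2 max pooling, ReLU after each conv and FC1, linear FC2 output;
no local response normalisation), so extraction is bit-reproducible.
Weights are pluggable via an `.npz` of named layer arrays; with none
supplied, a seeded He-normal initialisation is used, making the extractor a
structured random projection. Random projections preserve the monotone LNC
signal carried by the image (verified as a correlation property in the
tests) but are noisier than a trained network's features — a limitation to
keep in mind when interpreting the deep-feature column of any synthetic
report.

## Feature selection and fusion

* VIs and DFs are ranked by **out-of-bag permutation importance** of a
  seeded regression forest (default 500 trees, all features considered per
  split, minimum leaf size 3, bootstrap of the calibration samples): per
  tree, the OOB mean squared error is measured before and after permuting
  each feature's OOB column (one shared permutation per tree, which makes
  scores exactly equivariant under column reordering up to split
  tie-breaking inside the tree learner); the mean error increase over trees,
  floored at 0 and normalised to max = 1, is the relative importance.
* PFs are ranked by **|Pearson r|** with LNC, r computed from the
  product-moment formula (zero-variance features score 0 with a warning).
* Retention: the top 30% of each spectral ranking, with round-half-down
  (26 → 8, 25 → 7; ties in ranks broken lexicographically for
  determinism); deep features keep those with relative importance > 0.45,
  capped at the first 20 by rank, with a top-k fallback (default on) that
  retains exactly the cap when the absolute threshold is not informative —
  which is the typical situation on synthetic data.
* Fusion is the ordered concatenation VI → PF → DF (8 + 7 + 20 = 35
  features); duplicate names across families are an error.

## Regression grid

Three estimators per feature set, 3 × 4 = 12 cells. PLSR (default 5 latent
components, capped at the feature count) and SVR (RBF kernel, C = 10,
g = 1/n_features, scikit-learn's default epsilon) operate on standardised
features; GBDT (learning rate 0.1, 300 trees, depth 3, seeded) is
scale-free. These hyperparameter values are package conventions — exposed
in every run manifest — because the methodology this grid follows names the
hyperparameters without printing values. There is no inner tuning loop by
default. Goodness of fit: R² = 1 − SS_res/SS_tot and RMSE, evaluated
separately on calibration and validation samples; both agree with direct
formula evaluation to 1e−10 in the test suite.

## Synthetic canopy generator

The generator exists because field datasets of this kind are restricted; it
is first-class, tested code that defines the package's study conditions.

A canopy endmember spectrum is built from: a 0.05 visible baseline plus a
Gaussian green peak at 550 nm (amplitude 0.055, σ 18 nm); a logistic
red-edge blend (scale 10 nm) onto a NIR plateau; a multiplicative Gaussian
chlorophyll well at 670 nm (σ 28 nm) and water dip at 970 nm (σ 22 nm);
values clipped to [0, 1]. Soil is a linear ramp from 0.12 (360 nm) to 0.32
(1025 nm) — the simplest spectrum distinguishable from canopy that
exercises soil-background removal. Cube patches default to 32 × 32 pixels
(desk scale; the 1392 × 1040 frame is available via `patch_size`): pixels
are canopy or soil (Bernoulli per the sample's soil fraction), ~30% of
canopy pixels are self-shaded (illumination × 0.5), canopy pixels get
multiplicative N(1, 0.03) jitter, and every pixel gets additive N(0,
noise_sd) band noise (default sd 0.005 reflectance). The sample's spectrum
is the mean over canopy-labelled pixels of the rendered cube.

LNC (drawn uniformly from 1–5 % dry mass, a typical wheat range) drives
four monotone links: a *saturating* chlorophyll-well depth
(0.35 + 0.60·(1 − e^(−0.55·(lnc−1)))), a linear red-edge inflection
(700 + 6·(lnc−1) nm), a linear water-dip depth, and ground cover
(soil fraction falling by 0.06 per % N) — nitrogen-starved wheat tillers
less, and cover is a purely spatial trait invisible to the canopy-mean
spectrum but visible to the image-based deep features. In the default
(nuisance-on) mode, each link carries biological scatter (chl ±0.10,
red edge ±6 nm, water ±0.03, cover ±0.03, uniform) plus LNC-independent
draws for NIR plateau (U(0.39, 0.49)) and illumination (U(0.92, 1.08)).
The scatter magnitudes were set so that, as in real canopy nitrogen
studies, no single family explains LNC: chlorophyll-driven indices
saturate, the families carry partly complementary information (cover is
visible only to the image pathway, the water region only to the continuum
parameters), and fusing them beats every single family for every regressor.
With the default random-projection CNN weights the deep family is the
noisiest on validation; with nuisance off the links are deterministic,
which is the mode the monotonicity invariants are tested in.

**What the generator does not emulate:** radiative-transfer realism
(no PROSAIL-class leaf/canopy physics), multi-season or cultivar/density
factor structure (the calibration/validation split is a tag, not a second
simulated season), spatially correlated canopy texture (pixel classes are
i.i.d.), and sensor artefacts beyond additive Gaussian noise. Passing tests
therefore demonstrate that the pipeline's arithmetic, selection logic and
model plumbing behave as specified and that its qualitative orderings hold
under the generator's statistical structure — not that the numeric R²/RMSE
levels transfer to any real field dataset.

## Problem sizes and numerical choices

The default synthetic experiment uses n = 200 samples (70/30 split). The
recovery suite runs the full pipeline at n = 200 over five seeds, plus one
noise-free n = 300 run; the fusion-vs-VI dominance check is asserted on the
mean validation R² over the five seeds per model (it is a stochastic
ordering; for GBDT it additionally holds on every individual seed), and the
noise-free GBDT fusion run must reach validation R² ≥ 0.9. The deep-signal
correlation property is checked at n = 100 noise-free samples. Cubes are
stored float32. Determinism is absolute: one integer seed fixes the
dataset, the forest, the extractor weights and GBDT, and rerunning a
pipeline config reproduces every artifact byte for byte.

Degenerate inputs are handled explicitly rather than silently: empty ROI
masks, out-of-grid wavelength lookups, windows containing no bands,
regions with fewer than three bands, zero-variance correlation inputs,
constant regression targets and invalid hyperparameters all raise; an
undefined index or region parameter inside a batch extraction becomes NaN
with a recorded reason.

## Known limitations

* Without trained convolutional weights the deep features are random
  projections; they carry the image's LNC signal but with extra variance,
  which makes the deep and fused columns of a synthetic report noisier than
  a trained extractor would produce.
* The 26-index census reproduces two catalogue quirks (GNDVI ≡ NDVI II,
  MSR without the square root) by design; users wanting the textbook
  variants should add them under new names rather than edit the census.
* OOB permutation importance is computed over trees fitted with exhaustive
  split search; with strongly collinear features importance spreads across
  the collinear group, as with any permutation importance.
* The ENVI reader supports the common scalar dtypes, BSQ/BIL/BIP
  interleaves, and nm/µm wavelength units; exotic header features (bad
  bands lists, per-band gains) are ignored.
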