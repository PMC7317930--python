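# Methods

## Scope and rationale

The package re-implements, as tested code, the measurement chain of a
quantitative immunogold study of GABA_B1_ in CA1 of wild-type and APP/PS1
mice at 1, 6 and 12 months: SDS-FRL surface densities along the
somato-dendritic axis, cluster composition, presynaptic active-zone
densities, pre-embedding membrane/intracellular partitions, histoblot and
band densitometry, and the two-way ANOVA + Bonferroni comparison layer.
The raw micrographs are not public, so correctness is established by
**parameter recovery**: a calibrated generator plants known quantities and
every stage must recover them.

## Generative model for SDS-FRL point patterns

A P-face profile of area A (µm²) carries the superposition of

* a **clustered process**: parent centres Poisson(λ_c·A), uniform in the
  polygon; each parent draws K = 3 + Poisson(µ − 3) offspring, displaced
  isotropically by a Gaussian of scale σ_r truncated at 3σ_r;
* a **scattered process**: Poisson(λ_s·A), uniform.

Expected density is exactly λ_c·µ + λ_s.  The calibration decomposes each
transcribed per-condition mean density D as λ_s = f_s·D,
λ_c = (1 − f_s)·D/µ with scattered fraction f_s = 0.2 (particles are
predominantly clustered, a minority scattered) and offspring mean µ = 6
(wild type) or 4.5 (APP/PS1, whose clusters are smaller).  Values of the
densities themselves are in `src/immunogold/data/calibration.yaml`; entries
marked `reported` carry the study's group means, entries marked `assumed`
complete the 11-compartment gradient where no value was published (graded
soma < apical < oblique < spine, highest in slm, genotypes equal wherever no
difference was found).  Where two published versions of the same number
disagree, the running-text version is used and the variant is recorded
under `alternates:`.

Design choices:

* **Offspring law 3 + Poisson(µ − 3)** guarantees every generated cluster
  satisfies the min-3 membership rule, making cluster-count recovery
  well-posed; sub-threshold groups come from the scattered process.
* **Truncation at 3σ_r** bounds cluster support, so "well separated" can be
  made exact for planted-recovery tests.
* **Offspring falling outside the profile are re-drawn**, conserving the
  expected count at the cost of slight anisotropy against the membrane
  edge; densities stay unbiased.
* **Cluster radius σ_r = 20 nm** (tens-of-nm aggregates; no published
  value) and **raster scale 1 nm/px** (a 10 nm particle spans 10 px) are
  configurable defaults.
* **Between-animal variability** is a multiplicative lognormal effect with
  CV = 0.08 on the intensities, tagged per animal (4 animals/group), so the
  "mean ± SEM between animals" convention has something real to average.

### Planted clusters for composition analysis

The 12-month cluster-composition conditions plant an **exact** number of
clusters over the pooled 140 µm² oblique-dendrite reference area: centres
follow a hard-core process (min separation 300 nm) inside profiles eroded
by the cluster support radius; sizes are 3 + Geometric(p) truncated to the
recorded range (p = 0.22 WT / 0.40 APP/PS1, matching the recorded size
ranges over a few hundred draws); member displacements are re-sampled until
each cluster is internally single-linkage connected at 50 nm — a planted
cluster is one aggregation by definition, so its members must form one
linkage component.  Under these conditions single linkage recovers totals
and memberships exactly at any seed.

### Pre-embedding scenes

Each particle is membrane-associated with probability p (the transcribed
membrane percentage); membrane particles are placed within d = 25 nm of the
membrane contour, intracellular particles uniformly in the interior eroded
by d.  The classifier uses the same 25 nm default: silver-enhanced
particles within ~20–30 nm of a membrane are visually scored as
membrane-associated, and placing "intracellular" truth beyond that distance
mirrors the fact that a particle within the association distance is not
visually distinguishable from membrane labeling.  The split is therefore
exactly recoverable and the recovered percentage is binomial around p
(SE ≈ 1.1 points at n = 2000).

### Rasterization

Particles are dark anti-aliased disks (analytic edge coverage) on a bright
background (level 0.78 of full scale) with a low-frequency shading field
(Gaussian-filtered noise, σ = 150 px, amplitude 0.06) and per-pixel
Gaussian noise (σ = 0.03).  The model reproduces what matters for
detection — contrast, crowding, slow illumination drift — and deliberately
omits platinum-shadowing texture, intramembrane-particle relief and 3-D
membrane topology; passing tests therefore certify the measurement chain,
not detector performance on real replicas.

## Detection

Inverted image → scale-normalised Laplacian-of-Gaussian over a scale band
(diameter 10 nm ± 40%, 5 scales) → local maxima above a response threshold
(default 0.15 on the normalised scale) → greedy non-maximum suppression at
the expected diameter → sub-pixel centre-of-mass refinement.  Raising the
threshold can only remove detections (monotonicity), and identical inputs
give identical outputs.

Gold disks closer than ~one diameter physically overlap and present no
interior intensity minimum, so peak finding alone undercounts crowded
clusters.  A splitting stage therefore re-examines dark-mask connected
components: a component whose area exceeds 1.35 single-disk areas implies
n ≈ area/disk-area particles, and if fewer peaks were found inside, the
component is re-populated with n deterministically-initialised weighted
k-means centroids.  A lone disk's mask area stays within ~8% of nominal
under the default noise, so the 1.35 factor cannot split single particles;
pairs are resolved down to ~3.5 nm separation.  Residual misses are pairs
below that separation (≈1–2% of clustered particles at the calibrated
intensities); measured recall is ~0.96–0.99 with precision ~1.0.

The seeded semi-automated mode snaps operator-given points to the local
response maximum within one expected diameter and drops seeds in flat
regions.

Validation matching is a one-to-one assignment (Hungarian algorithm on
gate-clipped distances, gate 10 nm) maximising matched pairs; recall,
precision and localisation RMSE are exact functions of that matching.

## Quantification conventions

* Densities are count/area per profile; areas from the polygon (shoelace,
  via the geometry library).  Profiles below 0.01 µm² are excluded.
* Background correction max(ρ_P − ρ_E, 0) is applied at the condition
  level (mean E-face density, which the generator sets to 0.3/µm²);
  both raw and corrected densities are reported because the published
  numbers do not state which convention they follow.
* The gradient table aggregates profile → animal mean → group mean ± SEM
  (animal is the experimental unit); profile-level statistics are emitted
  as diagnostics.
* Boundary particles within 1 nm of a profile outline count as inside.

## Statistics

Two-way fixed-effects ANOVA via OLS with Type II sums of squares when cell
counts differ (balanced designs reproduce hand sum-of-squares arithmetic to
1e-10 relative).  Pairwise genotype contrasts per compartment are
two-sample t tests with Bonferroni adjustment (m = 11 for gradient tables);
adjusted p is never below raw p and familywise error is controlled at the
nominal level on null simulations.  For the synthetic 6-month dataset the
per-compartment contrasts use profile-level n (16 dendrites / 21 spines per
group, the published sample sizes): with 4 animals per group the
animal-level test is underpowered for the spine effect, and the published
n indicates the profile was the unit entering the posthoc tests.  The
12-month dataset shows a genotype main effect in every run; the 6-month
dataset is significant only in slm oblique dendrites and spines —
the published structure.

## Densitometry

Dark-high convention: density = 255 − pixel for 8-bit scans (white level −
pixel generally).  Region measurements are means over pixel centres inside
0.10 mm circular cursors; exactly eight background ROIs are required in
strict mode and their mean is subtracted, making corrected values invariant
to constant intensity offsets.  Band quantification integrates
background-subtracted inverted intensity over a band window and divides by
the loading-control window.  The synthetic blot generator plants region
intensities (equal between genotypes, as observed) with Gaussian-blurred
edges and additive noise; group comparisons on such blots are
non-significant in ≥95% of seeds.

## Problem sizes

Recovery runs use the published sample sizes where they exist (16 oblique
dendrites, 21 spines per genotype; 140 µm² pooled reference area) and
otherwise sizes chosen for estimator precision: 400 axon terminals per
presynaptic condition (pooled AZ area 20 µm², SE ≈ 2%) and ~77
pre-embedding profiles (n ≥ 2000 particles, binomial SE ≈ 1 point).

## Known limitations

* The raster model omits replica texture; detection performance on real
  micrographs is not certified by these tests.
* The single-linkage distance (50 nm) and the membrane-association
  distance (25 nm) are defaults for unpublished parameters; both are
  surfaced in report headers and configurable.
* The `assumed` calibration entries are plausible values, not published
  measurements; only the `reported` entries reproduce published numbers.
* Mixed-effects models, Ripley's K / pair-correlation diagnostics and
  nonparametric group tests are out of scope.
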