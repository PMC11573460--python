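# Methods

This note records the models implemented by `forageselect`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## Study design emulated

The synthetic trial mirrors a three-strategy sheep grazing experiment:
lambs alone (LA), lambs and ewes mixed (LM and EM, co-located in shared
plots), and ewes alone (EA), each with 3 replicate plots, 3 sampling
periods, and a configurable number of animals per plot (default 3, giving
36 animals and 108 animal–period fecal samples in the default layout). Vegetation is surveyed with 10 quadrats per plot (30 per plot
group and period); quadrat area is 0.25 m², so plot biomass is reported
in g m⁻².

## Vegetation

Quadrats of one plot/period are pooled before any index is computed.
Relative abundance uses clipped dry biomass as the abundance measure nᵢ:
the survey weighs biomass and records no individual counts, so a
count-based Shannon index is possible (any non-negative abundance works
through the same functions) but biomass is the default. Diversity is
H′ = −Σ pᵢ ln pᵢ with 0·ln 0 ≡ 0. Availability (VRA) groups the 37-species
pool into six food items — Poaceae, Cyperaceae, Rosaceae, Amaryllidaceae,
Fabaceae, and the pooled remainder as forbs — via a required
species→item map; community and per-item nutrient contents (CP, NDF, ADF,
% of dry matter) are biomass-weighted means. Plot mean height is
biomass-weighted over the species present.

## Behavior

Tri-axial acceleration is separated into static and dynamic components by
subtracting a centered running mean per axis. The smoothing window
defaults to 2 s and the classification epoch to 60 s; neither is dictated
by the measurement model, both are configurable, and results are
insensitive to them as long as the window is much shorter than a bout.
ODBA is the sum of absolute dynamic accelerations; an epoch whose mean
ODBA exceeds 0.1 g is grazing, strictly below is non-grazing, and an
epoch exactly at the threshold — a measure-zero event — is labelled
non-grazing. Edges of a trace use truncated running means so the output
keeps the input length. Input is expected in gravitational units; a flag
converts from m s⁻². Grazing and non-grazing durations always sum to the
observation window (13 h from 0530 to 1830 in the emulated protocol).

## Intake (marker chain)

An inert external marker (TiO₂, 2.5 g day⁻¹) yields fecal dry-matter
output FO = dose/[TiO₂] with the concentration in g marker per g fecal
DM. Ash (% of fecal DM) gives fecal organic matter
FOM = FO·(1 − ash/100). Digestibility comes from fecal crude protein via
the exponential regression OMD = a − b·e^(−c·FCP/s) with a = 0.899,
b = 0.644, c = 0.5774, s = 100 and FCP in % of fecal DM — the literal
left-to-right reading of the source calibration, whose typesetting leaves
the FCP units ambiguous; all four constants live in `OmdModel`, so an
alternative calibration is a configuration change. Under this reading OMD
is strictly increasing in FCP and confined to (0.255, 0.899); the
asymptote is never attained at finite FCP. OMI = FOM/(1 − OMD). No
marker-recovery correction is applied (the marker is assumed inert and
evenly distributed), and pooled multi-day grab samples are treated as one
sample per animal–period.

## Diet from metabarcoding

The pipeline starts at denoised ASV read counts: primer trimming, quality
filtering and denoising are performed upstream by their standard tools
and are out of scope here. ASVs are assigned to species only on exact,
case-insensitive, gap-free sequence identity to exactly one reference
barcode; sequences matching no reference, or duplicated across species,
stay unassigned. DRA excludes unassigned reads from the denominator and
reports their fraction per sample. DRA is treated as an unbiased estimate
of diet proportion — no copy-number or recovery-bias correction — which
is exactly what the generator's multinomial model produces; with real
rbcL data this is an assumption, not a fact. Diet CP/NDF/ADF are
DRA-weighted means of the food items' nutrient content taken from the
matching plot/period vegetation. Dietary richness is the expected ASV
count of a subsample standardized to the minimum assigned depth of the
comparison set (configurable), estimated by 1000 without-replacement
bootstrap iterations; a with-replacement flag exists because the
field-standard choice is not universal. Without-replacement rarefaction
has a closed hypergeometric form which the test suite uses as the oracle.

## Selectivity

Jacobs' D = (r − p)/(r + p − 2rp) compares each sample's diet proportion
r with the availability p of the same plot and period (a flag pools
availability to strategy level). D is undefined when an item is absent
from, or constitutes the entirety of, both diet and vegetation; such
cells are NaN and excluded, not imputed as 0. Departure from neutrality
is tested with Wilcoxon signed-rank against 0: exact null up to n = 25
after zero handling, normal approximation with continuity correction
above; zeros are dropped before ranking (Wilcoxon's original method, the
common package default), with Pratt's method available.

## Comparative statistics

Bray–Curtis dissimilarity and one-way perMANOVA are implemented directly.
perMANOVA uses the distance-based decomposition: SS_total is the sum of
all squared pairwise distances over n, SS_within sums within-group
squared distances over the group size (unbalanced-safe), and
pseudo-F = (SS_between/(k−1))/(SS_within/(n−k)). The null is free
permutation of group labels, 999 permutations by default, with the
add-one estimator p = (1 + #{F* ≥ F})/(1 + n_perm); an exact mode
enumerates all distinct label arrangements for small n. Permutations are
free — not restricted within plots — matching the reported analysis
style; a restricted scheme would be the conservative alternative when
animals share plots. NMDS is nonmetric (monotone-regression) scaling with
Kruskal stress-1, best of 20 random starts, principal-axis rotated; a
degenerate all-equal distance matrix triggers a warning and the achieved
stress is reported (an exact zero-stress embedding exists only for
n ≤ k + 1). t-tests are pooled-variance by default (the emulated design
averages three sheep per plot over three periods, giving nine values per
group and df = 16), Welch by flag. The richness regression is OLS on
z-standardized covariates (height, biomass, diversity, CP, NDF, ADF) so
coefficients are comparable effect sizes, with per-coefficient Wald
statistics, 95 % CIs and adjusted R²; rank-deficient designs are rejected
with the collinear columns named.

## Synthetic-data generator

The generator is first-class code with explicit ground truth:

* **Species pool** — 37 species by default across the six items with mean
  biomass shares {Poaceae 0.45, Cyperaceae 0.15, Rosaceae 0.12,
  Amaryllidaceae 0.06, Fabaceae 0.07, forbs 0.15}; the five named
  families then hold 85 % of biomass, matching the "> 81 %" character of
  the emulated steppe site. Family-typical nutrient ranges put forbs and
  legumes above graminoids in CP and below them in NDF. Barcodes are
  unique random 80-mers — long enough to be unambiguous, short enough to
  keep FASTA fixtures tiny.
* **Quadrats** — per-quadrat composition ~ Dirichlet(dispersion × mean
  shares) with dispersion 50 (moderate patchiness), total biomass
  lognormal around 40 g per 0.25 m² quadrat (≈160 g m⁻², a realistic
  steppe standing crop) with σ = 0.3.
* **Diets** — expected family diet ∝ availability × preference,
  renormalized; individual diets are Dirichlet about that expectation
  with concentration 100 (few-percent individual variation). With all
  preferences equal the expected Jacobs' D is 0 for every item. The
  family share is spread over species within a family by within-family
  availability; optionally a per-animal Dirichlet draw around that spread
  (the pipeline default, concentration 3) makes species-level diets
  sparse, as real diets are — without it every animal consumes every
  species and depth-standardized richness is degenerate. Family-level
  proportions are identical either way.
* **Reads** — multinomial over species barcodes at the true species
  proportions. A scalar depth gives exact row sums; the pipeline draws
  per-sample library sizes (lognormal, CV 0.3) so that minimum-depth
  standardization is non-trivial, as in real sequencing runs.
* **Accelerometry** — two-state Markov bouts (mean 30 min grazing, 20 min
  non-grazing), 13 h at 1 Hz; within a bout the per-axis dynamic noise is
  scaled so expected ODBA matches the state mean (0.3 g grazing, 0.02 g
  non-grazing — well separated across the 0.1 g threshold); gravity is
  projected through a slowly drifting pitch/roll random walk. The sample
  rate is configurable; the threshold rule is rate-agnostic once ODBA is
  epoch-averaged.
* **Fecal chemistry** — TiO₂ concentration is dose/true FO with
  multiplicative lognormal noise (CV 5 % by default; unit mean); fecal CP
  inverts the OMD regression at the true OMD, so ground-truth OMD is
  drawn inside the regression's attainable band (default 0.29–0.335,
  corresponding to realistic fecal CP of roughly 6–23 %); ash is carried
  through so derived FOM equals true FOM. With noise set to zero the
  intake chain recovers FO, OMD and OMI exactly — the round-trip oracle.

What the generator does **not** emulate: PCR amplification bias, chimeras
and sequencing error (reads are clean multinomials over true barcodes);
marker passage kinetics; multi-class ethograms (ruminating vs walking);
spatial movement; plant phenology across periods beyond independent
redraws. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated stochastic models, not robustness to these
real-data artifacts.

## Reproducibility and problem sizes

A single global seed derives per-stage seeds by hashing the stage name
(crc32), so any stage can be rerun alone and the pipeline's outputs are
byte-identical across reruns; the manifest records sha256 checksums of
every file. The test suite uses deliberately small problem sizes — e.g.
1000 null simulations with 199 permutations for the perMANOVA size check,
400-iteration rarefactions, a 13 h 1 Hz trace for classification
accuracy — chosen as the smallest sizes at which the Monte-Carlo error
bounds in the assertions are meaningful.

## Known limitations

* The OMD regression's FCP units are a calibration choice; if the source
  calibration expected g kg⁻¹ of fecal OM the constants must be refit
  (`OmdModel` makes this a config change).
* Wilcoxon exact p-values with heavily tied D values fall back to the
  conditional distribution handling of the underlying implementation.
* perMANOVA assumes exchangeability under the null; with animals nested
  in plots the free-permutation p is anti-conservative, and a restricted
  scheme is not implemented.
* NMDS is a local optimizer; 20 random starts make configuration recovery
  reliable at these sizes but global optimality is not guaranteed.
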