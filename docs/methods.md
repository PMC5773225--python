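# Methods

## Measurement model

NanoSIMS reports accumulated ion counts c[¹H], c[²H], c[¹²C], c[¹³C] per
cell region of interest (ROI). Atom fractions are count ratios,
X(¹³C) = c[¹³C]/(c[¹³C]+c[¹²C]) and analogously for hydrogen. Counting is
Poisson, so the relative error of a count ratio a/b is √(1/a + 1/b);
`isocell` reports it in percent and, following standard practice for this
instrument class, retains only cells with ratio errors below 10% for
²H/¹H and below 1% for ¹³C/¹²C (strict inequalities). Day-to-day
instrument variation is removed per image by subtracting the difference
between the outside-ROI atom fraction of the analyzed filter and that of
an unlabeled reference filter; because this is a constant shift per image,
within-image rankings are unaffected. Excess atom fractions subtract the
natural abundances of unlabeled biomass (¹³C: 0.009928, ²H: 0.0002642).
Slightly negative excess fractions are legitimate noise around zero and
are kept in all output tables; they are clipped to zero only at the
inversion step.

If several outside-ROI background records exist for one image they are
averaged with a warning; a missing background for any image is a hard
error naming the image.

## Mass-balance model

During a labeling period of T hours a cell growing exponentially at total
rate μ_tot = μ_glc + μ_ara + μ_AOC replaces a fraction
f_new = 1 − e^(−μ_tot·T) of its biomass. New biomass draws carbon from the
two sugar pathways and from assimilable organic carbon (AOC) in proportion
to the corresponding rates. Carbon entering through the arabinose pathway
carries the heavy-carbon purity of the medium arabinose; in a chemostat the
unlabeled pre-switch sugar pool washes out as e^(−Dt), so over the labeling
period the effective purity is the washout average
p̄ = (1 − ū)·p + ū·x_nat with ū = (1 − e^(−DT))/(DT)
(ū ≈ 0.805 at D = 0.15 h⁻¹, T = 3 h; in batch mode ū is the constant
unlabeled medium fraction). The transfer coefficients κ_C and η_H absorb
everything between substrate uptake and biomass isotope content: for
carbon, the AOC contribution to new biomass made on a single sugar; for
hydrogen, additionally exchange with water, which is not modelled as a
separate kinetic process. Both are fixed by single-substrate calibration
plateaus measured after ≥10 generations (new-biomass fraction
1 − 2⁻¹⁰ > 99%), where x_max = x_nat + coeff·(p − x_nat):

    κ_C = (0.70 − 0.009928)/(0.99 − 0.009928) = 0.70410
    η_H = (0.14 − 0.0002642)/(0.97 − 0.0002642) = 0.14410

The measurable excess fractions are then

    Xᴱ(¹³C) = (μ_ara/μ_tot)·f_new·κ_C·(p̄_ara − x_nat,C)
    Xᴱ(²H)  = (μ_glc/μ_tot)·f_new·η_H·(p̄_glc − x_nat,H)

### Inversion

Dividing each excess fraction by its channel gain gives
A = (μ_ara/μ_tot)·f_new and G = (μ_glc/μ_tot)·f_new, whose sum
(1 − μ_AOC/μ_tot)(1 − e^(−μ_tot·T)) is strictly increasing in μ_tot above
μ_AOC. The scalar root is bracketed on (μ_AOC + 10⁻¹², 5·μ_max] and solved
with Brent's method at absolute tolerance 10⁻¹⁰ h⁻¹; the sugar rates follow
in closed form, μ_ara = A·μ_tot/f_new, μ_glc = G·μ_tot/f_new. Degenerate
inputs: A + G = 0 maps to (0, 0, μ_AOC) exactly; enrichment below the
bracket floor pins μ_tot at the floor (within root tolerance of μ_AOC);
enrichment above the capacity at the cap returns rates scaled onto the cap
with `converged=False`. The forward-then-invert round trip is the identity
to better than 10⁻⁸ relative error over rates in [0, 0.3]² h⁻¹ (verified
against a 2000×2000 brute-force grid-search oracle).

μ_AOC is a single shared constant per experiment — between-cell variation
in AOC assimilation and water exchange is not identifiable from two
isotope channels. Its default, 0.010 h⁻¹, makes the default population
means self-consistent: total 0.037 h⁻¹ minus glucose 0.010 h⁻¹ minus
arabinose 0.017 h⁻¹.

### Specialization index

s = (g − a)/(g + a) with availability-normalized rates g = μ_glc/S_glc,
a = μ_ara/S_ara; with the equal 10 μM supplies of carbon-limited medium
this reduces to (μ_glc − μ_ara)/(μ_glc + μ_ara). s is antisymmetric under
swapping the sugars and undefined (NaN, excluded from distributions) when
both sugar rates are zero, rather than coerced to 0.

## Paired transcription-vs-assimilation analysis

Reporter fluorescence is corrected as raw − filter background −
autofluorescence per channel; negative corrected values are retained
(clipping would bias per-field means) and flagged. The four channels
(corrected mCherry, corrected GFP, Xᴱ(²H), Xᴱ(¹³C)) are standardized to
mean 0, sd 1 within each field of view using the sample (n−1) standard
deviation — per-field cell numbers are small, and standardization absorbs
any per-field additive offsets. All standardized values of all four
channels are pooled per analysis set and min–max normalized to [0, 1];
cells missing any channel are dropped before pairing. The indices are
(mCherry′ − GFP′)/(mCherry′ + GFP′) and (Xᴱ(²H)′ − Xᴱ(¹³C)′)/(Xᴱ(²H)′ +
Xᴱ(¹³C)′), undefined where a denominator is not positive. Both Pearson and
Spearman correlations between the two indices are reported; no
multiple-testing correction is applied, and pooled as well as
per-replicate statistics are emitted.

## Synthetic-data generator

The generator emulates a carbon-limited chemostat population and its
measurement chain; all sampling flows through one seeded generator, so
identical seeds give byte-identical tables.

- **Growth rates.** μ_tot = μ_AOC + X with X lognormal, scaled so that
  μ_tot has the default mean 0.037 h⁻¹ and CV 0.724. The additive form
  (rather than drawing μ_tot directly and subtracting μ_AOC) keeps every
  cell's sugar-derived rate strictly positive while preserving the stated
  mean and CV exactly; the lognormal is a modelling choice (positive,
  right-skewed, consistent with a CV near 0.7), not a measured shape.
- **Specialization.** s is Gaussian clipped to (−0.999, 0.999) —
  continuous and unimodal. Defaults s_mean = −0.30, s_sd = 0.18 put ≈95%
  of cells at s < 0. The sugar split inverts the specialization contrast
  under the configured supplies.
- **Counts.** Expected atom fractions are natural abundance + forward-model
  excess + a per-field drift offset (Normal with sd `drift_13C`/`drift_2H`);
  each isotope channel is one Poisson draw with expectation (element total
  × fraction). Default expected totals are 2×10⁶ carbon and 3×10⁵ hydrogen
  ions per cell, chosen so that typical cells are measured comfortably
  inside the QC bounds while the poorly labeled tail (a few percent of
  cells) fails them — mirroring QC that removes a minority of real cells.
  The filter table carries each field's drifted outside-ROI fractions and
  an undrifted reference record, so drift correction is exact up to
  counting noise.
- **Fluorescence.** A shared lognormal global-expression factor multiplies
  both channels (raw GFP and mCherry are positively correlated even with
  zero coupling, reproducing the global-noise signature), while the channel
  ratio shifts as e^(±coupling·s); per-field additive backgrounds and a
  constant autofluorescence complete the raw intensities.

What passing recovery tests show: the inversion and correction chain is
consistent end-to-end under Poisson noise, drift, and QC truncation. What
they do not show: correctness of the lognormal/clipped-Gaussian population
shapes for real populations, ROI segmentation quality, instrument dead-time
or quasi-simultaneous-arrival effects, or spatial structure on the filter —
none of which are modelled.

## Numerical and design choices

- QC comparisons are strict (<); records exactly at a threshold are
  removed.
- "Top/bottom 20%" groups are the ⌈0.2·n⌉ cells after a stable descending
  sort, compared by group means by default (`stat="median"` available);
  the quintile factor is undefined (NaN, warned) if the bottom-group mean
  is not positive.
- Spearman uses average ranks for ties; correlation pairs with non-finite
  values are dropped and n is reported.
- Population summaries are emitted pooled and per replicate; the
  across-replicate mean CV is reported with its standard error.
- Table output uses ≥6 significant digits; every pipeline stage logs
  input/output record counts and writes a JSON run manifest (seed, config
  hash, package versions).
- Problem sizes in the test-suite and acceptance computations (250–1000
  synthetic cells, 50×50 round-trip grid, 2000×2000 oracle grid, 100
  random oracle cells) were chosen to make sampling error small relative
  to the tolerances tested while keeping runs desk-scale.

## Known limitations

- The transfer-coefficient formulation assumes the calibration plateaus
  transfer unchanged to mixed-substrate growth; pathway-specific isotope
  fractionation beyond the fitted coefficients is not modelled.
- μ_AOC is shared across cells; genuine cell-to-cell AOC variation would
  be absorbed into the sugar-rate estimates.
- Batch mode treats the medium label fraction as constant over the
  labeling window (appropriate for windows short relative to substrate
  depletion).
- The specialization index becomes noise-dominated for cells with very
  low total enrichment; such cells typically also fail QC.
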