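# isocell

Single-cell metabolic analysis of dual stable-isotope labeling experiments
measured by NanoSIMS (nanometer-scale secondary ion mass spectrometry).

Clonal bacterial populations growing on mixtures of two sugars — here
glucose and arabinose supplied to *E. coli* in carbon-limited chemostats —
can hide large cell-to-cell differences in which sugar each cell actually
assimilates and how fast it grows. Feeding ¹³C-arabinose and ²H-glucose for
a short labeling period and counting isotope-specific secondary ions per
cell turns each cell's biomass into a record of its own substrate use.
`isocell` takes the tabular per-cell ion counts exported by upstream image
processing and carries them through to per-cell growth rates and
specialization statistics:

- **`isocell.nanosims`** — atom fractions ¹³C/(¹³C+¹²C) and ²H/(²H+¹H) per
  cell ROI, per-image drift correction against an unlabeled reference
  filter, excess atom fractions above natural abundance, and Poisson
  counting-error QC (ratio errors below 10% for ²H/¹H and 1% for ¹³C/¹²C).
- **`isocell.experiment` / `isocell.model`** — the mass-balance model. With
  washout-averaged label purities p̄ (the unlabeled sugar pool decays as
  e^(−Dt) after the chemostat medium switch), new-biomass fraction
  f_new = 1 − e^(−μ_tot·T), and transfer coefficients κ_C, η_H fixed by
  single-substrate calibrations (≈70% ¹³C and ≈14% ²H plateaus):

      Xᴱ(¹³C) = (μ_ara/μ_tot) · f_new · κ_C · (p̄_ara − x_nat)
      Xᴱ(²H)  = (μ_glc/μ_tot) · f_new · η_H · (p̄_glc − x_nat)

  Inverting the two equations per cell (a monotone scalar root find in
  μ_tot) yields growth rates on glucose, arabinose and assimilable organic
  carbon (AOC), and the specialization index
  s = (g − a)/(g + a) with availability-normalized rates g, a
  (s = −1 arabinose-only, 0 proportional, +1 glucose-only).
- **`isocell.coexpression`** — paired transcription-vs-assimilation
  analysis: background/autofluorescence-corrected reporter intensities
  (P_araE–GFP, P_ptsG–mCherry), per-field standardization, [0,1]
  normalization of all four channels, and the transcriptional and sugar
  specialization indices.
- **`isocell.simulate`** — a synthetic-data generator with known per-cell
  ground truth (lognormal growth rates, unimodal specialization, Poisson
  ion-counting noise, per-field drift, coupled reporter fluorescence) for
  end-to-end parameter-recovery testing.
- **`isocell.stats`** — CVs, top/bottom quintile heterogeneity factors,
  Spearman/Pearson correlations, KS and Mann-Whitney tests, population
  summaries.

The modelling surface follows the statsmodels convention:
`SingleCellLabelingModel(measurements, experiment, calibration).fit()`
returns a `LabelingResults` with the per-cell estimate table,
`summary()` and `population_summary()`.

## Worked example

Simulate a 250-cell carbon-limited chemostat experiment, process the ion
counts, and invert the model:

```bash
printf 'population:\n  n_cells: 250\n' > config.yaml
isocell simulate --config config.yaml --seed 1 --out-dir sim
isocell process --counts sim/counts.tsv --filters sim/filters.tsv --out meas.tsv
isocell infer --measurements meas.tsv --out estimates.tsv
```

which prints

```
Single-cell dual-isotope labeling model
=======================================================
mode: chemostat    T_label: 3.0 h    mu_AOC: 0.01 1/h
kappa_C: 0.7041    eta_H: 0.1441
cells fitted: 242 (of 250 input)
-------------------------------------------------------
                  mean        CV
mu_total        0.0345     0.679
mu_glc          0.0089     1.031
mu_ara          0.0157     0.966
-------------------------------------------------------
fraction s < 0 (arabinose-preferring): 0.955  (n=242)
top-vs-bottom quintile factor: 3.91
top-quintile vs population speedup: 1.94
```

8 of the 250 simulated cells fail the Poisson-error QC. The recovered mean
total growth rate (0.0345 h⁻¹) and its CV (0.679) sit close to the
generative population values (0.037 h⁻¹, CV 0.724); about 95% of cells
preferentially assimilate arabinose (s < 0); and the most active 20% of
cells grow about 3.9-fold faster than the least active 20% and about
1.9-fold faster than the population average. `isocell constants` prints
the derived chemostat and calibration constants (D = 0.15 h⁻¹, doubling
time 4.62 h, volume-change time 6.67 h, κ_C = 0.704, η_H = 0.144);
`isocell pair` and `isocell summarize` complete the pipeline.

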