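# tspoquant

Quantification of TSPO PET with an arterial input function, built for
[18F]-FEPPA-style neuroinflammation studies: second-generation TSPO
radioligands have no reference region, so regional binding must be
quantified as the **total distribution volume**

```
VT = K1/k2 · (1 + k3/k4)
```

from a two-tissue compartment model (2-TCM) driven by the
metabolite- and dispersion-corrected parent radioligand concentration
in arterial plasma. Because TSPO binding affinity is genetically
stratified (rs6971: high-affinity HAB vs mixed-affinity MAB carriers;
low-affinity LABs are not quantifiable with FEPPA), the group analysis
must treat genotype as a factor alongside disease.

The package covers the full chain, for researchers analysing dynamic
TSPO PET with arterial sampling:

- **`tspoquant.input_function`** — builds cp(t) from the continuous
  sampler record and timed manual samples: Richardson–Lucy
  deconvolution of the line dispersion (monoexponential kernel,
  τ = 16 s), curve merging with an exponential tail, a bi-exponential
  blood-to-plasma ratio and a Hill parent-fraction model
  fp(t) = 1 − a·t^b/(c + t^b).
- **`tspoquant.compartment_model`** — exact forward simulation of the
  reversible 2-TCM with a 5% vascular signal, bounded multi-start
  nonlinear least squares, VT with its delta-method standard error,
  and the %COV = 100·SE(VT)/VT quality filter (≤ 20 retained).
- **`tspoquant.graphical_analysis`** — Logan graphical VT for ROI
  curves and voxel-wise parametric VT images (t* = 30 min default, or
  auto-selected from the linearity of the plot).
- **`tspoquant.pvc`** — Müller-Gärtner partial-volume correction from
  gray/white/CSF probability maps and the scanner PSF
  (4.4/4.4/4.5 mm FWHM default).
- **`tspoquant.cohort_stats`** — per-region Type-III factorial ANCOVA
  (disease × genotype, injected amount as nuisance covariate), Levene
  variance gating of the significance level (α = 0.01 fallback),
  stratified pooled-variance t tests, Pearson clinical correlations,
  and genotype percentage differences
  100·(HAB − MAB)/((HAB + MAB)/2).
- **`tspoquant.synthetic_data`** — a ground-truth generator (input
  functions, TACs, image phantoms, genotype-stratified cohorts
  calibrated to published FEPPA group means) so the whole pipeline is
  testable without any raw PET data.
- **`tspoquant.cli`** — a `tspoquant` command with `simulate`,
  `input-fn`, `fit-tac`, `logan-image`, `pvc`, `cohort-stats` and
  `demo` subcommands.

## Worked example

Simulate a cohort with the default calibrated design and run the
group analysis:

```python
from tspoquant import CohortDesign, simulate_cohort
from tspoquant.cohort_stats import region_summary, overall_percent_difference

table, truth = simulate_cohort(CohortDesign(seed=1))
summaries = region_summary(table)
s = next(x for x in summaries if x.roi == "frontal")
print(f"frontal genotype: F(1,{s.anova['genotype'].df[1]}) = "
      f"{s.anova['genotype'].statistic:.1f}, p = {s.anova['genotype'].p:.2g}")
print(f"frontal disease:  F(1,{s.anova['disease'].df[1]}) = "
      f"{s.anova['disease'].statistic:.1f}, p = {s.anova['disease'].p:.2f}")
print(f"overall %diff HC: {overall_percent_difference(summaries, 'HC'):.1f}")
print(f"overall %diff PD: {overall_percent_difference(summaries, 'PD'):.1f}")
```

prints

```
frontal genotype: F(1,39) = 60.3, p = 2e-09
frontal disease:  F(1,39) = 0.6, p = 0.46
overall %diff HC: 37.6
overall %diff PD: 35.2
```

— a strong genotype main effect, a null disease effect, and HAB
binding 30–45% above MAB, which is the structure the generator is
calibrated to. The same run from the shell:

```bash
tspoquant demo --seed 1 --out-dir demo/
```

writes `demo/summary.csv` (per-region cell means, percentage
differences, ANCOVA F/p), `demo/cohort.csv`, and a `report.json`
embedding the fully resolved configuration.

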