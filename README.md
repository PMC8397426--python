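# twinstable

Stability, heritability and conservation of longitudinal ¹H-NMR urinary
metabolomic profiles in a classic twin design.

## The problem

Urinary metabolite levels fluctuate with diet, lifestyle and physiology.
For nutrition and biomarker research it matters which spectral regions of a
urinary NMR profile are *stable* — reproducible within a person over months
— and why: how much of that stability is driven by genes, by environment
shared within a family, and by environment unique to the individual.
`twinstable` implements that analysis end to end for repeated-visit twin
cohorts (monozygotic and dizygotic same-sex pairs measured at three visits
over two months), together with a synthetic-data generator with known
genetic/environmental structure so every stage is testable without any
cohort download.

## The models

**Variance decomposition and ICC.** For a normalized, normality-transformed
bin level $Y_{ij}$ of twin $i$ in family $j$:

$$Y_{ij} = \mu + \alpha\,a_{ij} + \delta\,g_{ij} + \gamma\,w_{ij} + \phi\,h_{ij} + B_{ij} + F_j + \varepsilon$$

with random intercepts $B_{ij}\sim N(0,\sigma_B^2)$ (interindividual),
$F_j\sim N(0,\sigma_F^2)$ (intrafamily) and residual
$\varepsilon\sim N(0,\sigma_W^2)$ (intraindividual), and fixed effects for
age, sex, fat-free mass (FFM) and diet quality (HEI score). The intraclass
correlation

$$\mathrm{ICC} = \frac{\sigma_B^2+\sigma_F^2}{\sigma_B^2+\sigma_F^2+\sigma_W^2}$$

classifies each bin: excellent (≥ 0.75), good (0.51–0.74), fair
(0.40–0.50), poor (< 0.40). Bins with ICC ≥ 0.51 form the **stable
metabolome**. Covariates are tested per bin by likelihood-ratio ANOVA with
Benjamini–Hochberg FDR control across all bins × covariates.

**Longitudinal Cholesky ACE model.** Stable bins are modeled across twin
pairs with lower-triangular path matrices $a, c, e$ loading additive
genetic (A), shared environmental (C) and unique environmental (E) latent
factors per visit; MZ pairs share A fully, DZ pairs with coefficient 0.5.
Squared standardized path coefficients (A1–A3, C1–C3, E1–E3) give the
proportion of each visit's variance due to factors arising at that visit or
persisting from earlier ones, with profile-likelihood confidence intervals
and a boundary-corrected (½χ²₀ + ½χ²₁) likelihood-ratio power simulation
for detecting A.

**Conservation index.** Each individual's baseline profile is correlated
with every participant's 2-month profile; the self-correlation's rank among
the $N$ correlations gives $1-\frac{\mathrm{rank}-1}{N-1}$ — 1.00 means the
individual is most similar to themselves after two months. Variants: stable
bins only, or the full profile weighted by covariate-adjusted longitudinal
bin correlations.

## Worked example

```python
from twinstable import twin_sem
from twinstable.pipeline_io import PipelineConfig, run_pipeline

power = twin_sem.simulate_power(44, 20, (0.77, 0.0, 0.23), reps=500, seed=1)
print(f"power to detect A=0.77 with 44 MZ + 20 DZ pairs: {power:.3f}")

manifest = run_pipeline(PipelineConfig(seed=1), "out/")
print(manifest["stages"]["classify"])
```

prints

```
power to detect A=0.77 with 44 MZ + 20 DZ pairs: 0.884
{'n_stable': 78, 'fraction_percent': 19.5}
```

The first line is the simulated power of the likelihood-ratio test dropping
the additive genetic component when the true standardized ACE proportions
are (0.77, 0, 0.23) at the design's sample size — comfortably above the
conventional 0.80. The second line: of 400 simulated 0.02-ppm bins, 78
(19.5%) exceed the ICC 0.51 cutoff and constitute the stable metabolome
under the default generator. The full default run (128 individuals × 3
visits × 400 bins, Cholesky ACE fits for the top 10 stable bins) takes a
few minutes and writes `cohort.csv`, `bins.csv`, `icc.csv`, `stable.csv`,
`sem.csv`, `conservation.csv` and a `manifest.json` whose config hash and
seed make reruns byte-identical.

The same stages are exposed on the command line:

```sh
twinstable run --seed 1 --out out/
twinstable simulate --n-mz 44 --n-dz 20 --out cohort.csv
twinstable decompose --bins bins.csv --cohort cohort.csv --out icc.csv
twinstable classify --icc icc.csv --out stable.csv
```

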