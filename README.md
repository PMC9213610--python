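# crossclock

Cross-species DNA methylation aging analysis: elastic-net epigenetic
clocks with lifespan-aware age transforms, epigenome-wide association
(EWAS) of age with Stouffer meta-analysis, annotation-level enrichment
statistics, and sample-integrity QC — plus a synthetic-data generator so
every stage can be validated at desk scale with known ground truth.

## Who this is for

Comparative epigenomics groups building methylation age clocks on
conserved-probe arrays (e.g., marsupial vs placental studies, where
maximum lifespans differ ~29-fold) and anyone who needs the statistical
core of such studies — penalized clock fitting, leave-one-sample-out
evaluation, correlation screening, meta-analysis, island / PRC2 /
chromatin-state enrichment — as tested, scriptable Python.

## The model

An epigenetic clock is a sparse linear predictor of (transformed) age from
beta values `x` (per-probe methylation fractions):

    ŷ = t⁻¹( β₀ + Σⱼ βⱼ xⱼ ),   β̂ = argmin ‖t(age) − β₀ − Xβ‖² / (2n)
                                         + λ ( α‖β‖₁ + (1−α)‖β‖₂²/2 )

with the elastic-net mixing fixed at α = 0.5 and λ chosen by internal
ten-fold cross-validation over a 100-value log grid (1-SE rule by
default).  Two transforms `t` align species with very different
lifespans: **relative age** `age / maxLifespan`, and a **log-linear**
transform, logarithmic before the species' age at sexual maturity and
linear after it.  Accuracy is reported as the Pearson correlation R
between leave-one-sample-out (LOOCV) predictions and actual age plus the
median absolute error.

The EWAS screens each probe by Pearson correlation with age (Student-t
p, n − 2 df) and carries the Fisher z `atanh(r)·√(n−3)` as the
effect-size scale; tissues combine by Stouffer's √n-weighted method;
enrichment uses Fisher exact / hypergeometric tests against the
array-conditioned background with BH and Bonferroni adjustments.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from crossclock import (AgeTransformSpec, fit_clock, loocv_evaluate,
                        simulate_dataset, SimulationConfig, SpeciesSpec)

cfg = SimulationConfig(
    species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 40)],  # lifespan, maturity, n/tissue
    tissues=["ear", "liver"], n_probes=2000, frac_age_related=0.1, seed=11,
)
matrix, sheet, annotation, truth = simulate_dataset(cfg)
transform = AgeTransformSpec.from_sample_sheet("identity", sheet)
predictions, ev = loocv_evaluate(matrix, sheet, transform, seed=1)
print(f"N={ev.n} LOOCV R={ev.pearson_r:.2f} mae={ev.median_abs_error:.2f} y")
```

prints

```
N=80 LOOCV R=1.00 mae=0.08 y
```

— 80 samples of a 4.2-year-lifespan species, out-of-sample age correlation
1.00 (0.995 unrounded) with a median error of 0.08 years, because 10% of
the 2000 simulated probes carry a real age signal.

The numbered scripts under `analysis/` walk the full study and write
their tables under `results/`; their headline printed lines:

```
02: tissue: purity=1.000 oob_error=0.000          # platemap QC on clean data
03: dual-species chronological clock: short-lived R=0.71 mae=0.50 y
03: dual-species relative clock:      short-lived R=0.76 mae=0.39 y
04: ear-liver aging z concordance r = 0.84; 188 top CpGs shared
05: placental_like: island z-shift t=+3.66 p=0.00025; PRC2 p=0.0018
05: opossum_like:   island z-shift t=-1.17 p=0.24;    PRC2 p=1
06: combined: 4.9% of the top later-aging CpGs are top development CpGs
```

The relative-age clock beating the chronological clock in the short-lived
species (03), and the island/PRC2 signals appearing only under the
placental-like regime (05), are the package's computational restatements
of the qualitative contrasts such cross-species studies report.

There is also a CLI:

```bash
crossclock simulate --config cfg.json --out data/
crossclock fit-clock --beta data/beta_matrix.tsv --samples data/sample_sheet.tsv \
    --constants data/species_constants.tsv --transform relative --out clock.json
crossclock loocv ... ; crossclock ewas ... ; crossclock qc ... ; crossclock run ...
```

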