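# epiclockbench

Benchmarking the robustness of DNA-methylation (DNAm) age estimation across
Infinium-style array platforms and preprocessing methods, on fully synthetic
data with known ground truth.

## The problem

Epigenetic clocks predict an individual's age from methylation fractions
(beta values) at a fixed panel of CpG sites: a pan-tissue style clock uses
353 CpGs and a log-linear age transform, a blood-specific (Hannum-style)
clock uses 71 CpGs on the raw age scale. Newer array platforms drop a
subset of those CpGs (19/353 and 6/71 respectively), and labs preprocess
raw fluorescence intensities in different ways before computing betas.
Both facts raise the same practical question: **how stable is the DNAm-age
estimate under platform changes, missing clock probes, and preprocessing
choices?**

This package makes that question testable without any cohort download. A
generative model produces two-platform intensity data with age-dependent
clock CpGs, out-of-band background, dye bias, platform-specific probe
dropout and technical replicates; the full analysis stack then runs on it:

* **Beta computation** — `beta = M / (M + U + 100)` per probe and sample.
* **Preprocessing** (`raw`, `gs`, `quantile`, `noob`) — GenomeStudio-style
  negative-control subtraction + channel scaling; design-type-stratified
  quantile normalization; normal-exponential background deconvolution on
  out-of-band intensities (noob), where each observed intensity
  `X = S + B`, `S ~ Exp(alpha)`, `B ~ N(mu_b, sigma_b)` is replaced by the
  posterior mean `E[S | X = x]`.
* **Clock engine** — gold-standard-mean imputation of missing clock CpGs,
  per-sample three-component beta-mixture quantile calibration to the
  gold-standard profile, the linear score
  `s = b0 + sum_j b_j * beta_j`, and the age transform
  `F(age) = log(age+1) - log(21)` below 20 years, `(age-20)/21` above.
* **Evaluation** — cross-platform/preprocessing correlations and median
  absolute errors, the reduced-clock (334 vs 353 CpG) experiment, the two
  epigenetic age-acceleration measures (`DNAm age - age` vs OLS residuals
  of DNAm age on age), Kendall rank concordance across methods, probe-wise
  cross-platform correlations vs beta range, technical-replicate
  concordance, and SNP-probe identity checks.

## Worked example

```python
from epiclockbench import RunConfig, SimulationConfig, run_full_study

result = run_full_study(RunConfig(sim=SimulationConfig(seed=1)))
print(result.report.cross_platform[["preprocessing", "clock", "r", "median_abs_diff"]])
```

On the default study (172 subjects aged 19–50, four preprocessing methods,
two clocks, 12 replicate pairs), the pan-tissue-style clock's
cross-platform agreement per preprocessing method is:

```
preprocessing          clock        r  median_abs_diff
          raw pan-tissue-353 0.990099         0.775747
           gs pan-tissue-353 0.985515         0.865497
     quantile pan-tissue-353 0.989411         0.859608
         noob pan-tissue-353 0.982210         0.921901
```

i.e. the same samples assayed on both simulated platforms receive DNAm
ages that correlate at r ≈ 0.98–0.99 with sub-year median absolute
differences, for every preprocessing route. Masking the 19
platform-absent clock CpGs and re-imputing them with gold-standard means
leaves the estimates nearly unchanged (`reduced_clock` r = 0.9993), and a
systematic preprocessing shift moves the acceleration *difference* measure
one-for-one while leaving the acceleration *residual* measure untouched —
the package's central reproducible contrast.

The same study can be run step by step from the shell:

```bash
epiclock-bench run-all --seed 1 --out results/study
```

or as the numbered analysis scripts (`analysis/01_simulate_cohort.py` …
`analysis/04_evaluate.py`), each of which prints what it found and writes
its tables under `results/`.

## Layout

```
src/epiclockbench/   core types & I/O, simulator, preprocessing,
                     clock engine, evaluation, pipeline, CLI
analysis/            numbered narrative drivers over the library
scripts/acceptance.py  end-to-end summary-statistics recomputation
tests/               unit, property and acceptance-level pytest suite
docs/methods.md      model, assumptions, parameter choices, limitations
```
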