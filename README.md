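# pepdiscover

Discovery and external validation of serum-peptidome diagnostic panels
from MALDI-TOF mass spectra.

Low-molecular-weight serum peptides (the ≤10 kDa "peptidome") carry
degradation signatures of disease — in particular, case/control profiling
studies of colorectal cancer have built logistic peptide panels from
bead-fractionated serum analysed by MALDI-TOF MS. `pepdiscover`
implements that whole workflow as a reusable, tested library and CLI for
anyone who wants to run, scrutinise or simulate such a study:

1. **Preprocessing** of raw profile spectra over *m/z* 1,000–10,000:
   5-point moving-average smoothing, baseline estimation from the lowest
   points between dominant local maxima, local-noise estimation
   (1.4826 × sliding-window MAD), total-ion-current (TIC) normalisation,
   and peak detection at a signal-to-noise cut-off S/N ≥ 5 with
   half-height centroiding.
2. **Cross-sample alignment** of per-sample peak lists into reference
   peaks by single-linkage gap clustering within a 0.1 % relative mass
   tolerance, yielding a samples × peaks intensity matrix (absent → 0),
   filtered to peaks present in ≥ 50 % of samples.
3. **Candidate screening**: per peak, a Shapiro–Wilk normality gate
   chooses Student's pooled *t* or the exact/tie-corrected Mann–Whitney
   U-test; each peak is summarised by its tendency (up/down in cases),
   group means, P-value and ROC AUC with a Hanley–McNeil 95 % CI
   (AUC ≡ U/n₁n₂). Peaks with P < 0.05 become candidates.
4. **Panel construction**: forward-stepwise multivariate binary logistic
   regression (likelihood-ratio entry P < 0.05, Wald removal P > 0.10,
   IRLS maximum likelihood with explicit separation detection), reported
   as β, OR = e^β, 95 % CI and Wald P per peak.
5. **External validation**: the frozen panel (coefficients, intercept,
   0.5 probability cut-off) applied unchanged to an independent cohort;
   performance reported as a confusion matrix with accuracy, sensitivity
   and specificity (Wald 95 % CIs) and the panel ROC AUC.

Because studies of this kind rarely deposit raw spectra, the package
ships a first-class **synthetic cohort generator** that emulates the
two-cohort design (100/100 discovery, 91/91 validation): ten
class-discriminative peptide peaks with fixed group means and calibrated
per-peak discriminative power, abundant and sparse nuisance peaks, an
exponentially decaying baseline, additive detector noise, per-spectrum
TIC variation and up to 0.1 % per-spectrum mass miscalibration — with
full ground truth for every planted peak.

## Worked example

```python
from pepdiscover import CohortConfig, generate_cohort, PipelineConfig
from pepdiscover.pipeline import discover_from_spectra
from pepdiscover.univariate import stats_to_frame
from pepdiscover.panel import odds_ratios

cohort = generate_cohort(CohortConfig(n_cases=100, n_controls=100, seed=1))
result = discover_from_spectra(cohort.spectra, cohort.labels, PipelineConfig())
print(result.funnel)
```

```
{'peaks_detected_total': 10751, 'reference_peaks': 454,
 'peaks_present_ge_min_frac': 22, 'significant_candidates': 11, 'panel_size': 6}
```

Of 454 aligned reference peaks, 22 were detected in at least half the
samples, 11 differed significantly between cases and controls, and the
stepwise search kept a 6-peak panel. The candidate table
(`stats_to_frame(result.candidates)`) shows the screen per peak —
intensities are on the TIC-normalised scale, and an AUC below 0.5 means
the peak is higher in controls:

```
    mz tendency  mean_case  mean_control  p_value         test   auc  auc_lo  auc_hi
1895.2       up   0.006091      0.000985 1.94e-13 mann_whitney 0.800   0.738   0.861
1943.9     down   0.002278      0.008403 9.10e-17 mann_whitney 0.160   0.104   0.216
2020.8       up   0.006055      0.001487 8.22e-11 mann_whitney 0.763   0.697   0.829
2080.6     down   0.000953      0.004030 3.11e-17 mann_whitney 0.155   0.100   0.209
2104.4     down   0.000386      0.001456 6.81e-14 mann_whitney 0.194   0.134   0.255
2656.7     down   0.002159      0.002510 7.27e-04 mann_whitney 0.362   0.285   0.438
3154.6     down   0.000500      0.006187 6.05e-25 mann_whitney 0.079   0.039   0.118
3238.2       up   0.003430      0.001178 9.64e-04 mann_whitney 0.634   0.557   0.711
3875.7     down   0.001547      0.002731 4.40e-10 mann_whitney 0.245   0.178   0.312
4042.5     down   0.001534      0.004508 1.81e-15 mann_whitney 0.174   0.117   0.232
6106.8     down   0.002571      0.003028 4.83e-02 mann_whitney 0.419   0.340   0.498
```

Ten of the eleven candidates are the generator's planted markers; 6106.8
is a chance false positive among the equal-mean nuisance peaks, exactly
what a P < 0.05 screen without multiplicity correction should produce.
The fitted panel (`odds_ratios(result.model)`; β per part-per-10⁴ of
total ion current):

```
    mz   beta    OR  ci_low  ci_high  p_value
1895.2  0.042 1.043   1.001    1.088   0.0453
1943.9 -0.032 0.968   0.945    0.992   0.0098
2080.6 -0.081 0.922   0.867    0.981   0.0104
3154.6 -0.201 0.818   0.741    0.902   0.0001
3875.7 -0.066 0.936   0.876    1.000   0.0507
6106.8 -0.065 0.937   0.890    0.986   0.0117
```

and its training-cohort performance (`result.performance`):

```
accuracy 97.0%  sensitivity 99.0% (97.0%-100.0%)
specificity 95.0% (90.7%-99.3%)  AUC 0.990 (0.976-1.000)
```

## Command line

```sh
pepdiscover simulate --config cohort.yaml --out data/ --seed 1
pepdiscover preprocess --manifest data/manifest.csv --out peaks/
pepdiscover discover   --manifest data/manifest.csv --out discovery/
pepdiscover validate   --model discovery/model.json \
                       --manifest validation/manifest.csv --out report/
```

`discover` writes the peak matrix, candidate table, frozen model JSON and
a JSON + Markdown report with the full peak-count funnel and provenance
block (config hash, seed, package version). Exit codes distinguish
configuration (2), I/O (3) and statistical (4) errors.

## Layout

- `pepdiscover.synthetic` — cohort generator and ground truth
- `pepdiscover.spectra` — spectrum/manifest text I/O (+ minimal mzML reader)
- `pepdiscover.preprocess` — smoothing, baseline, noise, TIC, peak detection
- `pepdiscover.matrix` — alignment, peak matrix, presence filter
- `pepdiscover.univariate` — normality-gated tests, ROC/AUC, χ², screening
- `pepdiscover.panel` — IRLS logistic fit, stepwise selection, validation
- `pepdiscover.pipeline` / `pepdiscover.cli` — orchestration and CLI

See `docs/methods.md` for the statistical model, parameter defaults and
the generator's assumptions and limitations.
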