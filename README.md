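# radioseg

Piecewise multivariate linear regression of cellular radiosensitivity on
genome-wide copy-number variation.

Radiosensitivity of cell strains is measured by the surviving fraction at
2 Gy (SF2), the fraction of cells that keep colony-forming ability after a
2 Gy dose (from the linear-quadratic survival model
`SF = exp(-αD - βD²)` at D = 2 Gy).  Copy-number variation (CNV) is
measured per microarray marker as the fold change
`FC = log2(sample/reference)`.  radioseg is for researchers asking which
CNV markers track radiosensitivity — and, specifically, whether *different*
markers matter in radio-sensitive (RS), normally-sensitive (NS) and
radio-resistant (RR) cells.

Instead of thresholding SF2 up front, the package:

1. screens markers by Pearson/Spearman correlation of FC with SF2
   (Benjamini–Hochberg corrected) and keeps a candidate pool at
   unadjusted Pearson p < 10⁻⁵;
2. fits multiple-input single-output (MISO) linear models
   `SF2 = a + Σ b_m·FC_m + ε` by greedy forward selection with a Bayes
   factor criterion (add while BF ≥ 10, at most ⌊n/10⌋ features);
3. sorts samples by SF2 and finds, by exact dynamic programming, the
   partition into K contiguous segments minimising the overall weighted
   mean relative error `MRE = Σ_k MRE_k·n_k/N = Σ_i RE_i/N`, where
   `RE_i = |pred−obs|/|obs|`, each segment carrying its own local model;
   K is chosen when the outer segment borders stabilise;
4. labels the lowest-SF2 segment RS and the highest RR, and compares the
   two groups marker-by-marker with the Mann–Whitney U test and the Glass
   rank-biserial correlation `r = 2(meanrank_A − meanrank_B)/n =
   2U_A/(n_A n_B) − 1`, categorised at |r| = 0.1/0.3/0.5/0.7.

A synthetic-cohort generator (`radioseg.simulate`) produces study-scale
cohorts with planted segment-wise FC→SF2 structure and full ground truth,
which is how the pipeline is validated end to end.  See
[docs/methods.md](docs/methods.md) for the model, assumptions and
numerical choices.

## Worked example

`examples/03_segmented_regression.py` generates a 129-sample cohort with
five planted SF2 regimes and 10,000 null markers, splits off a
range-spanning 13-sample validation set, screens markers, and runs the
segmentation scan:

```text
K  breakpoints                              weighted MRE
2  0.3277                                   0.0826
3  0.2779/0.3602                            0.0502
4  0.2275/0.2779/0.3602                     0.0228
5  0.2275/0.2779/0.3602/0.4088              0.0121
6  0.2275/0.2779/0.3602/0.3938/0.4116       0.0113
true planted boundaries: 0.2300/0.2835/0.3613/0.4100

2-segment comparison: DP split 0.0826 <= mean split 0.0915
```

Reading the output: the weighted MRE falls as K grows; the recovered
breakpoints (each the highest SF2 in its segment) sit at the planted
regime boundaries from K = 4 on and repeat verbatim across K — the
stabilisation signal used to pick K.  The optimised 2-segment split is
never worse than the conventional mean-SF2 split.  Each segment's local
model selects markers from its own planted support (printed by the full
script), so the RS and RR segments end up with their own distinctive
markers.  The other examples show screening calibration
(`01_simulate_and_screen.py`), the global model and why a single linear
model is not enough (`02_global_model.py`), and the RS-vs-RR effect-size
comparison under DP-based versus quartile-based grouping
(`04_group_comparison.py`).

A thin CLI mirrors the library for shell use:

```bash
radioseg simulate --seed 1 --out-prefix cohort
radioseg screen --fc cohort.fc.tsv --phenotype cohort.pheno.tsv --out records.tsv
radioseg segment --fc ... --phenotype ... --candidates cands.txt --out seg.json
```

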