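# turnoverkit

Precursor-pool-corrected protein turnover analysis from heavy-leucine
([5,5,5-²H₃]-leucine) metabolic labeling, for proteomics groups measuring
how interventions such as calorie restriction or rapamycin remodel tissue
proteome dynamics in vivo.

Animals switched to a heavy-leucine diet incorporate label into newly
synthesized protein. For each tryptic peptide, the observed isotopologue
envelope is a two-component mixture

> I ∝ (1 − f)·E_nat + f·E_lab(p),

where *f* is the fraction of molecules made after the diet switch, E_nat
the natural-abundance envelope of the peptide, and E_lab(*p*) the envelope
of protein synthesized from a precursor pool whose free leucine is a
fraction *p* heavy (each of the peptide's L leucines shifts the envelope by
+3 mass units with probability *p*). turnoverkit deconvolutes this mixture
per peptide, estimates *p* per sample from multi-leucine peptides (for
L = 1 only the product f·p is identifiable), pools *f* per protein with
AUC weights over uniquely mapping peptides, and fits first-order kinetics

> f(t) = 1 − e^(−kt),  HL = ln 2 / k

by through-origin regression of −ln(1 − f) on labeling time, giving each
protein's half-life HL in days. On top of the half-lives it provides the
group-comparison layer — pairwise half-life ratios with a proportion
z-test, per-protein Welch tests on rate constants with Benjamini–Hochberg
q-values, differential abundance from summed chromatographic AUC,
pathway/compartment summaries with one-way ANOVA, Spearman comparison of
comparisons — plus quantification of polysome-profile A254 traces
(baseline correction, valley segmentation into 40S/60S/80S/2/3/4/≥5,
per-peak AUC ratios, loading-trend tests) and a synthetic-study generator
with known ground truth for every stage. See `docs/methods.md` for the
full model and the design choices.

## Worked example

Simulate a two-cohort study — 60 proteins, control (YCL) and calorie
restriction (YCR) with a 1.6× half-life effect, 12 mice per cohort at
labeling days 3/7/12/17, 5 % intensity noise — then recover the effect:

```sh
$ turnoverkit simulate --seed 3 --n-proteins 60 --cohorts YCL,YCR \
      --hl-multiplier YCR=1.6 --out study
wrote 5376 rows to study/peptides.tsv

$ turnoverkit compare study/peptides.tsv --group-a YCR --group-b YCL \
      --out hl_ratios.tsv
median ratio 1.599; proportion above 1 = 1.000 (z = 7.68, p = 1.58e-14); wrote 59 proteins to hl_ratios.tsv
```

The median per-protein half-life ratio (1.599) recovers the injected 1.6×
effect; the z-test says the proportion of proteins with a longer half-life
under calorie restriction (here all 59 shared proteins) is incompatible
with a no-effect 50:50 split. The per-protein table carries each
half-life pair, the log₂ ratio, and Welch-test p/q-values:

```
protein  hl_a    hl_b    ratio   log2_ratio  p_value   q_value
P0000    2.379   1.473   1.615   0.692       1.9e-14   ...
P0001    4.922   3.100   1.588   0.667       6.1e-14   ...
```

The same stages are available as library calls (`simulate_study`,
`fit_all_turnover`, `compute_hl_ratios`, …) and as further subcommands:
`enrich` (per-sample pool enrichment), `turnover` (half-life table),
`polysome` (trace quantification), and `run` (end-to-end from a JSON
config, writing TSV outputs and a run manifest).

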