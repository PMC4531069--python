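# Methods

## The measurement model

In a heavy-leucine metabolic labeling experiment, animals are switched to a
diet in which leucine carries three deuteriums ([5,5,5-²H₃]-leucine).
Protein made after the switch incorporates heavy leucine from the free
precursor pool; protein made before does not. For a tryptic peptide with
`L` leucines observed by LC-MS, the isotopologue envelope — the vector of
relative intensities at nominal mass offsets 0, 1, 2, … — is a mixture:

    I ≈ A · [ (1 − f) · E_nat + f · E_lab(p) ]

where `f` is the fraction of molecules synthesized after the diet switch,
`A` the total chromatographic abundance (summed labeled plus unlabeled
area), `E_nat` the natural-abundance envelope fixed by the peptide's
elemental composition, and `E_lab(p)` the envelope of protein synthesized
from a pool in which a fraction `p` of free leucine is heavy. Each heavy
leucine shifts the envelope by +3 nominal offsets, so

    E_lab(p) = Σ_{h=0}^{L} C(L,h) p^h (1−p)^{L−h} · shift(E_nat, 3h).

The ~0.009 Da defect between 3×²H and 3×¹³C is far below unit resolution
and is ignored; envelopes are binned at unit spacing. Envelopes are
truncated at `3L + 6` offsets by default (> 99.99 % of mass for tryptic
peptides) and renormalized. Residue compositions and IUPAC isotope
abundances ship as TSV data files and can be replaced, which is also how
the tests substitute degenerate single-isotope tables.

## Deconvolution

With `p` known, the mixture is linear in `(A(1−f), Af)` and solved by
closed-form 2×2 nonnegative least squares (the analytic normal equations,
falling back to the better single-component fit when a coefficient would go
negative — those fits carry a `clipped` flag). With `p` free, the residual
is scanned on a deterministic 101-point grid over [0, 1], refined by golden
section to 1e−6, and the final choice among {refined point, best grid
point, p = 0} is made with the directly computed residual; ties resolve to
the smallest `p`, so an unlabeled sample reports `p = 0` rather than an
arbitrary point on the flat objective.

A peptide with one leucine cannot separate `f` from `p` — only the product
of per-site label probabilities is observable — so pool enrichment is
estimated from peptides with `L ≥ 2` only: per-peptide joint fits, sample
`p` = median, spread reported as the median absolute deviation. One pool
per sample (mouse liver at sacrifice) is assumed; per-peptide `f` is then
re-fit with the sample `p` held fixed. For large tables the per-sample
joint fits use at most 200 peptides (deterministic, ordered by sequence);
the median is insensitive to this and it bounds runtime. Fraction-new
values pushed outside [0, 1] by noise are clipped, flagged, and retained;
the kinetics layer can exclude flagged points via `drop_clipped`.

## Turnover kinetics

At steady state the fraction new follows `f(t) = 1 − exp(−k t)`, so
`y = −ln(1 − f)` is linear in time through the origin with slope `k`, and
the half-life is `HL = ln 2 / k` (the half-time of appearance of newly
synthesized protein). Peptide-level `f` is pooled per protein and mouse as
the AUC-weighted mean over unique peptides only; shared peptides are
discarded. Fits need at least 4 points (one mouse per design timepoint);
points with `f ≥ 1 − 1e−6` are excluded from the log transform and
flagged; `k ≤ 0` yields an infinite half-life with a flag rather than an
error.

The regression weights each point by `(1 − f)²`, the delta-method inverse
variance of the log transform under homoscedastic noise on `f` — this is
Gauss–Newton on the untransformed exponential. The weighting matters for
inference, not the point estimate: the transform amplifies noise most at
late timepoints, which also carry the most leverage in a through-origin
fit, and an unweighted slope SE is then anti-conservative (empirically
~2–3× too many null proteins at p < 0.05). `weighting="none"` and
`zero_intercept=False` are available for sensitivity analysis.

Steady state itself is verified, not assumed: per-peptide total AUC is
regressed on time and a one-sample test checks that the slope distribution
centers on zero.

## Group comparisons

* **Half-life ratios** — per shared protein, `HL_A/HL_B` with the summary
  median; the "z-test for proportions" tests H₀: Pr(ratio > 1) = ½ with
  `z = (p̂ − ½)/√(¼/n)` (ties at exactly 1 dropped, refused below n = 10);
  a one-sample t-test on log₂ ratios is exposed as a cross-check since the
  proportion reading of that phrase is one of two defensible ones.
* **Per-protein tests** — Welch-style t on the difference of rate
  constants using each group's slope SE, Welch–Satterthwaite degrees of
  freedom, Benjamini–Hochberg q-values.
* **Differential abundance** — per mouse, protein abundance is the summed
  total AUC of its unique peptides. Samples are scaled by median-of-ratios
  size factors (median across proteins of the ratio to the per-protein
  geometric-mean reference), then recentered so the median protein shows
  zero fold change; plain per-sample median scaling is biased when a
  minority of proteins genuinely change in one direction, which inflates
  the observed FDR several-fold in the injected-change simulations. Groups
  are compared by Welch t on log₂ abundance with BH q-values.
* **Pathway summaries** — membership is a user-supplied mapping table
  (protein_id, pathway_name, category); per pathway and group the half-life
  quartiles and 5th/95th percentiles are reported with a one-way ANOVA
  across groups. Extreme-turnover selections take the shortest- or
  longest-lived `⌊fraction·n⌋` proteins with identifier tie-breaks.
* **Correlations** — Spearman rank correlation (average ranks, two-sided
  t-approximation p) between per-protein log-ratio vectors of two
  comparisons; constant inputs are flagged degenerate rather than guessed.

## Polysome profiles

Traces are two-column (position, absorbance) CSVs, top of gradient first.
A linear baseline anchored at the flanking minima (by default the end
samples, which sit on pure baseline; a window is available for noisy ends)
is subtracted and the result clipped at zero. Peaks are local maxima above
a prominence threshold (default 2 % of the trace maximum); segment
boundaries are the valleys between consecutive maxima, labeled
40S/60S/80S/2/3/4 with everything beyond the expected count pooled into
the ≥5 segment extending to the gradient bottom. Areas are trapezoidal;
ratios are to the summed segment area, so they are invariant to detector
gain. The loading-trend test regresses percent-of-control (against the
control-cohort mean per segment) on the integer loading index; a
zero-residual fit reports p at machine tiny with a degenerate flag.

## Synthetic studies

The generator emulates the study design it is meant to exercise: six
cohorts (young/old × control/calorie-restricted/rapamycin), 12 mice per
cohort — three euthanized at each of labeling days 3, 7, 12, 17 — protein
half-lives log-normal with median 3 days and log-sd 0.8, peptide counts
2–5 per protein with leucine counts weighted toward 1–3, abundances
log-normal (median 1e6 AUC units), pool enrichment rising as
`p(t) = p_max(1 − e^{−rate·t})` with `p_max = 0.5`, `rate = 0.5`/day, and
independent multiplicative log-normal noise (default CV 5 %) per
isotopologue intensity. Group effects are multiplicative on half-life
and/or abundance per cohort. Everything derives from one seed and is
byte-reproducible.

What it does **not** emulate: missing peptides, charge states, retention
drift, correlated noise across isotopologues, label recycling beyond what
the pool-enrichment parameter absorbs, shared (non-unique) peptides by
default, or between-mouse biological variance in half-life within a
cohort. Passing tests therefore demonstrate correctness of the inference
given the stated forward model, not robustness to every artifact of real
LC-MS data.

Default problem sizes in the test-suite simulations (300 proteins, 2
cohorts for effect-recovery and null studies; 100 proteins for
steady-state checks) are chosen so a full run completes in minutes on a
laptop while leaving the binomial/KS checks well powered; the full 6-cohort,
950-protein design is available through `SimulationConfig`.

## Numerical notes

* The vectorized residual scan over the enrichment grid uses the expanded
  quadratic form, which loses ~8 digits to cancellation near perfect fits;
  final parameter choices therefore always re-evaluate candidates with the
  direct residual.
* `natural_envelope` uses truncated binary-exponentiation convolution; the
  test oracle is an independent exhaustive multinomial enumeration.
* Half-life conversion is exact (`HL·k ≡ ln 2`); infinities are used for
  non-positive rates rather than sentinels.
* All stochastic tests fix seeds; the acceptance script derives all seeds
  from its `--seed` argument.

## Known limitations

* Sample enrichment assumes one well-mixed precursor pool per sample;
  tissue compartmentalization would bias `f` multiplicatively.
* The per-protein difference test treats the two slope estimates as
  independent Gaussians; with only 12 mice the Welch approximation is
  adequate (verified by null simulation) but not exact.
* Valley segmentation under-divides heavily overlapping polysome peaks;
  the generator warns when adjacent centers sit closer than one width.
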