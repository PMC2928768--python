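# Methods

## Model

Thermal denaturation of duplex DNA disrupts two sequence-dependent
interactions: base stacking within each dinucleotide step and Watson–Crick
hydrogen bonding within each base pair. `dnamelt` quantifies both with
small integers chosen relative to one another — stacking by step class
(RY 5 > RR = YY 3 > YR 2, reflecting the experimentally strongest stacking
of purine→pyrimidine steps) and hydrogen bonding per base (4 for the
triple-bonded G·C pair, 1 for the double-bonded A·T pair). A step score is
the stacking value plus the H-bond values of its two bases, giving the
16-entry table with extremes TA = 4 and GC = 13. Because complementary
steps contain the same base pairs and the stacking classes of a step and
its reverse complement coincide, the table is invariant under reverse
complementation: scoring either strand gives the same result. This is
asserted by tests, not assumed.

The per-base strength parameter of a sequence of n bases is

    E = (sum of the n−1 overlapping step scores) / n .

Note the division by the number of *bases*, not steps; the canonical
worked example (128/15 = 8.53 for a 15-mer) fixes this convention.

Melting temperature is then a log-linear function of E and the three
extrinsic variables:

    Tm = a_E·E + a_len·ln(Len) + a_salt·ln(Conc) + a_DNA·ln(DNA) + b ,

with published coefficients a_E = 7.35 °C per strength unit,
a_len = 17.34, a_salt = 4.96, a_DNA = 0.89 and b = −25.42 °C. Natural
logarithms are used throughout — never log₁₀. The transcription of these
coefficients is guarded by two build-time checks: the worked example must
reproduce 65.04 ± 0.01 °C with E carried at two decimals, and regressing
the published genome-scale salt-series predictions on ln(Na⁺) and
ln(DNA) must recover a_salt and a_DNA (the latter within a loose band:
that series varies the strand concentration over only two values, so the
coefficient is weakly determined there).

A three-term variant without the strand-concentration term is supported
structurally (`variant="three_term_no_dna"`); no published values are
asserted for it, and users obtain its coefficients by refitting.

## Units and their caveat

Na⁺ concentration is molar. Strand concentration is used exactly as
reported — molar for oligonucleotides, g/ml for genomic hyperchromicity
experiments — with only a unit *tag* recorded and no conversion. This
reproduces published genome-scale predictions, but it means the intercept
silently absorbs a unit-dependent offset when the two conventions are
mixed in one dataset; `dnamelt` keeps the tag precisely so users can
avoid such mixtures when refitting.

## Rounding of E

Internally E is carried at full floating precision. The `round_e_2dp`
toggle (default off) rounds E to two decimals before the temperature
equation, matching the hand-calculation convention of the worked example
(65.04 °C exactly; full precision gives ≈65.07 °C). The toggle exists for
reproducibility of printed two-decimal chains and changes predictions by
at most a_E·0.005 ≈ 0.037 °C.

## Genome extension

Long sequences are scanned with a fixed-width melting unit (default
70 bp), translated 1 bp at a time. Each window is scored independently
with Len = 70 inside the equation — the window, not the genome, is the
melting entity. The genome Tm is the unweighted mean over windows;
multi-chromosome inputs average per-chromosome means without length
weighting (a `length_weighted` option exists, off by default). Choices
made where the procedure was genuinely open:

* **Ambiguous bases.** Windows containing any non-ACGT character are
  skipped whole and counted, never partially scored — the strength table
  defines only canonical steps. Skip counts appear in every summary.
* **Circularity.** Chromosomes are treated as linear; for a bacterial
  genome the ≤ w−1 missing origin-spanning windows are negligible
  (< 2×10⁻⁵ of windows for a 4.6-Mb genome).
* **Soft-masking.** Lowercase bases are uppercased and scored; masking is
  composition-irrelevant to this model.
* **Coordinates.** 0-based, half-open internally and in bedGraph output;
  the TSV track carries explicit `start0/end0` window coordinates and
  round-trips bit-exactly (floats written via `repr`).
* **No hidden genome conditions.** Na⁺ and strand concentration must be
  given explicitly in genome mode; experimental compilations vary them,
  so defaults would be arbitrary.

The window-size scan (40–100 bp by default) exposes the convergence that
motivates the 70-bp choice: successive differences of the genome Tm
shrink toward the 60–70 bp plateau. For a constant-composition sequence
the scan follows the closed form a_E·s·(w−1)/w + a_len·ln w + const (s
the constant step score), which the tests check exactly.

## Regression machinery

`TmRegression` holds a dataset of (sequence, conditions, experimental Tm)
records and exposes three operations in the model/results idiom:

* `fit(variant)` — ordinary least squares of Tm on
  [E, ln Len, ln Conc, (ln DNA)] plus intercept, via statsmodels; no
  weighting or regularization. The results object carries coefficient
  estimates, standard errors, confidence intervals, Pearson r between
  fitted and observed Tm, r², mean absolute error, the RMS residual
  (standard error of estimate) and a `summary()` table. Rank-deficient
  designs raise an error naming the collinear predictors rather than
  returning a silently unstable fit.
* `evaluate(coefficients)` — prediction and the same agreement statistics
  under fixed coefficients, filling `pred_tm`/`residual` on each record;
  also provides normal-probability-plot data (sorted residuals against
  normal plotting-position quantiles).
* `parameter_combination_correlations()` — r for all 15 non-empty subsets
  of {E, Len, Conc, DNA}. Multi-predictor subsets report the non-negative
  correlation of the OLS fit with the observations; single-predictor
  subsets report the *signed* simple correlation, preserving the
  direction of raw associations (strand concentration alone typically
  anticorrelates with Tm in oligonucleotide compilations because higher
  concentrations accompany shorter, weaker duplexes).

A degenerate single-record evaluation reports a defined mean absolute
error but NaN correlation, with a warning.

## Synthetic data

The generators in `dnamelt.simulate` emulate the design space of a
typical oligonucleotide melting compilation: 123 records, lengths
15–100 nt, GC 0.2–0.8, Na⁺ 0.01–1 M and strand concentration
10⁻⁷–10⁻⁴ M sampled log-uniformly, with "experimental" Tm generated from
the model under known coefficients plus Gaussian noise of 1.36 °C (the
scale of a realistic fit's mean error). Bases are i.i.d. by default; a
first-order Markov generator exists for dinucleotide-correlated stress
tests of the profiler. Synthetic data carry none of the real-world
structure of melting compilations — duplicated sequences measured across
salt series, heteroscedastic measurement error, correlation between
length and concentration conventions — so passing recovery tests
demonstrates the correctness of the scoring, the equation and the OLS
plumbing, not predictive accuracy on laboratory data. Accuracy claims
require evaluating `TmRegression.evaluate` on transcribed experimental
tables via `read_dataset`.

Tests run at deliberately modest problem sizes — 50–100 kb synthetic
chromosomes, 100-seed recovery ensembles of 200 records — chosen as the
smallest scales at which the checked properties are non-trivial.

## Known limitations

* The model is phenomenological: no ΔH/ΔS decomposition, no
  nearest-neighbor thermodynamics, no cooperative melting-curve
  simulation; the melting unit is a fixed-width averaging device, not a
  statistical-mechanical domain.
* Only canonical A/C/G/T is scorable; IUPAC ambiguity codes are rejected
  in oligonucleotide mode and skip whole windows in genome mode.
* Mixing molar and g/ml strand concentrations in one refit biases the
  intercept (see Units above).
* Very short sequences (< ~15 nt) and extreme conditions lie outside the
  design space the coefficients were fitted on; predictions there are
  extrapolations.
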