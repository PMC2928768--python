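# dnamelt

Phenomenological prediction of DNA melting temperatures from dinucleotide
strength parameters, with sliding-window melting profiles for genome-scale
sequences.

## The problem and the model

The melting temperature Tm — the temperature at which half of a duplex
population is denatured — is needed wherever hybridization is engineered:
primer and probe design, PCR protocols, interpretation of hyperchromicity
experiments, and genome-scale searches for thermodynamically weak regions
(promoters, replication origins, AT-rich introns).

`dnamelt` scores the two interactions disrupted during melting with small
integer parameters assigned per dinucleotide step (an ordered base pair read
5′→3′):

* **stacking**, by the purine(R)/pyrimidine(Y) class of the step —
  RY = 5, RR = YY = 3, YR = 2;
* **Watson–Crick hydrogen bonding**, per base — G/C = 4 (triple H-bond
  pair), A/T = 1 (double).

Their sum gives a step score between 4 (TA) and 13 (GC); each score equals
that of its reverse complement, so only 10 of the 16 values are distinct
identities and every result is strand-symmetric. Summing over the n−1
overlapping steps of a sequence and dividing by n bases gives the per-base
strength parameter *E*, which enters a log-linear equation fitted by
multiple regression against experimental melting data:

```
Tm = a_E·E + a_len·ln(Len) + a_salt·ln([Na+]) + a_DNA·ln(DNA) + b
   = 7.35·E + 17.34·ln(Len) + 4.96·ln([Na+]) + 0.89·ln(DNA) − 25.42
```

with Len the length in bases, [Na+] the sodium concentration (molar) and
DNA the total nucleotide strand concentration (molar for oligonucleotides;
g/ml by convention for genomic hyperchromicity experiments — the value is
used as reported, with a unit tag). All logarithms are natural.

For long sequences, Tm is computed over a sliding 70-bp "melting unit"
(step 1 bp, Len = 70 inside the equation) and averaged over windows — and,
for multi-chromosome inputs, over chromosomes — yielding both per-position
melting profiles and a genome-average Tm.

## Worked example

The 15-mer `GACGACAAGACCGCG` at 0.22 M Na⁺ and 2×10⁻⁶ M strand
concentration:

```python
>>> from dnamelt import *
>>> cumulative_strength("GACGACAAGACCGCG")     # 14 dinucleotide steps
128
>>> strength_per_base("GACGACAAGACCGCG", round_2dp=True)
8.53
>>> cond = MeltingConditions(na_molar=0.22, strand_conc=2e-6)
>>> round(predict_tm_for_sequence("GACGACAAGACCGCG", cond, round_e_2dp=True), 2)
65.04
```

128 is the summed strength of the 14 steps (GA=8, AC=10, CG=10, …), 8.53
the per-base parameter E = 128/15, and 65.04 °C the predicted melting
temperature (the reported experimental value for this oligomer is 64.4 °C).
`round_e_2dp=True` carries E at two decimals as in hand calculation;
full precision gives 65.07 °C.

The same from the shell:

```
$ dnamelt predict --seq GACGACAAGACCGCG --na 0.22 --dna 2e-6 --round-e
seq     65.04
```

Refitting the equation on data (here a synthetic dataset generated from the
model itself, 123 records with 1.36 °C Gaussian noise) returns a results
object in the usual model/results style:

```python
>>> recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=123, noise_sd=1.36, seed=42))
>>> print(TmRegression(recs).fit().summary())
Tm regression (OLS on E, ln Len, ln Conc, ln DNA)
  n = 123
  a_E      =     7.3221  (se 0.1031)
  a_len    =    17.6479  (se 0.2354)
  a_salt   =     4.9424  (se 0.0907)
  a_DNA    =     0.8039  (se 0.0592)
  intercept=   -27.7914  (se 1.4514)
  r = 0.9955   r^2 = 0.9910
  mean |error| = 0.9907 degC
  std error of estimate = 1.2552 degC
```

Genome profiles (bedGraph + TSV tracks and a JSON summary):

```
$ dnamelt profile --fasta genome.fa --na 0.016 --dna 2e-5 --dna-units g_per_ml \
      --window 70 --out profile_out
$ dnamelt scan --fasta genome.fa --na 0.016 --dna 2e-5 --sizes 40:100:10
```

On a 100-kb synthetic chromosome at 50.8% GC (E. coli-like) under
0.016 M Na⁺ and 2×10⁻⁵ g/ml, the scan converges toward the 60–70 bp
melting-unit plateau and `genome_tm` reports an overall Tm of 78.21 °C
over 99,931 windows.

Other subcommands: `fit`, `evaluate`, `table2` (predictor-subset
correlations), `table` (the 16-entry strength table as TSV), `simulate`
(synthetic datasets with known generating coefficients).

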