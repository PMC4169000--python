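# dgescreen

Replicate-calibrated digital gene expression (DGE) screening for tag-count
transcriptomics, modelled on morpholino-knockdown screens in cnidarian
embryos: compare mapped-read counts between an uninjected control and a set
of knockdown conditions, score each transcript with an MA-plot z-statistic
calibrated against technical-replicate noise, filter cross-condition
artifacts and contaminants, and classify the survivors by their joint
response to two knockdowns. The package also ships the downstream analyses
(class/expression-pattern concordance, exact enrichment tests, qPCR
fold-change comparison) and a six-frame ORF predictor for assembled
transcripts.

## The statistic

For a transcript with counts `C1`, `C2` in two libraries with totals `n1`,
`n2` (pseudocount 0.5 on both counts):

```
M = log2(C1) - log2(C2)          A = (log2(C1) + log2(C2)) / 2
```

Under the random sampling null, `C1 ~ Binomial(K, p0)` with `K = C1 + C2`
and `p0 = n1/(n1+n2)`, giving

```
E[M]   = log2(p0 / (1 - p0))
Var[M] = 1 / (ln(2)^2 * K * p0 * (1 - p0))        (delta method)
z      = (M - E[M]) / sd[M]
```

Because duplicate embryo samples scatter more than binomial sampling alone
predicts, the screening z is instead calibrated empirically: the local mean
and SD of M are estimated in sliding windows along A from a
technical-replicate pair, and `z = (M - mean(M|A)) / SD(M|A)`. Transcripts
are tiered at |z| >= 3.3 and |z| >= 5.0; transcripts elevated (z > 5) in
all three of wnt3/fz1/fz3 are flagged as injection artifacts, transcripts
depleted (z < -5) in both wnt3 and fz3 as contaminants, and the remaining
strict-tier transcripts fall into four DGE classes from the (wnt3, fz1)
z-pair — classes that predict the transcript's spatial expression type
(oral, ingressing/endodermal, aboral, delayed).

## Worked example

```python
>>> from dgescreen import SimConfig, simulate_experiment, screen_experiment
>>> from dgescreen import evaluate_recovery, load_table1_fixture, class_pattern_table
>>> tables, truth = simulate_experiment(SimConfig(seed=7))
>>> records, ma, model = screen_experiment(tables)
>>> report = evaluate_recovery(records, truth)
>>> print(report.summary())
label	precision	recall
class1	0.8496	0.9600
class2	1.0000	0.8198
class3	1.0000	1.0000
class4	1.0000	1.0000
artifact	1.0000	1.0000
contaminant	1.0000	0.5556
null	0.9992	1.0000
```

A 20,000-gene simulated experiment (mean depth 100 reads/gene, 16-fold
planted effects) is screened end to end: ~94% of planted class genes get
their true class back, every planted injection artifact is flagged, and no
null gene is mistaken for an artifact or contaminant. Contaminant recall is
lower because a 10-fold depletion of a below-median-abundance gene sits at
the counting-noise detection floor in a single-library comparison.

The concordance between DGE classes and in situ expression-pattern types on
the packaged table of characterised transcripts:

```python
>>> print(class_pattern_table(load_table1_fixture()))
            O  IE  A  D  D_A  total
dge_class
1          11   2  0  0    0     13
2           1  11  0  0    0     12
3           0   0  9  0    1     10
4           0   0  1  7    3     11
```

11 of 13 class-1 transcripts show the Oral pattern, 11 of 12 class-2 the
Ingressing/Endodermal pattern, 9 of 10 class-3 the Aboral pattern, and 7 +
3 of 11 class-4 the Delayed or mixed Delayed/Aboral patterns.

The same operations are exposed as a CLI (`dgescreen simulate | zscore |
screen | classify | concordance | enrich | qpcr-compare | orf | run`).

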