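# Methods

## The random-sampling model and its calibration

The screen treats a transcript's mapped-read count as a draw from a pool of
`n` sequenced tags. Under the null hypothesis of equal expression, the
transcript's combined count `K = C1 + C2` across two libraries is split
binomially with probability `p0 = n1/(n1+n2)`; expression difference is
summarised on the MA plane, `M = log2 C1 - log2 C2` against
`A = (log2 C1 + log2 C2)/2`. The delta method gives the null moments
`E[M] = log2(p0/(1-p0))` and `Var[M] = 1/(ln2^2 K p0 (1-p0))`; an exact
enumeration over all `K+1` binomial outcomes (`rsm_null_moments_exact`) is
provided as the validation oracle, and the two agree within 5% relative
error for `K >= 100` and `0.1 <= p0 <= 0.9` (worst case ~4.3% at K=100,
p0=0.1).

The model assumes log2 counts are approximately normal across the
transcriptome (checked by `qq_normality`, a QQ correlation against standard
normal quantiles at plotting positions `(i-0.5)/n`). A two-sided p-value
`2(1-Phi(|z|))` is reported alongside z; cutoffs are expressed on the z
scale throughout because the mapping between the historical "1%" label and
the 3.3 threshold is not a plain normal tail and cannot be recovered — the
package treats 3.3/5.0 as what they operationally are, z-valued parameters.

### Replicate calibration (MATR/CTR)

Real duplicate embryo samples scatter more than binomial sampling predicts.
`fit_noise_model` estimates that scatter from a replicate pair: genes with
combined count >= 10 are ordered by A and scanned in fixed-count windows
(default 500 genes, 50% overlap); each window contributes a grid point at
its median A with a 10%-trimmed mean of M and the (ddof=1) SD of M, floored
at 1e-3. Between grid points the model interpolates linearly; outside the
observed range it clamps. The calibrated statistic is
`z = (M - mean(M|A)) / SD(M|A)`. With several replicate pairs, per-pair
curves are averaged pointwise on the union grid.

Numerical choices and degenerate inputs: identical replicates give all-zero
M and the SD floor everywhere; windows with tied median A keep the first
occurrence; genes with `K < 10` are excluded from fitting (their M is
dominated by discreteness) but still receive z-scores, flagged `low_count`.
Calibration statistics quoted anywhere in this package are computed over
non-low-count genes, matching how the screen uses them.

When case and control pool different numbers of libraries their totals
differ, and the raw M of a null gene is centred at `log2(n1/n2)`, not 0.
Because the noise model is fitted from a same-size pair, the pipeline
centres M at that null expectation before calibration; the reported M stays
the raw log2 ratio, so `sign(z) = sign(M - E[M])`.

A pseudocount of 0.5 is added to both counts before any logarithm (zero
counts stay finite; the value is configurable). Library-size differences
enter through `p0`, never by rescaling counts: that is the random-sampling
model's natural parameterisation and keeps counts integral. z divides by
the standard deviation of M, not the variance — the quantity must be
dimensionless for normal-tail thresholds to mean anything.

## Screening rules

Tiers at the wnt3 z: loose (|z| >= 3.3) and strict (|z| >= 5.0), boundary
values to the more significant tier. Filters, evaluated before class
assignment (flagged transcripts are never classified):

* injection artifact: z > +5 in wnt3, fz1 and fz3 — conditions with
  opposite phenotypes responding identically cannot be pathway-specific;
* contaminant: z < -5 in both wnt3 and fz3 (fz1 not required) — the
  signature of material present preferentially in unmanipulated eggs.

Contaminant wins over artifact should both ever match (impossible at the
default cutoffs, which need opposite wnt3 signs; asserted in the code).
Classes from the (wnt3, fz1) pair at the strict cutoff: wnt3-depleted
transcripts split into class 1 (fz1 > -5) and class 2 (fz1 <= -5);
wnt3-elevated into class 3 (fz1 < +5) and class 4 (fz1 >= +5). Exact
boundary values go to the strongly affected side (2/4); the historical
description uses open/closed interval language inconsistently, so the
choice is explicit and configurable. Classes use only wnt3 and fz1; fz3
and stbm are carried for filtering and reporting.

## The synthetic experiment generator

The generator emulates the screen's design: an uninjected control in
duplicate, wnt3 knockdown in duplicate, single fz1, fz3 and stbm libraries.
Baselines are log2-normal; each library's expected counts are the
label-adjusted relative abundances scaled to the library total; realised
counts are gamma-Poisson (negative binomial), variance `m + phi*m^2`, the
minimal standard model of replicate overdispersion (`phi = 0` degenerates
to Poisson). One master seed; per-library substreams spawned
deterministically, so identical configurations are bit-identical.

Planted labels: classes 1-4 as in the screening rules (class 2/4 effects
mirrored in stbm with independent noise, emulating the PCP interpretation
of the fz1/stbm similarity), artifacts elevated in every morpholino
condition, contaminants at 10% residual abundance in every morpholino
library (configurable factor), null genes unchanged.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes | 20,000 | transcriptome-scale reference set |
| mean depth | 100 reads/gene/library | deep tag sequencing; sets the detection floor |
| baseline_log2_mean | 7 | location only; normalised away per library |
| baseline_log2_sd | 1.0 | see below |
| dispersion | 0.05 | ~22% CV between duplicate embryo pools |
| effect_log2fc | 4 | strong knockdown responses (16-fold) |
| class fractions | 0.005 each | a few hundred responsive transcripts |
| artifact / contaminant | 0.001 each | rare, conspicuous nuisance transcripts |

The baseline spread deserves a note: real transcriptomes span a wider
dynamic range (log2-count SD nearer 2-3). At SD 2 and mean depth 100,
however, roughly a third of genes fall below the count level at which even
an oracle statistic could certify a 16-fold change, so planted-truth
recovery would measure the depth floor rather than the screen. The
generator therefore uses SD 1.0 — wide enough to exercise the A-dependence
of the noise model, narrow enough that planted effects are detectable in
principle. Consequences for external validity: passing recovery tests say
the screen finds what is statistically findable; they do not say a real
experiment at this depth detects all true responders across the full
abundance range. The same floor is visible inside the simulation:
contaminants carry only a 10-fold depletion and must clear z < -5 in a
single fz3 library, so below-median-abundance contaminants are genuinely
undetectable and contaminant recall plateaus well short of 1 at this depth
(the acceptance report prints the measured value).

What the generator does not emulate: sequence content and mappability,
GC/length biases, correlated biological variation between conditions,
partial knockdowns, and compositional effects beyond simple re-scaling.

## Downstream analyses

Concordance tallies count characterised transcripts per (class, pattern
group); the packaged table of 46 characterised transcripts (25 depleted, 21
elevated, loaded with a drift guard) uses patterns O, O_endo, IE, A, D,
D_A, with O_endo grouped into O and D_A kept distinct by default. ORF
completeness is not printed in the source table; the fixture marks all 46
complete, which is what their detailed characterisation implies. Real
per-class restricted-gene proportions for the full 126-transcript set are
not reconstructible from printed totals; the enrichment operation is
validated on constructed fixtures only.

`fisher_exact_2x2` conditions on both margins and sums hypergeometric
probabilities `<=` the observed table's ("sum of small p" two-sided
convention, the common default for 2x2 exact tests). The implementation
enumerates on exact integer weights `C(r1,k) C(r2,c1-k)` and converts a
single exact rational to float at the end, so ties are resolved exactly and
agreement with independent enumeration is at machine precision. The odds
ratio is the sample `ad/bc` (infinite when `bc = 0`, NaN for 0/0).

qPCR expression is `N = 2^-Ct`; fold changes are reference-normalised on
both platforms — `2^-ddCt` for cycle thresholds, the analogous
`(gene/ref)_exp / (gene/ref)_ctl` for mapped-read counts — so the two land
on one ratio scale.

## ORF prediction

Six reading frames per transcript; each frame's codons split at stops; each
inter-stop segment yields the maximal ORF of each admissible kind: the
complete first-ATG-to-stop ORF, a 5'-open ORF from the frame start when no
stop precedes (covering coding regions truncated by assembly; a stop-free
frame yields one doubly-open ORF), and a 3'-open first-ATG-to-end ORF.
Codons containing N translate to X and never count as start or stop.
Coordinates are 0-based half-open on the forward strand regardless of ORF
strand. A degenerate 5'-open segment consisting of a bare stop codon is
reported (length 3, empty peptide); the minimum-length filter removes it in
any practical configuration (the CLI default is 50 aa). "Best" means
longest, ties broken complete > partial, forward > reverse strand, lower
frame, smaller start — the ordering is explicit because the original
procedure's tie-breaks are unpublished, and it is deterministic by
construction. An optional trim step removes the 5' UTR upstream of the best
complete ORF's ATG.

## Problem sizes used in tests

Structural tests run on 2,000-3,000-gene simulations; calibration and
recovery checks on the full 20,000-gene defaults; the exact-test oracle is
exhaustive over all 2x2 tables with total <= 60 (<= 40 in the acceptance
script); ORF oracle equivalence uses 200 random sequences up to 2 kb. These
sizes make every Monte-Carlo assertion stable at fixed seeds.

## Known limitations

* The replicate noise model smooths with fixed-count windows; in very
  sparse A regions the grid is coarse and interpolation linear.
* The theoretical fallback z (no replicate pair) understates real
  variability by construction; the pipeline warns when it is used.
* Calibration guarantees are distributional (mean/SD/tail of z under the
  null), not per-gene error control; no multiple-testing machinery is
  provided because the screen thresholds raw z-scores.
* Cross-condition correlation checks (e.g. fz1 vs stbm) are validated on
  synthetic data only; real validation data are not packaged.
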