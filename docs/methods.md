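# Methods

## Scope and model

`mzt-m6a` analyses gene-level m6A immunoprecipitation data across the
mouse maternal-to-zygotic transition (MZT): paired antibody-IP and input
sequencing libraries at three stages — MII oocyte, late 1-cell (L1C) and
late 2-cell (L2C) embryo — each in triplicate, together with knockdown
RNA-seq, ribosome-profiling detection, proteomics detection and qPCR
validation data. All analyses start from gene-level count matrices;
read processing and quantification upstream of counts are out of scope,
as are positional (peak-level) m6A calls: the IP protocol modelled here
measures enrichment per transcript, not per site.

### Count model

Counts are negative binomial, `Var = mu + alpha * mu^2`. Per sample a
median-of-ratios size factor equalizes depth (reference genes are those
nonzero in every sample; with no such gene the package falls back to
total-count ratios and warns). Per-gene dispersions are method-of-moments
estimates computed within each design group on normalized counts,
averaged across groups, then shrunk 50% (on the log scale) toward a
robust Theil–Sen trend of log dispersion against log mean and floored at
`1e-8`. This is a deliberately simple, fully reproducible stand-in for
heavier empirical-Bayes machinery; both the shrinkage weight and the
floor are arguments.

### IP-vs-input test and calibration

Per stage, a two-group NB log-linear model with log size-factor offsets
is fit by per-group Newton iteration on the exact score equations (the
group means decouple, so the fit is vectorized across all genes). The
coefficient is the IP/input log2 fold-change; its standard error comes
from the Fisher information at the MLE.

The Wald statistic is referred to a **t distribution with
`df = (N - 2) / (1 - w)`** where `w = 0.5` is the dispersion-shrinkage
weight — `df = 8` for 3 + 3 samples. Rationale: with plug-in dispersions
estimated from 4 residual degrees of freedom the usual normal reference
is markedly anticonservative (measured type-I ~0.09–0.10 at nominal
0.05); treating the trend component of the shrunken dispersion as
noise-free doubles the effective information, and the resulting t
reference lands the empirical type-I error at ~0.04–0.05 across seeds.
When the caller supplies known dispersions the normal reference is used.
Genes with zero counts across a stage are untestable: P is NA and the
fold-change 0.

An all-zero group's mean is floored at half a read per summed size
factor so fold-changes stay finite; the shrunken estimate (below) then
pulls these noisy values toward zero.

### Relative m6A level

The per-stage "relative m6A level" is the normal-prior posterior mean
`lfc * prior_sd^2 / (prior_sd^2 + se^2)` with `prior_sd = 1` log2 unit by
default — a contraction of the raw fold-change that vanishes as the
standard error grows. Genes with NA tests take the mean per-replicate
fold-change unshrunk.

### Calling rule

Replicate pairs are matched by replicate number;
`lfc_r = log2((ip_r/sf + c) / (in_r/sf + c))` with pseudocount `c = 0.5`.
A replicate calls a gene when its raw input count strictly exceeds 1 and
either the stage P value is < 0.05 with `lfc_r > 0`, or the stage P is NA
with `lfc_r > 2`. A stage call needs at least 2 of 3 replicate calls; a
gene called in at least one stage enters the m6A-positive universe.
The input-count filter is applied to the raw count of the replicate being
scored (threshold and interpretation configurable).

## Dynamics, ZGA, integration

The ordered (MII, L1C, L2C) call pattern maps deterministically onto five
categories — maternal loss (100), inherited (111), de-novo gain (001 or
011), transient (010/101/110), untagged (000) — and the raw 8-pattern
tabulation is always emitted so users can regroup (e.g. count L1C gains
separately). Sankey edges count kept/lost/gained calls at each stage
boundary.

ZGA calls use stage-mean TPM with a strict `> 5` fold-change bound (L1C
vs MII for the minor wave, L2C vs L1C for the major wave) and an additive
pseudocount of 0.1 TPM; the pseudocount is internally rescaled with the
column totals so calls are invariant to uniform rescaling of the matrix.
mRNA direction for the coupling sets defaults to the sign of change
(threshold 1), since no explicit bound is imposed on "increase/decrease".

Ribo/protein matrices reduce to detection sets by the within-stage rule:
value strictly above threshold (default 0) in at least 2 replicates of at
least one stage; NaN encodes missing proteomic measurements. Protein
intensities are upper-quartile normalized, anchored at the geometric mean
of the per-sample 75th percentiles of positive values. The
translation-active ratio of a set is its detected fraction; its
significance comes from a resampling null (uniform size-matched subsets
of the universe, default 1000 draws) with
`p = (1 + #{null >= obs}) / (1 + B)`, never exactly zero. Knockdown DEGs
reuse the NB Wald machinery with group design: significant at P < 0.05
and |log2FC| > 1. Over-representation uses Fisher's exact test (the exact
test replaces the chi-squared for all 2x2 uses — deliberately, since it
is valid at any count); P values are BH-adjusted. Fisher and BH are
delegated to scipy/statsmodels and cross-checked in the test suite
against brute-force hypergeometric enumeration and the hand-applied
step-up formula.

## qPCR

ddCt relative quantities assume perfect doubling (efficiency 2,
configurable) and average replicate Cts on the cycle scale before
exponentiation. RIP recovery is
`%input = 100 * 2^[(Ct_input - log2(1/f)) - Ct_IP]` for an input aliquot
fraction `f` (3.32 cycles for the conventional 10% aliquot); spike-in
selectivity is the percent-input ratio of a methylated control (GFP)
over an unmodified one (mCherry). An exactly zero negative recovery
reports +inf with a warning.

## Synthetic data

The generator encodes the study conditions: 5000 genes, 3 stages x 3
replicates x {IP, input}, 1e6 reads per sample, NB dispersion 0.05, plus
Ctrl/KD RNA-seq (3 + 3) at L2C. Category proportions (5.6% maternal
loss, 3.5% inherited, 7.2% de-novo gain, 3.2% transient, 80.5% untagged)
are the class frequencies observed in real MZT m6A profiling of a ~17k
gene universe. Tagged stages carry log2 enrichment ~ Normal(3, 0.5)
floored at 0.5 — the true effect-size distribution of gene-level IP
enrichment is unknown, so this is a documented placeholder. Base
expression is lognormal (sigma 1.2 nats); about half of the
maternal-loss genes decay 4-fold after fertilization and about half of
the de-novo genes ride a 10-fold ZGA burst, with a further 22% of the
untagged pool bursting without m6A, mirroring the observed mRNA-coupling
fractions ("nearly half") and the non-m6A ZGA background. Translation is
a latent per-gene Bernoulli with propensity 0.52 baseline and 0.92 for
inherited genes (the observed 51.8% vs 91.8% gap); detection per
replicate is then Bernoulli at 0.95 for translated genes and 0.02
otherwise. Ct values follow `intercept - log2(abundance) + N(0, 0.2)`
with a 10% input aliquot, 0.5% baseline IP recovery and a 20-fold
spike-in enrichment.

One global seed expands into four independent substreams (truth, counts,
detection, Ct), so regenerating one block never reshuffles another; all
outputs are bit-reproducible for a fixed config.

What the generator does **not** emulate: length biases of library
preparation, GC effects, sample-quality outliers, batch structure,
isoform-level variation, correlated dispersion across stages, or the
detection-intensity relationship of real mass spectrometry (dropout here
is independent of intensity). Passing recovery tests therefore shows the
decision rules and statistics behave as specified under a faithful NB
world, not that the pipeline is robust to every artifact of real data.

## Problem sizes and determinism

Desk-scale defaults keep everything within minutes on one CPU: 5000
genes for recovery runs, 2000 for calibration runs, 999–2000 resampling
draws, 200 repeats for the uniformity check. All stochastic tests are
seeded; the acceptance script derives every substream from its single
`--seed` argument.

## Known limitations

* The NB test has no outlier handling or independent filtering; NA
  P values arise only from all-zero stages.
* The moderated-df t reference is a calibration heuristic, not an exact
  small-sample distribution; it is validated empirically in the suite.
* The resampling empirical P is discrete (granularity `1/(B+1)`) and
  slightly conservative under heavy ties; with universes of ~10^4 genes
  the effect is negligible.
* Upper-quartile anchoring uses one common scalar across all samples;
  per-batch anchoring is not implemented.
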