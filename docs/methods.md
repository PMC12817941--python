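# Methods

## Pull-down enrichment scoring

Each protein carries three sense-probe and three antisense-probe peptide
spectrum counts.  Scoring averages each arm and forms

    FC = mean(sense) / max(mean(antisense), floor),     floor = 1 (PSM counts)

The pseudo-count floor keeps a single stray antisense spectrum (mean 1/3)
from tripling the ratio; it is exposed as `denominator_floor` and can be
set to 0 for the raw ratio.  Because the floor is a genuine analysis
choice, every call also records the unfloored ratio, and rows where the
two disagree at table precision carry an `inconsistent_with_floor` flag —
on the bundled nuclear table this flags ELAVL1 (sense 6,3,3; antisense
0,0,2), whose published value matches the raw ratio while the other
low-antisense rows match the floored one.  The two readings are reported
side by side rather than silently reconciled.

Classification order: *unique* (all sense replicates positive, all
antisense zero) → *even* (FC exactly 1 after flooring) / *antisense-
enriched* (FC < 1) → *below threshold* (FC < 2) → *inconsistent* →
*enriched*.  "Inconsistent replicates" is operationalized as a sense-arm
coefficient of variation (sample SD / mean) above 0.6, or a zero count
among otherwise positive sense replicates; both knobs are parameters.  The
0.6 default is deliberately permissive: every row of the two bundled
tables has CV ≤ 0.45, so the published candidate lists are retained while
grossly discordant triples (e.g. 40, 2, 2) are dropped.  Ratios are kept
at full precision internally and rounded half-up to one decimal only when
rendering tables.  A literature-based filter for interferon/antiviral
relevance is inherently manual; an optional user-supplied allow-list can
stand in for it, and nothing is filtered by default.

## Count preprocessing

**Filter.**  A gene is kept when it has ≥ 30 reads in ≥ 3 samples of
either the perturbation group (all perturbed-line samples, any dose) or
the control group, evaluated within each experiment; with both
experiments loaded, passing in either experiment suffices (`'all'`
available).  The group split follows cell line, not treatment, because
the design's biological grouping is the line.

**TMM.**  The trimmed mean of M-values with the method's standard
defaults: reference sample = upper-quartile count rate closest to the
mean upper quartile; M/A computed over genes positive in both sample and
reference; 30% two-sided trim on M and 5% on A (rank-based, average
ties); factor = inverse-variance weighted mean of surviving M-values
using the delta-method binomial variance; factors rescaled to geometric
mean 1.  The implementation was verified during development against an
independent literal re-implementation (tests/oracles.py) and reproduces
reference factors from the method's canonical implementation to 10
decimals on small instances.  Note the precision weights make factors
only *approximately* invariant to rescaling one sample's counts (~0.1%);
exact invariance would require unweighted trimming.

**log2 CPM.**  `log2((count + p_s) / (L_s + 2 p_s) * 1e6)` with effective
library size `L_s = library size × TMM factor` and a per-sample prior
`p_s = prior_count × L_s / mean(L)`, so zeros map to a consistent CPM
floor.  `prior_count` defaults to 3 pseudo-reads, the convention of the
trend-moderated workflow this feeds; it is configurable because it
materially affects low-count genes.

## The moderated linear model

Per gene, ordinary least squares on a cell-means design — one indicator
column per (cell line, dose) cell, so `d_g = n − #cells` residual df are
shared across genes and every contrast is an explicit vector over cell
means (this makes the contrast-of-contrasts literal and auditable, at the
price of refusing rank-deficient designs rather than reparameterizing).

Variance moderation follows the standard empirical-Bayes recipe for a
scaled-chi-square likelihood with an inverse-chi-square prior whose scale
follows a mean-expression trend:

* bias-corrected log variances `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`
  (unbiased for `log σ²_g`);
* trend: lowess of `e_g` on mean log2 CPM, span 0.5 (configurable);
  genes with `s²_g = 0` are excluded from the fit and receive the
  interpolated trend value;
* prior df by moment matching: `trigamma(d0/2) = Var(e − trend) −
  trigamma(d_g/2)`, solved by Newton iteration on the trigamma function;
  non-positive excess dispersion gives `d0 = ∞` (full shrinkage to the
  trend);
* posterior `s̃²_g = (d0 s²0(g) + d_g s²_g)/(d0 + d_g)`, moderated
  t on `d0 + d_g` df.

With fewer than 10 genes the moment estimates are meaningless, so
moderation is refused with a warning and ordinary t-statistics are used
(`d0 = 0`).  Note the exact-flat-variance limit: when every `s²_g` is
equal the estimator returns the bias-corrected constant
`s² · exp(log(d/2) − ψ(d/2))` (≈ 1.04 s² at d = 24), not `s²` itself —
this is the correct moment inversion, and the tests pin the constant.

Both raw and Benjamini–Hochberg adjusted p-values are always computed;
the discovery threshold in this workflow is the raw p < 0.05 (the adjusted
criterion is typically satisfied only by the perturbed lncRNA itself in
studies of this effect size), and keeping both makes that explicit.

## IFN-responsive filtering and the core set

Responsiveness is the control line's response log2FC > 1.25, strict and
signed (the filter targets interferon-*stimulated*, i.e. up-regulated,
genes; an unsigned option exists).  A KD (OE) hit requires the effect
contrast's raw p < 0.05 for any KD line (the single OE line) at a dose
where the gene is responsive in that experiment — the most conservative
reading of "in at least one of the two doses"; an `'all'`-lines rule is
available.  A positive-control perturbation (e.g. STAT1 knockdown, which
attenuates the whole response pathway) is modelled and contrasted but
never contributes to hit calling.  Responsive genes partition into
KD-only / OE-only / both / neither; the heatmap matrix juxtaposes
per-line per-dose response log2FCs with the effect log2FCs, copied
verbatim from the contrast tables.

## Synthetic data

`simulate_counts` emulates the two-experiment factorial design: a KD
experiment (control gRNA line, two lncRNA-KD lines, one STAT1-KD line)
and an OE experiment (control, one OE line), 3 doses × 3 replicates per
line.  Counts are negative binomial, `var = μ + φμ²`, with a single
shared dispersion φ = 0.05 (typical bulk biological CV ≈ 22%; a single φ
keeps the moment checks closed-form — robustness to a dispersion *trend*
is exactly what the moderation step supplies, so the generator does not
duplicate it).  Means are `μ = libsize × 2^(b_g + response)` with
panel-wide baselines `b_g ~ Normal(7, 2)` log2 counts (a 2,000-gene
bulk-depth panel, median ≈ 128 reads) and relative library sizes
log-uniform on [0.5, 2].

Planted structure: 100 ISGs respond to dose with log2FC drawn from
[1.5, 6] (two uniform draws, sorted, so high ≥ low); 15 core genes have
that response shifted −1 log2 in both KD lines and +1 in the OE line;
15 KD-only and 5 OE-only genes are shifted in one experiment; the STAT1
line multiplies every ISG response by 0.5.  ISG baselines are drawn from
Normal(8, 1): the responsive genes such an analysis retains must clear
both the 30-read filter and the 1.25-log2FC response filter, so a planted
ISG at the detection floor — where the CPM prior compresses fold changes
below detectability for *any* method — would test nothing but shot noise.
Truth (flags and every true response log2FC) is returned with the data
and linked by a checksum.

`simulate_pulldown` plants Poisson PSM tables: background (both arms at
`base_mean` = 20), enriched (sense mean × 8) and unique proteins
(antisense identically 0; sense counts zero-truncated Poisson so the
unique-binding definition is satisfiable by construction).

What the generator does **not** model: batch effects beyond library
size, gene–gene correlation, isoforms, dose–response saturation,
count-level outliers, or variance trends.  Passing recovery tests on
these simulations therefore demonstrates the *procedures* are correct
and calibrated under the stated model, not that real perturbation data
will yield the same rates.

## Problem sizes, power, and known limitations

Tests and the acceptance script run the RNA-seq pipeline at 2,000 genes —
large enough for stable trend/moment estimation (the moderation recovery
check uses 5,000 simulated variances) while keeping the full suite in tens
of seconds.  Null calibration of the contrast-of-contrasts is checked as
the pooled fraction of raw p < 0.05 across all effect contrasts (binomial
noise at 2,000 genes is ~0.5%, so [0.03, 0.07] is a meaningful band).

At the default conditions (φ = 0.05, triplicates, ±1 log2 modulation) a
single effect contrast has ≈ 70% power per dose, so the OE experiment —
one perturbed line — detects a planted core gene with probability ≈ 0.85
once the two (correlated) doses are combined, and the KD experiment with
two lines ≈ 0.97.  Expected core-set sensitivity is therefore ≈ 0.85 and
seed-to-seed variation around it is real; recovery tests fix their seeds.
The false-discovery proportion of the "both" set is dominated by
single-experiment genes picking up a chance hit in the other experiment
(≈ 0.1–0.19 per gene), giving FDP ≈ 0.15–0.3 at the default composition.

Other limitations: the cell-means model has no observation weights or
random effects; TMM assumes a majority of non-differential genes (the
simulated high-dose libraries are ~60% ISG reads, near the method's
comfort zone — factors stay within ~0.07 log2 of a median-ratio oracle);
the ORA universe is the filtered gene set, so results are conditional on
the expression filter; pathway activation scoring (directional z-scores)
is proprietary to commercial knowledge bases and out of scope.
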