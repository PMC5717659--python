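# Methods

`vocalappraisal` implements a Bayesian analysis pipeline for cross-cultural
appraisal ratings of vocal emotion expressions: listeners from two cultures
rate vocal stimuli from two speaker cultures on six appraisal dimensions
(novelty, pleasantness, goal conduciveness, urgency, power, norm
compatibility) using a 1–5 scale, and the analysis asks (i) whether the
mean ratings follow theory-based directional predictions, (ii) whether the
two listener cultures differ, (iii) how reliable the raters are, and (iv)
which acoustic cues track the ratings.

## Rating model and preprocessing

Raw ratings are ordinal 1–5 judgements.  To remove idiosyncratic response
bias and scale use, every participant's ratings are z-transformed per
appraisal dimension across *all* stimuli that participant rated (both
speaker cultures pooled), using the n−1 sample standard deviation.  A
participant–dimension group with zero variance carries no ordering
information; its z-values are set to 0 with a warning rather than dropping
the participant, preserving cell sample sizes.  Participants who did not
rate at least one stimulus from every (emotion × speaker culture) cell are
excluded before standardization, mirroring the usual exclusion rule for
incomplete listening designs.

The z ratings are averaged per participant within each (dimension, emotion,
speaker culture) cell, and those participant means are summarized across
participants of the same listener culture into cell means and standard
errors (sample sd / √n).  The default design yields 6 × 8 × 2 × 2 = 192
cells.

## Grid-based Bayesian inference

Each cell is analyzed on a grid of plausible population means, −3 to +3 in
z units with step 0.001 (6001 nodes; 0 is always a node).  Components:

- **Prior.**  For a (dimension, emotion) pair with a directional
  prediction, a half-normal with sd 1 in the predicted direction; without
  a prediction, a standard normal centred on 0.  The single prior scale
  sd = 1 is fixed; no alternative scales are explored.
- **Likelihood.**  Normal density centred on the observed cell mean with
  the cell standard error as sd.  Mass falling outside the grid is
  truncated and renormalized; a warning fires when ≥ 1% of the analytic
  mass is lost, since truncation then starts to distort results.
- **Posterior.**  Nodewise product of prior and likelihood, renormalized
  so that Σ density·step = 1.  Densities are computed in log space and
  exponentiated after subtracting the maximum, so extreme means do not
  underflow.  If prior and likelihood supports are disjoint at machine
  precision (a directional prior against a likelihood entirely on the
  other side of zero), the posterior collapses to a point mass at the
  support node nearest the likelihood peak, with a warning.
- **Credible interval.**  The narrowest contiguous node window holding at
  least 95% of the posterior mass.  Tie-break: minimal width, then
  maximal coverage, then leftmost.  Coverage is flat to second order
  around the centred placement of a symmetric posterior, so a pure
  "leftmost narrowest" rule drifts left by several nodes; preferring
  maximal coverage keeps the window centred (matching mean ± 1.96 sd for
  near-normal posteriors to about one grid step) while remaining
  deterministic for flat or multimodal cases.
- **Bayes factor.**  Savage–Dickey density ratio at the point null:
  prior density at 0 over posterior density at 0.  BF > 3 is categorized
  as support for an effect, BF < 1/3 as support for a mean near zero,
  anything else (including exactly 3 or 1/3 — the inequalities are
  strict) as inconclusive.

Grid accuracy: halving the step changes BFs and interval endpoints by less
than 1e−3, and across randomized cases the Savage–Dickey ratio matches an
independent marginal-likelihood computation (the two are mathematically
identical for a point null) to better than 1e−3 relative error.  One
caveat is inherent to any grid method: when a directional prior meets a
likelihood pressed hard against the support boundary at 0, the
prior×likelihood product varies on a scale of a few grid steps and
continuous-integration references differ at the O(step·|mean|/se²) level;
the discrete construction remains internally exact.

## Prediction evaluation

The built-in prediction table encodes 36 directional predictions
(high/low) over the 6 × 8 dimension–emotion grid; the remaining 12 pairs
carry no prediction and receive the symmetric prior.  Across the 4 culture
conditions this gives 144 predicted cells.  Per-cell categories are
tallied overall and split by listener culture × in-/out-group (in-group =
listener culture equals speaker culture, derived at evaluation time).

The joint accuracy of the predictions is summarized by a Beta posterior
under a uniform prior: Beta(supported + 1, not-supported + 1), whose mean
for 113 supported of 144 is 114/146 ≈ 0.781.  An alternative bookkeeping
that uses the total prediction count + 1 as the first shape parameter is
available behind `literal=True`; it is not the default because only the
conventional form has the usual Beta-binomial interpretation.

## Listener-culture comparisons

For each of the 96 (dimension, emotion, speaker culture) triples, the two
listener cultures' cell means are compared with the same engine: the
likelihood is centred on the mean difference (oriented first-minus-second
in sorted culture-label order, i.e. Australia − India for the default
labels; the orientation is cosmetic under the symmetric prior) with the
pooled standard error √(se₁² + se₂²) — the standard independent-groups
form — and the prior is the symmetric standard normal, since no direction
is predicted for culture differences.

## Inter-rater reliability

Primary measure: randomized split-half correlations.  Raters in a
(dimension, culture) group are repeatedly partitioned into halves of size
⌊n/2⌋ and ⌈n/2⌉ (10 000 splits by default, sampled uniformly without
enforcing uniqueness); each half's per-stimulus mean profile is computed
over the raters in that half who rated the stimulus, and the two profiles
are correlated over stimuli covered by both halves (pairwise-complete, as
required by incomplete designs).  Splits with fewer than 2 common stimuli
or a constant profile are discarded and redrawn, with a count reported.
The Spearman–Brown prophecy formula R = 2r/(1+r) is applied to the *mean*
of the split correlations.

Cross-check: for complete designs, the two-way average-measures intraclass
correlation in its consistency form, (MS_stimuli − MS_error)/MS_stimuli,
computed from the classical mean-squares decomposition with stimuli as
targets and raters as judges.  The consistency variant (rather than
absolute agreement) is the right companion to split-half correlation,
which is itself insensitive to rater mean offsets; the choice is labelled
in the output.  On complete synthetic designs the two measures agree to
the second decimal, and the test suite verifies the ICC against an
independent library implementation.

## Acoustic correlates

Cue tables (default emulation: 88 cues) are z-scored within speaker (n−1
sd) to remove between-voice baseline differences; speakers must contribute
at least 2 stimuli.  Factor retention uses Horn's parallel analysis on the
cue correlation matrix: observed eigenvalues are compared against the 95th
percentile (the centile is a package choice, recorded in output) of
eigenvalues from 1000 random standard-normal datasets of the same shape,
retaining leading components until the first failure.  The retained
components' PCA loadings (correlation matrix, because cues live on
heterogeneous scales) are varimax-rotated with Kaiser normalization;
factors are ordered by rotated sum of squared loadings and signed so each
factor's largest-magnitude loading is positive.  Cue selection for the
correlation table is a human judgement: the module reports ranked loadings
and accepts an explicit cue list rather than auto-selecting.

Per-stimulus mean z-ratings per (dimension, listener culture) are Pearson-
correlated with selected cue values, separately within each speaker
culture (64 stimuli each in the default design).  Zero-variance series
yield an undefined (NaN) marker, never 0.

## Synthetic data generator

The generator emulates the study design so every stage is testable with
known ground truth: 2 speaker × 2 listener cultures, 8 emotions × 8
stimuli per speaker culture (128 stimuli), 6 dimensions, and by default 80
listeners in the incomplete-design culture and 40 in the complete-design
culture.  Ratings follow an ordered-threshold model: latent judgement =
cell effect + listener-culture offset + optional per-stimulus deviation +
participant bias (normal, sd 0.3) + participant scale (lognormal, sd 0.2)
× residual noise (sd 1), discretized by fixed cutpoints (−1.2, −0.4, 0.4,
1.2).  The bias/scale terms produce exactly the idiosyncratic scale use
the per-participant z-transform removes; the lognormal scale guarantees
positivity.  Speakers are assigned to stimuli in a shuffled round-robin,
so each voice portrays a random mix of emotions and per-speaker centering
does not align with emotion blocks.

The incomplete design keeps each stimulus per participant with probability
0.643 (≈ 82 of 128 stimuli on average, the study-scale mean) and repairs
any (emotion × speaker culture) group that fell below the minimum by
restoring randomly chosen dropped stimuli.  The distribution of subset
sizes beyond its mean is a modelling choice; Bernoulli thinning is the
simplest mechanism consistent with the coverage guarantee.

Acoustic cues follow a linear factor model: cue = Σ loading × per-emotion
factor score + per-speaker baseline (sd 1) + noise (sd 0.5), with optional
direct links from a cue to a stimulus's latent appraisal value.  Two
defaults matter for interpretation:

- `stimulus_effect_sd` defaults to 0.  With it nonzero, all listeners
  share each stimulus's latent deviation, so condition-cell means carry
  common stimulus-sampling error that the across-participant standard
  error does not see — cell means are then systematically off-null even
  under a null generator.  The default keeps the false-support control
  meaningful; stimulus-level variation is switched on explicitly where a
  scenario needs it (e.g. cue–appraisal correlation recovery).
- Factor scores are per-emotion, so with 8 emotions the between-stimulus
  factor structure has rank ≤ 7; the default 9-factor emulation can never
  be fully recovered by any method.  Recovery checks therefore use
  3-factor tables with exactly orthogonal (Hadamard) per-emotion scores.

A culture offset that shifts *all* emotions of one dimension equally is
removed exactly by the per-participant z-transform and is therefore
undetectable by construction; detectable culture effects must vary across
emotions.  `directional_culture_offsets` builds such a pattern by
amplifying one dimension's predicted directions for one listener culture.

What passing tests on synthetic data do *not* show: real raters are not
conditionally independent given an ordered-threshold latent model, real
stimuli within an emotion differ systematically in ways the default
generator omits, and real acoustic cues are not linear factor mixtures.
The pipeline's headline percentages on synthetic data characterize the
method under its own assumptions, not the empirical phenomenon.

## Determinism and problem sizes

All randomness flows from seeded numpy generators; per-stage sub-seeds are
derived from one master seed via CRC-stable stage labels, so stages rerun
in isolation reproduce their in-pipeline output and full reruns are
byte-identical.  Simulation-based checks run at study scale (40 listeners
per culture, 128 stimuli) and complete in seconds; reliability uses the
full 10 000 splits (vectorized over splits); oracle validation of the
Bayes engine uses ~200 randomized cases on the full 6001-node grid.
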