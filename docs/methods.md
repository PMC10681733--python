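# Methods

## Scope and data model

The package analyses two experiment families that share one statistical
core. Tables are held as a features × samples intensity matrix with explicit
missingness (`NaN`), per-feature metadata, and a linear/log2 scale tag;
literal zeros in input files are converted to missing on read because in the
MaxQuant dialect a zero means "not quantified". Feature identity is the
leading accession of the protein-group id list; PTM sites are keyed
`<accession>_<position>_<multiplicity>`, and every multiplicity state
(`___1/2/3`) is treated as an independent feature throughout — no
aggregation across multiplicity is performed.

## Moderated two-group testing

All group comparisons are two-group contrasts on log2 intensities (the
designs analysed here are all pairwise: bait vs control, treated vs
untreated, mutant vs wildtype). Per-feature residual variances are shrunk
toward a prior estimated across features with the standard empirical-Bayes
moment estimator on the scaled-F distribution of sample variances (log-chi²
moment matching with a Newton inversion of the trigamma function). The
moderated t has residual + prior degrees of freedom; `prior_df` may be
forced to 0 (ordinary pooled t) or ∞ (prior variance only). Features with
fewer than two valid values in a group receive `NaN` statistics and are
excluded from the BH adjustment rather than erroring. A wholly constant
matrix yields zero statistics and p = 1. Trend/robust variants of the
variance prior are not implemented; the plain estimator reproduces limma's
`lmFit`/`eBayes` two-group output to near machine precision, which the test
suite verifies against Bioconductor limma via `Rscript` as an independent
oracle.

BH adjustment delegates to `statsmodels` (`fdr_bh`); k-means to
scikit-learn with seeded random-observation initialization, 10 restarts and
a 300-iteration cap, so labels are bit-reproducible given the seed.

## AP-MS arm

Chain: feature filters (≥ 2 razor & unique peptides, no contaminants, no
reverse hits) → log2 → imputation → moderated test → calls; optionally a
second pass with background renormalization.

**Imputation.** Missing values are assumed missing-not-at-random
(left-censored). A feature is kept if at least one experimental group has
≥ 2 valid values (default `min_valid_per_group = 2`); its missing entries
are drawn from `Normal(mean_s − 1.8·sd_s, (0.3·sd_s)²)` where the moments
are computed per sample over observed values only, before any imputation
(no feedback). Draws are seeded. The defaults 1.8 / 0.3 are the
conventional down-shifted-normal parameters for LFQ data.

**Background renormalization.** When the bait enriches a large share of the
proteome, the "most features are unchanged" assumption behind between-run
normalization fails. On request (a config flag, not a heuristic — it is
meant for runs where inspection shows global enrichment), features are
k-means clustered (default k = 3: background / enriched / depleted) on the
one-dimensional per-feature bait-minus-control mean log2 difference; the
cluster whose median difference is closest to zero (ties toward the larger
cluster) is taken as background, and each sample is shifted so background
medians agree across samples (anchored at the grand median of all
background entries). Whether the original tool clusters per-sample
intensities or group differences is not recoverable; the 1-D
group-difference choice is the simplest statistic consistent with
"background = unregulated" and is recorded in the run log. The second pass
re-imputes the renormalized pre-imputation table with a seed derived from
the run seed and re-tests.

**Calls.** Enriched if log2 FC ≥ log2 of the linear fold-change cutoff and
BH-adjusted p ≤ the FDR cutoff; depleted symmetrically. The fold-change
cutoff is interpreted on the linear scale by default (1.5-fold), with a
log2-scale option.

## TMT arm

Chain: isotopic-impurity correction (linear scale, per plex) → log2 →
within-plex median normalization → between-plex IRS → site-to-protein
normalization → moderated test.

Impurity correction solves `observed = M·true` per feature, where column j
of M gives the fraction of channel j's signal observed in each channel.
Genuinely negative solutions (over-subtraction in near-empty channels) are
set missing; float noise around zero is clamped to zero. When no impurity
matrix is supplied, identity is assumed with a warning, since vendor lot
sheets vary.

Median normalization shifts each sample so its observed median equals the
plex-wide grand median (median of per-sample medians — the per-plex target;
a global target across plexes would partially absorb the batch effect IRS
is responsible for). IRS anchors each feature's reference-channel
intensities at their geometric mean across plexes and rescales all of a
plex's channels by the corresponding factor; on log2 data this is an exact
additive shift. Features without an observed reference value in every plex
are dropped. Site intensities are then normalised by subtracting the
parent protein's log2 intensity per sample; sites whose parent protein is
unquantified are dropped (mirroring the rule used for external-ratio
integration). Rank order within samples is preserved by all these steps.

## Downstream site analyses

Regulated-site calls default to fold change ≥ 1.5 / FDR 0.05 for
phosphosites and ≥ 2 / FDR 0.01 for acetyl sites (the acetylome's higher
baseline variance warrants stricter cutoffs); both are overridable. No
localization-probability filter is applied by default (a configurable
cutoff exists but is off). "Responsive in WT, stable in mutants" means
called up or down in wildtype and ns in every mutant; an optional absolute
fold-change guard can tighten "stable" beyond non-significance. SQ
annotation looks only at the window center and the residue immediately
C-terminal (S followed by Q; T-Q behind an explicit flag). Fold-change
concordance is the squared Pearson correlation over inner-joined site
keys. External SILAC ratios are normalised to protein ratios
(log2 site − log2 protein; sites of unquantified proteins discarded) and
mapped by the case-insensitive (gene, position, window-center-15-mer) key,
dropping keys that match more than one target site. Network edges are kept
at combined confidence ≥ 0.7 by default, self-loops removed, degree-0
nodes dropped unless requested otherwise. Multi-acetylated-peptide sites
carry a flag but are not excluded.

## Synthetic data

The AP-MS generator draws log2 baselines from Normal(25, 2) (typical LFQ
magnitudes, keeping imputation in a realistic regime), replicate noise
sd 0.3, per-sample shifts U(−0.5, 0.5), additive bait effects
U(2, 12) log2 for the designated interactors, and logistic MNAR dropout
with midpoint 22 and steepness 1 (≈ 10–15 % missingness overall,
concentrated at low intensity). It also salts in contaminant / reverse /
single-peptide features so the filters have real work.

The TMT generator builds two 10-channel plexes (untreated / treated), each
3 genotypes × 3 replicates + 1 reference channel. The reference is a single
pooled aliquot: per feature, the linear mean over all 18 samples, identical
in both plexes before distortion — this matches how a reference pool is
mixed once and split, and it is what makes IRS identifiable; a per-plex
pool would let treatment effects leak into the reference and bias effect
estimates. Plexes are distorted by a multiplicative batch factor
2^U(−1, 1) and reporter channels mixed through a tri-diagonal impurity
matrix (2 % spill to adjacent channels; a synthetic stand-in for a vendor
lot sheet). Regulated sites (default 10 %) receive treatment effects of
±U(1, 3) log2 in wildtype, attenuated multiplicatively in the mutants
(defaults 0.3 and 0.7). Sequence windows are uniform over the 20 canonical
amino acids with a fixed central S; exactly the requested fraction of
regulated sites (default 0.536) carries SQ, against a 10 % background rate.

What the generators do **not** emulate: peptide-to-protein roll-up and
shared peptides, co-isolation interference beyond the impurity matrix,
abundance-dependent variance heterogeneity, protein-level regulation
confounding site calls, correlated missingness across samples, and
compositional bias in sequence windows. Passing recovery tests therefore
demonstrates that the estimators invert exactly the distortions they are
designed for — batch factors, impurity mixing, left-censored dropout — not
that every idiosyncrasy of real acquisitions is handled.

## Numerical choices and edge cases

- Zero-variance rows z-score to zeros (constant features are legitimate
  after imputation); constant inputs to the correlation are an error.
- The trigamma inverse uses Newton iteration with asymptotic fallbacks;
  when the spread of log sample variances is within chi-square sampling
  noise the prior df is ∞ and the posterior variance is the prior.
- k-means ties in background detection break toward the larger cluster.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds (e.g. the renormalization re-imputation pass) are
  deterministic functions of the run seed.
- Problem sizes in the test suite and acceptance script (hundreds to a few
  thousand features, 3–6 replicates, 5–20 seeds) were chosen as the
  smallest at which the Monte-Carlo bounds are stable; they mirror the
  structure, not the scale, of real studies.

## Known limitations

Only two-group contrasts (no multi-factor designs or interaction terms);
no protein-group inference or match-between-runs; no spectrum-level
modelling; TMT channel chemistry beyond the user-supplied impurity matrix
is not modelled; network analysis stops at edge filtering and degrees
(no layout or modularity classes).
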