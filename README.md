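# ptmquant

Quantitative mass-spectrometry analysis for interactome and PTM studies:

- **AP-MS differential enrichment** — call the interactors of an
  affinity-purified bait against a control pull-down from label-free (LFQ)
  protein intensities, with left-censored imputation of missing values,
  optional background-cluster renormalization for heavily enriched
  pull-downs, and empirical-Bayes moderated t-tests.
- **TMT multi-plex PTM quantification** — take reporter-ion intensities of
  phospho- or acetyl-site tables through isotopic-impurity correction,
  within-plex median normalization, between-plex internal-reference scaling
  (IRS), site-to-protein normalization, and moderated group comparisons.
- **Downstream site analyses** — regulated-site calls, sets of sites
  responsive in wildtype but stable in mutants, SQ-motif annotation
  (the ATM/ATR substrate motif S-Q), fold-change concordance (r²) between
  genotypes, ortholog mapping, integration of external SILAC site ratios,
  and confidence-filtered interaction-network edges.

Input tables follow the MaxQuant output dialect (`proteinGroups` with
`LFQ intensity <sample>` or `Reporter intensity corrected` columns;
`Phospho (STY)`/`Acetyl (K)` site tables with `___1/2/3` multiplicity
suffixes). A synthetic-data module generates both designs with known ground
truth, so the whole pipeline is testable without any external download.

## The statistics in brief

For each feature (protein group or PTM site) on log2 scale, the two-group
comparison uses a moderated t-statistic: per-feature sample variances
*s²_g* (residual df *d_g*) are shrunk toward a prior *s²₀* with df *d₀*
estimated across features by moment matching on the scaled-F distribution
of the *s²_g*,

    s̃²_g = (d₀·s²₀ + d_g·s²_g) / (d₀ + d_g),
    t_g = (x̄_A − x̄_B) / (s̃_g · √(1/n_A + 1/n_B)),

with p-values from the t distribution on *d_g + d₀* df and
Benjamini–Hochberg adjustment. (This reproduces limma's `lmFit`/`eBayes`
two-group results; the test suite cross-checks against it.)

Missing LFQ values are imputed — for features with ≥ 2 valid values in at
least one group — by draws from `Normal(μ_s, σ_s)` per sample *s*, where
`μ_s = mean_s − 1.8·sd_s` and `σ_s = 0.3·sd_s` over that sample's observed
values: missingness in AP-MS is left-censored (low-abundance proteins drop
out), so imputed values belong in the left tail.

TMT reporter mixing is inverted per feature by solving
`observed = M · true` with the channel impurity matrix *M*; IRS rescales
each plex per feature so the shared pooled reference channel agrees across
plexes (geometric-mean anchoring), removing multiplicative plex batch
effects; PTM-site intensities are normalised to parent-protein intensities
(log2 subtraction) before testing, so calls reflect modification
stoichiometry rather than protein abundance.

Default call thresholds: interactors and phosphosites at fold change ≥ 1.5
and BH-adjusted p ≤ 0.05; acetyl sites at fold change ≥ 2 and adjusted
p ≤ 0.01.

## Worked example

Simulate a bait-vs-control pull-down (2000 protein groups, 50 true
interactors with 2–12 log2 enrichment, 3 + 3 replicates) and analyse it:

```sh
ptmquant simulate --kind apms --n-features 2000 --n-interactors 50 \
    --seed 7 --out demo/sim
ptmquant apms --table demo/sim/proteinGroups.tsv --design demo/sim/design.tsv \
    --bait bait --control control --fc 1.5 --fdr 0.05 --seed 7 --out demo/apms
```

`demo/apms/run_log.json` records the chain:

```
n_features_raw: 2000   n_features_filtered: 1880   n_features_tested: 1801
n_enriched: 51         n_depleted: 0
```

2000 simulated features lose 120 to the contaminant/decoy/peptide-evidence
filters and 79 more to the ≥ 2-valid-values imputation rule; 51 features are
called enriched at FC ≥ 1.5, FDR 5%. The top of `results.tsv`:

```
feature_id   log2_fc        t            p        adj_p  n_valid_a  n_valid_b
    P00010   11.046   42.619   1.20e-09   5.41e-07          3          3
    P00019   11.114   44.801   8.50e-10   5.41e-07          3          3
    P00045   11.286   42.712   1.18e-09   5.41e-07          3          3
```

Against the simulation's ground truth (`demo/sim/truth_interactors.tsv`),
49 of the 50 true interactors are recovered with 2 false calls — the kind
of sensitivity/FDR trade-off the acceptance checks quantify over many
seeds.

The same pattern works for the TMT arm (`ptmquant simulate --kind tmt`,
then `ptmquant tmt --proteins ... --sites ... --impurity ...`), for the
downstream site analyses (`ptmquant ptm`) and for network-edge filtering
(`ptmquant net`). Every run writes a `manifest.json` with input checksums,
parameters and seeds; identical inputs + seed give byte-identical outputs.

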