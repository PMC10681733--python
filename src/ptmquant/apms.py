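"""AP-MS interactome arm: left-censored imputation, background-cluster
renormalization and differential enrichment.

Affinity-purification MS compares a bait pull-down against a control
pull-down.  Low-abundance prey proteins drop out of the control runs in an
intensity-dependent way (missing not at random), so missing log2 LFQ values
are imputed from a per-sample normal distribution shifted into the left tail
of that sample's observed intensity distribution.  When the bait enriches a
large fraction of the proteome, between-run normalisation built on the
"most proteins are unchanged" assumption fails; in that case a background
cluster of unregulated proteins is identified by k-means on per-feature
group differences and every sample is re-anchored to the background median
before a second round of testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .io_tables import (
    LOG2,
    QuantTable,
    SampleDesign,
    ThresholdConfig,
    filter_features,
    log2_transform,
)
from .stats_core import kmeans_cluster, moderated_two_group_test


@dataclass(frozen=True)
class ImputationParams:
    """Left-shifted normal imputation: draws come from
    Normal(mean_s - shift * sd_s, (width * sd_s)^2) where mean_s / sd_s are the
    observed (pre-imputation) log2 intensity moments of sample s."""

    shift: float = 1.8
    width: float = 0.3
    min_valid_per_group: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift <= 0 or self.width <= 0:
            raise ParameterError("shift and width must be positive")
        if self.min_valid_per_group < 1:
            raise ParameterError("min_valid_per_group must be positive")


def impute_missing(table: QuantTable, design: SampleDesign, params: ImputationParams) -> QuantTable:
    """Impute missing log2 intensities from a down-shifted normal.

    Features with fewer than ``min_valid_per_group`` observed values in every
    experimental group are dropped (no group gives evidence the protein was
    really there).  Per-sample imputation moments are estimated from observed
    values only.  Draws are seeded and reproducible.
    """
    if table.scale != LOG2:
        raise ParameterError("imputation operates on log2 intensities")
    samples = [s for s in design.sample_ids if s in table.samples]
    X = table.intensities[samples].to_numpy(dtype=float)

    valid_per_group = []
    for g in design.groups:
        cols = [samples.index(s) for s in design.samples_in_group(g) if s in samples]
        valid_per_group.append(np.sum(np.isfinite(X[:, cols]), axis=1))
    keep = np.max(np.vstack(valid_per_group), axis=0) >= params.min_valid_per_group
    X = X[keep]
    index = table.feature_ids[keep]

    rng = np.random.default_rng(params.seed)
    out = X.copy()
    for j, s in enumerate(samples):
        col = X[:, j]
        obs = col[np.isfinite(col)]
        if obs.size < 2:
            raise DataError(f"sample {s!r} has fewer than two observed values")
        mu = obs.mean() - params.shift * obs.std(ddof=1)
        sigma = params.width * obs.std(ddof=1)
        miss = ~np.isfinite(col)
        out[miss, j] = rng.normal(mu, sigma, size=int(miss.sum()))

    intens = pd.DataFrame(out, index=index, columns=samples)
    return QuantTable(intens, table.meta.loc[index], scale=LOG2)


def detect_background_cluster(
    table: QuantTable,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    k: int = 3,
    seed: int = 0,
) -> pd.Index:
    """Identify unregulated "background" features by k-means.

    Features are clustered in one dimension on their between-group mean log2
    difference (bait minus control); the cluster whose median difference is
    closest to zero is returned, ties broken toward the larger cluster.
    """
    if k > table.n_features:
        raise ParameterError(f"k={k} exceeds number of features ({table.n_features})")
    a = [s for s in design.samples_in_group(group_a) if s in table.samples]
    b = [s for s in design.samples_in_group(group_b) if s in table.samples]
    diff = (
        table.intensities[a].mean(axis=1) - table.intensities[b].mean(axis=1)
    ).to_numpy(dtype=float)
    if np.isnan(diff).any():
        raise ParameterError("background detection requires an imputed (complete) table")
    labels = kmeans_cluster(diff[:, None], k=k, seed=seed)
    best, best_key = None, None
    for lab in range(k):
        members = labels == lab
        if not members.any():
            continue
        key = (abs(float(np.median(diff[members]))), -int(members.sum()))
        if best_key is None or key < best_key:
            best, best_key = lab, key
    return table.feature_ids[labels == best]


def renormalize_to_background(table: QuantTable, background) -> QuantTable:
    """Re-anchor every sample so background medians agree across samples.

    Per sample, the offset (median over background features in that sample)
    minus (grand median over all background entries) is subtracted from all
    features; within-sample differences between features are untouched.
    """
    background = pd.Index(background)
    if len(background) == 0:
        raise ParameterError("background feature set is empty")
    if not background.isin(table.feature_ids).all():
        missing = background[~background.isin(table.feature_ids)]
        raise ParameterError(f"background features not in table: {list(missing[:5])}")
    bg = table.intensities.loc[background]
    grand = float(np.nanmedian(bg.to_numpy(dtype=float)))
    offsets = bg.median(axis=0, skipna=True) - grand
    intens = table.intensities - offsets
    return QuantTable(intens, table.meta, scale=table.scale)


def call_enriched(results: pd.DataFrame, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Classify each feature as enriched / depleted / ns from its log2 fold
    change and BH-adjusted p-value."""
    cut = thresholds.log2_fc_cutoff
    lfc = results["log2_fc"].to_numpy(dtype=float)
    adj = results["adj_p"].to_numpy(dtype=float)
    sig = np.isfinite(adj) & (adj <= thresholds.fdr_cutoff)
    direction = np.where(
        sig & (lfc >= cut), "enriched", np.where(sig & (lfc <= -cut), "depleted", "ns")
    )
    return pd.DataFrame(
        {
            "direction": direction,
            "log2_fc": lfc,
            "adj_p": adj,
            "fc_cutoff": thresholds.fc_cutoff,
            "fdr_cutoff": thresholds.fdr_cutoff,
            "fc_scale": thresholds.fc_scale,
        },
        index=results.index,
    )


@dataclass
class ApmsConfig:
    """Parameters of the end-to-end AP-MS workflow."""

    group_bait: str
    group_control: str
    thresholds: ThresholdConfig = field(default_factory=lambda: ThresholdConfig(1.5, 0.05))
    imputation: ImputationParams = field(default_factory=ImputationParams)
    min_razor_unique: int = 2
    background_renorm: bool = False
    background_k: int = 3
    seed: int = 0


def run_apms_workflow(
    table: QuantTable, design: SampleDesign, config: ApmsConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full AP-MS enrichment chain on a raw linear-scale table.

    filter -> log2 -> impute -> moderated test, then optionally: detect the
    background cluster, renormalize to it, re-impute the filtered (pre-first-
    imputation) table with a derived seed and re-test.  Returns
    ``(calls, results, run_log)``.
    """
    imp = ImputationParams(
        shift=config.imputation.shift,
        width=config.imputation.width,
        min_valid_per_group=config.imputation.min_valid_per_group,
        seed=config.seed,
    )
    filtered = filter_features(table, min_razor_unique=config.min_razor_unique)
    logged = log2_transform(filtered)
    imputed = impute_missing(logged, design, imp)
    results = moderated_two_group_test(
        imputed.intensities, design, config.group_bait, config.group_control
    )
    log = {
        "n_features_raw": int(table.n_features),
        "n_features_filtered": int(filtered.n_features),
        "n_features_tested": int(imputed.n_features),
        "min_razor_unique": config.min_razor_unique,
        "imputation": {"shift": imp.shift, "width": imp.width,
                       "min_valid_per_group": imp.min_valid_per_group, "seed": imp.seed},
        "thresholds": {"fc_cutoff": config.thresholds.fc_cutoff,
                       "fdr_cutoff": config.thresholds.fdr_cutoff,
                       "fc_scale": config.thresholds.fc_scale},
        "groups": {"bait": config.group_bait, "control": config.group_control},
        "background_renorm": config.background_renorm,
        "seed": config.seed,
    }
    if config.background_renorm:
        background = detect_background_cluster(
            imputed, design, config.group_bait, config.group_control,
            k=config.background_k, seed=config.seed,
        )
        renorm = renormalize_to_background(imputed, background)
        # re-impute from the pre-imputation missingness pattern, shifted to the
        # renormalized scale, with a seed derived from the run seed
        offsets = imputed.intensities.loc[background].median(axis=0) - float(
            np.median(imputed.intensities.loc[background].to_numpy())
        )
        relogged = QuantTable(
            logged.intensities.loc[renorm.feature_ids] - offsets, logged.meta.loc[renorm.feature_ids], scale=LOG2
        )
        reimp = ImputationParams(
            shift=imp.shift, width=imp.width,
            min_valid_per_group=imp.min_valid_per_group,
            seed=(config.seed * 1000003 + 1) % (2**31),
        )
        reimputed = impute_missing(relogged, design, reimp)
        results = moderated_two_group_test(
            reimputed.intensities, design, config.group_bait, config.group_control
        )
        log["background"] = {
            "k": config.background_k,
            "n_background": int(len(background)),
            "clustering_statistic": "per-feature bait-minus-control mean log2 difference",
            "reimpute_seed": reimp.seed,
        }
    calls = call_enriched(results, config.thresholds)
    log["n_enriched"] = int((calls["direction"] == "enriched").sum())
    log["n_depleted"] = int((calls["direction"] == "depleted").sum())
    return calls, results, log
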