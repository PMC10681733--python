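"""Downstream PTM-site analyses: regulation calls, cross-genotype set logic,
SQ-motif annotation, fold-change concordance, ortholog mapping, external
SILAC-ratio integration, network-edge filtering and profile clustering.

The SQ motif (serine immediately followed by glutamine) is the preferred
substrate motif of the DNA-damage-response kinases ATM and ATR; the fraction
of regulated phosphosites falling on SQ motifs, and the squared correlation
of site fold changes between genotypes, summarise how strongly a mutant
attenuates DDR signalling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, UndefinedResultError
from .io_tables import QuantTable, ThresholdConfig
from .stats_core import kmeans_cluster, squared_pearson, zscore_rows

#: default cutoffs per dataset: phospho FC 1.5 / FDR 0.05; acetyl is filtered
#: more stringently (FC 2 / FDR 0.01) because of its higher baseline variance
DATASET_THRESHOLDS = {
    "phospho": ThresholdConfig(fc_cutoff=1.5, fdr_cutoff=0.05),
    "acetyl": ThresholdConfig(fc_cutoff=2.0, fdr_cutoff=0.01),
}


def filter_by_localization_prob(sites: QuantTable, min_prob: float | None = None) -> QuantTable:
    """Optionally drop sites below a localization-probability cutoff.

    Off by default (``min_prob=None`` is the identity): the standard
    workflow applies no localization filter, but a cutoff (e.g. 0.75) can be
    opted into.  Sites without a recorded probability are kept.
    """
    if min_prob is None:
        return sites
    if not 0.0 <= min_prob <= 1.0:
        raise ParameterError("min_prob must lie in [0, 1]")
    prob = sites.meta.get("localization_prob")
    if prob is None:
        return sites
    keep = prob.isna() | (prob >= min_prob)
    return sites.subset(sites.feature_ids[keep.to_numpy(dtype=bool)])


def call_regulated_sites(
    results: pd.DataFrame,
    dataset: str = "phospho",
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Classify each site as up / down / ns against the dataset's cutoffs."""
    if thresholds is None:
        if dataset not in DATASET_THRESHOLDS:
            raise ParameterError(f"unknown dataset {dataset!r}; expected phospho or acetyl")
        thresholds = DATASET_THRESHOLDS[dataset]
    cut = thresholds.log2_fc_cutoff
    lfc = results["log2_fc"].to_numpy(dtype=float)
    adj = results["adj_p"].to_numpy(dtype=float)
    sig = np.isfinite(adj) & (adj <= thresholds.fdr_cutoff)
    direction = np.where(sig & (lfc >= cut), "up", np.where(sig & (lfc <= -cut), "down", "ns"))
    return pd.DataFrame(
        {"direction": direction, "log2_fc": lfc, "adj_p": adj},
        index=results.index,
    )


def responsive_in_wt_stable_in_mutants(
    wt: pd.DataFrame,
    mutants: list[pd.DataFrame] | tuple[pd.DataFrame, ...] = (),
    max_mutant_abs_log2_fc: float | None = None,
) -> pd.Index:
    """Sites regulated (up or down) in wildtype but unaffected in every mutant.

    "Unaffected" means called ns in each mutant; ``max_mutant_abs_log2_fc``
    optionally adds an absolute fold-change guard on top of non-significance.
    With no mutants the result is simply the WT-regulated set.
    """
    selected = wt.index[wt["direction"].isin(["up", "down"])]
    for mut in mutants:
        common = selected.intersection(mut.index)
        if len(wt.index.intersection(mut.index)) == 0:
            raise DataError("mutant call set shares no sites with the wildtype set")
        stable = mut.loc[common, "direction"] == "ns"
        if max_mutant_abs_log2_fc is not None:
            stable &= mut.loc[common, "log2_fc"].abs() <= max_mutant_abs_log2_fc
        selected = common[stable.to_numpy()]
    return selected


def _check_window(window: str) -> str:
    if not isinstance(window, str) or len(window) < 3 or len(window) % 2 == 0:
        raise DataError(f"malformed sequence window {window!r} (need odd length >= 3)")
    return window


def annotate_sq_motif(window: str, include_tq: bool = False, residue: str | None = None) -> bool:
    """True iff the centered residue is S (or T, when ``include_tq``) and the
    residue immediately C-terminal is Q."""
    window = _check_window(window)
    center = len(window) // 2
    aa = window[center]
    if residue is not None and aa != residue:
        raise DataError(f"window center {aa!r} does not match residue {residue!r}")
    allowed = ("S", "T") if include_tq else ("S",)
    return aa in allowed and window[center + 1] == "Q"


def annotate_sq_motifs(sites: QuantTable, include_tq: bool = False) -> pd.Series:
    """Vectorised SQ annotation over a site table's sequence windows."""
    return sites.meta["sequence_window"].map(lambda w: annotate_sq_motif(w, include_tq))


def sq_fraction(site_keys, annotations: pd.Series) -> float:
    """Percentage of the given sites that carry an SQ motif (one-decimal)."""
    keys = pd.Index(site_keys)
    if len(keys) == 0:
        raise UndefinedResultError("SQ fraction undefined for an empty site set")
    missing = keys[~keys.isin(annotations.index)]
    if len(missing):
        raise DataError(f"sites without SQ annotation: {list(missing[:5])}")
    flags = annotations.loc[keys].astype(bool)
    return round(100.0 * float(flags.sum()) / len(keys), 1)


def compare_fc_scatter(
    wt_fc: pd.Series,
    mutant_fc: pd.Series,
    sq_flags: pd.Series | None = None,
    site_filter: str = "all",
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of per-site log2 fold changes between two
    genotypes, with an optional restriction to SQ-motif sites.  Returns the
    r-squared and the paired table (scatter-plot input)."""
    if site_filter not in ("all", "sq"):
        raise ParameterError(f"site_filter must be 'all' or 'sq', got {site_filter!r}")
    paired = pd.DataFrame({"wt": wt_fc, "mutant": mutant_fc}).dropna()
    if sq_flags is not None:
        paired = paired.join(sq_flags.rename("sq"), how="inner")
        if site_filter == "sq":
            paired = paired[paired["sq"].astype(bool)]
    if len(paired) < 3:
        raise DataError(f"need >= 3 common sites after filtering, got {len(paired)}")
    r2 = squared_pearson(paired["wt"], paired["mutant"])
    return r2, paired


def map_orthologs(features, orthologs: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Map species-A features through an ortholog pair table.

    ``orthologs`` needs two columns (A id, B id; first two columns are used).
    Features with at least one pair map (one-to-many expanded, flagged
    ambiguous); features with none go on the excluded list.
    """
    features = list(features)
    if orthologs.shape[1] < 2:
        raise ParameterError("ortholog table needs two id columns")
    a_col, b_col = orthologs.columns[:2]
    pairs = orthologs[[a_col, b_col]].drop_duplicates()
    grouped = pairs.groupby(a_col)[b_col].agg(list)
    rows, excluded = [], []
    for f in features:
        if f in grouped.index:
            targets = grouped.loc[f]
            for t in targets:
                rows.append({"source_id": f, "ortholog_id": t, "ambiguous": len(targets) > 1})
        else:
            excluded.append(f)
    mapping = pd.DataFrame(rows, columns=["source_id", "ortholog_id", "ambiguous"])
    return mapping, excluded


def _window_core(window: str, core: int = 15) -> str:
    window = _check_window(window)
    center = len(window) // 2
    half = core // 2
    if center < half or center + half >= len(window):
        return window
    return window[center - half: center + half + 1]


def integrate_external_ratio_sites(
    external_sites: pd.DataFrame,
    external_proteins: pd.DataFrame,
    target_sites: QuantTable,
) -> pd.DataFrame:
    """Normalise external site H/L ratios to protein ratios and map them onto
    a target site table.

    ``external_sites`` needs columns ``gene``, ``position``, ``window``,
    ``ratio_hl``; ``external_proteins`` needs ``gene`` and ``ratio_hl``.
    Site log2 ratio minus protein log2 ratio is computed; sites whose protein
    has no quantified ratio are discarded.  Mapping onto the target table uses
    the (case-insensitive gene, position, window-center-15-mer) key; keys that
    match more than one target site are removed as ambiguous.  Returns the
    target site metadata restricted to matched sites with an appended
    ``external_log2_ratio`` column.
    """
    for col in ("gene", "position", "window", "ratio_hl"):
        if col not in external_sites.columns:
            raise ParameterError(f"external site table lacks column {col!r}")
    ext = external_sites.copy()
    if (pd.to_numeric(ext["ratio_hl"], errors="coerce") <= 0).any():
        raise ParameterError("H/L ratios must be positive")
    prot = external_proteins.set_index(external_proteins["gene"].str.lower())["ratio_hl"]
    ext["gene_key"] = ext["gene"].str.lower()
    ext["protein_ratio"] = ext["gene_key"].map(prot)
    ext = ext.dropna(subset=["protein_ratio"])  # sites of unquantified proteins discarded
    ext["norm_log2_ratio"] = np.log2(ext["ratio_hl"].astype(float)) - np.log2(
        ext["protein_ratio"].astype(float)
    )
    ext["key"] = list(zip(ext["gene_key"], ext["position"].astype(int),
                          ext["window"].map(_window_core)))

    meta = target_sites.meta
    target_keys = pd.Series(
        list(zip(meta["gene_name"].str.lower(), meta["position"].astype(int),
                 meta["sequence_window"].map(_window_core))),
        index=meta.index,
    )
    # drop keys that hit more than one target site (ambiguous mapping)
    counts = target_keys.value_counts()
    unique_keys = set(counts.index[counts == 1])
    key_to_site = {k: i for i, k in target_keys.items() if k in unique_keys}

    matched = ext[ext["key"].isin(key_to_site)]
    out = meta.loc[[key_to_site[k] for k in matched["key"]]].copy()
    out["external_log2_ratio"] = matched["norm_log2_ratio"].to_numpy()
    return out


def filter_network_edges(
    edges: pd.DataFrame,
    min_score: float = 0.7,
    drop_disconnected: bool = True,
) -> tuple[list, pd.DataFrame, pd.Series]:
    """Keep edges whose combined confidence score passes ``min_score``.

    Self-loops are removed first.  When ``drop_disconnected``, nodes left with
    degree 0 are dropped from the node list.  Returns (nodes, filtered edges,
    per-node degree) — degrees feed degree-proportional node sizing downstream.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ParameterError("min_score must lie in [0, 1]")
    for col in ("node1", "node2", "combined_score"):
        if col not in edges.columns:
            raise ParameterError(f"edge table lacks column {col!r}")
    scores = edges["combined_score"].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        raise ParameterError("combined scores must lie in [0, 1]")
    clean = edges[edges["node1"] != edges["node2"]].copy()
    kept = clean[clean["combined_score"].astype(float) >= min_score].reset_index(drop=True)
    all_nodes = pd.unique(pd.concat([clean["node1"], clean["node2"]], ignore_index=True))
    degree = pd.Series(0, index=pd.Index(all_nodes, name="node"), dtype=int)
    for col in ("node1", "node2"):
        counts = kept[col].value_counts()
        degree.loc[counts.index] += counts.astype(int)
    if drop_disconnected:
        degree = degree[degree > 0]
    return list(degree.index), kept, degree


def cluster_site_profiles(
    sites: QuantTable, k: int, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """z-score each site's intensity profile across samples and k-means
    cluster the profiles (heatmap input).  Rows must be complete."""
    Z = zscore_rows(sites.intensities)
    labels = kmeans_cluster(Z.to_numpy(), k=k, seed=seed)
    return pd.Series(labels, index=sites.feature_ids, name="cluster"), Z
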