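"""Synthetic datasets with the statistical structure the pipeline assumes,
plus ground truth for recovery tests.

Two designs are emulated.  The AP-MS design is a bait pull-down versus a
control pull-down (few replicates each): log2 LFQ-like baseline abundances
around 25 +/- 2, additive bait enrichment for a subset of true interactors,
small per-sample offsets, and intensity-dependent (MNAR) dropout following a
logistic curve, so low-abundance values go missing preferentially — the
regime the left-shifted imputation rule is built for.  The TMT design is two
10-channel plexes (untreated / treated), each carrying three genotypes x
three replicates plus one pooled reference channel; plexes differ by a
multiplicative batch factor and reporter channels are mixed through an
isotopic-impurity matrix before output, so the correction/normalization
chain has real work to undo.  Every generator is a pure function of its
parameters and seed, and the returned truth object suffices to score
sensitivity, FDR and effect-estimation bias of any downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_tables import LINEAR, QuantTable, SampleDesign
from .tmt import ImpurityMatrix

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_TMT10_CHANNELS = ("126C", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment."""

    seed: int
    true_interactors: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_regulated_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    plex_batch_factors: dict = field(default_factory=dict)
    sample_shifts: dict = field(default_factory=dict)
    missingness_params: tuple | None = None


def apply_mnar_missingness(
    matrix: np.ndarray, midpoint: float, steepness: float, seed: int = 0
) -> np.ndarray:
    """Drop entries of a log2 matrix with probability
    1 / (1 + exp(steepness * (value - midpoint))) — a logistic left-censoring
    curve, monotone nonincreasing in intensity."""
    if steepness <= 0:
        raise ParameterError("steepness must be positive")
    X = np.asarray(matrix, dtype=float).copy()
    rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        p_drop = 1.0 / (1.0 + np.exp(steepness * (X - midpoint)))
    drop = rng.random(X.shape) < p_drop
    X[drop] = np.nan
    return X


def generate_sequence_windows(
    n: int, sq_positive: int, width: int = 31, seed: int = 0, center_residue: str = "S"
) -> list[str]:
    """Random amino-acid windows with a fixed center residue; exactly
    ``sq_positive`` of them carry Q at the center+1 position, the rest any
    non-Q residue there."""
    if sq_positive > n:
        raise ParameterError("sq_positive cannot exceed n")
    if width < 3 or width % 2 == 0:
        raise ParameterError("width must be odd and >= 3")
    rng = np.random.default_rng(seed)
    center = width // 2
    non_q = _AMINO_ACIDS[_AMINO_ACIDS != "Q"]
    windows = []
    for i in range(n):
        chars = rng.choice(_AMINO_ACIDS, size=width)
        chars[center] = center_residue
        chars[center + 1] = "Q" if i < sq_positive else rng.choice(non_q)
        windows.append("".join(chars))
    # fixed-order assignment of the SQ-positive slots keeps the generator a
    # pure function of (n, sq_positive, seed)
    return windows


def simulate_apms_experiment(
    n_features: int = 2000,
    n_interactors: int = 50,
    reps_per_group: int = 3,
    effect_range: tuple[float, float] = (2.0, 12.0),
    seed: int = 0,
    noise_sd: float = 0.3,
    mnar_midpoint: float = 22.0,
    mnar_steepness: float = 1.0,
    frac_contaminant: float = 0.02,
    frac_reverse: float = 0.01,
    frac_low_evidence: float = 0.03,
) -> tuple[QuantTable, SampleDesign, SyntheticTruth]:
    """Simulate a bait-vs-control AP-MS experiment with known interactors.

    Returns a linear-scale protein-groups table (with MNAR dropout applied and
    a small admixture of contaminant / reverse / single-peptide features that
    the standard filters should remove), the sample design, and the truth.
    """
    if n_interactors >= n_features:
        raise ParameterError("n_interactors must be smaller than n_features")
    if reps_per_group < 2:
        raise ParameterError("need at least two replicates per group")
    lo, hi = effect_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ParameterError("effect_range must be a finite (low, high) pair")
    rng = np.random.default_rng(seed)

    bait_samples = [f"bait_{r + 1}" for r in range(reps_per_group)]
    ctrl_samples = [f"ctrl_{r + 1}" for r in range(reps_per_group)]
    samples = bait_samples + ctrl_samples
    n_samples = len(samples)

    feature_ids = [f"P{i:05d}" for i in range(n_features)]
    baseline = rng.normal(25.0, 2.0, size=n_features)
    effects = rng.uniform(lo, hi, size=n_interactors)
    interactor_ids = feature_ids[:n_interactors]

    sample_shifts = rng.uniform(-0.5, 0.5, size=n_samples)
    log2 = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    log2[:n_interactors, :reps_per_group] += effects[:, None]
    log2 += sample_shifts[None, :]
    log2 = apply_mnar_missingness(
        log2, mnar_midpoint, mnar_steepness, seed=int(rng.integers(2**31))
    )

    razor = rng.poisson(10.0, size=n_features) + 2
    is_contaminant = np.zeros(n_features, dtype=bool)
    is_reverse = np.zeros(n_features, dtype=bool)
    decoy_pool = np.arange(n_interactors, n_features)
    n_con = int(frac_contaminant * n_features)
    n_rev = int(frac_reverse * n_features)
    n_low = int(frac_low_evidence * n_features)
    flagged = rng.choice(decoy_pool, size=n_con + n_rev + n_low, replace=False)
    is_contaminant[flagged[:n_con]] = True
    is_reverse[flagged[n_con:n_con + n_rev]] = True
    razor[flagged[n_con + n_rev:]] = 1

    meta = pd.DataFrame(
        {
            "gene_name": [f"GENE{i}" for i in range(n_features)],
            "protein_ids": [[fid] for fid in feature_ids],
            "razor_unique_peptides": razor,
            "is_contaminant": is_contaminant,
            "is_reverse": is_reverse,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    intens = pd.DataFrame(np.power(2.0, log2), index=meta.index, columns=samples)
    table = QuantTable(intens, meta, scale=LINEAR)

    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["bait"] * reps_per_group + ["control"] * reps_per_group,
                "replicate": list(range(1, reps_per_group + 1)) * 2,
                "plex_id": None,
                "channel": None,
                "is_reference": False,
            }
        )
    )
    truth = SyntheticTruth(
        seed=seed,
        true_interactors=pd.DataFrame(
            {"feature_id": interactor_ids, "log2_effect": effects}
        ),
        sample_shifts=dict(zip(samples, sample_shifts)),
        missingness_params=(mnar_midpoint, mnar_steepness),
    )
    return table, design, truth


def default_impurity_matrix(n_channels: int = 10, spill: float = 0.02) -> ImpurityMatrix:
    """Tri-diagonal impurity matrix: each channel leaks ``spill`` of its
    signal into each adjacent channel (synthetic stand-in for a vendor lot
    sheet)."""
    M = np.eye(n_channels) * (1.0 - 2.0 * spill)
    for i in range(n_channels - 1):
        M[i, i + 1] = spill
        M[i + 1, i] = spill
    M[0, 0] += spill
    M[-1, -1] += spill
    return ImpurityMatrix(tuple(_TMT10_CHANNELS[:n_channels]), M)


def simulate_tmt_ptm_experiment(
    n_proteins: int = 400,
    sites_per_protein: float = 2.0,
    genotypes: tuple[str, ...] = ("WT", "HDAC1_CI", "GSE1_KO"),
    reps: int = 3,
    frac_regulated: float = 0.10,
    sq_frac: float = 0.536,
    background_sq_frac: float = 0.10,
    attenuation: dict | None = None,
    effect_range: tuple[float, float] = (1.0, 3.0),
    frac_down: float = 0.5,
    noise_sd: float = 0.3,
    protein_noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[QuantTable, QuantTable, SampleDesign, ImpurityMatrix, SyntheticTruth]:
    """Simulate a two-plex TMT PTM experiment with known regulated sites.

    Plexes are "untreated" and "treated"; each carries ``genotypes`` x
    ``reps`` samples plus one reference channel — a single pooled aliquot
    (per-feature linear mean of all samples, identical in both plexes before
    distortion), mirroring how the reference pool is mixed once and split.  A fraction of sites respond to
    treatment in WT with log2 effects drawn from ``effect_range`` (a
    ``frac_down`` share downward); in each mutant the effect is multiplied by
    its attenuation factor (default: GSE1_KO 0.3, HDAC1_CI 0.7).  Exactly
    ``round(sq_frac * n_regulated)`` regulated sites carry SQ windows; the
    background SQ rate is ``background_sq_frac``.  Reporter signals pass
    through a per-plex batch factor 2^U(-1,1) and the impurity matrix before
    output.  Returns (protein table, site table, design, impurity matrix,
    truth); both tables are linear-scale.
    """
    if not 0.0 <= frac_regulated <= 1.0 or not 0.0 <= sq_frac <= 1.0:
        raise ParameterError("fractions must lie in [0, 1]")
    if len(genotypes) * reps + 1 > 10:
        raise ParameterError("design exceeds 10 TMT channels per plex")
    if attenuation is None:
        attenuation = {"GSE1_KO": 0.3, "HDAC1_CI": 0.7}
    rng = np.random.default_rng(seed)

    plexes = ("untreated", "treated")
    channel_labels = _TMT10_CHANNELS[: len(genotypes) * reps + 1]
    sample_rows = []
    for plex in plexes:
        ch = iter(channel_labels)
        for g in genotypes:
            for r in range(1, reps + 1):
                sample_rows.append((f"{g}_r{r}_{plex}", f"{g}_{plex}", r, plex, next(ch), False))
        sample_rows.append((f"REF_{plex}", None, 1, plex, next(ch), True))
    design = SampleDesign(
        pd.DataFrame(sample_rows, columns=["sample_id", "group", "replicate", "plex_id", "channel", "is_reference"])
    )

    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]
    gene_names = [f"GENE{i}" for i in range(n_proteins)]
    protein_base = rng.normal(25.0, 2.0, size=n_proteins)

    n_sites_per = rng.poisson(sites_per_protein, size=n_proteins)
    n_sites_per[n_sites_per == 0] = 1
    site_protein_idx = np.repeat(np.arange(n_proteins), n_sites_per)
    n_sites = len(site_protein_idx)
    positions = np.concatenate([rng.choice(np.arange(10, 800), size=c, replace=False) for c in n_sites_per])
    site_offset = rng.normal(-2.0, 1.0, size=n_sites)

    n_reg = int(round(frac_regulated * n_sites))
    reg_idx = rng.choice(n_sites, size=n_reg, replace=False)
    signs = np.where(rng.random(n_reg) < frac_down, -1.0, 1.0)
    magnitudes = rng.uniform(effect_range[0], effect_range[1], size=n_reg)
    effects = signs * magnitudes

    n_sq_reg = int(round(sq_frac * n_reg))
    windows = np.empty(n_sites, dtype=object)
    reg_windows = generate_sequence_windows(n_reg, n_sq_reg, seed=int(rng.integers(2**31)))
    windows[reg_idx] = reg_windows
    bg_idx = np.setdiff1d(np.arange(n_sites), reg_idx)
    n_sq_bg = int(round(background_sq_frac * len(bg_idx)))
    windows[bg_idx] = generate_sequence_windows(len(bg_idx), n_sq_bg, seed=int(rng.integers(2**31)))

    # per-sample true log2 signals (before batch / impurity distortion)
    non_ref = [s for s in design.sample_ids if not s.startswith("REF_")]
    effect_by_site = np.zeros(n_sites)
    effect_by_site[reg_idx] = effects
    prot_log2 = {}
    site_log2 = {}
    for s in non_ref:
        row = design.table.set_index("sample_id").loc[s]
        genotype = str(row["group"]).rsplit("_", 1)[0]
        treated = row["plex_id"] == "treated"
        p = protein_base + rng.normal(0.0, protein_noise_sd, size=n_proteins)
        factor = attenuation.get(genotype, 1.0) if genotype != "WT" else 1.0
        site_effect = effect_by_site * factor if treated else 0.0
        site = p[site_protein_idx] + site_offset + site_effect + rng.normal(0.0, noise_sd, size=n_sites)
        prot_log2[s] = p
        site_log2[s] = site

    impurity = default_impurity_matrix(len(channel_labels))
    batch = {p: float(2.0 ** rng.uniform(-1.0, 1.0)) for p in plexes}

    def assemble(values_by_sample: dict, n_feat: int) -> pd.DataFrame:
        # the reference is one pool mixed from every sample and split across
        # plexes, so its composition (per-feature linear mean of all samples)
        # is identical in both plexes before batch / impurity distortion
        ref = np.column_stack([2.0 ** values_by_sample[s] for s in non_ref]).mean(axis=1)
        cols = {}
        for plex in plexes:
            plex_samples = [s for s in design.samples_in_plex(plex) if not s.startswith("REF_")]
            lin = np.column_stack([2.0 ** values_by_sample[s] for s in plex_samples])
            full = np.column_stack([lin, ref]) * batch[plex]
            mixed = (impurity.matrix @ full.T).T
            for j, s in enumerate(plex_samples + [f"REF_{plex}"]):
                cols[s] = mixed[:, j]
        return pd.DataFrame(cols)

    prot_intens = assemble(prot_log2, n_proteins)
    prot_intens.index = pd.Index(protein_ids, name="feature_id")
    prot_meta = pd.DataFrame(
        {
            "gene_name": gene_names,
            "protein_ids": [[p] for p in protein_ids],
            "razor_unique_peptides": rng.poisson(10.0, size=n_proteins) + 2,
            "is_contaminant": False,
            "is_reverse": False,
        },
        index=prot_intens.index,
    )
    proteins = QuantTable(prot_intens, prot_meta, scale=LINEAR)

    site_keys = [f"{protein_ids[i]}_{positions[j]}_1" for j, i in enumerate(site_protein_idx)]
    site_intens = assemble(site_log2, n_sites)
    site_intens.index = pd.Index(site_keys, name="feature_id")
    site_meta = pd.DataFrame(
        {
            "gene_name": [gene_names[i] for i in site_protein_idx],
            "protein_ids": [[protein_ids[i]] for i in site_protein_idx],
            "protein_id": [protein_ids[i] for i in site_protein_idx],
            "razor_unique_peptides": 2,
            "is_contaminant": False,
            "is_reverse": False,
            "residue": "S",
            "position": positions,
            "sequence_window": windows,
            "localization_prob": rng.uniform(0.8, 1.0, size=n_sites),
            "multiplicity": 1,
            "multi_modified_flag": False,
        },
        index=site_intens.index,
    )
    sites = QuantTable(site_intens, site_meta, scale=LINEAR)

    reg_keys = [site_keys[j] for j in reg_idx]
    truth = SyntheticTruth(
        seed=seed,
        true_regulated_sites=pd.DataFrame(
            {
                "site_key": reg_keys,
                "log2_effect": effects,
                "direction": np.where(effects > 0, "up", "down"),
                "is_sq": [windows[j][15] == "S" and windows[j][16] == "Q" for j in reg_idx],
            }
        ),
        plex_batch_factors=batch,
    )
    return proteins, sites, design, impurity, truth
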