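"""TMT multi-plex arm: reporter-ion impurity correction, within-plex median
normalization, between-plex internal-reference scaling (IRS), and PTM-site to
protein normalization.

Isobaric labelling quantifies up to ten samples per MS run via reporter ions,
but each label leaks a known fraction of its signal into neighbouring
channels (isotopic impurity) — undone here by solving the linear mixing
system per feature.  Samples measured in different plexes are only comparable
through the shared reference channel (a pooled aliquot of all samples
labelled identically in every plex): IRS rescales each plex per feature so
the reference agrees across plexes, removing the multiplicative plex batch
effect.  Finally, PTM-site intensities are normalised to their parent
protein's abundance so that site-level group comparisons reflect changes in
modification stoichiometry rather than protein amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError, PtmQuantError
from .io_tables import LINEAR, LOG2, QuantTable, SampleDesign


@dataclass(frozen=True)
class ImpurityMatrix:
    """Channel cross-contamination: entry (i, j) is the fraction of channel
    j's true signal observed in channel i.  Columns sum to ~1."""

    channels: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (len(self.channels), len(self.channels)):
            raise ParameterError("impurity matrix must be square over the channel labels")
        if np.any(M < 0):
            raise ParameterError("impurity fractions must be non-negative")
        if np.any(np.diag(M) <= 0.5):
            raise ParameterError("impurity diagonal entries must exceed 0.5")
        if np.any(M.sum(axis=0) > 1.02):
            raise ParameterError("impurity columns must sum to <= 1.02")
        object.__setattr__(self, "matrix", M)

    @classmethod
    def identity(cls, channels) -> "ImpurityMatrix":
        return cls(tuple(channels), np.eye(len(channels)))


def read_impurity_matrix(path) -> ImpurityMatrix:
    t = pd.read_csv(path, sep="\t", index_col=0)
    return ImpurityMatrix(tuple(t.columns), t.to_numpy(dtype=float))


def write_impurity_matrix(imp: ImpurityMatrix, path) -> None:
    pd.DataFrame(imp.matrix, index=list(imp.channels), columns=list(imp.channels)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def correct_isotope_impurities(reporters, impurity: ImpurityMatrix):
    """Invert reporter-channel mixing: solve observed = M @ true per feature.

    ``reporters`` is a linear-scale features x channels matrix (ndarray or
    DataFrame) whose column order matches ``impurity.channels``.  Missing
    entries stay missing; negative solutions (over-subtraction of impurity
    from near-empty channels) are clamped to missing.
    """
    is_df = isinstance(reporters, pd.DataFrame)
    X = np.asarray(reporters, dtype=float)
    if X.shape[1] != len(impurity.channels):
        raise ParameterError("channel count mismatch between reporters and impurity matrix")
    M = impurity.matrix
    if np.linalg.cond(M) > 1e12:
        raise PtmQuantError("impurity matrix is numerically singular")
    nan_mask = ~np.isfinite(X)
    filled = np.where(nan_mask, 0.0, X)
    corrected = np.linalg.solve(M, filled.T).T
    corrected[nan_mask] = np.nan
    # distinguish float noise around zero from genuine over-subtraction
    tol = 1e-9 * np.nanmax(np.abs(filled), axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        corrected[corrected < -tol] = np.nan
        corrected[corrected < 0] = 0.0
    if is_df:
        return pd.DataFrame(corrected, index=reporters.index, columns=reporters.columns)
    return corrected


def median_normalize_within_plex(plex: QuantTable) -> QuantTable:
    """Shift each sample (log2 scale) so its observed median equals the
    plex-wide grand median (median of the per-sample medians); missingness
    and within-sample feature differences are unchanged."""
    if plex.scale != LOG2:
        raise ParameterError("median normalization operates on log2 intensities")
    medians = plex.intensities.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()][0]
        raise PtmQuantError(f"sample {bad!r} has no observed values")
    grand = float(medians.median())
    intens = plex.intensities - (medians - grand)
    return QuantTable(intens, plex.meta, scale=LOG2)


@dataclass
class PlexSet:
    """A multi-plex experiment: one QuantTable per plex (columns restricted to
    that plex's channels) sharing a feature universe, plus the design naming
    each plex's reference sample."""

    tables: dict
    design: SampleDesign

    def __post_init__(self) -> None:
        if not self.tables:
            raise DesignError("PlexSet requires at least one plex")
        scales = {t.scale for t in self.tables.values()}
        if len(scales) != 1:
            raise ParameterError("all plexes must share a scale")
        for plex_id in self.tables:
            self.design.reference_sample(plex_id)  # raises if absent

    @property
    def scale(self) -> str:
        return next(iter(self.tables.values())).scale

    @classmethod
    def from_table(cls, table: QuantTable, design: SampleDesign) -> "PlexSet":
        plexes = design.plex_ids
        if not plexes:
            raise DesignError("design declares no plexes")
        tables = {}
        for p in plexes:
            cols = [s for s in design.samples_in_plex(p) if s in table.samples]
            tables[p] = QuantTable(table.intensities[cols], table.meta, scale=table.scale)
        return cls(tables, design)


def irs_normalize(plexes: PlexSet) -> QuantTable:
    """Internal-reference scaling across plexes.

    Per feature, each plex is rescaled by (geometric mean of the feature's
    reference-channel intensities across plexes) / (this plex's reference
    intensity), so every feature's reference intensities agree across plexes
    afterwards.  Features lacking an observed reference value in any plex are
    dropped.  Returns the combined (all plexes' samples) table.
    """
    plex_ids = list(plexes.tables)
    log_scale = plexes.scale == LOG2
    refs = {}
    for p in plex_ids:
        ref_sample = plexes.design.reference_sample(p)
        tab = plexes.tables[p]
        if ref_sample not in tab.samples:
            raise DesignError(f"reference sample {ref_sample!r} missing from plex {p!r} table")
        refs[p] = tab.intensities[ref_sample]

    ref_df = pd.DataFrame(refs)
    keep = ref_df.notna().all(axis=1)
    if log_scale:
        anchor = ref_df.mean(axis=1)  # arithmetic mean of log2 = log2 geometric mean
    else:
        anchor = np.exp(np.log(ref_df).mean(axis=1))

    pieces = []
    for p in plex_ids:
        tab = plexes.tables[p]
        sub = tab.intensities.loc[keep]
        if log_scale:
            scaled = sub.add(anchor[keep] - ref_df.loc[keep, p], axis=0)
        else:
            scaled = sub.mul(anchor[keep] / ref_df.loc[keep, p], axis=0)
        pieces.append(scaled)
    combined = pd.concat(pieces, axis=1)
    meta = next(iter(plexes.tables.values())).meta.loc[keep]
    return QuantTable(combined, meta, scale=plexes.scale)


def normalize_sites_to_protein(sites: QuantTable, proteins: QuantTable) -> QuantTable:
    """Subtract parent-protein log2 intensity from each site, per sample.

    Sites whose parent protein (``protein_id`` in the site metadata) is not
    quantified in the protein table are dropped.  Afterwards a site's group
    difference reflects modification stoichiometry, not protein abundance.
    """
    if sites.scale != LOG2 or proteins.scale != LOG2:
        raise ParameterError("site/protein normalization operates on log2 intensities")
    shared = [s for s in sites.samples if s in proteins.samples]
    if not shared:
        raise DesignError("no overlapping samples between site and protein tables")
    if "protein_id" not in sites.meta.columns:
        raise ParameterError("site metadata lacks 'protein_id'")
    parents = sites.meta["protein_id"]
    have = parents.isin(proteins.feature_ids)
    keep = sites.feature_ids[have]
    prot = proteins.intensities.loc[parents[have].to_numpy(), shared]
    prot.index = keep
    intens = sites.intensities.loc[keep, shared] - prot
    return QuantTable(intens, sites.meta.loc[keep], scale=LOG2)
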