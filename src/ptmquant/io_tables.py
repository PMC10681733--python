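"""Quantification-table I/O, feature filtering and scale transforms.

The tables handled here follow the MaxQuant output dialect: a protein-groups
table with one ``LFQ intensity <sample>`` (or ``Reporter intensity corrected
<k> <sample>``) column per sample, and PTM-site tables (``Phospho (STY)
Sites``, ``Acetyl (K) Sites``) whose intensity columns carry a multiplicity
suffix (``___1``/``___2``/``___3``).  All tables are held in memory as a
:class:`QuantTable`: a features x samples intensity matrix (``NaN`` marks a
missing value; MaxQuant's literal zeros are converted to missing on read,
because a zero means "not quantified", not "absent at zero abundance") plus
per-feature metadata and an explicit linear/log2 scale tag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, ParameterError, ScaleError

LINEAR = "linear"
LOG2 = "log2"

# Canonical MaxQuant column names, with accepted aliases per dialect.
_META_ALIASES = {
    "Majority protein IDs": ["Majority protein IDs", "Protein IDs", "Protein"],
    "Gene names": ["Gene names", "Gene Names", "Gene name"],
    "Razor + unique peptides": ["Razor + unique peptides"],
    "Reverse": ["Reverse"],
    "Potential contaminant": ["Potential contaminant", "Contaminant"],
    "Amino acid": ["Amino acid"],
    "Position": ["Position", "Positions within proteins"],
    "Sequence window": ["Sequence window", "Sequence Window"],
    "Localization prob": ["Localization prob", "Localization probability"],
}

_INTENSITY_PREFIXES = ("LFQ intensity ", "Reporter intensity corrected ", "Intensity ")
_SITE_SUFFIX_RE = re.compile(r"^(.*)___([0-9]+)$")


@dataclass
class QuantTable:
    """Features x samples intensity matrix with feature metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by unique feature id, one column per sample,
        ``NaN`` for missing values.  On the linear scale all finite entries
        are non-negative.
    meta
        DataFrame sharing the intensity index.  For protein groups it carries
        ``gene_name``, ``protein_ids`` (list of accessions), ``razor_unique_peptides``,
        ``is_contaminant`` and ``is_reverse``; site tables add ``residue``,
        ``position``, ``sequence_window``, ``multiplicity`` and
        ``localization_prob``.
    scale
        ``"linear"`` or ``"log2"``.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if not self.intensities.index.is_unique:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise FormatError(f"duplicate feature ids: {sorted(map(str, dups))}")
        if not self.intensities.index.equals(self.meta.index):
            raise FormatError("intensity and metadata indices disagree")
        vals = self.intensities.to_numpy(dtype=float)
        if self.scale == LINEAR and np.nanmin(vals, initial=0.0) < 0:
            raise ParameterError("linear-scale intensities must be non-negative")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def subset(self, feature_ids) -> "QuantTable":
        return replace(
            self,
            intensities=self.intensities.loc[feature_ids],
            meta=self.meta.loc[feature_ids],
        )

    def copy(self) -> "QuantTable":
        return replace(self, intensities=self.intensities.copy(), meta=self.meta.copy())


@dataclass
class SampleDesign:
    """Sample annotation: group, replicate, and optional plex/channel layout.

    ``table`` has columns ``sample_id``, ``group``, ``replicate``, ``plex_id``,
    ``channel``, ``is_reference``.  Reference samples are pooled-aliquot
    channels shared between plexes; they carry no experimental group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "group"]
        for col in required:
            if col not in t.columns:
                raise DesignError(f"sample design lacks column {col!r}")
        for col, default in (("replicate", 1), ("plex_id", None), ("channel", None), ("is_reference", False)):
            if col not in t.columns:
                t = t.assign(**{col: default})
        t = t.copy()
        t["is_reference"] = t["is_reference"].astype(bool)
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample ids in design")
        if t.loc[~t["is_reference"], "group"].isna().any():
            raise DesignError("non-reference sample without group")
        if t["plex_id"].notna().any():
            for plex, sub in t.groupby("plex_id"):
                if int(sub["is_reference"].sum()) != 1:
                    raise DesignError(f"plex {plex!r} must contain exactly one reference sample")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        g = self.table.loc[~self.table["is_reference"], "group"]
        return list(pd.unique(g.dropna()))

    def samples_in_group(self, group: str) -> list[str]:
        sub = self.table[(self.table["group"] == group) & ~self.table["is_reference"]]
        return list(sub["sample_id"])

    @property
    def plex_ids(self) -> list[str]:
        p = self.table["plex_id"].dropna()
        return list(pd.unique(p))

    def samples_in_plex(self, plex_id: str) -> list[str]:
        return list(self.table.loc[self.table["plex_id"] == plex_id, "sample_id"])

    def reference_sample(self, plex_id: str) -> str:
        sub = self.table[(self.table["plex_id"] == plex_id) & self.table["is_reference"]]
        if len(sub) != 1:
            raise DesignError(f"plex {plex_id!r} has no unique reference sample")
        return str(sub["sample_id"].iloc[0])

    def subset(self, sample_ids) -> "SampleDesign":
        keep = self.table[self.table["sample_id"].isin(list(sample_ids))]
        return SampleDesign(keep.reset_index(drop=True))


@dataclass(frozen=True)
class ThresholdConfig:
    """Fold-change / FDR cutoffs used for enrichment and regulation calls.

    ``fc_cutoff`` is interpreted on ``fc_scale``: a linear fold change
    (e.g. 1.5 means |log2 FC| >= log2 1.5) or directly in log2 units.
    """

    fc_cutoff: float
    fdr_cutoff: float
    fc_scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0 or self.fdr_cutoff <= 0:
            raise ParameterError("cutoffs must be strictly positive")
        if self.fdr_cutoff >= 1:
            raise ParameterError("fdr_cutoff must be < 1")
        if self.fc_scale not in (LINEAR, LOG2):
            raise ParameterError(f"unknown fc_scale {self.fc_scale!r}")
        if self.fc_scale == LINEAR and self.fc_cutoff <= 1:
            raise ParameterError("linear fold-change cutoff must exceed 1")

    @property
    def log2_fc_cutoff(self) -> float:
        return float(np.log2(self.fc_cutoff)) if self.fc_scale == LINEAR else float(self.fc_cutoff)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _resolve(columns, canonical: str) -> str | None:
    for alias in _META_ALIASES[canonical]:
        if alias in columns:
            return alias
    return None


def _intensity_columns(columns) -> list[tuple[str, str, int | None]]:
    """Return (column, sample_id, multiplicity) for every intensity column."""
    out = []
    for col in columns:
        for prefix in _INTENSITY_PREFIXES:
            if col.startswith(prefix) and len(col) > len(prefix):
                rest = col[len(prefix):]
                m = _SITE_SUFFIX_RE.match(rest)
                if m:
                    out.append((col, m.group(1), int(m.group(2))))
                else:
                    out.append((col, rest, None))
                break
    return out


def _plus_flag(series: pd.Series | None, n: int) -> np.ndarray:
    if series is None:
        return np.zeros(n, dtype=bool)
    return series.fillna("").astype(str).str.strip().eq("+").to_numpy()


def read_quant_table(path, dialect: str = "protein_groups") -> QuantTable:
    """Parse a MaxQuant-dialect TSV into a linear-scale :class:`QuantTable`.

    Empty intensity cells and literal zeros become missing.  For the
    ``site_table`` dialect each multiplicity state of a site is expanded into
    an independent feature keyed ``<accession>_<position>_<multiplicity>``;
    states with no quantified sample are dropped.
    """
    if dialect not in ("protein_groups", "site_table"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    icols = _intensity_columns(raw.columns)
    if not icols:
        raise FormatError(
            "no intensity columns found; expected at least one column such as "
            f"'{_INTENSITY_PREFIXES[0]}<sample>'"
        )
    n = len(raw)

    ids_col = _resolve(raw.columns, "Majority protein IDs")
    if ids_col is None:
        raise FormatError("missing column 'Majority protein IDs'")
    protein_ids = [s.split(";") if s else [] for s in raw[ids_col]]
    lead = [ids[0] if ids else f"feature{i}" for i, ids in enumerate(protein_ids)]

    gene_col = _resolve(raw.columns, "Gene names")
    genes = raw[gene_col] if gene_col else pd.Series([""] * n)
    razor_col = _resolve(raw.columns, "Razor + unique peptides")
    razor = (
        pd.to_numeric(raw[razor_col].replace("", "0"), errors="coerce").fillna(0).astype(int)
        if razor_col
        else pd.Series(np.zeros(n, dtype=int))
    )
    rev_col = _resolve(raw.columns, "Reverse")
    con_col = _resolve(raw.columns, "Potential contaminant")

    meta = pd.DataFrame(
        {
            "gene_name": genes.to_numpy(dtype=object),
            "protein_ids": protein_ids,
            "razor_unique_peptides": razor.to_numpy(),
            "is_reverse": _plus_flag(raw[rev_col] if rev_col else None, n),
            "is_contaminant": _plus_flag(raw[con_col] if con_col else None, n),
        }
    )

    def numeric(col: str) -> np.ndarray:
        v = pd.to_numeric(raw[col].mask(raw[col] == ""), errors="coerce").to_numpy(dtype=float)
        v[v == 0.0] = np.nan  # MaxQuant zero means not quantified
        return v

    if dialect == "protein_groups":
        samples = list(dict.fromkeys(s for _, s, _ in icols))
        data = {s: None for s in samples}
        for col, s, mult in icols:
            if mult is not None:
                raise FormatError(f"multiplicity-suffixed column {col!r} in protein_groups table")
            data[s] = numeric(col)
        intens = pd.DataFrame(data, index=pd.Index(lead, name="feature_id"))
        if not intens.index.is_unique:
            dups = sorted(intens.index[intens.index.duplicated()].unique())
            raise FormatError(f"duplicate feature ids: {dups}")
        return QuantTable(intens, meta.set_index(intens.index), scale=LINEAR)

    # site_table: expand multiplicities
    aa_col = _resolve(raw.columns, "Amino acid")
    pos_col = _resolve(raw.columns, "Position")
    win_col = _resolve(raw.columns, "Sequence window")
    loc_col = _resolve(raw.columns, "Localization prob")
    if pos_col is None:
        raise FormatError("missing column 'Position'")
    positions = pd.to_numeric(raw[pos_col], errors="coerce").astype("Int64")
    mults = sorted({m for _, _, m in icols if m is not None})
    if not mults:
        raise FormatError("site_table dialect requires '___<multiplicity>' intensity columns")
    samples = list(dict.fromkeys(s for _, s, _ in icols))

    rows, metas = [], []
    for m in mults:
        cols = {s: c for c, s, mm in icols if mm == m}
        mat = np.column_stack([numeric(cols[s]) if s in cols else np.full(n, np.nan) for s in samples])
        for i in range(n):
            if np.all(np.isnan(mat[i])):
                continue
            acc = lead[i]
            pos = positions.iloc[i]
            key = f"{acc}_{pos}_{m}"
            rows.append((key, mat[i]))
            metas.append(
                {
                    "feature_id": key,
                    "gene_name": genes.iloc[i],
                    "protein_ids": protein_ids[i],
                    "razor_unique_peptides": int(razor.iloc[i]),
                    "is_reverse": bool(_plus_flag(raw[rev_col] if rev_col else None, n)[i]),
                    "is_contaminant": bool(_plus_flag(raw[con_col] if con_col else None, n)[i]),
                    "protein_id": acc,
                    "residue": raw[aa_col].iloc[i] if aa_col else "",
                    "position": int(pos) if pd.notna(pos) else -1,
                    "sequence_window": raw[win_col].iloc[i] if win_col else "",
                    "localization_prob": float(raw[loc_col].iloc[i]) if loc_col and raw[loc_col].iloc[i] else np.nan,
                    "multiplicity": m,
                    "multi_modified_flag": m >= 2,
                }
            )
    if not rows:
        raise FormatError("site table contains no quantified site/multiplicity states")
    index = pd.Index([k for k, _ in rows], name="feature_id")
    if not index.is_unique:
        dups = sorted(index[index.duplicated()].unique())
        raise FormatError(f"duplicate feature ids: {dups}")
    intens = pd.DataFrame(np.vstack([v for _, v in rows]), index=index, columns=samples)
    meta = pd.DataFrame(metas).set_index("feature_id")
    return QuantTable(intens, meta, scale=LINEAR)


def write_quant_table(table: QuantTable, path, dialect: str = "protein_groups") -> None:
    """Write a QuantTable back to its TSV dialect (missing -> empty cell)."""
    if dialect not in ("protein_groups", "site_table"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    meta = table.meta
    out = pd.DataFrame(
        {
            "Majority protein IDs": [";".join(p) if isinstance(p, (list, tuple)) and p else str(i)
                                     for i, p in zip(table.feature_ids, meta.get("protein_ids", [[]] * len(meta)))],
            "Gene names": meta.get("gene_name", pd.Series("", index=meta.index)).to_numpy(dtype=object),
            "Razor + unique peptides": meta.get("razor_unique_peptides", pd.Series(0, index=meta.index)).to_numpy(),
            "Reverse": np.where(meta.get("is_reverse", pd.Series(False, index=meta.index)).to_numpy(dtype=bool), "+", ""),
            "Potential contaminant": np.where(meta.get("is_contaminant", pd.Series(False, index=meta.index)).to_numpy(dtype=bool), "+", ""),
        }
    )
    if dialect == "site_table":
        for src, dst in (("residue", "Amino acid"), ("position", "Position"),
                         ("sequence_window", "Sequence window"), ("localization_prob", "Localization prob")):
            if src in meta.columns:
                out[dst] = meta[src].to_numpy()
        mult = meta["multiplicity"].to_numpy() if "multiplicity" in meta.columns else np.ones(len(meta), dtype=int)
        for s in table.samples:
            for m in sorted(set(int(x) for x in mult)):
                col = np.where(mult == m, table.intensities[s].to_numpy(dtype=float), np.nan)
                out[f"Intensity {s}___{m}"] = [_fmt(v) for v in col]
    else:
        prefix = "LFQ intensity " if table.scale == LINEAR else "LFQ intensity "
        for s in table.samples:
            out[prefix + s] = [_fmt(v) for v in table.intensities[s].to_numpy(dtype=float)]
    out.to_csv(path, sep="\t", index=False)


def _fmt(v: float) -> str:
    return "" if not np.isfinite(v) else f"{v:.10g}"


def read_sample_design(path) -> SampleDesign:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    t = t.replace("", None)
    if "replicate" in t.columns:
        t["replicate"] = pd.to_numeric(t["replicate"], errors="coerce").fillna(1).astype(int)
    if "is_reference" in t.columns:
        t["is_reference"] = t["is_reference"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes", "+"))
    return SampleDesign(t)


def write_sample_design(design: SampleDesign, path) -> None:
    t = design.table.copy()
    t["is_reference"] = t["is_reference"].map(lambda b: "1" if b else "0")
    t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature filtering and scale transforms
# ---------------------------------------------------------------------------

def filter_features(
    table: QuantTable,
    min_razor_unique: int = 2,
    drop_contaminants: bool = True,
    drop_reverse: bool = True,
) -> QuantTable:
    """Apply the standard feature filters: peptide-count evidence >=
    ``min_razor_unique``, no potential contaminants, no reverse (decoy) hits.
    Row order is preserved; the operation is idempotent."""
    if min_razor_unique < 0:
        raise ParameterError("min_razor_unique must be non-negative")
    meta = table.meta
    keep = meta.get("razor_unique_peptides", pd.Series(0, index=meta.index)).to_numpy() >= min_razor_unique
    if drop_contaminants and "is_contaminant" in meta.columns:
        keep &= ~meta["is_contaminant"].to_numpy(dtype=bool)
    if drop_reverse and "is_reverse" in meta.columns:
        keep &= ~meta["is_reverse"].to_numpy(dtype=bool)
    return table.subset(table.feature_ids[keep])


def log2_transform(table: QuantTable) -> QuantTable:
    """Move a linear-scale table to log2.  Zeros (already stored as missing)
    and missing entries stay missing; positive entries become log2(x)."""
    if table.scale == LOG2:
        raise ScaleError("table is already on log2 scale")
    vals = table.values().copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(vals > 0, np.log2(vals), np.nan)
    intens = pd.DataFrame(vals, index=table.feature_ids, columns=table.samples)
    return QuantTable(intens, table.meta, scale=LOG2)


def delog2_transform(table: QuantTable) -> QuantTable:
    """Inverse of :func:`log2_transform` (missing stays missing)."""
    if table.scale == LINEAR:
        raise ScaleError("table is already on linear scale")
    vals = np.power(2.0, table.values())
    intens = pd.DataFrame(vals, index=table.feature_ids, columns=table.samples)
    return QuantTable(intens, table.meta, scale=LINEAR)
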