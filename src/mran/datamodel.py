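"""Core data types, file IO, compositional normalization and prevalence filtering.

The pipeline consumes a *processed* community table: samples (site, depth,
year-month) by features, where features are OTU relative abundances plus
environmental variables (temperature, chl-a, nutrients, ...).  Environmental
columns ride along in the same table, classed separately, so the network
stage can treat them as nodes next to the OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CYANOBACTERIAL",
    "NON_CYANOBACTERIAL",
    "ENVIRONMENTAL",
    "ParseError",
    "ValidationError",
    "SampleKey",
    "TaxonomyMap",
    "AbundanceTable",
    "SeriesSet",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "prevalence_filter",
    "split_partitions",
    "split_series",
]

CYANOBACTERIAL = "cyanobacterial"
NON_CYANOBACTERIAL = "non_cyanobacterial"
ENVIRONMENTAL = "environmental"

_META_COLUMNS = ("site", "depth", "date")


class ParseError(ValueError):
    """A file could not be parsed into the expected layout."""


class ValidationError(ValueError):
    """Parsed data violates a structural invariant."""


class SampleKey(NamedTuple):
    """Identity of one water sample: site, depth (m) and year-month."""

    site: str
    depth: float
    date: str  # "YYYY-MM"


def _normalize_date(raw) -> str:
    """Truncate any parseable timestamp to year-month resolution."""
    try:
        return str(pd.Period(str(raw), freq="M"))
    except Exception as exc:  # pragma: no cover - pandas raises many types
        raise ParseError(f"unparseable date {raw!r}") from exc


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (phylum..genus), as free-text labels."""

    lineages: dict[str, tuple[str, ...]]

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return self.lineages.get(otu_id, ("unclassified",))

    def is_cyanobacterial(self, otu_id: str) -> bool:
        return any("cyanobacteria" == r.strip().lower() for r in self.lineage(otu_id))


@dataclass
class AbundanceTable:
    """Samples x features matrix with per-feature class labels.

    ``data`` is indexed by a (site, depth, date) MultiIndex; OTU columns hold
    relative abundances in [0, 1] (fractions of the *original* whole
    community — filtering never renormalizes), environmental columns hold
    raw measurements on their own scales.
    """

    data: pd.DataFrame
    feature_class: pd.Series  # feature -> one of the three class constants

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature identifiers: {dups}")
        missing = set(self.data.columns) - set(self.feature_class.index)
        if missing:
            raise ValidationError(f"features without a class label: {sorted(missing)}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample keys: {dups}")

    # -- feature views -------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def otu_features(self) -> list[str]:
        return [f for f in self.data.columns if self.feature_class[f] != ENVIRONMENTAL]

    @property
    def env_features(self) -> list[str]:
        return [f for f in self.data.columns if self.feature_class[f] == ENVIRONMENTAL]

    @property
    def cyano_features(self) -> list[str]:
        return [f for f in self.data.columns if self.feature_class[f] == CYANOBACTERIAL]

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(s, float(d), str(m)) for s, d, m in self.data.index]

    def subset_features(self, features: Sequence[str]) -> "AbundanceTable":
        feats = list(features)
        return AbundanceTable(self.data[feats].copy(), self.feature_class[feats].copy())

    def validate_closure(self, tol: float = 1e-9) -> None:
        """Check per-sample OTU fractions sum to one (pre-filter tables only)."""
        otus = self.otu_features
        sums = self.data[otus].sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=tol):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"sample {self.samples[bad]} OTU fractions sum to {sums[bad]!r}, not 1"
            )


@dataclass
class SeriesSet:
    """The monthly series of one (site, depth): an AbundanceTable slice sorted by date."""

    key: tuple[str, float]
    table: AbundanceTable
    missing_months: list[str] = field(default_factory=list)

    @property
    def dates(self) -> list[str]:
        return [k.date for k in self.table.samples]


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------

def _classify_features(
    otu_columns: Iterable[str], taxonomy: TaxonomyMap | None
) -> dict[str, str]:
    classes = {}
    for f in otu_columns:
        if taxonomy is not None and taxonomy.is_cyanobacterial(f):
            classes[f] = CYANOBACTERIAL
        else:
            classes[f] = NON_CYANOBACTERIAL
    return classes


def read_abundance_table(
    path,
    dialect: str = "tsv",
    metadata=None,
    taxonomy: TaxonomyMap | None = None,
    env_features: Sequence[str] = (),
) -> AbundanceTable:
    """Read a samples x features table and convert counts to relative abundances.

    Parameters
    ----------
    path:
        Tab-separated file.  For ``dialect="tsv"`` the first three columns
        must be ``site``, ``depth``, ``date`` (ISO year-month) followed by
        one column per feature.  For ``dialect="mothur_shared"`` the usual
        ``label``/``Group``/``numOtus`` leading columns are expected and
        ``metadata`` (a TSV with columns group, site, depth, date) maps each
        Group to its sample key.
    env_features:
        Column names to class as environmental (kept on their raw scale and
        excluded from the sum-to-one closure).
    taxonomy:
        When given, OTUs whose lineage contains the phylum *Cyanobacteria*
        are classed cyanobacterial; otherwise every OTU defaults to
        non-cyanobacterial.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(
                f"{path}: header line 1 lacks required column(s) {missing}; "
                f"found {list(df.columns)[:6]}"
            )
    elif dialect == "mothur_shared":
        shared = pd.read_csv(path, sep="\t")
        for col in ("label", "Group", "numOtus"):
            if col not in shared.columns:
                raise ParseError(f"{path}: not a mothur shared file (missing {col!r})")
        if metadata is None:
            raise ParseError("mothur_shared dialect requires a sample metadata file")
        meta = pd.read_csv(metadata, sep="\t")
        meta.columns = [c.lower() for c in meta.columns]
        meta = meta.set_index("group")
        df = shared.drop(columns=["label", "numOtus"])
        df = df.rename(columns={"Group": "group"})
        for col in _META_COLUMNS:
            df[col] = df["group"].map(meta[col])
        df = df.drop(columns=["group"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df["date"] = [_normalize_date(d) for d in df["date"]]
    df["depth"] = df["depth"].astype(float)
    keys = list(zip(df["site"].astype(str), df["depth"], df["date"]))
    seen: set = set()
    for k in keys:
        if k in seen:
            raise ValidationError(f"duplicate sample key {SampleKey(*k)}")
        seen.add(k)

    values = df.drop(columns=list(_META_COLUMNS))
    values.index = pd.MultiIndex.from_tuples(keys, names=_META_COLUMNS)
    values = values.astype(float)

    env = [c for c in env_features if c in values.columns]
    otu_cols = [c for c in values.columns if c not in env]
    otus = values[otu_cols]
    if (otus.to_numpy() < 0).any():
        bad = otus.columns[(otus < 0).any(axis=0)].tolist()
        raise ValidationError(f"negative abundance values in feature(s) {bad}")
    row_sums = otus.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValidationError("a sample has zero total OTU count")
    values[otu_cols] = otus.div(row_sums, axis=0)

    classes = _classify_features(otu_cols, taxonomy)
    classes.update({c: ENVIRONMENTAL for c in env})
    return AbundanceTable(values, pd.Series(classes, dtype=object))


def write_abundance_table(table: AbundanceTable, path) -> None:
    """TSV writer; round-trips values to 12 significant digits."""
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_taxonomy(path) -> TaxonomyMap:
    """Two-column TSV: otu_id <tab> semicolon-separated lineage."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected otu_id and lineage columns")
    lineages = {
        str(r[0]): tuple(p.strip() for p in str(r[1]).split(";") if p.strip())
        for r in df.itertuples(index=False)
    }
    return TaxonomyMap(lineages)


# ----------------------------------------------------------------------
# Filtering and partitioning
# ----------------------------------------------------------------------

def prevalence_filter(
    table: AbundanceTable,
    min_prevalence: float = 0.20,
    detection_threshold: float = 0.0,
) -> AbundanceTable:
    """Keep features occurring in at least ``min_prevalence`` of samples.

    A feature "occurs" in a sample when its value is strictly greater than
    ``detection_threshold``.  Environmental features are always retained.
    Relative abundances are *not* renormalized afterwards: retained OTUs stay
    fractions of the original whole community.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    n = len(table.data)
    keep = []
    for f in table.features:
        if table.feature_class[f] == ENVIRONMENTAL:
            keep.append(f)
            continue
        occ = (table.data[f].to_numpy() > detection_threshold).sum()
        if occ / n >= min_prevalence:
            keep.append(f)
    if not [f for f in keep if table.feature_class[f] != ENVIRONMENTAL]:
        raise ValidationError(
            f"no features retained at min_prevalence={min_prevalence}"
        )
    return table.subset_features(keep)


def split_partitions(
    table: AbundanceTable, renormalize: bool = False
) -> tuple[AbundanceTable, AbundanceTable]:
    """Split the OTU features into cyanobacterial / non-cyanobacterial tables.

    Environmental columns belong to neither partition.  With
    ``renormalize=True`` each partition's rows are rescaled to within-
    partition proportions; by default values are copied unchanged.
    """
    cyano = [f for f in table.features if table.feature_class[f] == CYANOBACTERIAL]
    non = [f for f in table.features if table.feature_class[f] == NON_CYANOBACTERIAL]
    if not non:
        warnings.warn("non-cyanobacterial partition is empty")
    if not cyano:
        warnings.warn("cyanobacterial partition is empty")
    parts = []
    for feats in (cyano, non):
        sub = table.subset_features(feats)
        if renormalize and feats:
            sums = sub.data.sum(axis=1)
            sums = sums.replace(0.0, np.nan)
            sub.data = sub.data.div(sums, axis=0).fillna(0.0)
        parts.append(sub)
    return parts[0], parts[1]


def split_series(table: AbundanceTable) -> list[SeriesSet]:
    """One SeriesSet per (site, depth), ordered by date, with gap bookkeeping."""
    out = []
    for (site, depth), idx in sorted(
        table.data.groupby(level=["site", "depth"]).groups.items()
    ):
        sub = table.data.loc[list(idx)].sort_index(level="date")
        if len(sub) < 2:
            raise ValidationError(
                f"series ({site}, {depth}) has fewer than 2 time points"
            )
        sub_table = AbundanceTable(sub, table.feature_class.copy())
        dates = [pd.Period(d, freq="M") for d in sub.index.get_level_values("date")]
        full = pd.period_range(dates[0], dates[-1], freq="M")
        missing = [str(m) for m in full if m not in set(dates)]
        out.append(SeriesSet((site, float(depth)), sub_table, missing))
    return out
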