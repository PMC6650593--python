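"""Collapse taxon abundances into functional-group abundances.

A FAPROTAX-style mapping assigns ecological functions (nitrate reduction,
fermentation, ureolysis, ...) to taxa by name.  OTUs are matched through
their taxonomy lineage: an OTU belongs to a function when any of its rank
labels (or its own id) exactly equals one of the function's taxon
selectors.  OTUs mapped to several functions contribute fully to each; the
full reference database is not redistributed here — a small synthetic toy
mapping ships for tests and examples, and any real mapping file can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, NON_CYANOBACTERIAL, TaxonomyMap, ValidationError
from .modules import ModulePartition

__all__ = [
    "FunctionMap",
    "FunctionTable",
    "read_function_map",
    "toy_function_map",
    "collapse_functions",
    "normalize_function_table",
]


@dataclass
class FunctionMap:
    """Function label -> set of taxon selectors (rank names or OTU ids)."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [f for f, sel in self.mapping.items() if not sel]
        if empty:
            raise ValidationError(f"function(s) with empty selector sets: {empty}")

    @property
    def functions(self) -> list[str]:
        return list(self.mapping)

    def matches(self, otu_id: str, lineage: tuple[str, ...]) -> list[str]:
        pool = set(lineage) | {otu_id}
        return [f for f, sel in self.mapping.items() if pool & sel]


@dataclass
class FunctionTable:
    """Function x group matrix (group = (module, month) or (module, sample))."""

    values: pd.DataFrame
    normalization: str = "none"


def read_function_map(path) -> FunctionMap:
    """Parse a function mapping file.

    Two layouts are accepted: a two-column TSV (``function <tab> selector``,
    one selector per line), or a grouped layout where an unindented line
    starts a function and each following indented line is one selector.
    Lines starting with ``#`` are comments.
    """
    mapping: dict[str, set[str]] = {}
    current: str | None = None
    grouped = False
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line[0] in " \t":
            if current is None:
                raise ValidationError("selector line before any function header")
            grouped = True
            mapping[current].add(line.strip())
            continue
        parts = [p.strip() for p in line.split("\t") if p.strip()]
        if len(parts) >= 2 and not grouped:
            mapping.setdefault(parts[0], set()).add(parts[1])
            current = parts[0]
        else:
            current = parts[0]
            mapping.setdefault(current, set())
    return FunctionMap({f: frozenset(s) for f, s in mapping.items()})


def toy_function_map() -> FunctionMap:
    """The bundled synthetic toy mapping (for tests and examples)."""
    with resources.as_file(
        resources.files("mran").joinpath("data/toy_functions.tsv")
    ) as p:
        return read_function_map(p)


def collapse_functions(
    table: AbundanceTable,
    partition: ModulePartition,
    fmap: FunctionMap,
    taxonomy: TaxonomyMap,
    modules: list[int] | None = None,
    by: str = "month",
    otu_class: str | None = NON_CYANOBACTERIAL,
) -> FunctionTable:
    """Function x (module, month) table of summed member-OTU abundances.

    For each module and sample, a function's value is the sum of the
    relative abundances of the module's member OTUs mapped to that function
    (multi-function OTUs count fully in each; unmapped OTUs count nowhere),
    i.e. the module's function composition scaled by the module's total OTU
    abundance.  ``by="month"`` averages samples sharing a year-month;
    ``by="sample"`` keeps one column per sample.  Functions with no mapped
    member present are explicit zero rows.
    """
    if not fmap.mapping:
        raise ValidationError("empty function map")
    if by not in ("month", "sample"):
        raise ValueError("by must be 'month' or 'sample'")
    labels = modules if modules is not None else sorted(set(partition.labels.values()))
    functions = fmap.functions
    unmapped = []
    columns = {}
    dates = table.data.index.get_level_values("date")
    for label in labels:
        members = [
            f for f in partition.members(label)
            if f in table.data.columns
            and (otu_class is None or table.feature_class[f] == otu_class)
        ]
        per_func = pd.DataFrame(
            0.0, index=table.data.index, columns=functions
        )
        for otu in members:
            lineage = taxonomy.lineage(otu)
            if lineage == ("unclassified",) and otu not in taxonomy.lineages:
                unmapped.append(otu)
            hits = fmap.matches(otu, lineage)
            if not hits:
                unmapped.append(otu)
            for f in hits:
                per_func[f] += table.data[otu]
        if by == "month":
            grouped = per_func.groupby(dates).mean()
            for month, row in grouped.iterrows():
                columns[(label, month)] = row
        else:
            for key, row in per_func.iterrows():
                columns[(label, key)] = row
    if unmapped:
        import warnings

        warnings.warn(
            f"{len(set(unmapped))} OTU(s) map to no function and were ignored"
        )
    out = pd.DataFrame(columns)
    out.index.name = "function"
    return FunctionTable(out, "none")


def normalize_function_table(ftable: FunctionTable, mode: str = "none") -> FunctionTable:
    """Rescale a function table for display or comparison.

    ``none`` returns the input; ``per_group_fraction`` divides each column
    by its sum (zero-safe); ``min_max_per_function`` scales each function
    row to [0, 1].
    """
    v = ftable.values
    if mode == "none":
        return FunctionTable(v.copy(), "none")
    if mode == "per_group_fraction":
        sums = v.sum(axis=0).replace(0.0, np.nan)
        return FunctionTable(v.div(sums, axis=1).fillna(0.0), mode)
    if mode == "min_max_per_function":
        rng = (v.max(axis=1) - v.min(axis=1)).replace(0.0, np.nan)
        scaled = v.sub(v.min(axis=1), axis=0).div(rng, axis=0).fillna(0.0)
        return FunctionTable(scaled, mode)
    raise ValueError(f"unknown normalization mode {mode!r}")
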