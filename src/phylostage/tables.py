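"""Per-species developmental expression tables and BRI resampling.

An :class:`ExpressionTable` holds TPM-scale expression of ortholog groups
for one species, indexed group x (stage, replicate).  The on-disk layout is
a TSV whose first column is ``group_id`` and whose remaining headers are
``stage:replicate`` labels; stage order follows first appearance in the
header, exactly as written.

BRI ("biological replicate included") tables are built by picking one
replicate uniformly at random per (species, stage); a set of B such tables
quantifies how sensitive the conservation statistic is to replicate choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "ExpressionTable",
    "BRITable",
    "read_expression_table",
    "write_expression_table",
    "restrict_to_shared_groups",
    "bri_resample",
]


@dataclass
class ExpressionTable:
    """TPM-scale expression values for one species.

    ``data`` has the ortholog-group ids as index and a two-level column
    MultiIndex ``(stage, replicate)``.  Stage order is the column order.
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
            raise FormatError("expression columns must be a (stage, replicate) MultiIndex")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate group ids in table for {self.species}: {dups}")
        if df.columns.duplicated().any():
            raise FormatError(f"duplicate stage:replicate columns for {self.species}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric expression values for {self.species}")
        if np.isnan(values).any():
            raise FormatError(f"missing values (ragged rows?) in table for {self.species}")
        if (values < 0).any():
            raise FormatError(f"negative expression values in table for {self.species}")

    # -- accessors -------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for stage, _ in self.data.columns:
            if stage not in seen:
                seen.append(stage)
        return seen

    def replicates(self, stage: str) -> list[str]:
        return [rep for st, rep in self.data.columns if st == stage]

    def stage_values(self, stage: str, replicate: str) -> np.ndarray:
        return self.data[(stage, replicate)].to_numpy(dtype=float)

    def stage_mean(self, stage: str) -> np.ndarray:
        """Replicate-averaged expression profile of one stage."""
        return self.data[stage].to_numpy(dtype=float).mean(axis=1)

    def with_groups(self, groups: Sequence[str]) -> "ExpressionTable":
        return ExpressionTable(self.species, self.data.loc[list(groups)])


@dataclass
class BRITable:
    """One replicate-included table: a single replicate per (species, stage).

    ``vectors[species]`` is a groups x stages frame of the chosen replicate's
    values; ``provenance[(species, stage)]`` records which replicate was
    picked, so any BRI table can be reconstructed from its parents.
    """

    index: int
    species: tuple[str, ...]
    vectors: dict[str, pd.DataFrame]
    provenance: dict[tuple[str, str], str]

    def stage_vector(self, species: str, stage: str) -> np.ndarray:
        return self.vectors[species][stage].to_numpy(dtype=float)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _parse_header(columns: Iterable[str]) -> pd.MultiIndex:
    pairs = []
    for col in columns:
        if ":" not in col:
            raise FormatError(f"header column {col!r} is not of the form stage:replicate")
        stage, _, rep = col.partition(":")
        pairs.append((stage, rep))
    return pd.MultiIndex.from_tuples(pairs, names=["stage", "replicate"])


def read_expression_table(path: str | Path, species: str) -> ExpressionTable:
    """Read a ``group_id`` + ``stage:replicate`` TSV into a table.

    Ragged rows, duplicate group ids and negative values raise
    :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.index.name != "group_id":
        raise FormatError(f"{path}: first column must be named 'group_id'")
    df.columns = _parse_header(df.columns)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value ({exc})") from exc
    return ExpressionTable(species=species, data=df)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a table in the ``group_id`` + ``stage:replicate`` TSV layout."""
    flat = table.data.copy()
    flat.columns = [f"{st}:{rep}" for st, rep in table.data.columns]
    flat.index.name = "group_id"
    flat.to_csv(path, sep="\t")


# ----------------------------------------------------------------------
# Shared-group restriction
# ----------------------------------------------------------------------

def restrict_to_shared_groups(tables: Sequence[ExpressionTable]) -> list[ExpressionTable]:
    """Restrict every table to the intersection of group ids.

    The shared groups are ordered canonically (lexicographically) in every
    output table.  Raises ``ValueError`` naming the species whose table
    empties the intersection.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to restrict")
    shared = set(tables[0].groups)
    for table in tables[1:]:
        shared &= set(table.groups)
        if not shared:
            raise ValueError(
                f"no ortholog groups shared once {table.species} is included"
            )
    order = sorted(shared)
    return [t.with_groups(order) for t in tables]


# ----------------------------------------------------------------------
# BRI resampling
# ----------------------------------------------------------------------

def bri_resample(
    tables: Sequence[ExpressionTable],
    B: int,
    seed: int,
) -> list[BRITable]:
    """Draw ``B`` replicate-included tables.

    For every (species, stage) one replicate is chosen uniformly,
    independently across stages, species and tables; the same replicate may
    recur across tables.  Fully deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    for table in tables:
        for stage in table.stages:
            if not table.replicates(stage):
                raise ValueError(f"{table.species}/{stage} has no replicates")

    rng = np.random.default_rng(seed)
    species = tuple(t.species for t in tables)
    out: list[BRITable] = []
    for b in range(1, B + 1):
        vectors: dict[str, pd.DataFrame] = {}
        provenance: dict[tuple[str, str], str] = {}
        for table in tables:
            cols = {}
            for stage in table.stages:
                reps = table.replicates(stage)
                rep = reps[int(rng.integers(len(reps)))]
                provenance[(table.species, stage)] = rep
                cols[stage] = table.data[(stage, rep)].to_numpy(dtype=float)
            vectors[table.species] = pd.DataFrame(
                cols, index=table.data.index, columns=table.stages
            )
        out.append(BRITable(index=b, species=species, vectors=vectors, provenance=provenance))
    return out
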