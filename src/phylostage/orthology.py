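"""Reciprocal-best-hit 1:1 orthology and supergene concatenation.

Hit tables follow the conventional 12-column tab-separated similarity-search
layout (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore).  Best hits are chosen by bitscore (ties:
minimum e-value, then lexicographically smallest subject); a reciprocal best
pair is kept when the two directional best-hit maps agree.  One-to-one
ortholog sets across N species are anchored on a reference species: a set is
emitted only when the reference gene has a reciprocal partner in every other
species.  Pre-aligned per-set sequences can then be concatenated into a
per-species supermatrix with a partition table for phylogenetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

__all__ = [
    "HIT_COLUMNS",
    "OrthologSet",
    "read_hit_table",
    "write_hit_table",
    "best_hits",
    "reciprocal_best_pairs",
    "anchored_one_to_one",
    "concatenate_supergene",
    "read_fasta",
    "write_fasta",
    "write_partition_file",
]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


@dataclass
class OrthologSet:
    """One gene per species, keyed by the reference-species gene id."""

    reference_gene: str
    genes: dict[str, str]


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column hit TSV; malformed rows are rejected with line numbers."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                rows.append(
                    [conv(v) if (conv := _NUMERIC.get(c)) else v
                     for c, v in zip(HIT_COLUMNS, fields)]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def best_hits(hits: pd.DataFrame, evalue_max: float = 1e-5) -> dict[str, str]:
    """Best subject per query among hits passing the e-value filter.

    Multiple HSPs of one query-subject pair are collapsed to the
    max-bitscore row first.  Hits of a sequence against itself are ignored
    with a warning (self-species searches are not expected input).
    """
    df = hits[hits["evalue"] <= evalue_max]
    selfhits = df["qseqid"] == df["sseqid"]
    if selfhits.any():
        warnings.warn(
            f"ignoring {int(selfhits.sum())} self hits in hit table",
            RuntimeWarning,
            stacklevel=2,
        )
        df = df[~selfhits]
    if df.empty:
        return {}
    df = df.sort_values(
        ["bitscore", "evalue", "sseqid"], ascending=[False, True, True], kind="stable"
    )
    # max-bitscore HSP per (query, subject), then best subject per query
    df = df.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    df = df.drop_duplicates(subset="qseqid", keep="first")
    return dict(zip(df["qseqid"], df["sseqid"]))


def reciprocal_best_pairs(
    ab: Mapping[str, str], ba: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Pairs (a, b) with ab[a] == b and ba[b] == a, sorted by a."""
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


def anchored_one_to_one(
    reference: str,
    pair_maps: Mapping[str, Sequence[tuple[str, str]]],
) -> list[OrthologSet]:
    """1:1 ortholog sets anchored on the reference species.

    ``pair_maps[species]`` is the RBBH pair list (reference_gene, other_gene)
    for that species.  A set is emitted iff the reference gene has a partner
    in every species; output is sorted by reference gene id.
    """
    if not pair_maps:
        raise ValueError("no pair maps given")
    maps: dict[str, dict[str, str]] = {}
    for sp, pairs in pair_maps.items():
        m: dict[str, str] = {}
        seen_other: set[str] = set()
        for ref_gene, other in pairs:
            if ref_gene in m or other in seen_other:
                raise ValueError(
                    f"pair list for {sp} is not one-to-one at {ref_gene}/{other}"
                )
            m[ref_gene] = other
            seen_other.add(other)
        maps[sp] = m
    common = set.intersection(*(set(m) for m in maps.values()))
    return [
        OrthologSet(
            reference_gene=ref,
            genes={reference: ref, **{sp: maps[sp][ref] for sp in maps}},
        )
        for ref in sorted(common)
    ]


def concatenate_supergene(
    aligned: Mapping[str, Mapping[str, str]],
    order: Sequence[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-set alignments into a per-species supermatrix.

    ``aligned[set_id][species]`` is that species' aligned sequence for the
    set.  Returns the per-species concatenation (in the given set order) and
    a partition table of half-open column intervals ``(set_id, start, end)``.
    """
    if not order:
        raise ValueError("empty set order")
    species = sorted(aligned[order[0]])
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for set_id in order:
        seqs = aligned[set_id]
        missing = set(species) - set(seqs)
        if missing or set(seqs) - set(species):
            raise ValueError(f"set {set_id}: species do not match {species}")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"set {set_id}: aligned sequences differ in length")
        (width,) = lengths
        for sp in species:
            parts[sp].append(seqs[sp])
        partitions.append((set_id, offset, offset + width))
        offset += width
    return {sp: "".join(chunks) for sp, chunks in parts.items()}, partitions


# ----------------------------------------------------------------------
# FASTA and partition-file I/O
# ----------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_partition_file(
    partitions: Sequence[tuple[str, int, int]], path: str | Path
) -> None:
    """RAxML-style partition lines, 1-based inclusive: ``name = start-end``."""
    with open(path, "w") as fh:
        for name, start, end in partitions:
            fh.write(f"{name} = {start + 1}-{end}\n")
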