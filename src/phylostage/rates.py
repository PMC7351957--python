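"""Tajima relative-rate test and the lineage gene-loss presence screen.

The relative-rate test compares two lineages A and B against an outgroup O
on an aligned triplet: among sites where all three sequences carry ordinary
residues, ``m_A`` counts sites where only A differs from the outgroup state
and ``m_B`` where only B does.  Under equal rates the two counts have equal
expectation, so chi2 = (m_A - m_B)^2 / (m_A + m_B) is referred to the
chi-square distribution with one degree of freedom (count-based form, no
multiple-hit correction, no continuity correction).

The loss screen asks which anchor genes of an outgroup reference set are
supported in at least one comparison-set species but in no ingroup species;
presence per species is called from similarity hits with strict identity
and alignment-ratio floors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

__all__ = [
    "RRTResult",
    "PresenceMatrix",
    "tajima_rrt",
    "presence_call",
    "lineage_loss_screen",
]

# Ordinary residue alphabet (20 amino acids; nucleotide ACGT is a subset).
# Gaps, stops, X/ambiguity and anything else make a site unusable.
_VALID = np.zeros(256, dtype=bool)
for _ch in b"ACDEFGHIKLMNPQRSTVWY":
    _VALID[_ch] = True


@dataclass
class RRTResult:
    m_a: int
    m_b: int
    chi2: float | None
    df: int
    pvalue: float | None
    n_sites_used: int
    undefined: bool

    def swapped(self) -> "RRTResult":
        return RRTResult(self.m_b, self.m_a, self.chi2, self.df,
                         self.pvalue, self.n_sites_used, self.undefined)


@dataclass
class PresenceMatrix:
    """Boolean anchor-gene x species matrix with a declared species split."""

    data: pd.DataFrame
    ingroup: list[str]
    comparison: list[str]

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        ing, cmp_ = set(self.ingroup), set(self.comparison)
        if not ing or not cmp_:
            raise ValueError("both ingroup and comparison sets must be non-empty")
        if ing & cmp_:
            raise ValueError("ingroup and comparison species overlap")
        if (ing | cmp_) != cols:
            raise ValueError("ingroup + comparison must partition the matrix columns")


def tajima_rrt(seq_a: str, seq_b: str, seq_out: str) -> RRTResult:
    """Count-based relative rate test of lineages A and B against an outgroup."""
    if not len(seq_a) == len(seq_b) == len(seq_out):
        raise ValueError("aligned sequences must have equal lengths")
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    o = np.frombuffer(seq_out.upper().encode("ascii"), dtype=np.uint8)
    usable = _VALID[a] & _VALID[b] & _VALID[o]
    da = (a != o) & usable
    db = (b != o) & usable
    m_a = int((da & ~db).sum())
    m_b = int((db & ~da).sum())
    n_used = int(usable.sum())
    if m_a + m_b == 0:
        return RRTResult(m_a, m_b, None, 1, None, n_used, undefined=True)
    stat = (m_a - m_b) ** 2 / (m_a + m_b)
    return RRTResult(
        m_a, m_b, float(stat), 1, float(_chi2.sf(stat, 1)), n_used, undefined=False
    )


def presence_call(
    hits: pd.DataFrame,
    query_lengths: Mapping[str, int],
    id_min: float = 50.0,
    ratio_min: float = 30.0,
) -> dict[str, bool]:
    """Call a query gene present iff some hit clears both strict floors.

    A hit supports presence when ``pident > id_min`` and
    ``100 * length / query_length > ratio_min`` (both strictly).  Every
    query in ``query_lengths`` gets a call; queries without hits are absent.
    """
    calls = {gene: False for gene in query_lengths}
    for q, pid, aln in zip(hits["qseqid"], hits["pident"], hits["length"]):
        if q not in query_lengths:
            raise ValueError(f"no query length for {q!r}")
        if pid > id_min and 100.0 * aln / query_lengths[q] > ratio_min:
            calls[q] = True
    return calls


def lineage_loss_screen(matrix: PresenceMatrix) -> list[str]:
    """Anchor genes present in >=1 comparison species and absent in all ingroup."""
    df = matrix.data
    in_any_comparison = df[matrix.comparison].any(axis=1)
    in_no_ingroup = ~df[matrix.ingroup].any(axis=1)
    return sorted(df.index[in_any_comparison & in_no_ingroup].tolist())
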