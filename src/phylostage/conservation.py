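"""Cross-species stage-combination conservation scoring.

The central statistic works as follows.  A *stage combination* picks exactly
one developmental stage per species.  For a given combination, each species
contributes its whole-embryo ortholog-group expression vector at the chosen
stage; the rooted species tree is then traversed post-order and at every
internal node the expression distance

    expdist(x, y) = 1 - Spearman(x, y)

between the two child profiles is accumulated, after which the node exposes
the arithmetic mean of the child profiles (on TPM scale) to its parent.  The
total over internal nodes scores the combination; for two species this
reduces exactly to the pairwise 1 - Spearman.  Scoring every combination
exhaustively, the stages appearing in the top fraction ``q`` (default 1%)
of most-conserved combinations define the per-stage conservation percentage
Ptop.  Ptop is computed independently inside each BRI (replicate-included)
table and summarized by its mean and SD across the B tables; a Friedman
test over the B x stages Ptop matrix asks whether Ptop differs among stages
beyond replicate-choice noise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata

from .errors import CombinationCapError, UndefinedCorrelationError
from .tables import BRITable, ExpressionTable, bri_resample, restrict_to_shared_groups
from .tree import SpeciesTree, TreeNode

__all__ = [
    "CombinationScore",
    "PtopResult",
    "FriedmanResult",
    "expdist",
    "combination_distance",
    "score_all_combinations",
    "ptop_from_scores",
    "ptop_with_bri",
    "friedman_test",
    "pairwise_stage_matrix",
]

logger = logging.getLogger("phylostage")

DEFAULT_COMBINATION_CAP = 10_000_000

# Ordered mapping species -> (ordered mapping stage -> expression vector).
StageVectors = Mapping[str, Mapping[str, np.ndarray]]


@dataclass
class CombinationScore:
    """One stage combination and its summed node-wise expression distance."""

    combination: dict[str, str]
    expdist_total: float


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    n_blocks: int
    k: int
    tie_corrected: bool
    degenerate: bool = False


@dataclass
class PtopResult:
    """Mean/SD of Ptop over BRI tables, plus the raw B x stages matrices."""

    level: tuple[str, ...]
    B: int
    q: float
    mean: dict[str, pd.Series]
    sd: dict[str, pd.Series]
    matrices: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (species, stage, mean_ptop, sd_ptop) frame."""
        rows = []
        for sp in self.level:
            for stage in self.mean[sp].index:
                rows.append(
                    {
                        "species": sp,
                        "stage": stage,
                        "mean_ptop": self.mean[sp][stage],
                        "sd_ptop": self.sd[sp][stage],
                    }
                )
        return pd.DataFrame(rows)

    def friedman(self, species: str) -> FriedmanResult:
        """Friedman test of stage effects for one species (blocks = BRI tables)."""
        return friedman_test(self.matrices[species])


# ----------------------------------------------------------------------
# Expression distance
# ----------------------------------------------------------------------

def expdist(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Spearman correlation (Pearson on average ranks), in [0, 2].

    Raises :class:`UndefinedCorrelationError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("expdist expects two 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("expdist needs at least 3 aligned groups")
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    nx = float(np.dot(rxc, rxc))
    ny = float(np.dot(ryc, ryc))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError("constant vector: Spearman correlation undefined")
    rho = float(np.dot(rxc, ryc)) / math.sqrt(nx * ny)
    return 1.0 - rho


def _normalized_ranks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise centered unit-norm ranks; flags rows with zero rank variance."""
    r = rankdata(mat, axis=1)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1)
    degenerate = norm == 0.0
    norm[degenerate] = 1.0
    return r / norm[:, None], degenerate


# ----------------------------------------------------------------------
# Tree-aware scoring
# ----------------------------------------------------------------------

def _stage_matrix(vectors: StageVectors, species: str) -> np.ndarray:
    stages = list(vectors[species])
    return np.vstack([np.asarray(vectors[species][s], dtype=float) for s in stages])


def _eval_node(
    node: TreeNode,
    vectors: StageVectors,
    build_profile: bool,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Score a subtree over all of its stage sub-combinations.

    Returns ``(profiles, dists, undefined)`` where row ``i`` follows the
    C-order (leftmost leaf slowest) enumeration of stage indices, matching
    lexicographic stage-index order over the subtree's leaves.
    """
    if node.is_leaf:
        profiles = _stage_matrix(vectors, node.name)  # type: ignore[arg-type]
        n = profiles.shape[0]
        return profiles, np.zeros(n), np.zeros(n, dtype=bool)

    left, right = node.children
    lp, ld, lu = _eval_node(left, vectors, True)
    rp, rd, ru = _eval_node(right, vectors, True)
    assert lp is not None and rp is not None

    zl, dl_deg = _normalized_ranks(lp)
    zr, dr_deg = _normalized_ranks(rp)
    corr = zl @ zr.T
    dist = ld[:, None] + rd[None, :] + (1.0 - corr)
    undef = (lu | dl_deg)[:, None] | (ru | dr_deg)[None, :]

    profiles = None
    if build_profile:
        profiles = ((lp[:, None, :] + rp[None, :, :]) * 0.5).reshape(-1, lp.shape[1])
    return profiles, dist.ravel(), undef.ravel()


def _score_arrays(
    tree: SpeciesTree, vectors: StageVectors, cap: int = DEFAULT_COMBINATION_CAP
) -> tuple[np.ndarray, np.ndarray, list[str], list[list[str]]]:
    """Distances and undefined-flags for every combination, plus enumeration axes."""
    leaves = tree.leaves
    missing = [sp for sp in leaves if sp not in vectors]
    if missing:
        raise ValueError(f"no stage vectors for species {missing}")
    stage_lists = [list(vectors[sp]) for sp in leaves]
    n_total = math.prod(len(s) for s in stage_lists)
    if n_total > cap:
        raise CombinationCapError(
            f"{n_total} stage combinations exceed the cap of {cap}; "
            "raise the cap explicitly to proceed"
        )
    _, dists, undef = _eval_node(tree.root, vectors, build_profile=False)
    if undef.any():
        logger.warning(
            "%d/%d stage combinations excluded (undefined correlation at a node)",
            int(undef.sum()),
            n_total,
        )
    return dists, undef, leaves, stage_lists


def combination_distance(
    combo: Mapping[str, str], tree: SpeciesTree, bri: BRITable | StageVectors
) -> CombinationScore:
    """Score a single stage combination on the tree.

    ``bri`` may be a :class:`BRITable` or a plain species -> stage -> vector
    mapping.  Raises :class:`UndefinedCorrelationError` if any node profile
    is constant.
    """
    getter = bri.stage_vector if isinstance(bri, BRITable) else (
        lambda sp, st: np.asarray(bri[sp][st], dtype=float)
    )

    def walk(node: TreeNode) -> tuple[np.ndarray, float]:
        if node.is_leaf:
            if node.name not in combo:
                raise ValueError(f"combination is missing species {node.name!r}")
            return getter(node.name, combo[node.name]), 0.0
        (lp, ld), (rp, rd) = walk(node.children[0]), walk(node.children[1])
        d = expdist(lp, rp)
        return (lp + rp) * 0.5, ld + rd + d

    _, total = walk(tree.root)
    return CombinationScore(combination=dict(combo), expdist_total=total)


def score_all_combinations(
    tree: SpeciesTree,
    vectors: StageVectors | BRITable,
    cap: int = DEFAULT_COMBINATION_CAP,
) -> list[CombinationScore]:
    """Score every stage combination, in lexicographic stage-index order.

    Combinations whose correlation is undefined at any node (constant
    profile) are excluded from the returned list and logged.
    """
    if isinstance(vectors, BRITable):
        vectors = {
            sp: {st: vectors.stage_vector(sp, st) for st in vectors.vectors[sp].columns}
            for sp in vectors.species
        }
    dists, undef, leaves, stage_lists = _score_arrays(tree, vectors, cap)
    radices = [len(s) for s in stage_lists]
    idx = np.unravel_index(np.arange(dists.size), radices)
    out: list[CombinationScore] = []
    for i in range(dists.size):
        if undef[i]:
            continue
        combo = {sp: stage_lists[j][idx[j][i]] for j, sp in enumerate(leaves)}
        out.append(CombinationScore(combination=combo, expdist_total=float(dists[i])))
    return out


# ----------------------------------------------------------------------
# Ptop
# ----------------------------------------------------------------------

def _top_counts(
    dists: np.ndarray,
    undef: np.ndarray,
    radices: Sequence[int],
    q: float,
) -> tuple[list[np.ndarray], int]:
    """Per-leaf stage counts over the top-q fraction of valid combinations."""
    valid = np.flatnonzero(~undef)
    if valid.size == 0:
        raise UndefinedCorrelationError("every stage combination was undefined")
    n_top = max(1, int(round(q * valid.size)))
    # stable sort: distance ties resolved by lexicographic combination order
    order = np.argsort(dists[valid], kind="stable")
    top = valid[order[:n_top]]
    stage_idx = np.unravel_index(top, radices)
    counts = [np.bincount(stage_idx[j], minlength=radices[j]) for j in range(len(radices))]
    return counts, n_top


def ptop_from_scores(
    scores: Sequence[CombinationScore], q: float = 0.01
) -> dict[str, pd.Series]:
    """Ptop percentages per (species, stage) from a list of scored combinations.

    The top set holds ``max(1, round(q*N))`` smallest total distances, ties
    broken by position in ``scores`` (lexicographic order when the list came
    from :func:`score_all_combinations`).
    """
    if not scores:
        raise ValueError("no combination scores given")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    species = list(scores[0].combination)
    stage_order: dict[str, list[str]] = {sp: [] for sp in species}
    for s in scores:
        for sp in species:
            st = s.combination[sp]
            if st not in stage_order[sp]:
                stage_order[sp].append(st)
    dists = np.array([s.expdist_total for s in scores])
    n_top = max(1, int(round(q * len(scores))))
    top = np.argsort(dists, kind="stable")[:n_top]
    out: dict[str, pd.Series] = {}
    for sp in species:
        counts = {st: 0 for st in stage_order[sp]}
        for i in top:
            counts[scores[i].combination[sp]] += 1
        out[sp] = pd.Series(
            {st: 100.0 * c / n_top for st, c in counts.items()}, name=sp
        )
    return out


def ptop_with_bri(
    tables: Sequence[ExpressionTable],
    tree: SpeciesTree,
    B: int = 100,
    q: float = 0.01,
    seed: int = 0,
    cap: int = DEFAULT_COMBINATION_CAP,
) -> PtopResult:
    """Full pipeline: shared groups -> B BRI tables -> per-table Ptop -> mean/SD.

    The tree is restricted to the species of ``tables`` (the taxonomic level
    under analysis); Ptop is computed independently within each BRI table and
    the B x stages matrix per species is retained for the Friedman test.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    level = tuple(t.species for t in tables)
    sub = tree.restrict(level)
    leaf_order = sub.leaves
    by_species = {t.species: t for t in tables}
    shared = restrict_to_shared_groups([by_species[sp] for sp in leaf_order])
    bris = bri_resample(shared, B=B, seed=seed)

    stage_lists = {t.species: t.stages for t in shared}
    radices = [len(stage_lists[sp]) for sp in leaf_order]
    n_total = math.prod(radices)
    if n_total > cap:
        raise CombinationCapError(
            f"{n_total} stage combinations exceed the cap of {cap}"
        )

    ptop_rows: dict[str, list[np.ndarray]] = {sp: [] for sp in leaf_order}
    for bri in bris:
        vectors = {
            sp: {st: bri.vectors[sp][st].to_numpy(dtype=float) for st in stage_lists[sp]}
            for sp in leaf_order
        }
        dists, undef, leaves, _ = _score_arrays(sub, vectors, cap)
        counts, n_top = _top_counts(dists, undef, radices, q)
        for j, sp in enumerate(leaves):
            ptop_rows[sp].append(100.0 * counts[j] / n_top)

    mean: dict[str, pd.Series] = {}
    sd: dict[str, pd.Series] = {}
    matrices: dict[str, pd.DataFrame] = {}
    for sp in leaf_order:
        mat = pd.DataFrame(
            np.vstack(ptop_rows[sp]),
            index=pd.RangeIndex(1, B + 1, name="bri"),
            columns=stage_lists[sp],
        )
        matrices[sp] = mat
        mean[sp] = mat.mean(axis=0)
        sd[sp] = mat.std(axis=0, ddof=1) if B > 1 else mat.iloc[0] * 0.0
    return PtopResult(level=tuple(leaf_order), B=B, q=q, mean=mean, sd=sd, matrices=matrices)


# ----------------------------------------------------------------------
# Friedman test
# ----------------------------------------------------------------------

def friedman_test(ptop_matrix: pd.DataFrame | np.ndarray) -> FriedmanResult:
    """Friedman chi-square over blocks x treatments, with tie correction.

    chi2_F = 12/(B k (k+1)) * sum_j R_j^2 - 3 B (k+1), divided by the
    standard tie-correction factor 1 - sum(t^3 - t)/(B k (k^2 - 1)).
    If every block is entirely tied the statistic is reported as 0 with a
    warning.
    """
    m = np.asarray(ptop_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D blocks x treatments matrix")
    B, k = m.shape
    if B < 2 or k < 2:
        raise ValueError("Friedman test needs >=2 blocks and >=2 treatments")
    ranks = rankdata(m, axis=1)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (B * k * (k + 1)) * float(np.sum(rj**2)) - 3.0 * B * (k + 1)

    ties = 0.0
    tie_corrected = False
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        if (counts > 1).any():
            tie_corrected = True
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (B * k * (k * k - 1))
    if c <= 0.0:
        warnings.warn(
            "all blocks entirely tied: Friedman statistic undefined, reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return FriedmanResult(
            statistic=0.0, df=k - 1, pvalue=1.0, n_blocks=B, k=k,
            tie_corrected=tie_corrected, degenerate=True,
        )
    stat = max(stat / c, 0.0)
    p = float(_chi2.sf(stat, k - 1))
    return FriedmanResult(
        statistic=float(stat), df=k - 1, pvalue=p, n_blocks=B, k=k,
        tie_corrected=tie_corrected,
    )


# ----------------------------------------------------------------------
# Pairwise stage matrix
# ----------------------------------------------------------------------

def pairwise_stage_matrix(
    table_a: ExpressionTable, table_b: ExpressionTable
) -> pd.DataFrame:
    """All-stage-pairs expdist matrix between two species.

    Profiles are replicate means on the shared ortholog groups; entry
    ``(s_a, s_b)`` is ``expdist`` between the two stage profiles.
    """
    ra, rb = restrict_to_shared_groups([table_a, table_b])
    if len(ra.groups) < 3:
        raise ValueError("need at least 3 shared groups")
    mat = np.empty((len(ra.stages), len(rb.stages)))
    prof_a = [ra.stage_mean(s) for s in ra.stages]
    prof_b = [rb.stage_mean(s) for s in rb.stages]
    for i, pa in enumerate(prof_a):
        for j, pb in enumerate(prof_b):
            mat[i, j] = expdist(pa, pb)
    return pd.DataFrame(mat, index=ra.stages, columns=rb.stages)
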