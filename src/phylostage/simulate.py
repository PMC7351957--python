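"""Synthetic data with known ground truth for the whole pipeline.

The expression generator emulates a multi-species developmental RNA-seq
study: each ortholog group follows a smooth ancestral expression trajectory
over a common pseudo-time; along every branch of the species tree the
(log-scale) trajectory is perturbed by a smooth Gaussian curve whose
magnitude is stage-dependent -- the *divergence profile* -- times the branch
length.  An hourglass-shaped profile (minimum divergence at mid pseudo-time)
therefore produces data in which mid-developmental stages are the most
conserved across species; a flat profile produces no stage-dependent
conservation signal.  Species stage grids map stage ``i`` of ``S`` to
pseudo-time fraction ``i/(S-1)``; replicates add multiplicative lognormal
noise; every stage:replicate column is rescaled to a fixed TPM total.

The proteome generator evolves random protein sequences down the same tree
and emits all-vs-all similarity hit tables in the conventional 12-column
tabular layout, with within-group hits scoring above cross-group background
hits and optional decoy paralogs at reduced identity.  The read generator
samples error-prone fixed-length reads from a uniform random genome for the
k-mer genome-size estimator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError
from .tables import ExpressionTable
from .tree import SpeciesTree, TreeNode

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReadParams",
    "ProteomeParams",
    "ProteomeSet",
    "ReadSet",
    "hourglass_profile",
    "flat_profile",
    "simulate_expression_dataset",
    "simulate_proteome_set",
    "simulate_reads",
    "write_fastq",
    "write_ortholog_map",
    "write_ground_truth",
]

# Study-like defaults: 4 species on (Anj,(Apj,(Sp,Lv))) with unit branch
# lengths, 14-17 stages each, 2 replicates, thousands of ortholog groups.
DEFAULT_TREE = "(Anj:1,(Apj:1,(Sp:1,Lv:1):1):1);"

_DEFAULT_STAGE_COUNTS = {"Anj": 15, "Apj": 14, "Sp": 17, "Lv": 16}

_GRID_POINTS = 100
_KNOTS = 10
_TPM_TOTAL = 1.0e6

Profile = Callable[[np.ndarray], np.ndarray]


def default_stage_labels() -> dict[str, list[str]]:
    return {
        sp: [f"st{i + 1:02d}" for i in range(n)]
        for sp, n in _DEFAULT_STAGE_COUNTS.items()
    }


def hourglass_profile(sigma_min: float = 0.1, sigma_max: float = 1.0) -> Profile:
    """Quadratic divergence profile with its minimum at pseudo-time 0.5."""

    def prof(f):
        f = np.asarray(f, dtype=float)
        return sigma_min + (sigma_max - sigma_min) * (2.0 * f - 1.0) ** 2

    return prof


def flat_profile(sigma: float = 0.5) -> Profile:
    """Stage-independent divergence: no conserved phase by construction."""

    def prof(f):
        return np.full_like(np.asarray(f, dtype=float), sigma)

    return prof


@dataclass
class ReadParams:
    genome_length: int = 100_000
    coverage: float = 40.0
    read_length: int = 100
    error_rate: float = 0.005


@dataclass
class ProteomeParams:
    mutation_rate: float = 0.03      # substitutions/site per unit branch length
    decoy_fraction: float = 0.0      # extra paralog copies per species, as a fraction of groups
    decoy_extra_rate: float = 0.2    # additional per-site mutation load on decoys
    length_min: int = 150
    length_max: int = 450
    background_hit_fraction: float = 0.1  # genes that also receive a cross-group hit


@dataclass
class SimulationConfig:
    """Everything the generators need; one root seed drives all streams."""

    seed: int = 0
    tree_newick: str = DEFAULT_TREE
    stages_per_species: dict[str, list[str]] = field(default_factory=default_stage_labels)
    n_groups: int = 2000
    n_replicates: int = 2
    divergence_profile: Profile | Mapping[str, Profile] = field(
        default_factory=hourglass_profile
    )
    noise_sd: float = 0.25
    dropout_rate: float = 0.05
    read_params: ReadParams = field(default_factory=ReadParams)
    proteome: ProteomeParams = field(default_factory=ProteomeParams)

    def validate(self) -> SpeciesTree:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if self.noise_sd < 0.0:
            raise ConfigurationError("noise_sd must be >= 0")
        tree = SpeciesTree.from_newick(self.tree_newick)
        if set(tree.leaves) != set(self.stages_per_species):
            raise ConfigurationError(
                "tree leaves and stages_per_species disagree: "
                f"{sorted(tree.leaves)} vs {sorted(self.stages_per_species)}"
            )
        grid = np.linspace(0.0, 1.0, 11)
        for prof in self._profiles(tree.leaves).values():
            if np.any(np.asarray(prof(grid)) < 0.0):
                raise ConfigurationError("divergence profile must be >= 0 everywhere")
        return tree

    def _profiles(self, species: Sequence[str]) -> dict[str, Profile]:
        if callable(self.divergence_profile):
            return {sp: self.divergence_profile for sp in species}
        profs = dict(self.divergence_profile)
        missing = set(species) - set(profs)
        if missing:
            raise ConfigurationError(f"no divergence profile for {sorted(missing)}")
        return profs


@dataclass
class GroundTruth:
    """What the generator knows and downstream estimators should recover."""

    true_conserved_stages: dict[str, list[str]]
    true_ortholog_map: dict[str, dict[str, str]]
    true_genome_size: int


@dataclass
class ProteomeSet:
    sequences: dict[str, dict[str, str]]        # species -> gene id -> protein
    true_ortholog_map: dict[str, dict[str, str]]
    hit_tables: dict[tuple[str, str], pd.DataFrame]


@dataclass
class ReadSet:
    reads: list[tuple[str, str, str]]           # (id, sequence, quality)
    genome: str
    true_genome_size: int


# ----------------------------------------------------------------------
# Expression
# ----------------------------------------------------------------------

def _smooth_curves(rng: np.random.Generator, n_curves: int, grid: np.ndarray) -> np.ndarray:
    """Cubic-spline smoothing of Gaussian knot noise; (grid, n_curves) array."""
    knots = np.linspace(0.0, 1.0, _KNOTS)
    y = rng.normal(size=(_KNOTS, n_curves))
    return CubicSpline(knots, y, axis=0)(grid)


def _stage_fractions(n_stages: int) -> np.ndarray:
    if n_stages == 1:
        return np.array([0.0])
    return np.arange(n_stages) / (n_stages - 1)


def _interp_grid(values: np.ndarray, grid: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Linear interpolation of (grid, n) columns at the requested fractions."""
    pos = at * (len(grid) - 1)
    lo = np.clip(np.floor(pos).astype(int), 0, len(grid) - 2)
    w = pos - lo
    return (1.0 - w)[:, None] * values[lo] + w[:, None] * values[lo + 1]


def _node_profile(
    node: TreeNode, profiles: dict[str, Profile], grid: np.ndarray
) -> np.ndarray:
    """Divergence sigma on the grid for a branch: the mean over descendant species."""
    leaves = node.leaves()
    return np.mean([np.asarray(profiles[sp](grid), dtype=float) for sp in leaves], axis=0)


def simulate_expression_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionTable], GroundTruth]:
    """Generate per-species expression tables plus the ground truth."""
    tree = config.validate()
    rng = np.random.default_rng([config.seed, 1])
    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    n = config.n_groups
    profiles = config._profiles(tree.leaves)

    group_ids = [f"g{i:05d}" for i in range(n)]
    base = rng.normal(loc=1.0, scale=1.5, size=n)
    ancestral = base[None, :] + _smooth_curves(rng, n, grid)  # (grid, n) log scale

    species_log: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, acc: np.ndarray) -> None:
        sigma = _node_profile(node, profiles, grid)
        pert = sigma[:, None] * node.length * _smooth_curves(rng, n, grid)
        acc = acc + pert
        if node.is_leaf:
            species_log[node.name] = acc  # type: ignore[index]
        else:
            for child in node.children:
                walk(child, acc)

    for child in tree.root.children:
        walk(child, ancestral)

    tables: dict[str, ExpressionTable] = {}
    true_map: dict[str, dict[str, str]] = {gid: {} for gid in group_ids}
    for sp in tree.leaves:
        stages = config.stages_per_species[sp]
        fr = _stage_fractions(len(stages))
        log_at = _interp_grid(species_log[sp], grid, fr)  # (stages, n)
        keep = rng.random(n) >= config.dropout_rate
        eps = rng.normal(0.0, config.noise_sd, size=(len(stages), n, config.n_replicates))
        tpm = np.exp(log_at[:, :, None] + eps)  # (stages, n, reps)
        tpm = tpm[:, keep, :]
        cols = {}
        for si, stage in enumerate(stages):
            for r in range(config.n_replicates):
                col = tpm[si, :, r]
                cols[(stage, f"r{r + 1}")] = col * (_TPM_TOTAL / col.sum())
        kept_ids = [gid for gid, k in zip(group_ids, keep) if k]
        df = pd.DataFrame(cols, index=pd.Index(kept_ids, name="group_id"))
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["stage", "replicate"])
        tables[sp] = ExpressionTable(species=sp, data=df)
        for gid in kept_ids:
            true_map[gid][sp] = f"{sp}_{gid}"

    conserved: dict[str, list[str]] = {}
    for sp in tree.leaves:
        stages = config.stages_per_species[sp]
        sig = np.asarray(profiles[sp](_stage_fractions(len(stages))), dtype=float)
        lo, hi = float(sig.min()), float(sig.max())
        threshold = lo + 0.25 * (hi - lo)
        conserved[sp] = [st for st, s in zip(stages, sig) if s <= threshold]

    truth = GroundTruth(
        true_conserved_stages=conserved,
        true_ortholog_map=true_map,
        true_genome_size=config.read_params.genome_length,
    )
    return tables, truth


# ----------------------------------------------------------------------
# Proteomes and synthetic hit tables
# ----------------------------------------------------------------------

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# Deferred import keeps the column layout in one place (orthology module).
from .orthology import HIT_COLUMNS  # noqa: E402


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to one of the 19 others."""
    mask = rng.random(codes.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 20, size=n_mut)) % 20
    return codes


def _identity(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    m = min(a.size, b.size)
    matches = int(np.sum(a[:m] == b[:m]))
    return matches / m, m


def _hit_row(q: str, s: str, qa: np.ndarray, sa: np.ndarray) -> list:
    ident, length = _identity(qa, sa)
    matches = int(round(ident * length))
    bitscore = round(2.0 * ident * length, 1)
    evalue = 10.0 ** (-min(180.0, bitscore / 4.0))
    return [q, s, round(100.0 * ident, 2), length, length - matches, 0,
            1, length, 1, length, evalue, bitscore]


def simulate_proteome_set(
    config: SimulationConfig,
) -> ProteomeSet:
    """Random proteins evolved on the tree, plus synthetic all-vs-all hit tables.

    Within-group cross-species hits carry bitscores proportional to their
    true sequence identity; a fraction of genes additionally receives a
    low-identity cross-group background hit, and each species may carry decoy
    paralogs (extra-mutated copies) whose hits score below the true ortholog.
    """
    tree = config.validate()
    pp = config.proteome
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_groups
    group_ids = [f"g{i:05d}" for i in range(n)]
    lengths = rng.integers(pp.length_min, pp.length_max + 1, size=n)
    ancestral = [rng.integers(0, 20, size=int(L)) for L in lengths]

    leaf_codes: dict[str, list[np.ndarray]] = {}

    def walk(node: TreeNode, seqs: list[np.ndarray]) -> None:
        rate = pp.mutation_rate * node.length
        seqs = [_mutate(rng, s, rate) for s in seqs]
        if node.is_leaf:
            leaf_codes[node.name] = seqs  # type: ignore[index]
        else:
            for child in node.children:
                walk(child, seqs)

    for child in tree.root.children:
        walk(child, ancestral)

    species = tree.leaves
    true_map = {gid: {sp: f"{sp}_{gid}" for sp in species} for gid in group_ids}

    sequences: dict[str, dict[str, str]] = {}
    decoys: dict[str, list[tuple[str, int, np.ndarray]]] = {sp: [] for sp in species}
    n_decoys = int(round(pp.decoy_fraction * n))
    for sp in species:
        seqs = {
            f"{sp}_{gid}": leaf_codes[sp][i] for i, gid in enumerate(group_ids)
        }
        for j in range(n_decoys):
            src = int(rng.integers(n))
            codes = _mutate(rng, leaf_codes[sp][src], pp.decoy_extra_rate)
            name = f"{sp}_p{j:04d}"
            seqs[name] = codes
            decoys[sp].append((name, src, codes))
        sequences[sp] = {
            name: _AA[codes].tobytes().decode("ascii") for name, codes in seqs.items()
        }

    hit_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for qsp in species:
        for ssp in species:
            if qsp == ssp:
                continue
            rows = []
            for i, gid in enumerate(group_ids):
                q, s = f"{qsp}_{gid}", f"{ssp}_{gid}"
                rows.append(_hit_row(q, s, leaf_codes[qsp][i], leaf_codes[ssp][i]))
                if rng.random() < pp.background_hit_fraction and n > 1:
                    other = int(rng.integers(n - 1))
                    other += other >= i
                    rows.append(
                        _hit_row(q, f"{ssp}_{group_ids[other]}",
                                 leaf_codes[qsp][i], leaf_codes[ssp][other])
                    )
            for name, src, codes in decoys[qsp]:
                rows.append(
                    _hit_row(name, f"{ssp}_{group_ids[src]}", codes, leaf_codes[ssp][src])
                )
            hit_tables[(qsp, ssp)] = pd.DataFrame(rows, columns=HIT_COLUMNS)

    return ProteomeSet(sequences=sequences, true_ortholog_map=true_map, hit_tables=hit_tables)


# ----------------------------------------------------------------------
# Reads
# ----------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(config: SimulationConfig) -> ReadSet:
    """Uniform random genome plus error-prone fixed-length forward reads.

    The read count is ``floor(coverage * genome_length / read_length)``;
    substitution errors are applied per base at the configured rate and the
    quality line is a constant high Phred score.
    """
    rp = config.read_params
    if rp.genome_length < 1 or rp.coverage <= 0.0 or rp.read_length < 1:
        raise ConfigurationError("genome length, coverage and read length must be positive")
    if rp.read_length > rp.genome_length:
        raise ConfigurationError("read length exceeds genome length")
    if not 0.0 <= rp.error_rate <= 1.0:
        raise ConfigurationError("error rate must be in [0, 1]")
    rng = np.random.default_rng([config.seed, 3])
    genome = rng.integers(0, 4, size=rp.genome_length, dtype=np.uint8)
    n_reads = int(rp.coverage * rp.genome_length / rp.read_length)
    starts = rng.integers(0, rp.genome_length - rp.read_length + 1, size=n_reads)
    reads_codes = genome[starts[:, None] + np.arange(rp.read_length)]
    if rp.error_rate > 0.0:
        mask = rng.random(reads_codes.shape) < rp.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads_codes = reads_codes.copy()
        reads_codes[mask] = (reads_codes[mask] + shifts) % 4
    qual = "I" * rp.read_length
    reads = [
        (f"read_{i:07d}", _BASES[row].tobytes().decode("ascii"), qual)
        for i, row in enumerate(reads_codes)
    ]
    return ReadSet(
        reads=reads,
        genome=_BASES[genome].tobytes().decode("ascii"),
        true_genome_size=rp.genome_length,
    )


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_ortholog_map(
    true_map: Mapping[str, Mapping[str, str]], path: str | Path
) -> None:
    """TSV of group_id, species, comma-separated gene ids (one row per pair)."""
    with open(path, "w") as fh:
        fh.write("group_id\tspecies\tgene_ids\n")
        for gid in sorted(true_map):
            for sp in sorted(true_map[gid]):
                fh.write(f"{gid}\t{sp}\t{true_map[gid][sp]}\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
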