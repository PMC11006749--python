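"""Positional clustering of mutations along the protein sequence.

Driver mutations tend to recur at, or near, residues critical for protein
function.  Per gene this module computes the fraction of positioned mutations
falling into positional clusters: a *seed* is any residue carrying at least
``seed_min`` mutations, and a *cluster* is the maximal set of mutated
residues chainable to a seed through inter-residue steps of at most ``gap``.
The clustered fraction is

    F = (# mutations at cluster residues) / (# positioned mutations)

Significance is assessed by permutation: the same number of mutations is
placed uniformly at random over 1..protein_length and

    p = (1 + #{null F >= observed F}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AbtslcError
from .maf_io import MutationTable

DEFAULT_SEED_MIN = 2
DEFAULT_GAP = 5


@dataclass
class ClusterSet:
    """Clusters of one gene: intervals, member counts, clustered fraction."""

    clusters: list            # [(start_residue, end_residue, n_mutations), ...]
    total_positioned: int     # M
    clustered_fraction: float  # F
    p_value: float = None

    @property
    def n_clustered(self) -> int:
        return sum(c[2] for c in self.clusters)


def _validate(positions: np.ndarray, seed_min: int, gap: int) -> None:
    if seed_min < 2:
        raise AbtslcError("seed_min must be >= 2")
    if gap < 0:
        raise AbtslcError("gap must be >= 0")
    if positions.size and positions.min() < 1:
        raise AbtslcError("residue indices must be >= 1")


def find_clusters(positions, seed_min: int = DEFAULT_SEED_MIN,
                  gap: int = DEFAULT_GAP) -> "ClusterSet | None":
    """Cluster a multiset of residue indices.

    Returns None ("no data") when no positioned mutation exists.  Clusters
    are non-overlapping, sorted by start residue, and each contains at least
    one seed residue.
    """
    pos = np.asarray(sorted(positions), dtype=np.int64)
    _validate(pos, seed_min, gap)
    m = pos.size
    if m == 0:
        return None

    residues, counts = np.unique(pos, return_counts=True)
    is_seed = counts >= seed_min
    # partition residues into runs where consecutive mutated residues are
    # within `gap` of each other; a run is a cluster iff it contains a seed
    breaks = np.flatnonzero(np.diff(residues) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [residues.size - 1]))

    clusters = []
    for a, b in zip(starts, ends):
        if is_seed[a:b + 1].any():
            clusters.append((int(residues[a]), int(residues[b]),
                             int(counts[a:b + 1].sum())))
    n_clustered = sum(c[2] for c in clusters)
    return ClusterSet(clusters=clusters, total_positioned=m,
                      clustered_fraction=n_clustered / m)


def _clustered_fraction_rows(pos: np.ndarray, seed_min: int,
                             gap: int) -> np.ndarray:
    """Clustered fraction per row of an (n_rows, M) position array."""
    n, m = pos.shape
    if m == 1:
        return np.zeros(n)
    srt = np.sort(pos, axis=1)
    run_id = np.zeros((n, m), dtype=np.int64)
    run_id[:, 1:] = np.cumsum(np.diff(srt, axis=1) > gap, axis=1)
    gid = (np.arange(n)[:, None] * m + run_id).ravel()

    # element i starts a seed residue iff the value repeats seed_min-1 ahead
    mark = np.zeros((n, m), dtype=bool)
    k = seed_min - 1
    if k < m:
        mark[:, :m - k] = srt[:, :m - k] == srt[:, k:]
    seeded = np.zeros(n * m, dtype=bool)
    seeded[gid[mark.ravel()]] = True
    clustered = seeded[gid].reshape(n, m)
    return clustered.sum(axis=1) / m


def cluster_permutation_p(positions, protein_length: int,
                          n_perm: int = 999, seed: int = 0,
                          seed_min: int = DEFAULT_SEED_MIN,
                          gap: int = DEFAULT_GAP) -> float:
    """Permutation p-value for the clustered fraction of one gene.

    The null places the same number of mutations uniformly at random over
    residues 1..protein_length.  Raises when the protein length is missing
    or shorter than the largest observed position.
    """
    pos = np.asarray(sorted(positions), dtype=np.int64)
    _validate(pos, seed_min, gap)
    if pos.size == 0:
        raise AbtslcError("no positioned mutations (no data)")
    if protein_length is None or protein_length < pos.max():
        raise AbtslcError("protein_length missing or < max observed position")
    if n_perm < 100:
        raise AbtslcError("n_perm must be >= 100")

    observed = find_clusters(pos, seed_min, gap).clustered_fraction
    rng = np.random.default_rng(seed)
    null_pos = rng.integers(1, protein_length + 1, size=(n_perm, pos.size))
    null_f = _clustered_fraction_rows(null_pos, seed_min, gap)
    return float((1 + np.sum(null_f >= observed - 1e-12)) / (n_perm + 1))


def clustering_table(table: MutationTable, genes, protein_lengths: pd.Series,
                     seed_min: int = DEFAULT_SEED_MIN, gap: int = DEFAULT_GAP,
                     n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-gene clustered fraction and permutation p over a mutation table.

    ``protein_lengths`` maps gene symbol to canonical protein length; genes
    without positioned mutations or without a length are reported with
    missing statistics rather than dropped.
    """
    rows = []
    for i, gene in enumerate(sorted(dict.fromkeys(genes))):
        pos = table.df.loc[(table.df["gene"] == gene)
                           & table.df["protein_pos"].notna(), "protein_pos"]
        pos = pos.astype(int).to_numpy()
        row = {"gene": gene, "n_positioned": int(pos.size),
               "clustered_fraction": None, "n_clusters": None, "p": None}
        if pos.size:
            cs = find_clusters(pos, seed_min, gap)
            row["clustered_fraction"] = cs.clustered_fraction
            row["n_clusters"] = len(cs.clusters)
            length = protein_lengths.get(gene)
            if length is not None and not pd.isna(length) \
                    and length >= pos.max():
                row["p"] = cluster_permutation_p(
                    pos, int(length), n_perm=n_perm, seed=seed + i,
                    seed_min=seed_min, gap=gap)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
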