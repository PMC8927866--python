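"""Greedy clustering of interaction motifs by structural or energetic distance.

Structural distance is best-fit backbone RMSD; energetic distance between two
SCE matrices is r_E = 1 - r, one minus the Pearson correlation of their 400
entries (0 for perfectly correlated matrices, about 1 for unrelated ones, 2 for
anti-correlated).

Clustering runs a fixed number of greedy rounds: each round samples n items
from the remaining set, picks as medoid the sample with the most sampled
neighbors within radius d, collects every remaining item within d of the
medoid as one cluster, and removes it from the pool. A random-assignment
control with matched cluster sizes calibrates the within-cluster statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import kabsch_rmsd
from .potentials import EnergyMatrix, symmetrize

logger = logging.getLogger(__name__)

STRUCTURE_RADIUS = 0.5  # A, for clustering by best-fit RMSD
ENERGY_RADIUS = 0.3  # r_E units, for clustering by energetic distance
DEFAULT_ROUNDS = 100
DEFAULT_SAMPLE_COUNT = 1_000  # per-round sample size n (free parameter)

# RMSD bin edges for the structural-vs-energetic similarity profile
PROFILE_BIN_EDGES = np.concatenate([np.arange(0.0, 2.0, 0.2), [4.0]])


def energy_distance(a: EnergyMatrix, b: EnergyMatrix) -> float:
    """r_E = 1 - Pearson r over the 400 paired entries; nan when either matrix
    has zero variance."""
    x = a.values.ravel()
    y = b.values.ravel()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("zero-variance energy matrix; r_E undefined")
        return float("nan")
    return float(1.0 - np.corrcoef(x, y)[0, 1])


def pairwise_energy_distance(matrices: list[EnergyMatrix], symmetrized: bool = True) -> np.ndarray:
    """Pairwise r_E matrix; matrices are symmetrized first by default (the
    ordered/swapped ambiguity of SCE rows makes the symmetrized form the
    comparable one)."""
    mats = [symmetrize(m) if symmetrized and not m.symmetric else m for m in matrices]
    flat = np.stack([m.values.ravel() for m in mats])
    sd = flat.std(axis=1)
    if (sd == 0).any():
        logger.warning("%d zero-variance matrices in pairwise r_E", int((sd == 0).sum()))
    r = np.corrcoef(flat)
    return 1.0 - r


def pairwise_rmsd(coords: list[np.ndarray]) -> np.ndarray:
    """Pairwise best-fit RMSD matrix over motif coordinate sets."""
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
    return out


@dataclass
class Cluster:
    medoid: int  # index into the clustered item list
    members: list[int]  # includes the medoid
    distances: list[float]  # member distance to the medoid


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    metric: str
    params: dict = field(default_factory=dict)
    unassigned: list[int] = field(default_factory=list)

    @property
    def mean_member_distance(self) -> float:
        """Mean distance to the medoid over all members of all clusters."""
        dists = [d for c in self.clusters for d in c.distances]
        return float(np.mean(dists)) if dists else float("nan")

    @property
    def sizes(self) -> list[int]:
        return [len(c.members) for c in self.clusters]


def greedy_cluster(
    dist: np.ndarray,
    d: float,
    n: int = DEFAULT_SAMPLE_COUNT,
    rounds: int = DEFAULT_ROUNDS,
    seed: int = 0,
    metric: str = "rmsd",
) -> ClusterResult:
    """Greedy radius clustering on a precomputed pairwise distance matrix.

    Each round: sample min(n, |S|) remaining items without replacement; the
    sampled item with the largest number of sampled neighbors within d becomes
    the medoid (ties to the lowest index); every remaining item within d of the
    medoid forms the round's cluster and leaves the pool.
    """
    if n < 1:
        raise ValueError("sample count n must be >= 1")
    if d <= 0:
        raise ValueError("radius d must be positive")
    dist = np.asarray(dist)
    rng = np.random.default_rng(seed)
    remaining = np.arange(dist.shape[0])
    clusters: list[Cluster] = []
    for _ in range(rounds):
        if remaining.size == 0:
            logger.info("pool exhausted after %d rounds", len(clusters))
            break
        take = min(n, remaining.size)
        sampled = np.sort(rng.choice(remaining, size=take, replace=False))
        sub = dist[np.ix_(sampled, sampled)]
        neighbor_counts = (sub <= d).sum(axis=1)  # self included; constant shift
        medoid = int(sampled[int(np.argmax(neighbor_counts))])
        within = remaining[dist[medoid, remaining] <= d]
        clusters.append(
            Cluster(medoid=medoid, members=[int(i) for i in within],
                    distances=[float(dist[medoid, i]) for i in within])
        )
        remaining = remaining[~np.isin(remaining, within)]
    return ClusterResult(
        clusters=clusters, metric=metric,
        params={"d": d, "n": n, "rounds": rounds, "seed": seed},
        unassigned=[int(i) for i in remaining],
    )


def random_cluster_control(
    dist: np.ndarray, target_sizes: list[int], seed: int = 0, metric: str = "random"
) -> ClusterResult:
    """Random partition into clusters of exactly the given sizes, with the medoid
    of each random cluster chosen to minimize its summed within-cluster distance."""
    dist = np.asarray(dist)
    n_items = dist.shape[0]
    if sum(target_sizes) > n_items:
        raise ValueError(f"target sizes sum to {sum(target_sizes)} > {n_items} items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    clusters = []
    at = 0
    for size in target_sizes:
        members = np.sort(order[at : at + size])
        at += size
        sub = dist[np.ix_(members, members)]
        medoid = int(members[int(np.argmin(sub.sum(axis=1)))])
        clusters.append(
            Cluster(medoid=medoid, members=[int(i) for i in members],
                    distances=[float(dist[medoid, i]) for i in members])
        )
    return ClusterResult(
        clusters=clusters, metric=metric,
        params={"sizes": list(target_sizes), "seed": seed},
        unassigned=[int(i) for i in order[at:]],
    )


def rmsd_re_profile(
    coords: list[np.ndarray],
    matrices: list[EnergyMatrix],
    bin_edges: np.ndarray = PROFILE_BIN_EDGES,
) -> pd.DataFrame:
    """Relationship between structural and energetic similarity over all motif
    pairs: bin pairwise RMSD, summarize r_E per bin (mean, median, SE, count).

    Empty bins appear with count 0 and nan summaries.
    """
    if len(coords) != len(matrices) or len(coords) < 2:
        raise ValueError("need matching coords/matrices for at least 2 motifs")
    rmsd = pairwise_rmsd(coords)
    re = pairwise_energy_distance(matrices)
    iu = np.triu_indices(len(coords), k=1)
    r_flat, e_flat = rmsd[iu], re[iu]
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (r_flat >= lo) & (r_flat < hi)
        vals = e_flat[sel]
        rows.append(
            {
                "rmsd_lo": lo, "rmsd_hi": hi, "n_pairs": int(sel.sum()),
                "mean_re": float(np.mean(vals)) if len(vals) else float("nan"),
                "median_re": float(np.median(vals)) if len(vals) else float("nan"),
                "se_re": float(stats.sem(vals)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
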