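"""Patch-level analyses on the unipartite (shared-species) network.

Patch importance is ranked with Opsahl's weighted degree centrality

    C_i(alpha) = k_i^(1-alpha) * s_i^alpha,

which blends the number of connections k_i with the total connection
weight s_i through the tuning parameter alpha (alpha=0 gives plain
degree, alpha=1 gives strength; alpha=0.5 weighs both equally).

Community structure of the patch network is found with three standard
algorithms (multilevel/Louvain, walktrap, spinglass, via igraph), each
reported with its Newman-Girvan weighted modularity; the mixing
parameter mu (average fraction of a node's links leaving its community)
summarizes how well-separated the communities are.
"""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core import Partition, UnipartiteNetwork

__all__ = [
    "weighted_degree_centrality",
    "detect_communities",
    "newman_modularity",
    "mixing_parameter",
    "partition_agreement",
]

ALGORITHMS = ("multilevel", "walktrap", "spinglass")


def weighted_degree_centrality(
    net: UnipartiteNetwork, alpha: float = 0.5
) -> pd.DataFrame:
    """Opsahl weighted degree centrality table for every patch.

    Returns one row per patch with degree ``k``, strength ``s``,
    centrality ``C = k^(1-alpha) * s^alpha`` and descending rank (average
    rank on ties). Isolated nodes get C = 0.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    k = net.degrees.astype(float)
    s = net.strengths.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k > 0, k ** (1.0 - alpha) * s**alpha, 0.0)
    df = pd.DataFrame(
        {
            "patch": list(net.nodes),
            "habitat": [net.habitat_of.get(n, "") for n in net.nodes],
            "k": k.astype(int),
            "s": s.astype(int),
            "centrality": c,
        }
    )
    df["rank"] = df["centrality"].rank(ascending=False, method="average")
    return df


def newman_modularity(net: UnipartiteNetwork, part: Partition) -> float:
    """Newman-Girvan weighted modularity of a partition (direct formula).

    Q = (1/2W) * sum_ij (w_ij - s_i s_j / 2W) * delta(g_i, g_j), over all
    ordered node pairs including i = j (zero-weight diagonal).
    """
    g = np.asarray(part.membership(net.nodes))
    w = net.weights.astype(float)
    two_w = w.sum()  # sum over ordered pairs = 2W
    if two_w == 0:
        raise ValueError("network has no edges")
    s = w.sum(axis=1)
    same = g[:, None] == g[None, :]
    return float(((w - np.outer(s, s) / two_w) * same).sum() / two_w)


def detect_communities(
    net: UnipartiteNetwork,
    algorithm: str = "multilevel",
    seed: int = 0,
    walktrap_steps: int = 4,
    spinglass_spins: int = 25,
    spinglass_gamma: float = 1.0,
) -> Partition:
    """Detect communities of patches sharing species.

    ``algorithm`` is one of ``multilevel`` (Louvain), ``walktrap``
    (random walks, cut at maximal modularity) or ``spinglass`` (simulated
    annealing; requires a connected graph). All three use the edge
    weights. The result carries the Newman-Girvan weighted modularity of
    the partition and is deterministic given ``seed``.
    """
    if algorithm == "multimodel":  # name used interchangeably in the field
        algorithm = "multilevel"
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected {ALGORITHMS}")
    g = net.to_igraph()
    random.seed(seed)  # python-igraph draws from Python's random module
    if algorithm == "multilevel":
        clust = g.community_multilevel(weights="weight")
    elif algorithm == "walktrap":
        clust = g.community_walktrap(
            weights="weight", steps=walktrap_steps
        ).as_clustering()
    else:
        if not g.is_connected():
            raise ValueError(
                "spinglass requires a connected graph; run it per connected "
                "component or use multilevel/walktrap"
            )
        clust = g.community_spinglass(
            weights="weight", spins=spinglass_spins, gamma=spinglass_gamma
        )
    assignment = {net.nodes[i]: int(c) for i, c in enumerate(clust.membership)}
    part = Partition(assignment=assignment, quality=0.0, algorithm=algorithm, seed=seed)
    q = newman_modularity(net, part)
    return Partition(assignment=assignment, quality=q, algorithm=algorithm, seed=seed)


def mixing_parameter(net: UnipartiteNetwork, part: Partition) -> dict:
    """Mixing parameter mu of a partition: how much links cross communities.

    For each non-isolated node the external fraction of its links is
    computed twice — by edge count (k_ext / k) and by edge weight
    (s_ext / s) — and mu is the unweighted average over nodes. Both
    values lie in [0, 1]; 0 means no inter-community edges.
    """
    if not part.assignment:
        raise ValueError("empty partition")
    g = np.asarray(part.membership(net.nodes))
    w = net.weights
    adj = w > 0
    ext = g[:, None] != g[None, :]
    k = adj.sum(axis=1)
    s = w.sum(axis=1)
    keep = k > 0
    if not keep.any():
        raise ValueError("network has no edges")
    frac_deg = (adj & ext).sum(axis=1)[keep] / k[keep]
    frac_str = (w * ext).sum(axis=1)[keep] / s[keep]
    return {
        "algorithm": part.algorithm,
        "n_communities": part.n_communities,
        "mu_degree": float(frac_deg.mean()),
        "mu_strength": float(frac_str.mean()),
        "external_fraction_degree": dict(
            zip(np.asarray(net.nodes)[keep], frac_deg.tolist())
        ),
    }


def partition_agreement(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same node set.

    1 for identical partitions; expectation 0 for independent random
    partitions under the permutation model.
    """
    if set(a.assignment) != set(b.assignment):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a.assignment)
    return float(adjusted_rand_score(a.membership(nodes), b.membership(nodes)))
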