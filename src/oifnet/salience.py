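"""Link salience and keystone-species identification.

Strongly interacting species are "close": the effective distance of a directed
link is the reciprocal of its weight, dist(i, j) = 1 / W[i, j] (absent links
and the diagonal are unreachable).  For every reference node r the shortest-
path tree SPT(r) collects every link lying on any minimal-distance path from r
to each reachable node (all co-minimal paths contribute, so the result is
deterministic under ties).  The salience of a link is the fraction of
reference nodes whose tree contains it,

    SAL = (1/n) * sum_r SPT(r),      SAL[i, j] in {0, 1/n, ..., 1}.

Links salient for at least half the reference nodes are the "Pareto" links;
species are ranked keystone by how often they appear in the most salient
links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .network import InteractionMatrix

__all__ = [
    "SalienceMatrix",
    "effective_distance",
    "link_salience",
    "keystone_ranking",
]


@dataclass
class SalienceMatrix:
    SAL: np.ndarray                  # n x n, values in {0, 1/n, ..., 1}
    dist: np.ndarray                 # effective distances (inf when absent)
    spt: np.ndarray                  # n x n x n indicator, spt[r, i, j]
    species: list[str] = field(default_factory=list)
    directed: bool = True

    @property
    def n(self) -> int:
        return self.SAL.shape[0]


def effective_distance(W: np.ndarray | InteractionMatrix) -> np.ndarray:
    """dist = 1/W for positive weights; inf on the diagonal and absent links."""
    W = W.W if isinstance(W, InteractionMatrix) else np.asarray(W, dtype=float)
    with np.errstate(divide="ignore"):
        dist = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(dist, np.inf)
    return dist


def link_salience(W: np.ndarray | InteractionMatrix, directed: bool = True
                  ) -> SalienceMatrix:
    """Superpose shortest-path trees from every reference node.

    ``directed=False`` symmetrizes the matrix first (max of the two
    directions), the convention of the original undirected formulation; the
    default follows the directed TE weights with out-trees from each
    reference.
    """
    if isinstance(W, InteractionMatrix):
        species = W.species
        Wm = W.W
    else:
        Wm = np.asarray(W, dtype=float)
        species = [f"sp{i + 1}" for i in range(Wm.shape[0])]
    if not directed:
        Wm = np.maximum(Wm, Wm.T)
    n = Wm.shape[0]
    dist = effective_distance(Wm)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if np.isfinite(dist[i, j]):
                g.add_edge(i, j, weight=dist[i, j])
    spt = np.zeros((n, n, n), dtype=np.int8)
    for r in range(n):
        preds, _ = nx.dijkstra_predecessor_and_distance(g, r, weight="weight")
        for node, plist in preds.items():
            for p in plist:       # all co-minimal predecessors contribute
                spt[r, p, node] = 1
    SAL = spt.mean(axis=0)
    return SalienceMatrix(SAL=SAL, dist=dist, spt=spt, species=list(species),
                          directed=directed)


def keystone_ranking(sal: SalienceMatrix, top_k: int = 5,
                     endpoint: str = "both") -> dict:
    """Rank species by their frequency among the ``top_k`` most salient links.

    ``endpoint`` chooses which end of a salient link earns the credit:
    ``source``, ``target``, or ``both`` (the reference-terminal phrasing of the
    method is ambiguous, so all three conventions are available; ``both`` is
    the default and the two single-ended counts are always reported).

    Returns the top-pair listing, per-species counts, and the set of "Pareto"
    links (salience >= 1/2).
    """
    if endpoint not in ("source", "target", "both"):
        raise ValueError("endpoint must be 'source', 'target' or 'both'")
    n = sal.n
    iu, ju = np.nonzero(sal.SAL > 0)
    order = np.argsort(-sal.SAL[iu, ju], kind="stable")
    pairs = [(int(iu[k]), int(ju[k]), float(sal.SAL[iu[k], ju[k]]))
             for k in order]
    if len(pairs) < top_k:
        warnings.warn(f"only {len(pairs)} positive-salience links (< top_k={top_k})")
    top = pairs[:top_k]
    counts = {e: np.zeros(n, dtype=int) for e in ("source", "target", "both")}
    for i, j, _ in top:
        counts["source"][i] += 1
        counts["target"][j] += 1
        counts["both"][i] += 1
        counts["both"][j] += 1
    c = counts[endpoint]
    ranking = sorted(range(n), key=lambda k: (-c[k], k))
    pareto = [(sal.species[i], sal.species[j], s) for i, j, s in pairs if s >= 0.5]
    return {
        "top_pairs": [(sal.species[i], sal.species[j], s) for i, j, s in top],
        "counts": {e: counts[e] for e in counts},
        "ranking": [(sal.species[k], int(c[k])) for k in ranking],
        "pareto_links": pareto,
    }
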