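"""Neighbor-joining tree construction with nonparametric bootstrap support.

Saitou–Nei agglomeration on a K2P (or p) distance matrix: at each step the
pair minimizing the rate-corrected Q-criterion is joined; branch lengths
come from the standard three-point formulas with negative estimates clamped
to zero. Taxa are processed in canonical (sorted-ID) order and Q-ties break
lexicographically, so the result is deterministic and independent of input
record order. On an additive matrix NJ is exact: it recovers the generating
topology and reproduces the input distances.

Bootstrap support resamples alignment columns with replacement (Felsenstein
bootstrap), rebuilds distance matrix and NJ tree per replicate, and annotates
each internal edge of the point-estimate tree with the percentage of
replicates containing the same bipartition.
"""

from __future__ import annotations

import logging

import numpy as np

from barcode_associate.distmat import DistanceMatrix, build_matrix, matrix_from_encoded
from barcode_associate.records import Dataset
from barcode_associate.tree import PhyloTree, TreeError

logger = logging.getLogger(__name__)


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a fully defined distance matrix."""
    if dm.undefined:
        pairs = [(a, b) for (a, b, _) in dm.undefined]
        raise TreeError(f"distance matrix has undefined entries: {pairs}")
    n = len(dm.ids)
    if n < 2:
        raise TreeError("need at least 2 taxa")

    # Canonical ID sort makes join order, and hence tie-breaks, deterministic
    # regardless of input record order.
    order = sorted(range(n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]
    D = dm.d[np.ix_(order, order)].astype(float)

    tree = PhyloTree()
    # active clusters: parallel lists of (representative key, tree node id)
    keys: list[str] = list(ids)
    nodes: list[int] = [tree.add_node(name=sid) for sid in ids]

    if n == 2:
        tree.add_edge(nodes[0], nodes[1], max(D[0, 1], 0.0))
        return tree

    while len(keys) > 3:
        m = len(keys)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q is only symmetric up to rounding; canonicalize index pairs.
        cand = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in np.argwhere(Q <= qmin)}
        # ties resolved by lexicographic order of the cluster key pair
        i, j = min(cand, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = tree.add_node()
        tree.add_edge(parent, nodes[i], li)
        tree.add_edge(parent, nodes[j], lj)
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-cluster star: exact three-point branch lengths
    center = tree.add_node()
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        tree.add_edge(center, nodes[k], max(lk, 0.0))
    return tree


def bootstrap_support(
    ds: Dataset,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """NJ point tree annotated with Felsenstein bootstrap support.

    Replicates whose resampled matrix contains an undefined pair (saturation
    or zero overlap) are dropped and counted; a warning is emitted when more
    than 5% are dropped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = tree if tree is not None else nj(build_matrix(ds, model))
    point = point.copy()
    targets = point.nontrivial_splits()
    counts = {s: 0 for s in targets}

    X = ds.encoded()
    ids = ds.ids
    L = X.shape[1]
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        dmb = matrix_from_encoded(X[:, cols], ids, model)
        if dmb.undefined:
            dropped += 1
            continue
        rep_splits = nj(dmb).nontrivial_splits()
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    used = replicates - dropped
    if dropped > 0.05 * replicates:
        logger.warning(
            "%d of %d bootstrap replicates dropped (undefined pairs)",
            dropped,
            replicates,
        )
    if used == 0:
        raise TreeError("every bootstrap replicate had undefined pairs")
    point.support = {s: 100.0 * c / used for s, c in counts.items()}
    return point
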