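"""Permutation-based evaluation of a reconstructed network against a reference.

Both networks are restricted to their common node set; the observed number
of shared (undirected) edges is compared with the counts obtained after
uniformly permuting the node labels of the reconstructed subnetwork, which
preserves its topology exactly.  The empirical p-value is the fraction of
permutations whose common-edge count reaches or exceeds the observed one
(ties count against significance); the network is called significantly
better than random at p < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .containers import Gan, ReferenceNetwork, canonical_edge

SIGNIFICANCE_LEVEL = 0.1


@dataclass
class OverlapResult:
    common_nodes: list[str]
    gan_sub_edges: set[tuple[str, str]]     # reconstructed edges on the common nodes
    reference_sub_edges: set[tuple[str, str]]
    observed_common_edges: int

    @property
    def percent_common(self) -> float:
        if not self.gan_sub_edges:
            return float("nan")
        return 100.0 * self.observed_common_edges / len(self.gan_sub_edges)


@dataclass
class EvaluationResult:
    n_overlap_nodes: int
    observed_common_edges: int
    percent_common: float
    permutation_counts: np.ndarray = field(repr=False)
    p_value: float = 1.0
    n_permutations: int = 0
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def _as_edge_set(obj: Gan | ReferenceNetwork | Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    if isinstance(obj, Gan):
        return obj.edge_set()
    if isinstance(obj, ReferenceNetwork):
        return set(obj.edges)
    return {canonical_edge(a, b) for a, b in obj}


def overlap(gan: Gan | Iterable[tuple[str, str]], reference: ReferenceNetwork) -> OverlapResult:
    """Restrict both networks to their common nodes and count shared edges."""
    gan_edges = _as_edge_set(gan)
    ref_edges = _as_edge_set(reference)
    gan_nodes = {n for e in gan_edges for n in e}
    ref_nodes = {n for e in ref_edges for n in e}
    common = gan_nodes & ref_nodes
    if not common:
        raise ValueError(
            "the reconstructed network and the reference share no genes; "
            "check that both use the same symbol namespace"
        )
    gan_sub = {e for e in gan_edges if e[0] in common and e[1] in common}
    ref_sub = {e for e in ref_edges if e[0] in common and e[1] in common}
    return OverlapResult(
        common_nodes=sorted(common),
        gan_sub_edges=gan_sub,
        reference_sub_edges=ref_sub,
        observed_common_edges=len(gan_sub & ref_sub),
    )


def permutation_test(
    gan: Gan | Iterable[tuple[str, str]],
    reference: ReferenceNetwork,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    add_one: bool = False,
) -> EvaluationResult:
    """Node-label permutation test of the network's overlap with the reference.

    Each permutation relabels the reconstructed subnetwork's nodes by a
    uniform bijection of the same node set.  ``add_one`` switches to the
    (b + 1) / (n + 1) estimator; the default denominator is n, matching the
    granularity of permutation p-values at n = 1000.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    ov = overlap(gan, reference)
    if not ov.gan_sub_edges:
        raise ValueError("the reconstructed subnetwork has no edges on the common nodes")
    if rng is None:
        rng = np.random.default_rng(seed)
    nodes = ov.common_nodes
    index = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    adj_ref = np.zeros((m, m), dtype=bool)
    for a, b in ov.reference_sub_edges:
        adj_ref[index[a], index[b]] = adj_ref[index[b], index[a]] = True
    ui = np.array([index[a] for a, _ in ov.gan_sub_edges])
    vi = np.array([index[b] for _, b in ov.gan_sub_edges])
    counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(m)
        counts[i] = int(adj_ref[perm[ui], perm[vi]].sum())
    hits = int((counts >= ov.observed_common_edges).sum())
    if add_one:
        p = (hits + 1) / (n_permutations + 1)
    else:
        p = hits / n_permutations
    return EvaluationResult(
        n_overlap_nodes=m,
        observed_common_edges=ov.observed_common_edges,
        percent_common=ov.percent_common,
        permutation_counts=counts,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
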