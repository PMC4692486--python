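"""Inclusion-match agglomerative clustering of binary activation patterns.

Patterns are active-node sets.  The similarity between two patterns is the
symmetrized inclusion match ``max(|A&B|/|A|, |A&B|/|B|)``; clusters are
merged greedily while the best reference-pattern similarity exceeds a
threshold ``k``.  The double pass runs the algorithm twice: first with the
most-central member as each cluster's reference, then a smoothing pass over
the pass-1 clusters using majority (>50% activation) references.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryPattern:
    """An active-node set over ``n_total`` nodes (0-based indices)."""

    active: frozenset
    n_total: int

    def __post_init__(self):
        active = frozenset(int(i) for i in self.active)
        if active and (min(active) < 0 or max(active) >= self.n_total):
            raise ValueError("active indices out of range")
        object.__setattr__(self, "active", active)

    def __len__(self) -> int:
        return len(self.active)

    def to_vector(self) -> np.ndarray:
        v = np.zeros(self.n_total)
        v[list(self.active)] = 1.0
        return v


@dataclass
class Cluster:
    """A group of binary patterns with a reference pattern."""

    members: list                      # list of BinaryPattern
    reference: BinaryPattern
    member_indices: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def binarize(pattern, threshold: float = 0.5) -> BinaryPattern:
    """Active nodes are those with value strictly above the threshold."""
    v = np.asarray(pattern, dtype=float)
    return BinaryPattern(frozenset(np.flatnonzero(v > threshold).tolist()), v.size)


def inclusion(a: BinaryPattern, b: BinaryPattern) -> float:
    """Proportion of A contained in B: |A & B| / |A|, 0 for empty A."""
    if a.n_total != b.n_total:
        raise ValueError("patterns live on different node counts")
    if not a.active:
        return 0.0
    return len(a.active & b.active) / len(a.active)


def sim_incl(a: BinaryPattern, b: BinaryPattern) -> float:
    """Symmetrized inclusion match: max(incl(A,B), incl(B,A))."""
    return max(inclusion(a, b), inclusion(b, a))


def _majority_pattern(members) -> BinaryPattern:
    """Nodes active in strictly more than half of the member patterns."""
    n_total = members[0].n_total
    counts = np.zeros(n_total)
    for m in members:
        counts[list(m.active)] += 1
    active = np.flatnonzero(counts > len(members) / 2.0)
    return BinaryPattern(frozenset(active.tolist()), n_total)


def _central_pattern(members) -> BinaryPattern:
    """Member maximizing the summed inclusion match with all other members."""
    if len(members) == 1:
        return members[0]
    best, best_score = 0, -1.0
    for i, cand in enumerate(members):
        score = sum(sim_incl(cand, other) for j, other in enumerate(members) if j != i)
        if score > best_score:  # ties: lowest member index
            best, best_score = i, score
    return members[best]


def _reference(members, rule: str) -> BinaryPattern:
    if rule == "max_inclusion_score":
        return _central_pattern(members)
    if rule == "majority":
        return _majority_pattern(members)
    raise ValueError(f"unknown reference rule {rule!r}")


def agglomerate(
    patterns,
    k: float,
    reference_rule: str = "max_inclusion_score",
    initial_clusters=None,
):
    """Greedy agglomeration of patterns while max reference similarity > k.

    Clusters start as singletons (or as ``initial_clusters``, given as
    lists of pattern indices).  At each step the pair of clusters with the
    highest similarity between their reference patterns is merged; ties are
    broken by the lowest (i, j) index pair.  Stops when that maximum drops
    to ``k`` or below.  Returns a list of :class:`Cluster`, descending size.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns to cluster")
    if not (0.0 < k <= 1.0):
        raise ValueError("similarity threshold k must lie in (0, 1]")
    if initial_clusters is None:
        groups = [[i] for i in range(len(patterns))]
    else:
        groups = [list(g) for g in initial_clusters]
    refs = [_reference([patterns[i] for i in g], reference_rule) for g in groups]

    m = len(groups)
    sim = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim_incl(refs[i], refs[j])

    alive = list(range(m))
    while len(alive) > 1:
        sub = sim[np.ix_(alive, alive)]
        iu = np.triu_indices(len(alive), k=1)
        flat = sub[iu]
        best = int(np.argmax(flat))  # argmax scans row-major: lowest (i, j) wins ties
        if flat[best] <= k:
            break
        i, j = iu[0][best], iu[1][best]
        a, b = alive[i], alive[j]
        groups[a] = groups[a] + groups[b]
        refs[a] = _reference([patterns[idx] for idx in groups[a]], reference_rule)
        alive.remove(b)
        for other in alive:
            if other == a:
                continue
            lo, hi = min(a, other), max(a, other)
            sim[lo, hi] = sim_incl(refs[a], refs[other])

    clusters = [
        Cluster(
            members=[patterns[idx] for idx in groups[g]],
            reference=refs[g],
            member_indices=list(groups[g]),
        )
        for g in alive
    ]
    clusters.sort(key=lambda c: (-c.size, c.member_indices[0]))
    return clusters


def double_pass_cluster(patterns, k: float):
    """Two-pass clustering: central references, then a majority smoothing pass.

    Pass 1 clusters the raw patterns with most-central references; pass 2
    re-clusters the pass-1 clusters using majority references.  Degenerate
    clusters whose members are all empty are dropped with a warning.
    Result sorted by descending size.
    """
    pass1 = agglomerate(patterns, k, reference_rule="max_inclusion_score")
    initial = [c.member_indices for c in pass1]
    clusters = agglomerate(
        patterns, k, reference_rule="majority", initial_clusters=initial
    )
    kept = []
    for c in clusters:
        if all(len(m) == 0 for m in c.members):
            logger.warning("dropping cluster of %d all-empty patterns", c.size)
            continue
        kept.append(c)
    return kept


def cluster_core(cluster: Cluster, fraction: float) -> BinaryPattern:
    """Top ``round(fraction * n_total)`` nodes by activation frequency.

    Frequency ties are broken by the lower node index, making the core
    deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n_total = cluster.members[0].n_total
    counts = np.zeros(n_total)
    for m in cluster.members:
        counts[list(m.active)] += 1
    n_core = int(round(fraction * n_total))
    order = np.lexsort((np.arange(n_total), -counts))
    return BinaryPattern(frozenset(order[:n_core].tolist()), n_total)


def match_t_statistic(core: BinaryPattern, reference: BinaryPattern,
                      n_total: int = None):
    """Match fraction of a core against a reference set, with its t-value.

    m = |core & reference| / |core|; under the null hypothesis that the
    core is drawn independently, a core node lands in the reference with
    probability p = |reference| / n_total, so
    t = (m - p) * sqrt(n_core / (p (1 - p))).
    Returns ``(m, t)``.
    """
    if n_total is None:
        n_total = core.n_total
    if not core.active or not reference.active:
        raise ValueError("core and reference must be nonempty")
    n_core = len(core.active)
    m = len(core.active & reference.active) / n_core
    p = len(reference.active) / n_total
    t = (m - p) * math.sqrt(n_core / (p * (1.0 - p)))
    return m, t


def match_band(t: float) -> str:
    """Qualitative label for a match t-value."""
    if t > 9:
        return "strong"
    if t > 6:
        return "good"
    if t > 3:
        return "significant"
    return "n.s."
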