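"""Stage 3 — PPI interconnectivity of clustered miRNA target sets.

For every cluster, the number of protein-protein interactions bridging
the target sets of each pair of member miRNAs is summed and compared to
the same statistic on randomly sampled miRNA sets of equal count (the
permutation null).  Because same-family members share predicted targets
by construction of the seed rule, only the first member of each family
(in genomic order) is counted within a cluster.  Global evidence is
summarised by a Wilcoxon signed-rank test of observed counts against
per-cluster null medians and a Fisher test pooling bridging vs
non-bridging candidate protein pairs over clusters vs null replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .stats import (
    TestResult,
    fisher_exact_greater,
    permutation_pvalue,
    wilcoxon_signed_rank,
)
from .types import (
    ClusterSet,
    DomainError,
    FamilyMap,
    PPINetwork,
    TargetNetwork,
    canonical_pair,
)

logger = logging.getLogger("mircomplex")


def dedupe_family_targets(
    cluster_members: Sequence[str],
    families: FamilyMap,
    network: TargetNetwork,
) -> List[Tuple[str, Set[str]]]:
    """One representative per family, the first in genomic order.

    Members missing from the target network are skipped with a warning.
    """
    seen_families: Set[str] = set()
    out: List[Tuple[str, Set[str]]] = []
    for m in cluster_members:
        targets = network.targets_of.get(m)
        if targets is None:
            logger.warning("dedupe: miRNA %r not in target network", m)
            continue
        fam = families.family_of.get(m)
        if fam is None:
            raise DomainError(f"miRNA {m!r} missing from family map")
        if fam in seen_families:
            continue
        seen_families.add(fam)
        out.append((m, targets))
    return out


def count_inter_target_ppis(
    set_a: Set[str], set_b: Set[str], ppi: PPINetwork
) -> int:
    """PPI edges {u, v} with one endpoint in each set.

    An edge fully inside set_a ∩ set_b is counted once; the count is
    symmetric in (set_a, set_b).
    """
    adjacency = ppi.adjacency
    seen: Set[Tuple[str, str]] = set()
    small, other = (set_a, set_b) if len(set_a) <= len(set_b) else (set_b, set_a)
    for u in small:
        neighbours = adjacency.get(u)
        if not neighbours:
            continue
        for v in neighbours & other:
            seen.add(canonical_pair(u, v))
    return len(seen)


def _inter_pair_candidates(set_a: Set[str], set_b: Set[str]) -> int:
    """Number of distinct unordered protein pairs with one member per set."""
    inter = len(set_a & set_b)
    na, nb = len(set_a), len(set_b)
    # pairs u in A, v in B, u != v, unordered distinct:
    # |A||B| - inter (self pairs) - C(inter, 2) double-counted cross pairs
    return na * nb - inter - (inter * (inter - 1)) // 2


def _pairs_statistic(
    target_sets: Sequence[Set[str]], ppi: PPINetwork
) -> Tuple[int, int]:
    """Summed bridging edges and candidate pairs over all unordered set pairs."""
    edges = 0
    candidates = 0
    for i in range(len(target_sets)):
        for j in range(i + 1, len(target_sets)):
            edges += count_inter_target_ppis(target_sets[i], target_sets[j], ppi)
            candidates += _inter_pair_candidates(target_sets[i], target_sets[j])
    return edges, candidates


@dataclass
class InterconnectivityResult:
    cluster_id: str
    n_mirnas_used: int
    observed_edges: int
    null_edges: List[int]
    p_perm: float
    observed_pairs: int = 0
    null_pairs: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = len(self.null_edges)
        if r and not (1.0 / (r + 1) <= self.p_perm <= 1.0):
            raise DomainError("permutation p outside its achievable range")


def cluster_interconnectivity(
    cluster_id: str,
    cluster_members: Sequence[str],
    network: TargetNetwork,
    families: FamilyMap,
    ppi: PPINetwork,
    R: int = 1000,
    rng: np.random.Generator | int | None = None,
    exclude_same_family: bool = False,
    match_degree: bool = False,
) -> Optional[InterconnectivityResult]:
    """Permutation test of a cluster's inter-target PPI count.

    The null draws the same number of miRNAs uniformly without
    replacement from all non-cluster miRNAs in the network (optionally
    excluding same-family miRNAs, optionally matched on target-set size
    decile) and recomputes the statistic.  Returns None (with a warning)
    when family deduplication leaves < 2 representatives.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reps = dedupe_family_targets(cluster_members, families, network)
    if len(reps) < 2:
        logger.warning(
            "cluster %r: fewer than 2 family representatives, skipped", cluster_id
        )
        return None
    rep_sets = [t for _, t in reps]
    observed, observed_pairs = _pairs_statistic(rep_sets, ppi)

    member_set = set(cluster_members)
    candidates = [m for m in sorted(network.targets_of) if m not in member_set]
    if exclude_same_family:
        cluster_fams = {families.family_of.get(m) for m in cluster_members}
        candidates = [
            m for m in candidates if families.family_of.get(m) not in cluster_fams
        ]
    n_repr = len(reps)
    if len(candidates) < n_repr:
        raise DomainError(
            f"cluster {cluster_id!r}: only {len(candidates)} candidate miRNAs "
            f"for {n_repr} representatives"
        )

    size_bins: Dict[str, int] = {}
    bin_members: Dict[int, List[str]] = {}
    if match_degree:
        sizes = np.array([len(network.targets_of[m]) for m in candidates])
        edges = np.quantile(sizes, np.linspace(0, 1, 11)[1:-1])
        for m, s in zip(candidates, sizes):
            b = int(np.searchsorted(edges, s, side="right"))
            size_bins[m] = b
            bin_members.setdefault(b, []).append(m)

    null_edges: List[int] = []
    null_pairs: List[int] = []
    for _ in range(R):
        if match_degree:
            drawn: List[str] = []
            used: Set[str] = set()
            for rep, _targets in reps:
                size = len(network.targets_of[rep])
                b = int(np.searchsorted(edges, size, side="right"))
                pool = [m for m in bin_members.get(b, candidates) if m not in used]
                if not pool:
                    pool = [m for m in candidates if m not in used]
                pick = pool[int(rng.integers(len(pool)))]
                used.add(pick)
                drawn.append(pick)
        else:
            idx = rng.choice(len(candidates), size=n_repr, replace=False)
            drawn = [candidates[i] for i in idx]
        sets = [network.targets_of[m] for m in drawn]
        e, c = _pairs_statistic(sets, ppi)
        null_edges.append(e)
        null_pairs.append(c)

    p = permutation_pvalue(observed, null_edges, "greater")
    return InterconnectivityResult(
        cluster_id,
        n_repr,
        observed,
        null_edges,
        p,
        observed_pairs,
        null_pairs,
    )


def interconnectivity_all(
    clusters: ClusterSet,
    network: TargetNetwork,
    families: FamilyMap,
    ppi: PPINetwork,
    R: int = 1000,
    rng: np.random.Generator | int | None = None,
    exclude_same_family: bool = False,
    match_degree: bool = False,
) -> List[InterconnectivityResult]:
    """Run the permutation test for every cluster (skipping degenerate ones)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: List[InterconnectivityResult] = []
    for cid in sorted(clusters.clusters):
        res = cluster_interconnectivity(
            cid,
            clusters.clusters[cid],
            network,
            families,
            ppi,
            R=R,
            rng=rng,
            exclude_same_family=exclude_same_family,
            match_degree=match_degree,
        )
        if res is not None:
            out.append(res)
    return out


def global_interconnectivity_summary(
    results: Sequence[InterconnectivityResult], alpha: float = 0.05
) -> Tuple[TestResult, TestResult, int]:
    """Global Wilcoxon, Fisher and significant-cluster count.

    Wilcoxon signed-rank compares observed bridging counts against the
    per-cluster null medians (alternative greater).  The Fisher 2x2 pools
    (bridging edges, non-bridging candidate pairs) over clusters against
    the same pooled over all null replicates; its construction is
    reported in the TestResult method string so it can be swapped.
    """
    if len(results) < 6:
        raise DomainError(f"need >= 6 clusters with results, got {len(results)}")
    pairs = [
        (float(r.observed_edges), float(np.median(r.null_edges))) for r in results
    ]
    wilcoxon = wilcoxon_signed_rank(pairs, alternative="greater")

    a = sum(r.observed_edges for r in results)
    obs_pairs = sum(r.observed_pairs for r in results)
    c = sum(sum(r.null_edges) for r in results)
    null_pairs = sum(sum(r.null_pairs) for r in results)
    fisher = fisher_exact_greater(a, obs_pairs - a, c, null_pairs - c)
    fisher.method = (
        "fisher_exact[rows=cluster|pooled-null, cols=bridging|non-bridging pairs]"
    )
    n_significant = sum(1 for r in results if r.p_perm < alpha)
    return wilcoxon, fisher, n_significant
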