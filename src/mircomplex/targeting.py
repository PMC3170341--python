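"""Stage 1 — association of protein complexes with miRNA target sets.

For each unit (a single miRNA or a cluster, taken as the union of its
members' target sets) and each complex, the overlap N_c between the
unit's N_t targets and the K complex members is scored against the
hypergeometric upper tail in the universe N = N_T ∪ N_C (all targets
plus all complex members).  Family-wise correction is applied over all
materialised (unit, complex) pairs by default, or per unit with a second
Bonferroni level across units.

A record is emitted for every pair with N_c >= 1 (records with N_c = 1
feed the fold-change validation) but significance additionally requires
N_c >= min_targets (default 2: a "co-targeted" complex needs two hit
subunits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .stats import adjust_pvalues, hypergeom_tail_geq
from .types import (
    ClusterSet,
    ComplexCatalog,
    DomainError,
    TargetNetwork,
    ValidationError,
)

logger = logging.getLogger("mircomplex")

ASSOCIATION_COLUMNS = (
    "unit_id",
    "complex_id",
    "complex_description",
    "N_c",
    "N_t",
    "K",
    "N",
    "p_raw",
    "p_adj",
    "significant",
)


@dataclass
class AssociationRecord:
    unit_id: str
    complex_id: str
    complex_description: str
    N_c: int
    N_t: int
    K: int
    N: int
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False


def build_universe(network: TargetNetwork, catalog: ComplexCatalog) -> Set[str]:
    """Universe N = all miRNA targets N_T union all complex members N_C."""
    universe = network.all_targets | catalog.all_members
    if not universe:
        raise DomainError("empty protein universe")
    return universe


def _associate_units(
    unit_targets: Mapping[str, Set[str]],
    catalog: ComplexCatalog,
    universe: Set[str],
    alpha: float,
    min_targets: int,
    correction: str,
    correction_scope: str,
    family_m: int,
) -> List[AssociationRecord]:
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha={alpha} outside (0, 1)")
    if correction_scope not in ("pairs", "units"):
        raise DomainError(f"unknown correction scope {correction_scope!r}")
    N = len(universe)
    member_sets = {
        cid: cx.members & universe for cid, cx in catalog.complexes.items()
    }
    records: List[AssociationRecord] = []
    for unit_id, targets in unit_targets.items():
        t = targets & universe
        n_t = len(t)
        if n_t == 0:
            continue
        for cid, members in member_sets.items():
            k_size = len(members)
            if k_size == 0:
                continue
            n_c = len(t & members)
            if n_c == 0:
                continue
            p_raw = hypergeom_tail_geq(n_c, k_size, n_t, N)
            records.append(
                AssociationRecord(
                    unit_id,
                    cid,
                    catalog.complexes[cid].description,
                    n_c,
                    n_t,
                    k_size,
                    N,
                    p_raw,
                )
            )
    if not records:
        return records

    if correction_scope == "pairs":
        adjusted = adjust_pvalues(
            [r.p_raw for r in records], correction, m=len(records)
        )
        for r, p_adj in zip(records, adjusted):
            r.p_adj = p_adj
    else:  # per-unit step, then Bonferroni across the family of units
        by_unit: Dict[str, List[AssociationRecord]] = {}
        for r in records:
            by_unit.setdefault(r.unit_id, []).append(r)
        for unit_records in by_unit.values():
            adjusted = adjust_pvalues(
                [r.p_raw for r in unit_records], correction, m=len(unit_records)
            )
            for r, p_adj in zip(unit_records, adjusted):
                r.p_adj = min(1.0, p_adj * family_m)

    for r in records:
        r.significant = bool(r.p_adj < alpha and r.N_c >= min_targets)
    records.sort(key=lambda r: (r.p_raw, r.unit_id, r.complex_id))
    return records


def associate_single(
    network: TargetNetwork,
    catalog: ComplexCatalog,
    alpha: float = 0.05,
    min_targets: int = 2,
    correction: str = "holm",
    correction_scope: str = "pairs",
    family_m: Optional[int] = None,
) -> List[AssociationRecord]:
    """Associate every single miRNA's target set with every complex.

    ``family_m`` (used by the ``units`` correction scope) defaults to the
    number of miRNAs in the network — all miRNAs count toward the family
    even if they produced no overlap anywhere.
    """
    universe = build_universe(network, catalog)
    if family_m is None:
        family_m = len(network.targets_of)
    return _associate_units(
        network.targets_of,
        catalog,
        universe,
        alpha,
        min_targets,
        correction,
        correction_scope,
        family_m,
    )


def cluster_target_sets(
    clusters: ClusterSet, network: TargetNetwork
) -> Dict[str, Set[str]]:
    """Union of member target sets per cluster; unresolvable members skipped."""
    out: Dict[str, Set[str]] = {}
    for cid, members in clusters.clusters.items():
        union: Set[str] = set()
        n_found = 0
        for m in members:
            ts = network.targets_of.get(m)
            if ts is None:
                logger.warning("cluster %r: miRNA %r not in target network", cid, m)
                continue
            union |= ts
            n_found += 1
        if n_found == 0:
            logger.warning("cluster %r: no resolvable miRNAs, skipped", cid)
            continue
        out[cid] = union
    return out


def associate_cluster(
    clusters: ClusterSet,
    network: TargetNetwork,
    catalog: ComplexCatalog,
    alpha: float = 0.05,
    min_targets: int = 2,
    correction: str = "holm",
    correction_scope: str = "pairs",
    family_m: Optional[int] = None,
) -> List[AssociationRecord]:
    """Associate each cluster's unified target set with every complex."""
    universe = build_universe(network, catalog)
    unit_targets = cluster_target_sets(clusters, network)
    if family_m is None:
        family_m = len(clusters.clusters)
    return _associate_units(
        unit_targets,
        catalog,
        universe,
        alpha,
        min_targets,
        correction,
        correction_scope,
        family_m,
    )


def targeted_components(
    records: Iterable[AssociationRecord],
    network: TargetNetwork,
    catalog: ComplexCatalog,
    clusters: Optional[ClusterSet] = None,
) -> Set[str]:
    """Union over significant records of (complex members ∩ unit targets).

    Unit ids are resolved in the target network first; failing that, as
    cluster ids (whose target set is the member union).
    """
    cluster_sets = cluster_target_sets(clusters, network) if clusters else {}
    out: Set[str] = set()
    for r in records:
        if not r.significant:
            continue
        if r.unit_id in network.targets_of:
            targets = network.targets_of[r.unit_id]
        elif r.unit_id in cluster_sets:
            targets = cluster_sets[r.unit_id]
        else:
            raise DomainError(f"unit {r.unit_id!r} not resolvable")
        out |= targets & catalog.complexes[r.complex_id].members
    return out


def term_enrichment(
    foreground: Set[str],
    background: Set[str],
    annotation: Mapping[str, Set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of flat term -> gene sets.

    Per term, the over-representation p is the upper tail of the overlap
    of foreground with the term inside the background; the
    under-representation p is the complementary lower tail.
    Benjamini-Hochberg is applied across terms (separately per
    direction).  Terms disjoint from the background are skipped.
    """
    from statsmodels.stats.multitest import multipletests

    if not foreground <= background:
        raise DomainError("foreground must be a subset of background")
    n_bg = len(background)
    n_fg = len(foreground)
    rows = []
    for term, genes in annotation.items():
        in_bg = genes & background
        if not in_bg:
            continue
        k = len(foreground & in_bg)
        p_over = hypergeom_tail_geq(k, len(in_bg), n_fg, n_bg)
        # under-representation: P(X <= k) = 1 - P(X >= k + 1)
        if k + 1 > min(n_fg, len(in_bg)):
            p_under = 1.0
        else:
            p_under = max(0.0, 1.0 - hypergeom_tail_geq(k + 1, len(in_bg), n_fg, n_bg))
        rows.append((term, k, len(in_bg), n_fg, n_bg, p_over, p_under))
    df = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_over", "p_under"]
    )
    if len(df):
        df["q_over"] = multipletests(df["p_over"], method="fdr_bh")[1]
        df["q_under"] = multipletests(df["p_under"], method="fdr_bh")[1]
        df["significant_over"] = df["q_over"] < alpha
        df["significant_under"] = df["q_under"] < alpha
        df = df.sort_values("p_over", kind="stable").reset_index(drop=True)
    return df


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.unit_id,
                r.complex_id,
                r.complex_description,
                r.N_c,
                r.N_t,
                r.K,
                r.N,
                r.p_raw,
                r.p_adj,
                r.significant,
            )
            for r in records
        ],
        columns=list(ASSOCIATION_COLUMNS),
    )


def distinct_significant_complexes(records: Iterable[AssociationRecord]) -> Set[str]:
    """Distinct complex ids significant for at least one unit."""
    return {r.complex_id for r in records if r.significant}
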