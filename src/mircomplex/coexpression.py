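"""Stage 2 — co-expression of miRNAs that co-target the same complex.

Pairwise Pearson correlations (PC values) of miRNA expression profiles
across tissues/cell types are pooled for miRNA pairs that significantly
target a common complex and compared to the remaining pairwise PC values
with a one-sided KS test (foreground stochastically greater).  Two
controls guard against trivial explanations: pairs sharing a
transcription unit can be excluded from the foreground (polycistronic
miRNAs are co-expressed by construction) and the foreground can be
restricted to cross-family pairs (same-seed miRNAs share target sets by
definition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .stats import TestResult, ks_one_sided
from .targeting import AssociationRecord
from .types import ClusterSet, DomainError, ExpressionMatrix, FamilyMap, canonical_pair

logger = logging.getLogger("mircomplex")

Pair = Tuple[str, str]


def pairwise_pc(expr: ExpressionMatrix, mirnas: Iterable[str]) -> Dict[Pair, float]:
    """Pearson r for every unordered pair of the given miRNAs.

    miRNAs absent from the matrix and zero-variance profiles are skipped
    with a log message; requires >= 3 conditions.
    """
    wanted = sorted(set(mirnas))
    present = [m for m in wanted if m in expr.data.index]
    absent = len(wanted) - len(present)
    if absent:
        logger.info("pairwise_pc: %d miRNAs absent from expression matrix", absent)
    if len(expr.conditions) < 3:
        raise DomainError("correlation needs >= 3 conditions")
    if len(present) < 2:
        return {}
    sub = expr.data.loc[present].to_numpy(dtype=float)
    sds = sub.std(axis=1)
    keep = sds > 0.0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("pairwise_pc: skipped %d zero-variance profiles", n_zero)
    names = [m for m, k in zip(present, keep) if k]
    if len(names) < 2:
        return {}
    r = np.corrcoef(sub[keep])
    out: Dict[Pair, float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[canonical_pair(names[i], names[j])] = float(
                np.clip(r[i, j], -1.0, 1.0)
            )
    return out


def co_targeting_pairs(
    records: Iterable[AssociationRecord],
) -> Dict[Pair, Set[str]]:
    """Unordered miRNA pairs significant for >= 1 common complex.

    Returns pair -> set of shared complex ids.
    """
    units_of_complex: Dict[str, Set[str]] = {}
    for r in records:
        if r.significant:
            units_of_complex.setdefault(r.complex_id, set()).add(r.unit_id)
    out: Dict[Pair, Set[str]] = {}
    for cid, units in units_of_complex.items():
        ordered = sorted(units)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                out.setdefault(canonical_pair(ordered[i], ordered[j]), set()).add(cid)
    return out


@dataclass
class PCComparison:
    """KS comparison of foreground vs background PC values plus filter report."""

    result: TestResult
    n_foreground: int
    n_background: int
    frac_same_tu_excluded: float = 0.0
    n_cross_family_dropped: int = 0
    filters: List[str] = field(default_factory=list)


def compare_pc_distributions(
    foreground_pairs: Mapping[Pair, Set[str]] | Iterable[Pair],
    pc: Mapping[Pair, float],
    exclude_same_tu: bool = False,
    restrict_cross_family: bool = False,
    clusters: Optional[ClusterSet] = None,
    families: Optional[FamilyMap] = None,
    weight_by_complex: bool = False,
) -> PCComparison:
    """One-sided KS of co-targeting PC values vs all other PC values.

    The background is every defined pairwise PC value not in the
    (unfiltered) foreground, so no pair is double-counted.  With
    ``exclude_same_tu`` pairs whose members share a transcription unit
    are removed from the foreground and their fraction reported; with
    ``restrict_cross_family`` only cross-family pairs are kept.  A pair
    targeting several complexes contributes once unless
    ``weight_by_complex`` counts its multiplicity.
    """
    if isinstance(foreground_pairs, Mapping):
        fg_map: Dict[Pair, int] = {
            canonical_pair(*p): max(1, len(c)) for p, c in foreground_pairs.items()
        }
    else:
        fg_map = {canonical_pair(*p): 1 for p in foreground_pairs}
    fg_all = {p: w for p, w in fg_map.items() if p in pc}

    filters: List[str] = []
    fg = dict(fg_all)
    frac_same_tu = 0.0
    if exclude_same_tu:
        if clusters is None:
            raise DomainError("exclude_same_tu requires cluster/TU definitions")
        before = len(fg)
        fg = {
            (a, b): w
            for (a, b), w in fg.items()
            if clusters.tu_of.get(a) is None
            or clusters.tu_of.get(a) != clusters.tu_of.get(b)
        }
        frac_same_tu = (before - len(fg)) / before if before else 0.0
        filters.append(f"exclude_same_tu (removed {before - len(fg)})")
    n_family_dropped = 0
    if restrict_cross_family:
        if families is None:
            raise DomainError("restrict_cross_family requires a family map")
        before = len(fg)
        fg = {
            (a, b): w
            for (a, b), w in fg.items()
            if families.family_of.get(a) != families.family_of.get(b)
            or families.family_of.get(a) is None
        }
        n_family_dropped = before - len(fg)
        filters.append(f"restrict_cross_family (removed {n_family_dropped})")

    if not fg:
        raise DomainError(
            "empty foreground after filters: " + (", ".join(filters) or "none")
        )

    fg_values: List[float] = []
    for p, w in fg.items():
        fg_values.extend([pc[p]] * (w if weight_by_complex else 1))
    bg_values = [r for p, r in pc.items() if p not in fg_all]
    if not bg_values:
        raise DomainError("empty background: every defined pair is in the foreground")

    result = ks_one_sided(fg_values, bg_values, alternative="a_greater")
    return PCComparison(
        result=result,
        n_foreground=len(fg_values),
        n_background=len(bg_values),
        frac_same_tu_excluded=frac_same_tu,
        n_cross_family_dropped=n_family_dropped,
        filters=filters,
    )


def per_complex_mean_pc(
    records: Iterable[AssociationRecord], pc: Mapping[Pair, float]
) -> Dict[str, float]:
    """Mean pairwise PC of the miRNAs significantly targeting each complex.

    Complexes with fewer than 2 significant miRNAs with defined pairwise
    correlations are omitted.
    """
    units_of_complex: Dict[str, Set[str]] = {}
    for r in records:
        if r.significant:
            units_of_complex.setdefault(r.complex_id, set()).add(r.unit_id)
    out: Dict[str, float] = {}
    for cid, units in units_of_complex.items():
        ordered = sorted(units)
        values = [
            pc[canonical_pair(a, b)]
            for i, a in enumerate(ordered)
            for b in ordered[i + 1 :]
            if canonical_pair(a, b) in pc
        ]
        if values:
            out[cid] = float(np.mean(values))
    return out
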