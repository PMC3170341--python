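"""Domain types for the miRNA / protein-complex co-regulation analyses.

Identifiers (miRNA ids, protein ids, complex ids, cluster ids, family ids)
are opaque, case-sensitive strings throughout; no mapping between gene
symbols and protein accessions is attempted — harmonising namespaces is the
caller's job.

Every constructor validates its type's invariants; a structurally invalid
object is never built silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

import pandas as pd

logger = logging.getLogger("mircomplex")


class MirComplexError(Exception):
    """Base class for all package errors."""


class ParseError(MirComplexError, ValueError):
    """Malformed on-disk input; the message names the offending line."""


class ValidationError(MirComplexError, ValueError):
    """A domain-type invariant would be violated."""


class DomainError(MirComplexError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


class UndefinedCorrelationError(DomainError):
    """Pearson correlation requested for a zero-variance profile."""


class PipelineError(MirComplexError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Order-independent representation of an unordered pair of ids."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Target network and complex catalog
# ---------------------------------------------------------------------------

@dataclass
class TargetNetwork:
    """Bipartite miRNA -> protein target map.

    ``all_targets`` is the union of all target sets (the N_T of the
    association test); ``all_mirnas`` the set of miRNA ids.
    """

    targets_of: Dict[str, Set[str]]

    def __post_init__(self) -> None:
        if not self.targets_of:
            raise ValidationError("target network is empty")
        for m, ts in self.targets_of.items():
            if not m:
                raise ValidationError("empty miRNA identifier")
            if not isinstance(ts, set):
                self.targets_of[m] = set(ts)
                ts = self.targets_of[m]
            if any(not p for p in ts):
                raise ValidationError(f"empty protein identifier in targets of {m!r}")

    @property
    def all_mirnas(self) -> Set[str]:
        return set(self.targets_of)

    @property
    def all_targets(self) -> Set[str]:
        out: Set[str] = set()
        for ts in self.targets_of.values():
            out |= ts
        return out


@dataclass
class ProteinComplex:
    description: str
    members: Set[str]


@dataclass
class ComplexCatalog:
    """Non-redundant catalog of named protein complexes (>= 2 members each)."""

    complexes: Dict[str, ProteinComplex]

    def __post_init__(self) -> None:
        if not self.complexes:
            raise ValidationError("complex catalog is empty")
        seen: Dict[FrozenSet[str], str] = {}
        for cid, cx in self.complexes.items():
            if len(cx.members) < 2:
                raise ValidationError(f"complex {cid!r} has fewer than 2 members")
            if any(not p for p in cx.members):
                raise ValidationError(f"empty protein identifier in complex {cid!r}")
            key = frozenset(cx.members)
            if key in seen:
                raise ValidationError(
                    f"complexes {seen[key]!r} and {cid!r} have identical member sets"
                )
            seen[key] = cid

    @property
    def all_members(self) -> Set[str]:
        out: Set[str] = set()
        for cx in self.complexes.values():
            out |= cx.members
        return out


@dataclass
class EnrichmentContingency:
    """Counts feeding the hypergeometric association test.

    N_c targets of the unit inside the complex, out of N_t unit targets,
    against a complex of size K inside a universe of N proteins.
    """

    N_c: int
    N_t: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if min(self.N_c, self.N_t, self.K, self.N) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.N_c > min(self.N_t, self.K):
            raise ValidationError("overlap N_c exceeds min(N_t, K)")
        if self.K > self.N or self.N_t > self.N:
            raise ValidationError("K and N_t must not exceed the universe size N")


# ---------------------------------------------------------------------------
# Clusters, families, PPI
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Polycistronic miRNA clusters; member order is genomic order.

    Every clustered miRNA carries a transcription-unit id equal to its
    cluster id; a miRNA belongs to at most one cluster.
    """

    clusters: Dict[str, List[str]]
    tu_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assigned: Dict[str, str] = {}
        for cid, members in self.clusters.items():
            if len(members) < 2:
                raise ValidationError(f"cluster {cid!r} has fewer than 2 miRNAs")
            if len(set(members)) != len(members):
                raise ValidationError(f"cluster {cid!r} lists a miRNA twice")
            for m in members:
                if m in assigned:
                    raise ValidationError(
                        f"miRNA {m!r} assigned to clusters {assigned[m]!r} and {cid!r}"
                    )
                assigned[m] = cid
        for m, cid in assigned.items():
            tu = self.tu_of.setdefault(m, cid)
            if tu != cid:
                raise ValidationError(
                    f"clustered miRNA {m!r} has TU {tu!r} != cluster id {cid!r}"
                )


@dataclass
class FamilyMap:
    """miRNA -> seed-family id. Must cover every miRNA an analysis touches."""

    family_of: Dict[str, str]

    def __post_init__(self) -> None:
        for m, f in self.family_of.items():
            if not m or not f:
                raise ValidationError("empty miRNA or family identifier")


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction network, no self-loops."""

    edges: Set[Tuple[str, str]]
    _adjacency: Dict[str, Set[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            canon.add(canonical_pair(u, v))
        self.edges = canon

    @property
    def adjacency(self) -> Dict[str, Set[str]]:
        if self._adjacency is None:
            adj: Dict[str, Set[str]] = {}
            for u, v in self.edges:
                adj.setdefault(u, set()).add(v)
                adj.setdefault(v, set()).add(u)
            self._adjacency = adj
        return self._adjacency


# ---------------------------------------------------------------------------
# Expression, fold changes, sites
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """miRNA x condition matrix of non-negative expression levels.

    ``data`` is indexed by miRNA id with condition ids as columns.  At
    least 3 conditions are needed for any correlation analysis; readers
    accept fewer and the correlation stage rejects them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("expression levels must be non-negative")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate miRNA rows in expression matrix")

    @property
    def conditions(self) -> List[str]:
        return list(self.data.columns)

    @property
    def mirnas(self) -> List[str]:
        return list(self.data.index)


@dataclass
class FoldChangeTable:
    """Per-perturbation (over-expressed miRNA) log2 protein fold changes."""

    fold_changes: Dict[str, Dict[str, float]]

    def __post_init__(self) -> None:
        for pert, m in self.fold_changes.items():
            if not pert:
                raise ValidationError("empty perturbation identifier")
            for prot, fc in m.items():
                if not prot:
                    raise ValidationError(f"empty protein id in perturbation {pert!r}")
                if not math.isfinite(fc):
                    raise ValidationError(
                        f"non-finite fold change for {prot!r} in {pert!r}"
                    )

    @property
    def perturbations(self) -> List[str]:
        return list(self.fold_changes)


SITE_COLUMNS = ("mirna", "protein", "p_value", "energy")


@dataclass
class SiteTable:
    """Predicted duplex sites: (miRNA, protein, p_value, energy).

    Energy is a hybridisation stability score (kcal/mol-like; lower =
    more stable duplex).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"site table lacks columns {missing}")
        p = self.rows["p_value"]
        if ((p < 0) | (p > 1)).any() or p.isna().any():
            raise ValidationError("site p-values must lie in [0, 1]")
        e = self.rows["energy"]
        if (~e.map(math.isfinite)).any():
            raise ValidationError("site energies must be finite")

    def __len__(self) -> int:
        return len(self.rows)
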