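"""Readers and writers for the on-disk formats.

All formats are plain UTF-8 TSV with Unix newlines and no quoting.
Comment lines starting with ``#`` and one optional header row are
tolerated everywhere, so exports from target/complex databases that
carry a title line load unchanged.

Formats:

* target network  — 2 columns: mirna, protein
* complex catalog — GMT: complex_id, description, member1, member2, ...
* clusters        — 2 columns: cluster_id, mirna (rows in genomic order)
* families        — 2 columns: mirna, family_id
* PPI             — 2 columns: protein_a, protein_b
* expression      — matrix; first column mirna, header row of condition ids
* fold changes    — 3 columns: perturbation, protein, log2fc
* sites           — 4 columns: mirna, protein, p_value, energy
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

import pandas as pd

from .types import (
    SITE_COLUMNS,
    ClusterSet,
    ComplexCatalog,
    ExpressionMatrix,
    FamilyMap,
    FoldChangeTable,
    PPINetwork,
    ParseError,
    ProteinComplex,
    SiteTable,
    TargetNetwork,
    ValidationError,
    canonical_pair,
)

logger = logging.getLogger("mircomplex")


def _data_lines(path: str | Path) -> Iterator[Tuple[int, List[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _rows(
    path: str | Path, n_cols: int, header: Sequence[str]
) -> List[Tuple[int, List[str]]]:
    """Collect fixed-width rows, dropping an optional header line."""
    out: List[Tuple[int, List[str]]] = []
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            if [f.strip().lower() for f in fields] == list(header):
                continue
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
            )
        if any(not f.strip() for f in fields):
            raise ParseError(f"{path}: line {lineno}: empty field")
        out.append((lineno, [f.strip() for f in fields]))
    if not out:
        raise ParseError(f"{path}: no data rows")
    return out


# ---------------------------------------------------------------------------
# Target network
# ---------------------------------------------------------------------------

def read_target_network(path: str | Path) -> TargetNetwork:
    """Read a two-column miRNA -> protein map; duplicate rows collapse."""
    targets: Dict[str, Set[str]] = {}
    for _, (mirna, protein) in _rows(path, 2, ("mirna", "protein")):
        targets.setdefault(mirna, set()).add(protein)
    return TargetNetwork(targets)


def write_target_network(network: TargetNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mirna\tprotein\n")
        for mirna in sorted(network.targets_of):
            for protein in sorted(network.targets_of[mirna]):
                fh.write(f"{mirna}\t{protein}\n")


# ---------------------------------------------------------------------------
# Complex catalog (GMT)
# ---------------------------------------------------------------------------

def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read a GMT catalog; undersized complexes are dropped, duplicates merged.

    Complexes with < 2 distinct members are dropped with a warning (the
    association test needs >= 2 targets inside a complex, so they could
    never be reported).  Identical member sets are merged keeping the
    lexicographically smallest id, so the catalog is non-redundant and
    deterministic regardless of input order.
    """
    parsed: Dict[str, ProteinComplex] = {}
    first = True
    for lineno, fields in _data_lines(path):
        if first:
            first = False
            if (
                len(fields) >= 2
                and fields[0].strip().lower() in ("complex_id", "id")
                and fields[1].strip().lower() == "description"
            ):
                continue
        if len(fields) < 3:
            raise ParseError(
                f"{path}: line {lineno}: GMT rows need id, description and >= 1 member"
            )
        cid, desc, *members = (f.strip() for f in fields)
        if not cid or any(not m for m in members):
            raise ParseError(f"{path}: line {lineno}: empty identifier")
        if cid in parsed:
            raise ParseError(f"{path}: line {lineno}: duplicate complex id {cid!r}")
        member_set = set(members)
        if len(member_set) < 2:
            logger.warning("dropping complex %r: fewer than 2 distinct members", cid)
            continue
        parsed[cid] = ProteinComplex(desc, member_set)

    by_members: Dict[frozenset, str] = {}
    kept: Dict[str, ProteinComplex] = {}
    for cid in sorted(parsed):
        key = frozenset(parsed[cid].members)
        if key in by_members:
            logger.warning(
                "merging complex %r into %r (identical member sets)",
                cid,
                by_members[key],
            )
            continue
        by_members[key] = cid
        kept[cid] = parsed[cid]
    if not kept:
        raise ParseError(f"{path}: no valid complex remains after filtering")
    return ComplexCatalog(kept)


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cid in sorted(catalog.complexes):
            cx = catalog.complexes[cid]
            fh.write("\t".join([cid, cx.description, *sorted(cx.members)]) + "\n")


# ---------------------------------------------------------------------------
# Clusters and families
# ---------------------------------------------------------------------------

def read_clusters_families(
    cluster_path: str | Path, family_path: str | Path
) -> Tuple[ClusterSet, FamilyMap]:
    """Read cluster membership (genomic row order) and the family map.

    Errors on a miRNA assigned to two clusters and on clustered miRNAs
    absent from the family file; singleton clusters are rejected.
    """
    clusters: Dict[str, List[str]] = {}
    owner: Dict[str, str] = {}
    for lineno, (cid, mirna) in _rows(cluster_path, 2, ("cluster_id", "mirna")):
        if mirna in owner and owner[mirna] != cid:
            raise ValidationError(
                f"{cluster_path}: line {lineno}: miRNA {mirna!r} already in "
                f"cluster {owner[mirna]!r}"
            )
        if mirna in clusters.get(cid, ()):  # duplicate row
            continue
        owner[mirna] = cid
        clusters.setdefault(cid, []).append(mirna)

    family: Dict[str, str] = {}
    for _, (mirna, fid) in _rows(family_path, 2, ("mirna", "family_id")):
        family[mirna] = fid

    for cid, members in clusters.items():
        if len(members) < 2:
            raise ValidationError(f"cluster {cid!r} is a singleton")
        for m in members:
            if m not in family:
                raise ValidationError(
                    f"clustered miRNA {m!r} missing from family file {family_path}"
                )
    return ClusterSet(clusters), FamilyMap(family)


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cluster_id\tmirna\n")
        for cid in sorted(clusters.clusters):
            for mirna in clusters.clusters[cid]:  # preserve genomic order
                fh.write(f"{cid}\t{mirna}\n")


def write_families(families: FamilyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mirna\tfamily_id\n")
        for mirna in sorted(families.family_of):
            fh.write(f"{mirna}\t{families.family_of[mirna]}\n")


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def read_ppi(path: str | Path) -> PPINetwork:
    """Read an undirected edge list; self-loops dropped with a warning."""
    edges: Set[Tuple[str, str]] = set()
    n_loops = 0
    for lineno, (a, b) in _rows(path, 2, ("protein_a", "protein_b")):
        if a == b:
            n_loops += 1
            continue
        edges.add(canonical_pair(a, b))
    if n_loops:
        logger.warning("%s: dropped %d self-loop rows", path, n_loops)
    if not edges:
        raise ParseError(f"{path}: no edges remain")
    return PPINetwork(edges)


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a miRNA x condition matrix (header row of condition ids required)."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, header=0, dtype=str
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty expression matrix")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        return ExpressionMatrix(values)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="mirna", lineterminator="\n")


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def read_foldchanges(path: str | Path) -> FoldChangeTable:
    table: Dict[str, Dict[str, float]] = {}
    for lineno, (pert, protein, fc) in _rows(
        path, 3, ("perturbation", "protein", "log2fc")
    ):
        try:
            value = float(fc)
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric fold change {fc!r}"
            ) from None
        per = table.setdefault(pert, {})
        if protein in per:
            raise ParseError(
                f"{path}: line {lineno}: protein {protein!r} repeated in "
                f"perturbation {pert!r}"
            )
        per[protein] = value
    return FoldChangeTable(table)


def write_foldchanges(fc: FoldChangeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("perturbation\tprotein\tlog2fc\n")
        for pert in sorted(fc.fold_changes):
            for protein in sorted(fc.fold_changes[pert]):
                fh.write(f"{pert}\t{protein}\t{fc.fold_changes[pert][protein]:.6g}\n")


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> SiteTable:
    records = []
    for lineno, (mirna, protein, p, e) in _rows(path, 4, SITE_COLUMNS):
        try:
            p_value, energy = float(p), float(e)
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric p-value or energy"
            ) from None
        if not 0.0 <= p_value <= 1.0:
            raise ParseError(
                f"{path}: line {lineno}: p-value {p_value} outside [0, 1]"
            )
        records.append((mirna, protein, p_value, energy))
    df = pd.DataFrame(records, columns=list(SITE_COLUMNS))
    return SiteTable(df)


def write_sites(sites: SiteTable, path: str | Path) -> None:
    sites.rows.to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.6g"
    )
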