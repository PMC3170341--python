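"""Synthetic scenario bundles with planted coordinate regulation.

The generator emulates, at desk scale, the data landscape the analyses
consume: a miRNA -> protein target network (TargetScan-like), a catalog
of protein complexes (CORUM-like, overlapping membership allowed), miRNA
clusters/transcription units with a seed-family map (miRBase-like), a
PPI edge list, a miRNA x tissue expression matrix, per-perturbation
proteomics log2 fold changes, and a duplex-site table with p-value and
energy columns (RNAhybrid-like).

Planted effects drive every downstream stage: planted units (single
miRNAs or clusters) hit the members of their planted complex with
probability pi1 against a pi0 background; complexes are internally PPI-
dense; miRNAs that co-target a planted complex (and polycistronic
cluster members) share a latent expression factor with correlation rho;
targets of perturbed miRNAs shift by delta in log2 fold change; true
duplex sites get small p-values and low (stable) energies against
uniform-p, high-energy decoys.

All randomness flows from one seed through a single generator; stage-
local reseeding is forbidden so bundles are reproducible as wholes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .types import (
    SITE_COLUMNS,
    ClusterSet,
    ComplexCatalog,
    DomainError,
    ExpressionMatrix,
    FamilyMap,
    FoldChangeTable,
    PPINetwork,
    ProteinComplex,
    SiteTable,
    TargetNetwork,
    ValidationError,
    canonical_pair,
)

MAX_MEMBERSHIPS = 3  # cap on a protein's multi-complex membership


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted-effect sizes and problem dimensions of a scenario.

    pi0 is the background per-(miRNA, protein) target probability and
    pi1 the within-planted-complex probability; rho the planted
    expression correlation; delta (log2 units, <= 0) the mean target
    fold-change shift and sigma its noise scale.
    """

    n_proteins: int = 400
    n_complexes: int = 60
    complex_size_range: Tuple[int, int] = (4, 10)
    n_mirnas: int = 80
    n_clusters: int = 8
    cluster_size_range: Tuple[int, int] = (2, 4)
    n_families: int = 64
    pi0: float = 0.02
    pi1: float = 0.8
    planted_pairs: int = 10
    planted_units_per_complex: int = 1
    planted_cluster_fraction: float = 0.2
    ppi_within: float = 0.4
    ppi_background: float = 0.01
    n_conditions: int = 26
    rho: float = 0.6
    delta: float = -0.3
    sigma: float = 0.2
    n_perturbations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= self.pi1 <= 1.0:
            raise ValidationError("require 0 <= pi0 <= pi1 <= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("require 0 <= rho < 1")
        if self.sigma <= 0.0:
            raise ValidationError("require sigma > 0")
        if self.delta > 0.0:
            raise ValidationError("require delta <= 0")
        if self.complex_size_range[0] < 2:
            raise ValidationError("complexes need >= 2 members")
        if self.cluster_size_range[0] < 2:
            raise ValidationError("clusters need >= 2 miRNAs")
        if self.planted_pairs > self.n_complexes * (self.n_mirnas + self.n_clusters):
            raise DomainError("more planted pairs than (units x complexes)")


@dataclass
class GroundTruth:
    planted: List[Tuple[str, str, str]]  # (unit_id, kind {mirna, cluster}, complex_id)
    correlated_pairs: List[Tuple[str, str]]
    inert: bool = False


@dataclass
class ScenarioBundle:
    config: SyntheticConfig
    network: TargetNetwork
    catalog: ComplexCatalog
    clusters: ClusterSet
    families: FamilyMap
    ppi: PPINetwork
    expression: ExpressionMatrix
    fold_changes: FoldChangeTable
    sites: SiteTable
    ground_truth: GroundTruth


def _sample_complexes(
    cfg: SyntheticConfig, proteins: Sequence[str], rng: np.random.Generator
) -> Dict[str, ProteinComplex]:
    count: Dict[str, int] = {p: 0 for p in proteins}
    seen: Set[frozenset] = set()
    complexes: Dict[str, ProteinComplex] = {}
    lo, hi = cfg.complex_size_range
    for ci in range(cfg.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        for _ in range(20):  # resample on (rare) duplicate member sets
            eligible = [p for p in proteins if count[p] < MAX_MEMBERSHIPS]
            if len(eligible) < size:
                eligible = list(proteins)
            members = frozenset(
                eligible[i] for i in rng.choice(len(eligible), size, replace=False)
            )
            if members not in seen:
                break
        seen.add(members)
        for p in members:
            count[p] += 1
        cid = f"cpx{ci:03d}"
        complexes[cid] = ProteinComplex(f"synthetic complex {ci}", set(members))
    return complexes


def generate(config: SyntheticConfig) -> ScenarioBundle:
    """Build a complete, internally consistent scenario bundle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"prot{i:04d}" for i in range(cfg.n_proteins)]
    mirnas = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]

    complexes = _sample_complexes(cfg, proteins, rng)
    catalog = ComplexCatalog(complexes)

    # --- clusters (polycistronic transcription units) and families ---
    shuffled = [mirnas[i] for i in rng.permutation(cfg.n_mirnas)]
    clusters: Dict[str, List[str]] = {}
    cursor = 0
    lo, hi = cfg.cluster_size_range
    for ci in range(cfg.n_clusters):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > cfg.n_mirnas:
            raise DomainError("not enough miRNAs for the requested clusters")
        clusters[f"cl{ci:02d}"] = shuffled[cursor : cursor + size]
        cursor += size
    unclustered = shuffled[cursor:]
    cluster_set = ClusterSet(clusters)
    family_ids = rng.integers(0, cfg.n_families, size=cfg.n_mirnas)
    families = FamilyMap({m: f"fam{family_ids[i]:03d}" for i, m in enumerate(mirnas)})

    # --- planted (unit, complex) assignments ---
    n_cluster_units = min(
        int(round(cfg.planted_cluster_fraction * cfg.planted_pairs)), cfg.n_clusters
    )
    n_single_units = cfg.planted_pairs - n_cluster_units
    if n_single_units > len(unclustered):
        raise DomainError(
            f"need {n_single_units} unclustered miRNAs for planting, "
            f"have {len(unclustered)}"
        )
    single_units = unclustered[:n_single_units]
    cluster_units = sorted(clusters)[:n_cluster_units]
    unit_pool: List[Tuple[str, str]] = [(m, "mirna") for m in single_units] + [
        (c, "cluster") for c in cluster_units
    ]
    unit_pool = [unit_pool[i] for i in rng.permutation(len(unit_pool))]

    n_slots = math.ceil(cfg.planted_pairs / cfg.planted_units_per_complex)
    if n_slots > cfg.n_complexes:
        raise DomainError("more planted complexes than complexes available")
    complex_ids = sorted(complexes)
    planted_cids = [
        complex_ids[i] for i in rng.choice(cfg.n_complexes, n_slots, replace=False)
    ]
    planted: List[Tuple[str, str, str]] = []
    for idx, (unit, kind) in enumerate(unit_pool):
        cid = planted_cids[idx // cfg.planted_units_per_complex]
        planted.append((unit, kind, cid))

    # --- target network: background then planted overlays ---
    hits = rng.random((cfg.n_mirnas, cfg.n_proteins)) < cfg.pi0
    mirna_idx = {m: i for i, m in enumerate(mirnas)}
    protein_idx = {p: i for i, p in enumerate(proteins)}
    for unit, kind, cid in planted:
        members = sorted(complexes[cid].members)
        if kind == "mirna":
            row = mirna_idx[unit]
            planted_hits = rng.random(len(members)) < cfg.pi1
            for p, h in zip(members, planted_hits):
                if h:
                    hits[row, protein_idx[p]] = True
        else:
            # each targeted subunit is claimed by ONE cluster member, so the
            # cluster-level union carries signal its members alone lack
            member_mirnas = clusters[unit]
            for p in members:
                if rng.random() < cfg.pi1:
                    owner = member_mirnas[int(rng.integers(len(member_mirnas)))]
                    hits[mirna_idx[owner], protein_idx[p]] = True
    for i in range(cfg.n_mirnas):  # no miRNA may end up target-less
        if not hits[i].any():
            hits[i, int(rng.integers(cfg.n_proteins))] = True
    targets_of = {
        m: {proteins[j] for j in np.flatnonzero(hits[i])}
        for i, m in enumerate(mirnas)
    }
    network = TargetNetwork(targets_of)

    # --- PPI: dense inside complexes, sparse background ---
    edges: Set[Tuple[str, str]] = set()
    iu, ju = np.triu_indices(cfg.n_proteins, k=1)
    bg_mask = rng.random(iu.size) < cfg.ppi_background
    for a, b in zip(iu[bg_mask], ju[bg_mask]):
        edges.add(canonical_pair(proteins[a], proteins[b]))
    for cid in complex_ids:
        members = sorted(complexes[cid].members)
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                if rng.random() < cfg.ppi_within:
                    edges.add(canonical_pair(members[x], members[y]))
    ppi = PPINetwork(edges)

    # --- expression: latent-factor correlated groups ---
    groups: List[List[str]] = []
    by_complex: Dict[str, List[str]] = {}
    for unit, kind, cid in planted:
        if kind == "mirna":
            by_complex.setdefault(cid, []).append(unit)
    correlated_pairs: List[Tuple[str, str]] = []
    for cid in sorted(by_complex):
        units = by_complex[cid]
        if len(units) >= 2:
            groups.append(units)
            for i in range(len(units)):
                for j in range(i + 1, len(units)):
                    correlated_pairs.append(canonical_pair(units[i], units[j]))
    for cid in sorted(clusters):  # polycistronic members are co-expressed
        groups.append(clusters[cid])
    x = rng.standard_normal((cfg.n_mirnas, cfg.n_conditions))
    if cfg.rho > 0.0:
        w_shared = math.sqrt(cfg.rho)
        w_noise = math.sqrt(1.0 - cfg.rho)
        for group in groups:
            z = rng.standard_normal(cfg.n_conditions)
            for m in group:
                x[mirna_idx[m]] = w_shared * z + w_noise * rng.standard_normal(
                    cfg.n_conditions
                )
    values = np.maximum(0.0, 10.0 + x)
    expression = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(mirnas, name="mirna"),
            columns=[f"cond{c:02d}" for c in range(cfg.n_conditions)],
        )
    )

    # --- proteomics fold changes for perturbed miRNAs ---
    perturbed = list(single_units[: cfg.n_perturbations])
    for m in unclustered[n_single_units:]:
        if len(perturbed) >= cfg.n_perturbations:
            break
        perturbed.append(m)
    fold: Dict[str, Dict[str, float]] = {}
    for m in perturbed:
        noise = rng.normal(0.0, cfg.sigma, size=cfg.n_proteins)
        row = hits[mirna_idx[m]]
        fold[m] = {
            proteins[j]: float(noise[j] + (cfg.delta if row[j] else 0.0))
            for j in range(cfg.n_proteins)
        }
    fold_changes = FoldChangeTable(fold)

    # --- duplex site table: true sites vs decoys ---
    records: List[Tuple[str, str, float, float]] = []
    n_true = 0
    for i, m in enumerate(mirnas):
        for j in np.flatnonzero(hits[i]):
            records.append(
                (
                    m,
                    proteins[j],
                    float(rng.uniform(0.0, 0.02)),
                    float(rng.normal(-25.0, 3.0)),
                )
            )
            n_true += 1
    n_decoys = 0
    while n_decoys < n_true:
        i = int(rng.integers(cfg.n_mirnas))
        j = int(rng.integers(cfg.n_proteins))
        if hits[i, j]:
            continue
        records.append(
            (
                mirnas[i],
                proteins[j],
                float(rng.uniform(0.0, 1.0)),
                float(rng.normal(-12.0, 3.0)),
            )
        )
        n_decoys += 1
    sites = SiteTable(pd.DataFrame(records, columns=list(SITE_COLUMNS)))

    return ScenarioBundle(
        config=cfg,
        network=network,
        catalog=catalog,
        clusters=cluster_set,
        families=families,
        ppi=ppi,
        expression=expression,
        fold_changes=fold_changes,
        sites=sites,
        ground_truth=GroundTruth(planted, correlated_pairs, inert=False),
    )


def null_scenario(config: SyntheticConfig) -> ScenarioBundle:
    """Same dimensions, no planted effects: pi1 = pi0, rho = 0, delta = 0.

    The planted assignment list is kept (flagged inert) so calibration
    runs can still ask "would the planted pairs have been called?".
    """
    null_cfg = dataclasses.replace(
        config, pi1=config.pi0, rho=0.0, delta=0.0
    )
    bundle = generate(null_cfg)
    bundle.ground_truth.inert = True
    return bundle


SCENARIO_FILES = {
    "targets": "targets.tsv",
    "complexes": "complexes.gmt",
    "clusters": "clusters.tsv",
    "families": "families.tsv",
    "ppi": "ppi.tsv",
    "expression": "expression.tsv",
    "fold_changes": "foldchanges.tsv",
    "sites": "sites.tsv",
}


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> Path:
    """Write every input file, the ground truth and the config YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_target_network(bundle.network, out / SCENARIO_FILES["targets"])
    mio.write_complex_catalog(bundle.catalog, out / SCENARIO_FILES["complexes"])
    mio.write_clusters(bundle.clusters, out / SCENARIO_FILES["clusters"])
    mio.write_families(bundle.families, out / SCENARIO_FILES["families"])
    mio.write_ppi(bundle.ppi, out / SCENARIO_FILES["ppi"])
    mio.write_expression(bundle.expression, out / SCENARIO_FILES["expression"])
    mio.write_foldchanges(bundle.fold_changes, out / SCENARIO_FILES["fold_changes"])
    mio.write_sites(bundle.sites, out / SCENARIO_FILES["sites"])
    gt = bundle.ground_truth
    with open(out / "ground_truth.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record\tfield1\tfield2\tfield3\n")
        for unit, kind, cid in gt.planted:
            fh.write(f"planted\t{unit}\t{kind}\t{cid}\n")
        for a, b in gt.correlated_pairs:
            fh.write(f"correlated\t{a}\t{b}\t.\n")
        fh.write(f"inert\t{str(gt.inert).lower()}\t.\t.\n")
    cfg_dict = dataclasses.asdict(bundle.config)
    cfg_dict["complex_size_range"] = list(bundle.config.complex_size_range)
    cfg_dict["cluster_size_range"] = list(bundle.config.cluster_size_range)
    with open(out / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return out


def read_scenario(directory: str | Path) -> ScenarioBundle:
    """Reload a written scenario through the standard readers."""
    d = Path(directory)
    with open(d / "config.yaml", "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    raw["complex_size_range"] = tuple(raw["complex_size_range"])
    raw["cluster_size_range"] = tuple(raw["cluster_size_range"])
    cfg = SyntheticConfig(**raw)
    clusters, families = mio.read_clusters_families(
        d / SCENARIO_FILES["clusters"], d / SCENARIO_FILES["families"]
    )
    planted: List[Tuple[str, str, str]] = []
    correlated: List[Tuple[str, str]] = []
    inert = False
    with open(d / "ground_truth.tsv", "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            kind, f1, f2, f3 = line.rstrip("\n").split("\t")
            if kind == "planted":
                planted.append((f1, f2, f3))
            elif kind == "correlated":
                correlated.append((f1, f2))
            elif kind == "inert":
                inert = f1 == "true"
    return ScenarioBundle(
        config=cfg,
        network=mio.read_target_network(d / SCENARIO_FILES["targets"]),
        catalog=mio.read_complex_catalog(d / SCENARIO_FILES["complexes"]),
        clusters=clusters,
        families=families,
        ppi=mio.read_ppi(d / SCENARIO_FILES["ppi"]),
        expression=mio.read_expression(d / SCENARIO_FILES["expression"]),
        fold_changes=mio.read_foldchanges(d / SCENARIO_FILES["fold_changes"]),
        sites=mio.read_sites(d / SCENARIO_FILES["sites"]),
        ground_truth=GroundTruth(planted, correlated, inert),
    )
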