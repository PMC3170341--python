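"""End-to-end orchestration: run every stage, write TSVs, summary, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .coexpression import (
    co_targeting_pairs,
    compare_pc_distributions,
    pairwise_pc,
    per_complex_mean_pc,
)
from .downregulation import (
    complexes_with_min_targeted_subunits,
    filter_parclip_sites,
    foldchange_comparison,
    foldchange_summary_frame,
    fraction_downregulated,
    sites_to_network,
)
from .interconnectivity import (
    global_interconnectivity_summary,
    interconnectivity_all,
)
from .targeting import (
    associate_cluster,
    associate_single,
    distinct_significant_complexes,
    records_to_frame,
)
from .types import DomainError, MirComplexError, PipelineError, ValidationError

logger = logging.getLogger("mircomplex")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and toggles for a full run."""

    targets: str
    complexes: str
    outdir: str
    clusters: Optional[str] = None
    families: Optional[str] = None
    ppi: Optional[str] = None
    expression: Optional[str] = None
    fold_changes: Optional[str] = None
    sites: Optional[str] = None
    alpha: float = 0.05
    min_targets: int = 2
    correction: str = "holm"
    correction_scope: str = "pairs"
    R: int = 1000
    seed: int = 0
    run_coexpression: bool = True
    run_interconnectivity: bool = True
    run_downregulation: bool = True
    run_parclip: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.R < 1:
            raise ValidationError("R must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Dict:
    """Execute enabled stages in order; return the summary dict.

    Writes per-stage TSVs, summary.json and manifest.json under the
    output directory.  Any stage failure raises PipelineError naming the
    stage; partial outputs are retained alongside a FAILED marker.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {}
    stage = "load"
    try:
        network = mio.read_target_network(config.targets)
        catalog = mio.read_complex_catalog(config.complexes)
        clusters = families = None
        if config.clusters and config.families:
            clusters, families = mio.read_clusters_families(
                config.clusters, config.families
            )

        stage = "associate_single"
        single = associate_single(
            network,
            catalog,
            alpha=config.alpha,
            min_targets=config.min_targets,
            correction=config.correction,
            correction_scope=config.correction_scope,
        )
        records_to_frame(single).to_csv(
            out / "associations_single.tsv", sep="\t", index=False
        )
        summary["n_significant_pairs_single"] = sum(r.significant for r in single)
        summary["n_significant_complexes_single"] = len(
            distinct_significant_complexes(single)
        )

        cluster_records = []
        if clusters is not None:
            stage = "associate_cluster"
            cluster_records = associate_cluster(
                clusters,
                network,
                catalog,
                alpha=config.alpha,
                min_targets=config.min_targets,
                correction=config.correction,
                correction_scope=config.correction_scope,
            )
            records_to_frame(cluster_records).to_csv(
                out / "associations_cluster.tsv", sep="\t", index=False
            )
            summary["n_significant_complexes_cluster"] = len(
                distinct_significant_complexes(cluster_records)
            )

        if config.run_coexpression and config.expression:
            stage = "coexpression"
            expression = mio.read_expression(config.expression)
            pc = pairwise_pc(expression, network.all_mirnas)
            pairs = co_targeting_pairs(single)
            try:
                comparison = compare_pc_distributions(
                    pairs,
                    pc,
                    exclude_same_tu=False,
                    clusters=clusters,
                    families=families,
                )
                summary["coexpression_ks_p"] = comparison.result.p_value
                summary["coexpression_ks_D"] = comparison.result.statistic
                summary["coexpression_n_foreground"] = comparison.n_foreground
            except DomainError as exc:
                logger.warning("coexpression comparison skipped: %s", exc)
                summary["coexpression_ks_p"] = None
            mean_pc = per_complex_mean_pc(single, pc)
            pd.DataFrame(
                sorted(mean_pc.items()), columns=["complex_id", "mean_pc"]
            ).to_csv(out / "per_complex_mean_pc.tsv", sep="\t", index=False)

        if config.run_interconnectivity and config.ppi and clusters is not None:
            stage = "interconnectivity"
            ppi = mio.read_ppi(config.ppi)
            rng = np.random.default_rng(config.seed)
            results = interconnectivity_all(
                clusters, network, families, ppi, R=config.R, rng=rng
            )
            pd.DataFrame(
                [
                    (r.cluster_id, r.n_mirnas_used, r.observed_edges, r.p_perm)
                    for r in results
                ],
                columns=["cluster_id", "n_mirnas_used", "observed_ppis", "p_perm"],
            ).to_csv(out / "interconnectivity.tsv", sep="\t", index=False)
            summary["n_clusters_tested"] = len(results)
            summary["n_significant_clusters"] = sum(
                r.p_perm < config.alpha for r in results
            )
            if len(results) >= 6:
                try:
                    wilcoxon, fisher, n_sig = global_interconnectivity_summary(
                        results, alpha=config.alpha
                    )
                    summary["interconnectivity_wilcoxon_p"] = wilcoxon.p_value
                    summary["interconnectivity_fisher_p"] = fisher.p_value
                except DomainError as exc:
                    logger.warning("global interconnectivity summary: %s", exc)

        if config.run_downregulation and config.fold_changes:
            stage = "downregulation"
            fc = mio.read_foldchanges(config.fold_changes)
            comparisons = []
            for mirna in sorted(fc.fold_changes):
                try:
                    comparisons.append(
                        foldchange_comparison(mirna, network, catalog, fc)
                    )
                except DomainError as exc:
                    logger.warning("fold-change comparison for %s skipped: %s", mirna, exc)
            foldchange_summary_frame(comparisons).to_csv(
                out / "foldchange_summary.tsv", sep="\t", index=False
            )
            summary["n_foldchange_mirnas"] = len(comparisons)
            summary["n_foldchange_significant"] = sum(
                c.ks.p_value < config.alpha for c in comparisons
            )

        if config.run_parclip and config.sites:
            stage = "parclip"
            sites = mio.read_sites(config.sites)
            filtered = filter_parclip_sites(sites)
            mio.write_sites(filtered, out / "sites_filtered.tsv")
            site_net = sites_to_network(filtered)
            summary["n_sites_kept"] = len(filtered)
            summary["n_complexes_2plus_subunits"] = len(
                complexes_with_min_targeted_subunits(site_net, catalog)
            )
            summary["n_complexes_2plus_per_mirna"] = len(
                complexes_with_min_targeted_subunits(
                    site_net, catalog, per_mirna=True
                )
            )
            if config.fold_changes:
                fc = mio.read_foldchanges(config.fold_changes)
                summary["parclip_frac_downregulated"] = fraction_downregulated(
                    site_net, fc
                )
    except MirComplexError as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
    }
    for name in (
        "targets",
        "complexes",
        "clusters",
        "families",
        "ppi",
        "expression",
        "fold_changes",
        "sites",
    ):
        path = getattr(config, name)
        if path and Path(path).exists():
            manifest["inputs"][name] = _sha256(Path(path))
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("manifest.json",):
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
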