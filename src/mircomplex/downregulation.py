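"""Stage 4 — proteomics fold-change validation and PAR-CLIP site statistics.

After over-expression of a miRNA, its predicted targets inside protein
complexes should shift toward negative log2 fold changes relative to the
non-target components of the same complexes; a one-sided KS test per
miRNA quantifies this.  Independently, duplex-site predictions on
crosslink-centred regions are filtered on p-value and hybridisation
energy, and the resulting site-level target sets are intersected with
the complex catalog (subunit counts, membership-overlap hypergeometric
test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .stats import TestResult, hypergeom_tail_geq, ks_one_sided
from .types import (
    ComplexCatalog,
    DomainError,
    FoldChangeTable,
    SiteTable,
    TargetNetwork,
)

logger = logging.getLogger("mircomplex")


@dataclass
class FoldChangeComparison:
    mirna: str
    target_fcs: List[float]
    nontarget_fcs: List[float]
    ks: TestResult
    target_proteins: List[str]
    nontarget_proteins: List[str]


def foldchange_comparison(
    mirna: str,
    network: TargetNetwork,
    catalog: ComplexCatalog,
    fc: FoldChangeTable,
) -> FoldChangeComparison:
    """Targets vs non-targets within complexes holding >= 1 target.

    The component pool is the union of members of every complex that
    contains at least one target of the miRNA (significantly associated
    or not).  Components with a measured fold change are split into
    targets and non-targets and compared with a one-sided KS test,
    alternative: target fold changes stochastically smaller (more
    negative).
    """
    if mirna not in fc.fold_changes:
        raise DomainError(f"no fold-change perturbation for {mirna!r}")
    targets = network.targets_of.get(mirna)
    if not targets:
        raise DomainError(f"miRNA {mirna!r} has no targets in the network")
    pool: Set[str] = set()
    for cx in catalog.complexes.values():
        if cx.members & targets:
            pool |= cx.members
    if not pool:
        raise DomainError(f"no complex contains a target of {mirna!r}")
    measured = fc.fold_changes[mirna]
    target_prots = sorted(p for p in pool & targets if p in measured)
    nontarget_prots = sorted(p for p in pool - targets if p in measured)
    if not target_prots:
        raise DomainError(f"{mirna!r}: no measured target components")
    if not nontarget_prots:
        raise DomainError(f"{mirna!r}: no measured non-target components")
    target_fcs = [measured[p] for p in target_prots]
    nontarget_fcs = [measured[p] for p in nontarget_prots]
    ks = ks_one_sided(target_fcs, nontarget_fcs, alternative="a_less")
    return FoldChangeComparison(
        mirna, target_fcs, nontarget_fcs, ks, target_prots, nontarget_prots
    )


def filter_parclip_sites(
    sites: SiteTable,
    p_max: float = 0.02,
    energy_quantile: float = 0.25,
    quantile_method: str = "linear",
    energy_below: bool = True,
) -> SiteTable:
    """Keep sites with p < p_max and energy in the most stable quartile.

    The energy cut-off is the empirical quantile (type-7 / "linear" by
    default) of the energy column of the FULL input table — re-applying
    the filter to its own output would move the cut-off, so the filter
    is deliberately not idempotent and the quantile is always taken from
    the original table.  "Below the quantile" means strictly lower
    energy, i.e. a more stable duplex.
    """
    if len(sites) == 0:
        raise DomainError("empty site table")
    threshold = float(
        np.quantile(
            sites.rows["energy"].to_numpy(), energy_quantile, method=quantile_method
        )
    )
    logger.info("PAR-CLIP energy cut-off (q=%.2f): %.4g", energy_quantile, threshold)
    mask = sites.rows["p_value"] < p_max
    if energy_below:
        mask &= sites.rows["energy"] < threshold
    else:
        mask &= sites.rows["energy"] > threshold
    return SiteTable(sites.rows[mask].reset_index(drop=True))


def sites_to_network(sites: SiteTable) -> TargetNetwork:
    """Collapse a site table to a miRNA -> protein target network."""
    targets: Dict[str, Set[str]] = {}
    for mirna, protein in zip(sites.rows["mirna"], sites.rows["protein"]):
        targets.setdefault(str(mirna), set()).add(str(protein))
    return TargetNetwork(targets)


def complexes_with_min_targeted_subunits(
    network: TargetNetwork,
    catalog: ComplexCatalog,
    min_subunits: int = 2,
    per_mirna: bool = False,
) -> Set[str]:
    """Complexes with >= min_subunits members carrying target sites.

    With ``per_mirna`` a single miRNA must hit >= min_subunits distinct
    members of the same complex; otherwise any miRNA may contribute.
    """
    out: Set[str] = set()
    all_targets = network.all_targets
    for cid, cx in catalog.complexes.items():
        if per_mirna:
            for targets in network.targets_of.values():
                if len(cx.members & targets) >= min_subunits:
                    out.add(cid)
                    break
        else:
            if len(cx.members & all_targets) >= min_subunits:
                out.add(cid)
    return out


def membership_overlap_test(
    site_targets: Set[str], complex_members: Set[str], universe_size: int
) -> TestResult:
    """Hypergeometric test: are site-level targets enriched in complexes?

    The universe size must be supplied explicitly (e.g. the size of the
    proteome the complex catalog was curated from); no default is
    invented.
    """
    if len(site_targets) > universe_size or len(complex_members) > universe_size:
        raise DomainError("set sizes exceed the universe")
    k = len(site_targets & complex_members)
    p = hypergeom_tail_geq(k, len(complex_members), len(site_targets), universe_size)
    return TestResult(float(k), p, "greater", "hypergeom_membership_overlap")


def fraction_downregulated(
    site_network: TargetNetwork,
    fc: FoldChangeTable,
    threshold: float = -0.1,
) -> Dict[str, float]:
    """Fraction of site-target proteins moderately down-regulated.

    ``matched``: measurements of proteins that are site targets of the
    perturbed miRNA itself; ``pooled``: measurements of proteins that
    are site targets of any miRNA.  Both are reported side by side.
    """
    matched_n = matched_down = pooled_n = pooled_down = 0
    all_site_targets = site_network.all_targets
    for pert, measured in fc.fold_changes.items():
        own = site_network.targets_of.get(pert, set())
        for protein, value in measured.items():
            if protein in all_site_targets:
                pooled_n += 1
                pooled_down += value < threshold
            if protein in own:
                matched_n += 1
                matched_down += value < threshold
    return {
        "matched": matched_down / matched_n if matched_n else float("nan"),
        "pooled": pooled_down / pooled_n if pooled_n else float("nan"),
    }


def foldchange_summary_frame(
    comparisons: Sequence[FoldChangeComparison],
) -> pd.DataFrame:
    """Per-miRNA summary (n targets, n non-targets, D, p)."""
    return pd.DataFrame(
        [
            (
                c.mirna,
                len(c.target_fcs),
                len(c.nontarget_fcs),
                c.ks.statistic,
                c.ks.p_value,
            )
            for c in comparisons
        ],
        columns=["mirna", "n_targets", "n_nontargets", "D", "p_value"],
    )
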