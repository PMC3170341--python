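"""Fold-change validation and PAR-CLIP site statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from mircomplex import (
    ComplexCatalog,
    DomainError,
    FoldChangeTable,
    ProteinComplex,
    SiteTable,
    TargetNetwork,
    complexes_with_min_targeted_subunits,
    filter_parclip_sites,
    foldchange_comparison,
    fraction_downregulated,
    hypergeom_tail_geq,
    membership_overlap_test,
    sites_to_network,
)


def site_table(rows):
    return SiteTable(
        pd.DataFrame(rows, columns=["mirna", "protein", "p_value", "energy"])
    )


class TestFoldchangeComparison:
    def _larc_like(self):
        """A 19-member complex with 2 modestly down-regulated targets."""
        members = {f"sub{i:02d}" for i in range(17)} | {"DPF2", "SMARCC1"}
        catalog = ComplexCatalog({"larc": ProteinComplex("remodelling", members)})
        network = TargetNetwork({"let-7b": {"DPF2", "SMARCC1", "offcx"}})
        rng = np.random.default_rng(0)
        fcs = {m: float(rng.normal(0, 0.1)) for m in members}
        fcs["DPF2"] = -0.38
        fcs["SMARCC1"] = -0.2
        return network, catalog, FoldChangeTable({"let-7b": fcs})

    def test_targets_land_in_target_side(self):
        network, catalog, fc = self._larc_like()
        cmp = foldchange_comparison("let-7b", network, catalog, fc)
        assert sorted(cmp.target_fcs) == [-0.38, -0.2]
        assert len(cmp.nontarget_fcs) == 17
        assert cmp.ks.alternative == "a_less"

    def test_sides_are_disjoint_proteins(self):
        network, catalog, fc = self._larc_like()
        cmp = foldchange_comparison("let-7b", network, catalog, fc)
        assert not (set(cmp.target_proteins) & set(cmp.nontarget_proteins))

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        members = {f"p{i}" for i in range(80)}
        targets = {f"p{i}" for i in range(35)}
        catalog = ComplexCatalog({"cx": ProteinComplex("", members)})
        network = TargetNetwork({"m": targets})
        fcs = {
            p: float(rng.normal(-0.3 if p in targets else 0.0, 0.2)) for p in members
        }
        cmp = foldchange_comparison("m", network, catalog, FoldChangeTable({"m": fcs}))
        assert cmp.ks.p_value < 0.01

    def test_null_is_not_significant_on_average(self):
        rng = np.random.default_rng(2)
        members = {f"p{i}" for i in range(60)}
        targets = {f"p{i}" for i in range(25)}
        catalog = ComplexCatalog({"cx": ProteinComplex("", members)})
        network = TargetNetwork({"m": targets})
        ps = []
        for _ in range(40):
            fcs = {p: float(rng.normal(0, 0.2)) for p in members}
            cmp = foldchange_comparison(
                "m", network, catalog, FoldChangeTable({"m": fcs})
            )
            ps.append(cmp.ks.p_value)
        assert sum(p < 0.05 for p in ps) / len(ps) < 0.2

    def test_empty_side_errors_name_the_side(self):
        catalog = ComplexCatalog({"cx": ProteinComplex("", {"a", "b"})})
        network = TargetNetwork({"m": {"a", "b"}})
        fc = FoldChangeTable({"m": {"a": -0.1, "b": -0.2}})
        with pytest.raises(DomainError, match="non-target"):
            foldchange_comparison("m", network, catalog, fc)

    def test_missing_perturbation_rejected(self):
        catalog = ComplexCatalog({"cx": ProteinComplex("", {"a", "b"})})
        network = TargetNetwork({"m": {"a"}})
        with pytest.raises(DomainError):
            foldchange_comparison("m", network, catalog, FoldChangeTable({"other": {"a": 0.0}}))


def quantile_type7(values, q):
    """Oracle: hand implementation of the type-7 empirical quantile."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestFilterParclipSites:
    def _fixture40(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            rows.append(
                (
                    f"m{i % 5}",
                    f"p{i}",
                    float(rng.uniform(0, 0.05)),
                    float(rng.normal(-18, 5)),
                )
            )
        return rows

    def test_matches_hand_filter_on_40_rows(self):
        rows = self._fixture40()
        table = site_table(rows)
        cut = quantile_type7([r[3] for r in rows], 0.25)
        expected = {(r[0], r[1]) for r in rows if r[2] < 0.02 and r[3] < cut}
        kept = filter_parclip_sites(table)
        got = set(zip(kept.rows["mirna"], kept.rows["protein"]))
        assert got == expected

    def test_minimum_energy_low_p_kept(self):
        rows = self._fixture40()
        energies = [r[3] for r in rows]
        rows.append(("mX", "pX", 0.01, min(energies) - 10.0))
        kept = filter_parclip_sites(site_table(rows))
        assert ("mX", "pX") in set(zip(kept.rows["mirna"], kept.rows["protein"]))

    def test_high_p_dropped_regardless_of_energy(self):
        rows = [("m", f"p{i}", 0.001, float(-30 + i)) for i in range(10)]
        rows.append(("mX", "pX", 0.03, -1000.0))
        kept = filter_parclip_sites(site_table(rows))
        assert "pX" not in set(kept.rows["protein"])

    def test_output_subset_of_input(self):
        table = site_table(self._fixture40())
        kept = filter_parclip_sites(table)
        assert len(kept) <= len(table)
        merged = kept.rows.merge(table.rows, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_not_idempotent_quantile_recomputed(self):
        # the quantile must come from the original table: filtering twice
        # (recomputing on the filtered table) shrinks the kept set further
        rows = self._fixture40()
        once = filter_parclip_sites(site_table(rows))
        twice = filter_parclip_sites(once)
        assert len(twice) < len(once)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            filter_parclip_sites(site_table([]))


class TestMinTargetedSubunits:
    def _catalog(self):
        return ComplexCatalog(
            {
                "cx": ProteinComplex("", {"a", "b", "c"}),
                "other": ProteinComplex("", {"y", "z"}),
            }
        )

    def test_two_mirnas_one_subunit_each(self):
        net = TargetNetwork({"m1": {"a"}, "m2": {"b"}})
        cat = self._catalog()
        assert complexes_with_min_targeted_subunits(net, cat) == {"cx"}
        assert (
            complexes_with_min_targeted_subunits(net, cat, per_mirna=True) == set()
        )

    def test_one_mirna_two_subunits_in_both_modes(self):
        net = TargetNetwork({"m1": {"a", "b"}})
        cat = self._catalog()
        assert complexes_with_min_targeted_subunits(net, cat) == {"cx"}
        assert complexes_with_min_targeted_subunits(net, cat, per_mirna=True) == {"cx"}

    def test_matches_brute_force_counts(self, planted_bundle):
        b = planted_bundle
        net = sites_to_network(filter_parclip_sites(b.sites))
        any_mode = complexes_with_min_targeted_subunits(net, b.catalog)
        per_mode = complexes_with_min_targeted_subunits(net, b.catalog, per_mirna=True)
        exp_any, exp_per = set(), set()
        for cid, cx in b.catalog.complexes.items():
            hit = set()
            for m, ts in net.targets_of.items():
                inter = cx.members & ts
                hit |= inter
                if len(inter) >= 2:
                    exp_per.add(cid)
            if len(hit) >= 2:
                exp_any.add(cid)
        assert any_mode == exp_any and per_mode == exp_per


class TestMembershipOverlap:
    def test_disjoint_sets_p_one(self):
        res = membership_overlap_test({"a", "b"}, {"x", "y"}, universe_size=100)
        assert res.p_value == pytest.approx(1.0)

    def test_superset_closed_form(self):
        # sites cover all 3 complex members out of a 10-protein universe
        res = membership_overlap_test(
            {"a", "b", "c", "d", "e"}, {"a", "b", "c"}, universe_size=10
        )
        assert res.p_value == pytest.approx(hypergeom_tail_geq(3, 3, 5, 10))

    def test_oversized_sets_rejected(self):
        with pytest.raises(DomainError):
            membership_overlap_test({"a", "b"}, {"c"}, universe_size=1)

    def test_planted_enrichment_detected(self, planted_bundle):
        b = planted_bundle
        net = sites_to_network(filter_parclip_sites(b.sites))
        res = membership_overlap_test(
            net.all_targets, b.catalog.all_members, universe_size=5000
        )
        assert res.p_value < 0.05


class TestFractionDownregulated:
    def test_matched_and_pooled_reported(self):
        site_net = TargetNetwork({"m1": {"a"}, "m2": {"b"}})
        fc = FoldChangeTable({"m1": {"a": -0.5, "b": -0.5, "c": 0.2}})
        out = fraction_downregulated(site_net, fc, threshold=-0.1)
        assert out["matched"] == pytest.approx(1.0)  # only a, down
        assert out["pooled"] == pytest.approx(1.0)  # a and b, both down
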