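"""Consensus core detection, strict calls, top-N specificity, gene-list
profiling and dominant-isoform selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epicore as ec

from conftest import random_enrichment, toy_profile

# Hand enumeration of the printed 25-row consensus table: every cell below
# the 2.5-fold threshold, scanned row by row before the audit was coded.
EXPECTED_VIOLATIONS = {
    ("l(1)G0168", "adult_midgut", 2.4),
    ("Lola", "larval_midgut", 2.3),
    ("mthl3", "adult_salivary_gland", 2.2),
    ("Nhe1", "adult_midgut", 2.4),
    ("Smox", "adult_salivary_gland", 2.3),
    ("Smox", "adult_midgut", 2.4),
}


class TestCoreSignature:
    def test_bowl_passes_strict_consensus(self, table2_enrichment, config):
        result = ec.core_signature(table2_enrichment, config)
        assert result.table.at["Bowl", "overall_pass"]
        assert all(result.table.at["Bowl", f"pass__{t}"]
                   for t in config.epithelial_tissues)

    def test_mthl3_fails_strict_consensus(self, table2_enrichment, config):
        result = ec.core_signature(table2_enrichment, config)
        assert not result.table.at["mthl3", "overall_pass"]
        assert not result.table.at["mthl3", "pass__adult_salivary_gland"]

    def test_pass_count_on_printed_table(self, table2_enrichment, config):
        result = ec.core_signature(table2_enrichment, config)
        assert len(result) == 25
        assert len(result.pass_probes) == 20

    def test_vacuous_threshold_passes_all_defined(self, table2_enrichment,
                                                  config):
        result = ec.core_signature(table2_enrichment,
                                   config.replace(tau=1e-300))
        assert result.table["overall_pass"].all()

    def test_sorted_by_descending_min_evidence(self, table2_enrichment,
                                               config):
        result = ec.core_signature(table2_enrichment, config)
        mins = result.table["min_evidence"].to_numpy()
        assert (np.diff(mins[~np.isnan(mins)]) <= 1e-12).all()
        # mthl3 has the smallest printed row minimum (2.2) -> last
        assert result.table.index[-1] == "mthl3"

    def test_missing_cell_fails_gene(self, config):
        idx = pd.Index(["p0"], name="probe_id")
        fc = pd.DataFrame({"a": [9.0], "b": [np.nan]}, index=idx)
        enr = ec.EnrichmentTable(
            fc, pd.Series(["g0"], index=idx, name="gene_symbol"), "ref", 1.0)
        cfg = ec.AnalysisConfig(epithelial_tissues=("a", "b"),
                                reference_tissue="ref")
        result = ec.core_signature(enr, cfg)
        assert not result.table.at["p0", "overall_pass"]

    def test_empty_tissue_set_errors(self, table2_enrichment, config):
        with pytest.raises(ValueError, match="empty"):
            ec.core_signature(table2_enrichment,
                              config.replace(epithelial_tissues=()))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_per_gene_scan(self, seed, config):
        rng = np.random.default_rng(seed)
        enr = random_enrichment(rng, n_genes=20, tissues=("a", "b", "c"),
                                missing_rate=0.1)
        cfg = ec.AnalysisConfig(epithelial_tissues=("a", "b", "c"),
                                reference_tissue="ref", tau=2.0)
        result = ec.core_signature(enr, cfg)
        expected = set()
        for pid in enr.probe_ids:
            row = enr.fold_change.loc[pid, ["a", "b", "c"]]
            if all(not np.isnan(v) and v >= 2.0 for v in row):
                expected.add(pid)
        assert set(result.pass_probes) == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           tau_pair=st.tuples(st.floats(0.5, 4), st.floats(0.5, 4)))
    def test_threshold_monotonicity(self, seed, tau_pair):
        """Raising tau can only shrink the pass set."""
        rng = np.random.default_rng(seed)
        enr = random_enrichment(rng, n_genes=15, missing_rate=0.1)
        lo, hi = min(tau_pair), max(tau_pair)
        cfg = ec.AnalysisConfig(epithelial_tissues=("t1", "t2", "t3"),
                                reference_tissue="ref")
        pass_lo = set(ec.core_signature(enr, cfg.replace(tau=lo)).pass_probes)
        pass_hi = set(ec.core_signature(enr, cfg.replace(tau=hi)).pass_probes)
        assert pass_hi <= pass_lo


class TestCriterionAudit:
    def test_printed_table_violations_match_hand_scan(self, table2_enrichment,
                                                      config):
        result = ec.core_signature(table2_enrichment, config)
        audit = ec.criterion_audit(result, config)
        got = {(r.gene_symbol, r.tissue, r.value)
               for r in audit.itertuples()}
        assert got == EXPECTED_VIOLATIONS

    def test_vacuous_threshold_gives_empty_audit(self, table2_enrichment,
                                                 config):
        result = ec.core_signature(table2_enrichment,
                                   config.replace(tau=1e-300))
        assert ec.criterion_audit(result).empty

    def test_single_passing_gene_gives_empty_audit(self, config):
        idx = pd.Index(["p0"], name="probe_id")
        fc = pd.DataFrame({t: [9.0] for t in config.epithelial_tissues},
                          index=idx)
        enr = ec.EnrichmentTable(
            fc, pd.Series(["g0"], index=idx, name="gene_symbol"),
            config.reference_tissue, 1.0)
        result = ec.core_signature(enr, config)
        assert ec.criterion_audit(result, config).empty

    def test_empty_iff_all_included_pass(self, table2_enrichment, config):
        result = ec.core_signature(table2_enrichment, config)
        audit_pass_only = ec.criterion_audit(result, config,
                                             published=result.pass_probes)
        assert audit_pass_only.empty
        failing = [p for p in result.table.index
                   if not result.table.at[p, "overall_pass"]]
        audit_fail = ec.criterion_audit(result, config, published=failing)
        assert not audit_fail.empty

    def test_requires_consensus_mode(self, table2_enrichment, config):
        top = ec.tissue_specific_top_n(table2_enrichment,
                                       "adult_salivary_gland", config)
        with pytest.raises(ValueError, match="consensus"):
            ec.criterion_audit(top, config)


class TestStrictCallSignature:
    @staticmethod
    def _profile_with_calls(pf_rows, tissues):
        vals = np.full((len(pf_rows), len(tissues)), 100.0)
        return toy_profile(vals, tissues, present_fraction=pf_rows)

    def test_gene_present_everywhere_fails_outside_condition(self):
        prof = self._profile_with_calls([[1.0, 1.0, 1.0]], ["e1", "e2", "br"])
        cfg = ec.AnalysisConfig(epithelial_tissues=("e1", "e2"),
                                reference_tissue="whole_fly")
        res = ec.strict_call_signature(prof, cfg, inside=["e1", "e2"],
                                       outside=["br"])
        assert not res.table.at["p0", "overall_pass"]

    def test_toy_matrix_matches_hand_enumeration(self):
        # inside {e1,e2}, outside {br}: pass needs pf=1 inside, pf=0 outside
        pf = [[1.0, 1.0, 0.0],   # p0: passes
              [1.0, 0.5, 0.0],   # p1: fails inside e2
              [1.0, 1.0, 0.25],  # p2: fails outside
              [0.0, 0.0, 0.0]]   # p3: fails inside
        prof = self._profile_with_calls(pf, ["e1", "e2", "br"])
        cfg = ec.AnalysisConfig(epithelial_tissues=("e1", "e2"),
                                reference_tissue="whole_fly")
        res = ec.strict_call_signature(prof, cfg, inside=["e1", "e2"],
                                       outside=["br"])
        assert res.pass_probes == ["p0"]

    def test_overlapping_sets_rejected(self):
        prof = self._profile_with_calls([[1.0, 1.0]], ["e1", "e2"])
        cfg = ec.AnalysisConfig(epithelial_tissues=("e1",),
                                reference_tissue="whole_fly")
        with pytest.raises(ValueError, match="overlap"):
            ec.strict_call_signature(prof, cfg, inside=["e1", "e2"],
                                     outside=["e2"])

    def test_stricter_than_consensus_on_synthetic_atlas(
            self, default_synthetic, default_synthetic_profile, config):
        """The call-based rule finds (far) fewer genes than the fold-change
        consensus — the reason the enrichment criterion exists."""
        _, _ = default_synthetic
        prof = default_synthetic_profile
        enr = ec.fold_change(prof, config)
        consensus = ec.core_signature(enr, config)
        strict = ec.strict_call_signature(prof, config)
        assert len(strict.pass_probes) < len(consensus.pass_probes)


class TestTissueSpecificTopN:
    def test_top1_salivary_is_drip(self, table2_enrichment, config):
        res = ec.tissue_specific_top_n(table2_enrichment,
                                       "adult_salivary_gland",
                                       config.replace(top_n=1))
        assert list(res.table["gene_symbol"]) == ["Drip"]
        assert res.table.iloc[0]["adult_salivary_gland"] == 63.1

    def test_n_larger_than_table_keeps_full_sorted_list(
            self, table2_enrichment, config):
        res = ec.tissue_specific_top_n(table2_enrichment, "adult_midgut",
                                       config.replace(top_n=1000))
        assert len(res) == 25
        vals = res.table["adult_midgut"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()

    def test_unknown_tissue_errors(self, table2_enrichment, config):
        with pytest.raises(ValueError, match="not in enrichment"):
            ec.tissue_specific_top_n(table2_enrichment, "antenna", config)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_then_slice(self, seed):
        rng = np.random.default_rng(seed)
        enr = random_enrichment(rng, n_genes=30, tissues=("a", "b"),
                                missing_rate=0.15)
        cfg = ec.AnalysisConfig(epithelial_tissues=("a", "b"),
                                reference_tissue="ref", top_n=7)
        res = ec.tissue_specific_top_n(enr, "a", cfg)
        col = enr.fold_change["a"].dropna()
        order = sorted(col.index,
                       key=lambda p: (-col[p], enr.gene_symbols[p], p))
        assert list(res.table.index) == order[:7]

    def test_extension_property(self, table2_enrichment, config):
        """top_n(n+1) extends top_n(n) by exactly one gene until exhausted."""
        prev = None
        for n in range(1, 28):
            res = ec.tissue_specific_top_n(table2_enrichment, "larval_tubule",
                                           config.replace(top_n=n))
            ids = list(res.table.index)
            if prev is not None:
                assert ids[:len(prev)] == prev
                assert len(ids) - len(prev) in (0, 1)
            prev = ids

    def test_merged_cognate_ranking_uses_per_gene_max(self, table2_enrichment,
                                                      config):
        res = ec.tissue_specific_top_n(
            table2_enrichment, "adult_tubule", config.replace(top_n=3),
            merge_with="larval_tubule")
        # per-gene max of the two tubule columns: mthl3 56.7, Traf-like 26.3,
        # Cyp12e1#2 20.3
        assert list(res.table["gene_symbol"]) == ["mthl3", "Traf-like",
                                                  "Cyp12e1"]
        assert res.table.iloc[0]["adult_tubule|larval_tubule"] == 56.7


class TestProfileGeneList:
    def test_fixture_identity(self, table1_profile, table1_genelist, config):
        mapped = ec.profile_gene_list(table1_profile, table1_genelist, config)
        assert len(mapped) == 102
        assert mapped["in_atlas"].all()
        row = mapped[mapped["probe_id"] == "Drip"].iloc[0]
        assert row["adult_salivary_gland"] == 7135.0
        # duplicate-symbol rows align to their probes in order
        vha16 = mapped[mapped["gene_symbol"] == "Vha16-1"]
        assert list(vha16["probe_id"]) == ["Vha16-1#1", "Vha16-1#2"]
        assert list(vha16["adult_salivary_gland"]) == [4822.0, 13363.0]

    def test_unknown_symbol_flagged_not_dropped(self, table1_profile):
        gl = ec.GeneList(pd.DataFrame(
            {"gene_symbol": ["Drip", "no-such-gene"],
             "class_label": ["Water channels"] * 2}))
        mapped = ec.profile_gene_list(table1_profile, gl)
        assert len(mapped) == 2
        missing = mapped[mapped["gene_symbol"] == "no-such-gene"].iloc[0]
        assert not missing["in_atlas"]
        assert np.isnan(missing["adult_midgut"])

    def test_vatpase_subset_has_33_rows(self, table1_profile,
                                        table1_genelist, config):
        sub = table1_genelist.subset("V-ATPase subunits")
        mapped = ec.profile_gene_list(table1_profile, sub, config)
        assert len(mapped) == 33

    def test_empty_list_rejected(self, table1_profile):
        gl = ec.GeneList(pd.DataFrame({"gene_symbol": ["x"],
                                       "class_label": ["c"]}))
        gl.entries = gl.entries.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            ec.profile_gene_list(table1_profile, gl)


class TestDominantIsoform:
    def test_vha68_family_in_salivary_gland(self, table1_profile):
        dom = ec.dominant_isoform(table1_profile,
                                  ["vha68-1", "vha68-2", "vha68-3"],
                                  "adult_salivary_gland")
        assert dom.gene_symbol == "vha68-2"
        assert dom.signal == 13958.0
        assert not dom.ambiguous

    def test_vha100_family_in_tubule(self, table1_profile):
        dom = ec.dominant_isoform(
            table1_profile,
            ["vha100-1", "vha100-2", "Vha100-3", "Vha100-4", "Vha100-5"],
            "adult_tubule")
        assert dom.gene_symbol == "vha100-2"
        assert dom.signal == 3657.0
        assert dom.runner_up_ratio == pytest.approx(3657 / 419, rel=1e-9)

    def test_singleton_family(self, table1_profile):
        dom = ec.dominant_isoform(table1_profile, ["Drip"],
                                  "adult_salivary_gland")
        assert dom.gene_symbol == "Drip"
        assert np.isnan(dom.runner_up_ratio)

    def test_tie_is_flagged_and_deterministic(self):
        prof = toy_profile([[5.0], [5.0]], ["gut"],
                           probe_ids=["pB", "pA"], symbols=["gB", "gA"])
        dom = ec.dominant_isoform(prof, ["gB", "gA"], "gut")
        assert dom.gene_symbol == "gA"
        assert dom.ambiguous

    def test_absent_family_errors(self, table1_profile):
        with pytest.raises(ValueError, match="no family member"):
            ec.dominant_isoform(table1_profile, ["nope1", "nope2"],
                                "adult_tubule")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_family_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        vals = rng.lognormal(3, 1.5, (n, 2))
        prof = toy_profile(vals, ["a", "b"],
                           symbols=[f"g{i}" for i in range(n)])
        fam = [f"g{i}" for i in rng.choice(n, size=4, replace=False)]
        for t in ("a", "b"):
            dom = ec.dominant_isoform(prof, fam, t)
            best = max(fam, key=lambda g: prof.mean_signal.at[g.replace("g", "p"), t])
            assert dom.gene_symbol == best
            assert dom.signal == prof.mean_signal.at[best.replace("g", "p"), t]

    def test_family_profiles_dominant_is_maximal(self, table1_profile,
                                                 table1_genelist):
        fams = ec.family_profiles(table1_profile, table1_genelist,
                                  tissues=["adult_tubule"])
        gene_sig = table1_profile.gene_level_signal(["adult_tubule"])
        for row in fams.itertuples():
            members = table1_genelist.family(row.family_label)
            sigs = gene_sig.loc[[m for m in members
                                 if m in gene_sig.index], "adult_tubule"]
            assert row.signal >= sigs.max() - 1e-12
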