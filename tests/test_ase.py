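"""Allele-specific expression: exact test, call table, proportion summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regland import ase, synth
from regland.types import DataConsistencyError

from conftest import make_counts, make_haps


class TestBinomialTest:
    @pytest.mark.parametrize(
        "ref,alt,bias,exp_p,exp_fold,exp_dir",
        [
            (10, 10, 0.5, 1.0, 1.0, "ref_higher"),          # perfect balance
            (20, 0, 0.5, 2 * 0.5**20, np.inf, "ref_higher"),  # exact tail
            (15, 5, 0.75, 1.0, 1.0, "ref_higher"),           # at the null
        ],
    )
    def test_worked_examples(self, ref, alt, bias, exp_p, exp_fold, exp_dir):
        p, fold, d = ase.test_ase(ref, alt, bias)
        assert p == pytest.approx(exp_p, rel=1e-9)
        assert fold == pytest.approx(exp_fold) if np.isfinite(exp_fold) \
            else fold == exp_fold
        assert d == exp_dir

    @given(st.integers(0, 60), st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_minlike_convention(self, k, n):
        if k > n:
            k, n = n, k
        for bias in (0.3, 0.5, 0.62):
            mine = ase.binom_p_two_sided(k, n, bias)[0]
            ref = stats.binomtest(k, n, bias).pvalue
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @given(st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_at_unbiased_null(self, a, b):
        if a + b == 0:
            return
        pa, fa, _ = ase.test_ase(a, b, 0.5)
        pb, fb, _ = ase.test_ase(b, a, 0.5)
        assert pa == pytest.approx(pb)
        assert fa == pytest.approx(fb) or (np.isinf(fa) and np.isinf(fb))

    def test_p_monotone_in_imbalance(self):
        n, bias = 40, 0.5
        ps = [ase.test_ase(k, n - k, bias)[0] for k in range(n // 2, n + 1)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))

    def test_both_counts_zero_untestable(self):
        p, fold, d = ase.test_ase(0, 0, 0.5)
        assert np.isnan(p) and d is None

    def test_biased_null_shifts_the_centre(self):
        # at bias 0.75, a 3:1 split is the expectation, 1:1 is extreme
        assert ase.test_ase(30, 10, 0.75)[0] > 0.5
        assert ase.test_ase(20, 20, 0.75)[0] < 0.01


class TestCallTable:
    def _haps_all_het(self, n, n_sites=1):
        hap = np.zeros((n, 2, n_sites), dtype=np.int8)
        hap[:, 1, :] = 1
        return make_haps(hap)

    def test_monoallelic_filter(self):
        haps = self._haps_all_het(1)
        counts = make_counts([("S0", 0, 30, 0, 0.5)])
        strict = ase.call_ase_table(counts, haps, require_both_alleles=True)
        assert not strict.table["testable"].iloc[0]
        assert not strict.table["significant"].iloc[0]
        loose = ase.call_ase_table(counts, haps, require_both_alleles=False)
        row = loose.table.iloc[0]
        assert row["testable"]
        assert row["p_value"] == pytest.approx(min(2 * 0.5**30, 1.0))
        assert row["significant"]

    def test_higher_haplotype_follows_phase(self):
        # S0 is 0|1 (hap0 ref), S1 is 1|0 (hap0 alt)
        hap = np.array([[[0], [1]], [[1], [0]]], dtype=np.int8)
        haps = make_haps(hap)
        counts = make_counts([("S0", 0, 30, 2, 0.5), ("S1", 0, 2, 30, 0.5)])
        t = ase.call_ase_table(counts, haps).table
        # S0: ref higher -> over-expressed allele on hap0; S1: alt higher ->
        # over-expressed allele (alt) also on hap0
        assert t["direction"].tolist() == ["ref_higher", "alt_higher"]
        assert t["higher_haplotype"].tolist() == [0, 0]

    def test_non_heterozygous_row_rejected(self):
        hap = np.array([[[1], [1]]], dtype=np.int8)
        haps = make_haps(hap)
        counts = make_counts([("S0", 0, 10, 10, 0.5)])
        with pytest.raises(DataConsistencyError):
            ase.call_ase_table(counts, haps)


class TestProportionByDaf:
    def _callset(self, directions_sig, n_extra_nonsig, haps, site=0):
        """Build a callset frame by hand for one site."""
        rows = []
        i = 0
        for d in directions_sig:
            ref, alt = (30, 2) if d == "ref_higher" else (2, 30)
            rows.append((haps.sample_ids[i], site, ref, alt, 0.5))
            i += 1
        for _ in range(n_extra_nonsig):
            rows.append((haps.sample_ids[i], site, 15, 15, 0.5))
            i += 1
        return ase.call_ase_table(make_counts(rows), haps)

    def _het_haps(self, n, ancestral="ref"):
        hap = np.zeros((n, 2, 1), dtype=np.int8)
        hap[:, 1, 0] = 1
        return make_haps(hap, ancestral=np.array([ancestral]))

    def test_simple_proportion(self):
        haps = self._het_haps(4)
        cs = self._callset(["ref_higher", "ref_higher"], 2, haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps, min_het=3)
        assert len(rec) == 1
        assert rec["proportion"].iloc[0] == pytest.approx(0.5)
        assert rec["n_het_testable"].iloc[0] == 4

    def test_min_het_threshold(self):
        haps = self._het_haps(2)
        cs = self._callset(["ref_higher"], 1, haps)
        rec, win = ase.ase_proportion_by_daf(cs, haps, min_het=3)
        assert rec.empty and win.empty

    def test_derived_direction_loss_and_gain(self):
        # ancestral = ref, so derived = alt; all significant hets with the
        # alt allele lower expressed -> "loss"
        haps = self._het_haps(4, ancestral="ref")
        cs = self._callset(["ref_higher", "ref_higher"], 2, haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps)
        assert rec["derived_direction"].iloc[0] == "loss"
        cs = self._callset(["alt_higher", "alt_higher"], 2, haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps)
        assert rec["derived_direction"].iloc[0] == "gain"
        cs = self._callset(["alt_higher", "ref_higher"], 2, haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps)
        assert rec["derived_direction"].iloc[0] == "mixed"

    def test_perfect_phase_with_regulatory_variant(self):
        """A coding SNP in perfect phase with a strong regulatory variant:
        every heterozygote is imbalanced, so the proportion reaches 1."""
        haps = self._het_haps(6)
        cs = self._callset(["ref_higher"] * 6, 0, haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps)
        assert rec["proportion"].iloc[0] == pytest.approx(1.0)

    def test_chance_linkage_matches_enumeration_oracle(self):
        """Independent coding and regulatory SNPs at frequency 0.5: the mean
        ASE proportion equals the enumerated probability that a coding
        heterozygote is also heterozygous for the regulator (= 0.5)."""
        # oracle: enumerate the regulator's phased configurations given a
        # coding het -- each haplotype carries the regulatory allele with
        # probability 1/2 independently; ASE iff exactly one does
        p_reg_het = sum(
            0.5 * 0.5 for cfg in [(0, 1), (1, 0)]
        )
        rng = np.random.default_rng(77)
        n, n_sites = 40, 60
        hap = (rng.random((n, 2, 2 * n_sites)) < 0.5).astype(np.int8)
        haps = make_haps(hap, positions=np.arange(1, 2 * n_sites + 1) * 10)
        rows = []
        for s in range(0, 2 * n_sites, 2):  # even = coding, odd = regulator
            reg = s + 1
            for i in np.flatnonzero(haps.is_het[:, s]):
                if haps.is_het[i, reg]:
                    ref, alt = (28, 2) if hap[i, 0, reg] else (2, 28)
                else:
                    ref, alt = 15, 15
                rows.append((haps.sample_ids[i], s, ref, alt, 0.5))
        cs = ase.call_ase_table(make_counts(rows), haps)
        rec, _ = ase.ase_proportion_by_daf(cs, haps, min_het=3)
        tot = (rec["proportion"] * rec["n_het_testable"]).sum()
        n_het = rec["n_het_testable"].sum()
        sd = np.sqrt(p_reg_het * (1 - p_reg_het) / n_het)
        assert abs(tot / n_het - p_reg_het) <= 4 * sd


class TestCompareProportions:
    def _records(self, rng, n, shift, consequence):
        props = np.clip(rng.random(n) * 0.5 + shift, 0, 1)
        return pd.DataFrame({
            "site_index": np.arange(n),
            "n_het_testable": 5,
            "n_het_significant": (props * 5).astype(int),
            "proportion": props,
            "daf": rng.random(n),
            "consequence": consequence,
            "derived_direction": "unknown",
        })

    def test_identical_groups_no_shift(self, rng):
        a = self._records(rng, 100, 0.0, "synonymous")
        b = a.copy()
        b["consequence"] = "nonsynonymous"
        res = ase.compare_ase_proportions(
            pd.concat([a, b]), "nonsynonymous", "synonymous")
        assert res["overall_p"] > 0.9

    def test_shifted_group_detected(self, rng):
        a = self._records(rng, 200, 0.0, "synonymous")
        b = self._records(rng, 200, 0.3, "nonsynonymous")
        res = ase.compare_ase_proportions(
            pd.concat([a, b]), "nonsynonymous", "synonymous")
        assert res["overall_p"] < 1e-6
        tested = res["bins"][~res["bins"]["skipped"]]
        assert (tested["direction"] == "a_higher").mean() > 0.8

    def test_sparse_bin_flagged_not_dropped(self, rng):
        a = self._records(rng, 30, 0.0, "synonymous")
        b = self._records(rng, 30, 0.2, "nonsynonymous")
        a.loc[:, "daf"] = a["daf"] * 0.4          # empty upper DAF bins
        b.loc[:, "daf"] = b["daf"] * 0.4
        res = ase.compare_ase_proportions(
            pd.concat([a, b]), "nonsynonymous", "synonymous")
        skipped = res["bins"][res["bins"]["skipped"]]
        assert len(skipped) > 0
        assert skipped["p_value"].isna().all()

    def test_empty_group_rejected(self, rng):
        a = self._records(rng, 10, 0.0, "synonymous")
        with pytest.raises(ValueError, match="non-empty"):
            ase.compare_ase_proportions(a, "nonsynonymous", "synonymous")


def test_pooled_class_proportion_summary():
    hap = np.zeros((5, 2, 2), dtype=np.int8)
    hap[:, 1, :] = 1
    haps = make_haps(hap, consequence=np.array(["stop_gained", "synonymous"]))
    rows = [("S%d" % i, 0, 30, 2, 0.5) for i in range(3)]
    rows += [("S3", 0, 15, 15, 0.5), ("S4", 1, 16, 14, 0.5)]
    cs = ase.call_ase_table(make_counts(rows), haps)
    summ = ase.class_proportion_summary(cs, haps, "stop_gained")
    assert summ["n_testable"] == 4
    assert summ["n_significant"] == 3
    assert summ["proportion"] == pytest.approx(0.75)
    assert ase.pooled_proportion(66, 150) == pytest.approx(0.44)
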