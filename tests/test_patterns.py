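"""Trio DEG calling, mid-parent testing, and pattern classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trioexpress as tx
from trioexpress.patterns import classify_gene
from conftest import LIBS, make_count_table


def midparent_oracle(k, n, p0, support=4000):
    """Enumeration over the non-negligible pmf support of Binomial(n, p0)."""
    hi = min(n, support)
    xs = np.arange(hi + 1)
    pmf = stats.binom.pmf(xs, n, p0)
    return min(1.0, float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def five_lib_table(rows, scale=1_000_000):
    """CountTable from per-gene TPM-level rows plus a filler gene chosen so
    every library total equals ``scale`` exactly (counts == TPM)."""
    arr = np.array(rows, dtype=np.int64)
    filler = scale - arr.sum(axis=0)
    assert (filler > 0).all()
    arr = np.vstack([arr, filler])
    genes = [f"g{i}" for i in range(len(rows))] + ["filler"]
    return make_count_table(arr, libs=LIBS, genes=genes)


class TestMidparentTest:
    def test_observation_at_null_mode_is_one(self):
        p, d = tx.midparent_test(3, 1e6, 2.0, 4.0)
        assert p == 1.0
        assert d == "none"

    def test_hybrid_only_expression(self):
        p, d = tx.midparent_test(7, 1e6, 0.0, 0.0)
        assert p == 0.0 and d == "up"

    def test_no_expression_anywhere_errors(self):
        with pytest.raises(ValueError, match="skipped"):
            tx.midparent_test(0, 1e6, 0.0, 0.0)

    def test_matches_enumeration_oracle(self):
        p, d = tx.midparent_test(30, 1e6, 10.0, 10.0)
        assert p == pytest.approx(midparent_oracle(30, 1_000_000, 1e-5),
                                  abs=1e-12)
        assert d == "up"

    @pytest.mark.parametrize("seed", range(3))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            n = int(rng.integers(10_000, 2_000_000))
            tpm_m = float(rng.uniform(0, 40))
            tpm_p = float(rng.uniform(0, 40))
            p0 = 0.5 * (tpm_m + tpm_p) / 1e6
            k = int(rng.poisson(max(n * p0, 0.5) * rng.uniform(0.3, 3)))
            p, _ = tx.midparent_test(k, n, tpm_m, tpm_p)
            assert p == pytest.approx(midparent_oracle(k, n, p0), abs=1e-12)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "mid,m_sig,m_dir,p_sig,p_dir,expected", [
            (False, True, "up", True, "up", "additive"),
            (False, False, "none", False, "none", "additive"),
            (True, True, "up", True, "up", "over-dominance"),
            (True, True, "down", True, "down", "under-dominance"),
            (True, False, "none", True, "up", "maternal-ELD"),
            (True, False, "none", True, "down", "maternal-ELD"),
            (True, True, "up", False, "none", "paternal-ELD"),
            (True, True, "up", True, "down", "other-nonadditive"),
            (True, False, "none", False, "none", "other-nonadditive"),
        ])
    def test_decision_tree(self, mid, m_sig, m_dir, p_sig, p_dir, expected):
        assert classify_gene(mid, m_sig, m_dir, p_sig, p_dir) == expected


class TestCallTrioDEGs:
    def _fit(self, rows, **kwargs):
        t = five_lib_table(rows)
        norm = tx.normalize(t, reference="CC", scaling=False)
        de = {p: tx.pairwise_de(norm, p[0], p[1])
              for p in (("AC", "CC"), ("BC", "CC"), ("AC", "BC"))}
        trio = tx.call_trio_degs(de[("AC", "CC")], de[("BC", "CC")],
                                 de[("AC", "BC")], norm, **kwargs)
        return trio

    def test_ordered_gene_is_up(self):
        #       AA    BB    CC    AC    BC
        trio = self._fit([[50, 50, 5, 300, 100]])
        assert "g0" in trio.up and "g0" not in trio.down

    def test_flat_gene_not_a_deg(self):
        trio = self._fit([[100, 100, 100, 100, 100]])
        assert trio.total == 0

    def test_discordant_directions_excluded(self):
        trio = self._fit([[50, 50, 100, 500, 5]])
        assert trio.total == 0

    def test_strict_trio_requires_hybrid_contrast(self):
        # AC and BC both high vs CC but nearly equal to each other
        rows = [[50, 50, 5, 300, 295]]
        assert self._fit(rows).total == 1
        assert self._fit(rows, strict_trio=True).total == 0

    def test_inconsistent_gene_sets_error(self, fitted):
        other_norm = tx.normalize(
            five_lib_table([[10, 10, 10, 10, 10]]), reference="CC",
            scaling=False)
        with pytest.raises(ValueError, match="share one table"):
            tx.call_trio_degs(fitted.de_calls["AC_vs_CC"],
                              fitted.de_calls["BC_vs_CC"],
                              fitted.de_calls["AC_vs_BC"], other_norm)


class TestClassifyHybrid:
    def test_hybrid_equal_to_maternal_gives_maternal_eld(self):
        rng = np.random.default_rng(5)
        m = rng.poisson(400, size=40) + 50
        p = (m * 6).astype(np.int64)
        # AC equals its maternal parent; BC sits between AC and CC so the
        # trio ordering AC < BC < CC holds deterministically
        rows = [[int(m[i]), int(m[i]), int(p[i]), int(m[i]), int(2 * m[i])]
                for i in range(40)]
        t = five_lib_table(rows)
        norm = tx.normalize(t, reference="CC", scaling=False)
        de = {pr: tx.pairwise_de(norm, pr[0], pr[1])
              for pr in (("AC", "CC"), ("BC", "CC"), ("AC", "BC"),
                         ("AC", "AA"))}
        trio = tx.call_trio_degs(de[("AC", "CC")], de[("BC", "CC")],
                                 de[("AC", "BC")], norm)
        assert len(trio.down) >= 35  # hybrids far below paternal
        rec = tx.classify_hybrid(trio, norm, "AC", "AA", "CC",
                                 de_vs_maternal=de[("AC", "AA")],
                                 de_vs_paternal=de[("AC", "CC")])
        assert (rec["category"] == "maternal-ELD").all()

    def test_empty_trio_set_gives_empty_records(self, fitted):
        empty = tx.TrioDEGSet(up=frozenset(), down=frozenset())
        rec = tx.classify_hybrid(empty, fitted.normalized, "AC", "AA", "CC")
        assert len(rec) == 0

    def test_same_parents_error(self, fitted):
        with pytest.raises(ValueError, match="differ"):
            tx.classify_hybrid(fitted.trio, fitted.normalized, "AC", "CC",
                               "CC")

    def test_mixture_hybrid_mostly_additive(self):
        """A hybrid drawn from the exact 50/50 parental mixture should be
        classified additive at roughly the null rate."""
        rng = np.random.default_rng(8)
        g = 150
        a_lvl = rng.uniform(300, 900, g)
        c_lvl = a_lvl * 4  # parents differ 4x so genes are trio DEGs
        rows = []
        for i in range(g):
            mid = (a_lvl[i] + c_lvl[i]) / 2
            rows.append([int(rng.poisson(a_lvl[i])),
                         int(rng.poisson(a_lvl[i])),
                         int(rng.poisson(c_lvl[i])),
                         int(rng.poisson(mid)), int(rng.poisson(mid * 1.2))])
        t = five_lib_table(rows)
        norm = tx.normalize(t, reference="CC", scaling=False)
        de = {pr: tx.pairwise_de(norm, pr[0], pr[1])
              for pr in (("AC", "CC"), ("BC", "CC"), ("AC", "BC"),
                         ("AC", "AA"))}
        trio = tx.call_trio_degs(de[("AC", "CC")], de[("BC", "CC")],
                                 de[("AC", "BC")], norm)
        rec = tx.classify_hybrid(trio, norm, "AC", "AA", "CC",
                                 de_vs_maternal=de[("AC", "AA")],
                                 de_vs_paternal=de[("AC", "CC")])
        assert len(rec) >= 100
        assert (rec["category"] == "additive").mean() >= 0.9


class TestIntersections:
    def _records(self, items):
        df = pd.DataFrame(items, columns=["gene_id", "direction", "category"])
        return df.set_index("gene_id")

    def test_set_algebra_and_idempotence(self):
        a = self._records([("g1", "up", "over-dominance"),
                           ("g2", "up", "over-dominance"),
                           ("g3", "down", "over-dominance")])
        b = self._records([("g2", "up", "over-dominance"),
                           ("g3", "down", "over-dominance"),
                           ("g4", "up", "under-dominance")])
        got = tx.intersect_patterns(a, b, "over-dominance")
        assert got == {"g2", "g3"}
        assert tx.intersect_patterns(b, a, "over-dominance") == got
        assert tx.intersect_patterns(a, a, "over-dominance") == {"g1", "g2",
                                                                 "g3"}

    def test_direction_split(self):
        a = self._records([("g1", "up", "maternal-ELD"),
                           ("g2", "down", "maternal-ELD")])
        assert tx.intersect_patterns(a, a, "maternal-ELD", "up") == {"g1"}
        assert tx.intersect_patterns(a, a, "maternal-ELD", "down") == {"g2"}

    def test_unknown_category_errors(self):
        a = self._records([("g1", "up", "over-dominance")])
        with pytest.raises(ValueError, match="category"):
            tx.intersect_patterns(a, a, "sideways-dominance")


class TestSummary:
    def test_partition_invariants_on_fitted_run(self, fitted):
        s = fitted.pattern_summary
        for h in s.hybrids:
            assert (s.additive_total(h) + s.nonadditive_total(h)
                    == s.trio_total(h) == fitted.trio.total)
            for d in ("up", "down"):
                cat_sum = sum(s.count(h, d, c)
                              for c in tx.patterns.CATEGORIES)
                assert cat_sum == s.direction_total(h, d)

    def test_orientation_coherence(self, fitted):
        """An up trio gene cannot be under-dominant, nor a down gene
        over-dominant: the paternal call is the trio membership call."""
        for rec in fitted.patterns.values():
            up = rec[rec["direction"] == "up"]
            down = rec[rec["direction"] == "down"]
            assert not (up["category"] == "under-dominance").any()
            assert not (down["category"] == "over-dominance").any()

    def test_zero_records_summary_undefined(self):
        empty = pd.DataFrame(columns=["direction", "category"])
        empty.attrs["hybrid"] = "AC"
        empty2 = empty.copy()
        empty2.attrs["hybrid"] = "BC"
        s = tx.summarize_patterns(empty, empty2)
        assert s.trio_total() == 0
        assert s.pct_nonadditive("AC") is None
        assert s.maternal_eld_fold_ratio() is None
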