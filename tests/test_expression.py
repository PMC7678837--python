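"""Normalization, filtering, differential expression, markers, qPCR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxtrap.config import SimConfig
from oxtrap.expression import (
    apply_fc_cutoff,
    build_celltype_lists,
    consensus_markers,
    crossstudy_fc_correlation,
    define_marker_genes,
    differential_expression,
    filter_expressed,
    normalize_counts,
    relative_quantification,
    size_factors,
)
from oxtrap.simulate import simulate_trap_counts
from oxtrap.stats import bh_adjust, snk_pairwise, tukey_pairwise


def size_factors_oracle(x: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios: per-sample median of count/geomean over
    genes that are nonzero in every sample."""
    ref_rows = [g for g in range(x.shape[0]) if (x[g] > 0).all()]
    out = []
    for s in range(x.shape[1]):
        ratios = []
        for g in ref_rows:
            geo = np.prod(x[g]) ** (1.0 / x.shape[1])
            ratios.append(x[g, s] / geo)
        out.append(np.median(ratios))
    return np.array(out)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_library(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        np.testing.assert_allclose(
            size_factors(counts), [2 ** -0.5, 2 ** 0.5], rtol=1e-12
        )
        np.testing.assert_allclose(
            size_factors(counts), size_factors_oracle(counts.to_numpy(float))
        )

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"s1": [5, 0, 7]})
        np.testing.assert_allclose(size_factors(counts), [1.0])

    def test_no_reference_gene_errors_then_pseudo(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(counts)
        f = size_factors(counts, pseudo_reference=True)
        assert (f > 0).all()

    def test_normalisation_removes_planted_depth(self, rng):
        base = rng.integers(50, 500, size=100).astype(float)
        depth = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame(
            rng.poisson(np.outer(base, depth)), columns=list("abcd")
        )
        norm = normalize_counts(counts)
        col_medians = (norm / norm.mean(axis=1).to_numpy()[:, None]).median()
        np.testing.assert_allclose(col_medians, 1.0, atol=0.08)


def filter_oracle(x, groups, threshold):
    keep = []
    for g in range(x.shape[0]):
        ok = False
        for grp in set(groups):
            cols = [i for i, gg in enumerate(groups) if gg == grp]
            if all(x[g, c] > threshold for c in cols):
                ok = True
        keep.append(ok)
    return keep


class TestFilterExpressed:
    def _frame(self, rows, groups):
        df = pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(groups))])
        return df, pd.Series(groups, index=df.columns)

    def test_all_above_threshold_retained(self):
        df, groups = self._frame([[21, 22, 23]], ["a", "a", "a"])
        assert list(filter_expressed(df, groups)) == [0]

    def test_single_failing_sample_drops_gene(self):
        df, groups = self._frame(
            [[19, 50, 50, 5, 5, 5]], ["a", "a", "a", "b", "b", "b"]
        )
        assert list(filter_expressed(df, groups)) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = int(rng.integers(1, 40)), int(rng.integers(2, 8))
        x = rng.uniform(0, 60, size=(n_genes, n_samples))
        groups = [f"g{i}" for i in rng.integers(0, 3, n_samples)]
        df = pd.DataFrame(x, columns=[f"s{i}" for i in range(n_samples)])
        labels = pd.Series(groups, index=df.columns)
        got = filter_expressed(df, labels, threshold=20)
        expected = [i for i, k in enumerate(filter_oracle(x, groups, 20)) if k]
        assert list(got) == expected


class TestDifferentialExpression:
    def _toy(self, rng, n_genes=30):
        counts = pd.DataFrame(
            rng.integers(50, 400, size=(n_genes, 6)).astype(float),
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame(
            {"fraction": ["input"] * 3 + ["positive"] * 3,
             "treatment": "none", "study": "x",
             "subject": [f"m{i}" for i in range(6)]},
            index=pd.Index(counts.columns, name="sample"),
        )
        return counts, meta

    def test_constant_gene_f_zero_p_one(self, rng):
        counts, meta = self._toy(rng)
        counts.iloc[0] = 100.0
        de = differential_expression(counts, meta)
        assert de.table.iloc[0]["F"] == 0.0
        assert de.table.iloc[0]["p"] == 1.0

    def test_f_equals_squared_t_for_two_groups(self, rng):
        counts, meta = self._toy(rng)
        de = differential_expression(counts, meta)
        from scipy import stats as sps

        log = np.log2(counts + 1)
        for i in range(5):
            t, p = sps.ttest_ind(log.iloc[i, :3], log.iloc[i, 3:])
            assert de.table.iloc[i]["F"] == pytest.approx(t ** 2)
            assert de.table.iloc[i]["p"] == pytest.approx(p)

    def test_two_factor_design(self, rng):
        counts = pd.DataFrame(
            rng.integers(50, 400, size=(10, 8)).astype(float),
            columns=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {"fraction": ["input", "input", "positive", "positive"] * 2,
             "treatment": ["pbs"] * 4 + ["lps"] * 4,
             "study": "x", "subject": [f"m{i}" for i in range(8)]},
            index=pd.Index(counts.columns, name="sample"),
        )
        de = differential_expression(counts, meta, factor="fraction",
                                     factor2="treatment")
        assert de.table["p"].between(0, 1).all()

    def test_posthoc_flags_present(self, rng):
        counts, meta = self._toy(rng, n_genes=5)
        de = differential_expression(counts, meta, posthoc="snk")
        assert "snk_input_vs_positive" in de.table.columns


class TestBH:
    def test_textbook_vector(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_rank_and_bounded(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            q = bh_adjust(p)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert (q <= 1 + 1e-12).all() and (q >= p - 1e-12).all()


class TestFcCutoffAndMarkers:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["fc", "q"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_fc_cutoff_cases(self):
        table = self._table([(1.20, 0.001), (0.70, 0.01), (2.0, 0.20)])
        assert list(apply_fc_cutoff(table)) == ["g1"]

    def test_marker_definition_cases(self):
        table = self._table([(6.0, 0.01), (4.9, 0.001), (8.0, 0.20)])
        markers = define_marker_genes(table, "astrocyte")
        assert markers.genes == ["g0"]

    def test_planted_marker_recovery(self):
        cfg = SimConfig(seed=42)
        cm, truth = simulate_trap_counts(cfg, target="astrocyte")
        norm = normalize_counts(cm.counts)
        kept = filter_expressed(norm, cm.meta["fraction"])
        de = differential_expression(norm.loc[kept], cm.meta)
        markers = define_marker_genes(de, "astrocyte")
        planted = set(truth.marker_sets["astrocyte"])
        found = set(markers.genes)
        tp = len(found & planted)
        assert tp / len(planted) >= 0.9
        assert tp / len(found) >= 0.9


class TestCelltypeLists:
    def test_inclusive_cutoff_and_uniqueness(self):
        scores = pd.DataFrame(
            {"astrocyte": [3.5, 4.0, 1.0], "microglia": [1.0, 4.0, 5.0]},
            index=["gA", "gBoth", "gM"],
        )
        lists = build_celltype_lists(scores)
        assert lists["astrocyte"].genes == ["gA"]  # 3.5 inclusive
        assert lists["microglia"].genes == ["gM"]
        assert "gBoth" not in lists["astrocyte"].genes  # removed from both

    def test_matches_bruteforce_two_pass(self, rng):
        genes = [f"g{i}" for i in range(60)]
        scores = pd.DataFrame(
            rng.uniform(0, 6, size=(60, 3)), index=genes, columns=list("abc")
        )
        lists = build_celltype_lists(scores)
        for ct in "abc":
            expected = sorted(
                g for g in genes
                if scores.loc[g, ct] >= 3.5
                and sum(scores.loc[g, o] >= 3.5 for o in "abc") == 1
            )
            assert lists[ct].genes == expected


class TestConsensus:
    def test_membership_rules(self):
        res = consensus_markers({"A": ["g1", "g2"], "B": ["g1"], "C": ["g3"]})
        assert res["consensus"] == ["g1"]

    def test_reference_intersection(self):
        res = consensus_markers(
            {"A": ["g1", "g2"], "B": ["g1", "g2"]}, reference=["g2", "g9"]
        )
        assert res["method_independent"] == ["g2"]

    def test_counts_match_bruteforce(self, rng):
        sets = {s: set(rng.choice(40, size=15, replace=False).tolist())
                for s in "ABC"}
        res = consensus_markers({s: [f"g{i}" for i in v] for s, v in sets.items()})
        expected = sorted(
            f"g{i}" for i in set().union(*sets.values())
            if sum(i in v for v in sets.values()) >= 2
        )
        assert res["consensus"] == expected
        for combo, n in res["overlap_counts"].items():
            members = [
                i for i in set().union(*sets.values())
                if {s for s in sets if i in sets[s]} == set(combo)
            ]
            assert n == len(members)


class TestCrossStudyCorrelation:
    def test_self_and_inverse(self):
        fc = pd.Series([2.0, 4.0, 0.5, 1.0, 8.0, 0.25, 3.0, 1.5, 6.0, 0.75],
                       index=[f"g{i}" for i in range(10)])
        mat = crossstudy_fc_correlation({"a": fc, "b": fc, "inv": 1.0 / fc})
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert mat.loc["a", "inv"] == pytest.approx(-1.0)

    def test_matches_manual_covariance(self, rng):
        idx = [f"g{i}" for i in range(30)]
        a = pd.Series(np.exp(rng.normal(0, 1, 30)), index=idx)
        b = pd.Series(np.exp(rng.normal(0, 1, 30)), index=idx)
        mat = crossstudy_fc_correlation({"a": a, "b": b})
        x, y = np.log2(a.to_numpy()), np.log2(b.to_numpy())
        manual = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert mat.loc["a", "b"] == pytest.approx(manual)

    def test_too_few_shared_genes_is_na(self):
        a = pd.Series([2.0] * 5, index=[f"g{i}" for i in range(5)])
        b = pd.Series([2.0] * 5, index=[f"h{i}" for i in range(5)])
        mat = crossstudy_fc_correlation({"a": a, "b": b})
        assert np.isnan(mat.loc["a", "b"])


class TestRelativeQuantification:
    def _cts(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct"])

    def test_ddct_identities(self):
        cts = self._cts([
            ("cal", "Hprt", 20.0), ("cal", "tgt", 25.0),
            ("s_same", "Hprt", 21.0), ("s_same", "tgt", 26.0),   # ddCt 0
            ("s_up1", "Hprt", 20.0), ("s_up1", "tgt", 26.0),     # ddCt +1
            ("s_dn2", "Hprt", 20.0), ("s_dn2", "tgt", 23.0),     # ddCt -2
        ])
        rq = relative_quantification(cts, "Hprt", ["cal"]).set_index("sample")
        assert rq.loc["s_same", "rq"] == pytest.approx(1.0)
        assert rq.loc["s_up1", "rq"] == pytest.approx(0.5)
        assert rq.loc["s_dn2", "rq"] == pytest.approx(4.0)

    def test_missing_control_sample_dropped(self):
        cts = self._cts([
            ("cal", "Hprt", 20.0), ("cal", "tgt", 25.0),
            ("s_bad", "tgt", 23.0),
        ])
        rq = relative_quantification(cts, "Hprt", ["cal"])
        assert "s_bad" not in set(rq["sample"])


def studentized_range_p(diff, mse, n, k_span, dfe):
    from scipy.stats import studentized_range

    q = abs(diff) / np.sqrt(mse / n)
    return float(studentized_range.sf(q, k_span, dfe))


class TestPosthocProcedures:
    MEANS = pd.Series({"a": 10.0, "b": 10.5, "c": 14.0})
    MSE, N, DFE = 1.2, 5, 12

    def test_tukey_matches_direct_computation(self):
        res = tukey_pairwise(self.MEANS, self.N, self.MSE, self.DFE)
        for c in res:
            expected = studentized_range_p(
                self.MEANS[c.level_a] - self.MEANS[c.level_b],
                self.MSE, self.N, len(self.MEANS), self.DFE,
            )
            assert c.p == pytest.approx(expected)

    def test_tukey_matches_statsmodels(self, rng):
        groups = np.repeat(list("abc"), 6)
        y = rng.normal(0, 1, 18) + np.repeat([0.0, 1.0, 3.0], 6)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        sm = pairwise_tukeyhsd(y, groups)
        means = pd.Series({g: y[groups == g].mean() for g in "abc"})
        sse = sum(((y[groups == g] - means[g]) ** 2).sum() for g in "abc")
        ours = tukey_pairwise(means, 6, sse / 15, 15)
        ours_p = {tuple(sorted((c.level_a, c.level_b))): c.p for c in ours}
        for (g1, g2), p_sm in zip(
            itertools.combinations("abc", 2), sm.pvalues
        ):
            assert ours_p[(g1, g2)] == pytest.approx(p_sm, abs=1e-6)

    def test_snk_narrower_span_uses_smaller_critical_range(self):
        res = {tuple(sorted((c.level_a, c.level_b))): c
               for c in snk_pairwise(self.MEANS, self.N, self.MSE, self.DFE)}
        # widest pair (a, c) spans 3 means; (a, b) and (b, c) span 2
        assert res[("a", "c")].p == pytest.approx(
            studentized_range_p(4.0, self.MSE, self.N, 3, self.DFE)
        )
        assert res[("a", "b")].p == pytest.approx(
            studentized_range_p(0.5, self.MSE, self.N, 2, self.DFE)
        )

    def test_snk_stepwise_blocking(self):
        # widest stretch non-significant -> inner pairs cannot be declared
        means = pd.Series({"a": 10.0, "b": 10.1, "c": 10.2})
        res = snk_pairwise(means, 3, 5.0, 6)
        assert not any(c.significant for c in res)
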