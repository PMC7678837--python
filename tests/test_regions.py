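"""Metagene binning, island context, repeat levels, region comparisons."""

import numpy as np
import pandas as pd
import pytest

from oxtrap.regions import (
    BinScheme,
    GeneModel,
    bin_index_for_site,
    island_context_classify,
    island_context_levels,
    merge_intervals,
    metagene_profile,
    region_group_comparison,
    repeat_class_levels,
)
from oxtrap.stats import sidak_adjust

SCHEME = BinScheme()


def brute_force_bin(gene: GeneModel, scheme: BinScheme, pos: int):
    """Independent oracle: enumerate every bin's interval, then look up."""
    intervals = []  # (start, end, bin)
    L = gene.end - gene.start
    if gene.strand == "+":
        for b in range(scheme.flank_bins):
            s = gene.start - scheme.flank_bp + b * 200
            intervals.append((s, s + 200, b))
        for b in range(scheme.body_bins):
            s = gene.start + int(np.ceil(b * L / scheme.body_bins))
            e = gene.start + int(np.ceil((b + 1) * L / scheme.body_bins))
            intervals.append((s, e, scheme.flank_bins + b))
        for b in range(scheme.flank_bins):
            s = gene.end + b * 200
            intervals.append((s, s + 200, scheme.flank_bins + scheme.body_bins + b))
    else:
        for b in range(scheme.flank_bins):
            e = gene.end + scheme.flank_bp - b * 200
            intervals.append((e - 200, e, b))
        for b in range(scheme.body_bins):
            e = gene.end - int(np.ceil(b * L / scheme.body_bins))
            s = gene.end - int(np.ceil((b + 1) * L / scheme.body_bins))
            intervals.append((s, e, scheme.flank_bins + b))
        for b in range(scheme.flank_bins):
            e = gene.start - b * 200
            intervals.append((e - 200, e, scheme.flank_bins + scheme.body_bins + b))
    for s, e, b in intervals:
        if s <= pos < e:
            return b
    return None


class TestBinIndex:
    def test_last_upstream_bin_plus_strand(self):
        g = GeneModel("g", "chr1", 10_000, 12_700, "+")
        assert bin_index_for_site(g, SCHEME, 9_900) == 19

    def test_body_bin_arithmetic(self):
        g = GeneModel("g", "chr1", 10_000, 12_700, "+")
        assert bin_index_for_site(g, SCHEME, 10_100) == 21  # floor(27*100/2700)=1

    def test_outside_returns_none(self):
        g = GeneModel("g", "chr1", 10_000, 12_700, "+")
        assert bin_index_for_site(g, SCHEME, 100) is None
        assert bin_index_for_site(g, SCHEME, 50_000) is None

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(40):
            start = int(rng.integers(5_000, 50_000))
            length = int(rng.integers(27, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel("g", "chr1", start, start + length, strand)
            pos = rng.integers(start - 5_000, start + length + 5_000, size=250)
            for p in pos:
                assert bin_index_for_site(g, SCHEME, int(p)) == \
                    brute_force_bin(g, SCHEME, int(p)), (g, int(p))

    def test_strand_flip_mirrors_bins(self, rng):
        start, length = 20_000, 2_700
        plus = GeneModel("g", "chr1", start, start + length, "+")
        minus = GeneModel("g", "chr1", start, start + length, "-")
        for p in rng.integers(start - 4_000, start + length + 4_000, size=500):
            b_plus = bin_index_for_site(plus, SCHEME, int(p))
            b_minus = bin_index_for_site(minus, SCHEME, int(p))
            if b_plus is None:
                assert b_minus is None
            else:
                assert b_minus == SCHEME.total_bins - 1 - b_plus


class TestMetagene:
    def _paired(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "mC_pct"])

    def test_single_site_single_gene(self):
        g = GeneModel("g1", "chr1", 10_000, 12_700, "+")
        paired = self._paired([("chr1", 10_100, 70.0)])
        prof = metagene_profile(paired, [g])
        assert prof.bin_means[21] == pytest.approx(70.0)
        assert np.isnan(np.delete(prof.bin_means, 21)).all()
        assert prof.per_gene.loc["g1", "body"] == pytest.approx(70.0)

    def test_gene_order_invariance(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", 10_000 + 20_000 * i,
                           13_000 + 20_000 * i, "+") for i in range(4)]
        paired = self._paired(
            [("chr1", int(p), float(rng.uniform(0, 100)))
             for p in rng.integers(0, 100_000, 300)]
        )
        a = metagene_profile(paired, genes)
        b = metagene_profile(paired, genes[::-1])
        np.testing.assert_allclose(a.bin_means, b.bin_means)

    def test_short_gene_excluded(self):
        genes = [GeneModel("tiny", "chr1", 100, 110, "+"),
                 GeneModel("ok", "chr1", 10_000, 12_700, "+")]
        paired = self._paired([("chr1", 10_100, 50.0)])
        prof = metagene_profile(paired, genes)
        assert prof.excluded_genes == ["tiny"]

    def test_empty_gene_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            metagene_profile(self._paired([]), [])

    def test_bounds(self, rng):
        genes = [GeneModel("g", "chr1", 10_000, 13_000, "-")]
        paired = self._paired(
            [("chr1", int(p), float(rng.uniform(0, 100)))
             for p in rng.integers(6_000, 17_000, 500)]
        )
        prof = metagene_profile(paired, genes)
        ok = ~np.isnan(prof.bin_means)
        assert ((prof.bin_means[ok] >= 0) & (prof.bin_means[ok] <= 100)).all()


def anova2_oracle(df):
    """From-scratch balanced two-way ANOVA sums of squares (no interaction df
    check needed for the toys used here)."""
    grand = df["value"].mean()
    ss_a = sum(
        len(sub) * (sub["value"].mean() - grand) ** 2
        for _, sub in df.groupby("group")
    )
    ss_b = sum(
        len(sub) * (sub["value"].mean() - grand) ** 2
        for _, sub in df.groupby("region")
    )
    ss_cells = sum(
        len(sub) * (sub["value"].mean() - grand) ** 2
        for _, sub in df.groupby(["group", "region"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((sub["value"] - sub["value"].mean()) ** 2).sum()
        for _, sub in df.groupby(["group", "region"])
    )
    return ss_a, ss_b, ss_ab, ss_err


class TestRegionComparison:
    def _toy(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group in ("input", "positive"):
            for region in ("upstream", "body"):
                for i in range(4):
                    v = rng.normal(70, 1)
                    if group == "positive" and region == "upstream":
                        v -= shift
                    rows.append((f"{group}{i}", group, region, v))
        return pd.DataFrame(rows, columns=["sample", "group", "region", "value"])

    def test_identical_groups_f_near_zero(self):
        df = self._toy(shift=0.0, seed=1)
        # make groups exactly identical
        df.loc[df["group"] == "positive", "value"] = \
            df.loc[df["group"] == "input", "value"].to_numpy()
        res = region_group_comparison(df)
        row = res["anova"].loc["C(group)"]
        assert row["F"] == pytest.approx(0.0, abs=1e-10)
        assert row["PR(>F)"] == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self):
        df = self._toy(shift=10.0, seed=2)
        res = region_group_comparison(df)
        ss_a, ss_b, ss_ab, ss_err = anova2_oracle(df)
        tab = res["anova"]
        assert tab.loc["C(group)", "sum_sq"] == pytest.approx(ss_a)
        assert tab.loc["C(region)", "sum_sq"] == pytest.approx(ss_b)
        assert tab.loc["C(group):C(region)", "sum_sq"] == pytest.approx(ss_ab)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_err)

    def test_planted_shift_detected_with_sidak(self):
        df = self._toy(shift=15.0, seed=3)
        res = region_group_comparison(df)
        pw = res["pairwise"]
        up = pw[pw["region"] == "upstream"].iloc[0]
        assert up["p_sidak"] < 0.01

    def test_sidak_identity_for_single_comparison(self):
        p = np.array([0.2, 0.01, 0.75])
        np.testing.assert_allclose(sidak_adjust(p, m=1), p)


def island_oracle(pos, islands):
    """Distance-to-nearest-island classification, O(n_islands) per query."""
    best = None
    for s, e in islands:
        if s <= pos < e:
            return "island"
        d = (s - pos) if pos < s else (pos - (e - 1))
        best = d if best is None else min(best, d)
    if best is None:
        return "open_sea"
    if best <= 2000:
        return "shore"
    if best <= 4000:
        return "shelf"
    return "open_sea"


class TestIslandContext:
    ISL = np.array([[10_000, 11_000]])

    @pytest.mark.parametrize("pos,expected", [
        (10_500, "island"), (9_500, "shore"), (7_500, "shelf"), (4_000, "open_sea"),
        (11_500, "shore"), (13_500, "shelf"),
    ])
    def test_textbook_cases(self, pos, expected):
        assert island_context_classify(pos, self.ISL) == expected

    def test_close_islands_precedence(self):
        # two islands 3 kb apart: midpoint is 1.5 kb from each -> shore wins
        islands = np.array([[10_000, 11_000], [14_000, 15_000]])
        assert island_context_classify(12_500, islands) == "shore"

    def test_empty_islands_all_open_sea(self):
        labels = island_context_classify([1, 100, 10_000], np.empty((0, 2)))
        assert (labels == "open_sea").all()

    def test_partition_and_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 8))
            starts = np.sort(rng.integers(0, 80_000, n))
            islands = np.column_stack([starts, starts + rng.integers(200, 3_000, n)])
            pos = rng.integers(0, 90_000, 500)
            labels = island_context_classify(pos, islands)
            merged = merge_intervals(islands)
            for p, lab in zip(pos, labels):
                assert lab in ("island", "shore", "shelf", "open_sea")
                assert lab == island_oracle(int(p), merged), (int(p), merged)

    def test_levels_summary(self, rng):
        paired = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(0, 50_000, 400),
            "context": "CG",
            "mC_pct": rng.uniform(0, 100, 400),
            "hmC_pct": rng.uniform(0, 20, 400),
        })
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [12_000]})
        out = island_context_levels(paired, islands)
        assert set(out.index) <= {"island", "shore", "shelf", "open_sea"}
        assert (out["mC_pct"].dropna() <= 100).all()


class TestRepeatLevels:
    def _paired(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "context", "mC_pct", "hmC_pct"]
        )

    def test_single_line_mean(self):
        paired = self._paired([("chr1", 100, "CG", 80.0, 1.0),
                               ("chr1", 200, "CG", 60.0, 1.0),
                               ("chr1", 5_000, "CG", 10.0, 1.0)])
        repeats = pd.DataFrame(
            [("chr1", 50, 300, "LINE")],
            columns=["chrom", "start", "end", "repeat_class"],
        )
        out = repeat_class_levels(paired, repeats)
        assert out.loc["LINE", "mCG"] == pytest.approx(70.0)
        assert out.loc["non_repeat", "mCG"] == pytest.approx(10.0)

    def test_empty_repeats_non_repeat_is_genome_mean(self):
        paired = self._paired([("chr1", 100, "CG", 80.0, 1.0),
                               ("chr1", 200, "CG", 60.0, 1.0)])
        repeats = pd.DataFrame(columns=["chrom", "start", "end", "repeat_class"])
        out = repeat_class_levels(paired, repeats)
        assert list(out.index) == ["non_repeat"]
        assert out.loc["non_repeat", "mCG"] == pytest.approx(70.0)

    def test_overlap_oracle(self, rng):
        paired = self._paired(
            [("chr1", int(p), "CG", 50.0, 5.0)
             for p in rng.integers(0, 100_000, 2_000)]
        )
        rows = []
        for cls in ("LINE", "SINE", "LTR", "simple"):
            for _ in range(15):
                s = int(rng.integers(0, 99_000))
                rows.append(("chr1", s, s + int(rng.integers(100, 2_000)), cls))
        repeats = pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])
        out = repeat_class_levels(paired, repeats)
        # oracle: brute-force membership per class
        pos = paired["pos"].to_numpy()
        covered_any = np.zeros(len(pos), dtype=bool)
        for cls, sub in repeats.groupby("repeat_class"):
            mask = np.zeros(len(pos), dtype=bool)
            for _, r in sub.iterrows():
                mask |= (pos >= r.start) & (pos < r.end)
            covered_any |= mask
            expected = paired.loc[mask, "mC_pct"].mean()
            assert out.loc[cls, "mCG"] == pytest.approx(expected)
        assert out.loc["non_repeat", "mCG"] == pytest.approx(
            paired.loc[~covered_any, "mC_pct"].mean()
        )
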