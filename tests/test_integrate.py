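import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyltide.integrate import (BetaIntegrator, RegulatoryPotentialParams,
                                  ks_target_test, rank_product_p,
                                  rank_product_targets, regulatory_potential)


def naive_regulatory_potential(tss, peaks, window=100_000):
    """Independent double-loop evaluation of the distance-decay score."""
    out = {}
    for _, g in tss.iterrows():
        s = 0.0
        for _, p in peaks.iterrows():
            if p["chrom"] != g["chrom"]:
                continue
            d = abs((p["start"] + p["end"]) / 2.0 - g["tss"])
            if d <= window:
                s += np.exp(-(0.5 + 4.0 * d / window))
        out[g["gene_id"]] = s
    return out


def random_instance(rng, n_genes, n_peaks):
    tss = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_genes)],
        "chrom": rng.choice(["c1", "c2"], n_genes),
        "tss": rng.integers(0, 1_000_000, n_genes),
    })
    start = rng.integers(0, 1_000_000, n_peaks)
    peaks = pd.DataFrame({
        "chrom": rng.choice(["c1", "c2"], n_peaks),
        "start": start, "end": start + rng.integers(1, 2000, n_peaks),
    })
    return tss, peaks


class TestRegulatoryPotential:
    def test_peak_at_tss_scores_exp_minus_half(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [500_000]})
        peaks = pd.DataFrame({"chrom": ["c"], "start": [499_999], "end": [500_001]})
        s = regulatory_potential(tss, peaks)["score"][0]
        assert s == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_peak_outside_window_scores_zero(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [0]})
        peaks = pd.DataFrame({"chrom": ["c"], "start": [149_999], "end": [150_001]})
        assert regulatory_potential(tss, peaks)["score"][0] == 0.0

    def test_window_boundary_inclusive(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [0]})
        peaks = pd.DataFrame({"chrom": ["c"], "start": [99_999], "end": [100_001]})
        s = regulatory_potential(tss, peaks)["score"][0]
        assert s == pytest.approx(np.exp(-4.5), abs=1e-12)

    def test_two_peak_sum_closed_form(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [1_000_000]})
        peaks = pd.DataFrame({"chrom": ["c", "c"],
                              "start": [1_024_999, 1_049_999],
                              "end": [1_025_001, 1_050_001]})
        s = regulatory_potential(tss, peaks)["score"][0]
        assert s == pytest.approx(np.exp(-1.5) + np.exp(-2.5), abs=1e-9)
        assert s == pytest.approx(0.305215, abs=1e-6)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            tss, peaks = random_instance(rng, rng.integers(1, 11), rng.integers(0, 21))
            fast = regulatory_potential(tss, peaks).set_index("gene_id")["score"]
            slow = naive_regulatory_potential(tss, peaks)
            for g, v in slow.items():
                assert fast[g] == pytest.approx(v, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(14)
        tss, peaks = random_instance(rng, 8, 15)
        base = regulatory_potential(tss, peaks)["score"]
        shift = 123_456
        tss2 = tss.assign(tss=tss["tss"] + shift)
        peaks2 = peaks.assign(start=peaks["start"] + shift,
                              end=peaks["end"] + shift)
        moved = regulatory_potential(tss2, peaks2)["score"]
        assert np.allclose(base, moved, atol=1e-12)

    @given(st.integers(0, 100_000))
    @settings(max_examples=30)
    def test_score_decreasing_in_distance_and_bounded(self, d):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [200_000]})
        mk = lambda dd: pd.DataFrame({"chrom": ["c"], "start": [200_000 + dd],
                                      "end": [200_000 + dd + 1]})
        # midpoint of a width-1 peak at start s is s + 0.5
        s_near = regulatory_potential(tss, mk(d))["score"][0]
        s_far = regulatory_potential(tss, mk(d + 100))["score"][0]
        assert s_near >= s_far
        assert 0 <= s_near <= np.exp(-0.5)

    def test_negative_coordinates_rejected(self):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "tss": [-5]})
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="negative"):
            regulatory_potential(tss, peaks)


def score_frame(values):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(values))],
                         "score": values,
                         "n_peaks": [1] * len(values)})


class TestKS:
    def test_complete_separation(self):
        scores = score_frame(list(np.linspace(0.01, 0.2, 20))
                             + list(np.linspace(0.3, 0.6, 20)))
        group = [f"g{i}" for i in range(20, 40)]
        background = [f"g{i}" for i in range(20)]
        res = ks_target_test(scores, group, background)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-8

    def test_identical_samples_give_zero_statistic(self):
        vals = list(np.linspace(0.1, 0.9, 15))
        scores = score_frame(vals + vals)
        group = [f"g{i}" for i in range(15)]
        background = [f"g{i}" for i in range(15, 30)]
        res = ks_target_test(scores, group, background)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_wrong_direction_not_significant(self):
        scores = score_frame(list(np.linspace(0.5, 0.9, 20))
                             + list(np.linspace(0.0, 0.2, 20)))
        group = [f"g{i}" for i in range(20, 40)]  # group scores all SMALLER
        background = [f"g{i}" for i in range(20)]
        assert ks_target_test(scores, group, background).p_value > 0.5

    def test_overlap_rejected(self):
        scores = score_frame([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="overlap"):
            ks_target_test(scores, ["g0", "g1"], ["g1", "g2"])

    def test_small_group_warns_and_uses_exact(self):
        scores = score_frame(np.linspace(0, 1, 30))
        with pytest.warns(UserWarning, match="exact"):
            ks_target_test(scores, ["g28", "g29"],
                           [f"g{i}" for i in range(20)])

    def test_null_calibration_quick(self):
        """Randomly labeled groups reject at ~alpha over repeated draws."""
        rng = np.random.default_rng(15)
        vals = rng.normal(size=400)
        scores = score_frame(vals)
        ids = scores["gene_id"].to_numpy()
        rej = 0
        n = 400
        for _ in range(n):
            grp = rng.choice(ids, 40, replace=False)
            bg = np.setdiff1d(ids, grp)
            rej += ks_target_test(scores, list(grp), list(bg)).p_value < 0.05
        assert 0.03 <= rej / n <= 0.07


class TestRankProduct:
    def test_boundary_and_closed_form(self):
        assert rank_product_p(np.array([1.0]))[0] == pytest.approx(1.0)
        assert rank_product_p(np.array([0.01]))[0] == pytest.approx(
            0.01 * (1 - np.log(0.01)), rel=1e-12)
        assert rank_product_p(np.array([1e-4]))[0] == pytest.approx(1.0210e-3, rel=1e-3)

    def test_matches_monte_carlo_tail(self):
        rng = np.random.default_rng(16)
        u = rng.uniform(size=(1_000_000, 2)).prod(axis=1)
        for x in (0.01, 0.05, 0.2):
            emp = (u <= x).mean()
            se = np.sqrt(emp * (1 - emp) / len(u))
            assert abs(rank_product_p(np.array([x]))[0] - emp) < 3 * se

    def test_target_calling_restricts_to_top_da(self):
        n = 50
        rng = np.random.default_rng(17)
        scores = score_frame(rng.uniform(0.1, 1.0, n))
        de = pd.DataFrame({"gene": scores["gene_id"],
                           "log2FC": rng.normal(size=n),
                           "padj": rng.uniform(0, 0.04, n)})
        out = rank_product_targets(scores, de, da_top=20)
        assert len(out) == 20
        kept = set(out["gene"])
        top = set(scores.sort_values("score", ascending=False).head(20)["gene_id"])
        assert kept == top
        worst = out[(out["rp_rank"] == 20) & (out["de_rank"] == 20)]
        if len(worst):
            assert worst["rp_p"].iloc[0] == pytest.approx(1.0)

    def test_best_ranked_gene_is_most_significant(self):
        scores = score_frame([0.9, 0.5, 0.1])
        de = pd.DataFrame({"gene": ["g0", "g1", "g2"],
                           "log2FC": [3.0, 2.0, 1.0],
                           "padj": [1e-6, 1e-3, 1e-2]})
        out = rank_product_targets(scores, de, da_top=3)
        assert out.iloc[0]["gene"] == "g0"
        x = (1 / 3) * (1 / 3)
        assert out.iloc[0]["rp_p"] == pytest.approx(x * (1 - np.log(x)))

    def test_too_few_genes_rejected(self):
        scores = score_frame([0.5])
        de = pd.DataFrame({"gene": ["g0"], "log2FC": [1.0], "padj": [0.01]})
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_product_targets(scores, de)


class TestIntegrator:
    def test_direction_modes_and_determinism(self, small_study):
        from methyltide.meth import DifferentialMethylation
        from methyltide.txn import differential_expression
        dm = DifferentialMethylation().fit(
            small_study["tables"], small_study["groups"],
            small_study["islands"].rename(columns={"island_id": "name"}))
        de = differential_expression(small_study["counts"],
                                     small_study["metadata"], "3h")
        tss = small_study["genes"][["gene_id", "chrom", "tss", "strand"]]
        b1 = BetaIntegrator().fit(tss, dm.peaks_, de)
        b2 = BetaIntegrator().fit(tss, dm.peaks_, de)
        assert set(b1.results_) == {"combined", "hypo", "hyper"}
        pd.testing.assert_frame_equal(b1.results_["combined"].scores,
                                      b2.results_["combined"].scores)
        # all planted peaks are hypo, so hypo-mode reproduces combined
        pd.testing.assert_frame_equal(b1.results_["combined"].scores,
                                      b1.results_["hypo"].scores)

    def test_empty_peaks_skip_ks(self, small_study):
        from methyltide.txn import differential_expression
        de = differential_expression(small_study["counts"],
                                     small_study["metadata"], "3h")
        tss = small_study["genes"][["gene_id", "chrom", "tss", "strand"]]
        empty = pd.DataFrame(columns=["chrom", "start", "end", "direction"])
        b = BetaIntegrator(direction_mode="combined").fit(tss, empty, de)
        assert b.results_["combined"].ks == {}
        assert (b.results_["combined"].scores["score"] == 0).all()
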