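"""Module scores, bulk/single-cell TDS, and the BRS centroid classifier."""

import numpy as np
import pandas as pd
import pytest

from ptcatlas import (
    ModuleScoreParams,
    SimConfig,
    TDS_PANEL,
    braf_ras_cell_scores,
    brs,
    generate_single_cell_dataset,
    log_normalize,
    module_score,
    tds_bulk,
    tds_single_cell,
)
from ptcatlas._seeds import child_rng


def transcribed_module_score(lognorm, signature, params):
    """Literal independent transcription of the binned-control procedure."""
    avg = lognorm.mean(axis=1)
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=params.n_bins, labels=False, include_lowest=True)
    rng = child_rng(params.seed, "module_score")
    ctrl = set()
    present = [g for g in signature if g in lognorm.index]
    for g in present:
        pool = bins.index[(bins == bins[g]).to_numpy() & (bins.index != g)]
        if len(pool) == 0:
            continue
        replace = len(pool) < params.n_ctrl
        ctrl.update(rng.choice(np.asarray(pool), size=params.n_ctrl, replace=replace).tolist())
    sig_mean = lognorm.loc[present].mean(axis=0)
    ctrl_mean = (
        lognorm.loc[sorted(ctrl)].mean(axis=0)
        if ctrl
        else pd.Series(0.0, index=lognorm.columns)
    )
    return sig_mean - ctrl_mean


class TestModuleScore:
    def test_matches_literal_transcription(self, tiny_lognorm):
        params = ModuleScoreParams(n_bins=4, n_ctrl=1, seed=9)
        got = module_score(tiny_lognorm, ["g0", "g3"], params)
        want = transcribed_module_score(tiny_lognorm, ["g0", "g3"], params)
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), atol=1e-12)

    def test_per_cell_constant_matrix_scores_zero(self):
        mat = pd.DataFrame(
            np.tile([[1.0, 2.0, 0.5]], (6, 1)), index=[f"g{i}" for i in range(6)]
        )
        s = module_score(mat, ["g0", "g4"], ModuleScoreParams(n_bins=2, n_ctrl=2, seed=0))
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_signature_equals_universe_scores_near_zero(self, tiny_lognorm):
        with pytest.warns(UserWarning):
            s = module_score(
                tiny_lognorm,
                list(tiny_lognorm.index),
                ModuleScoreParams(n_bins=2, n_ctrl=10, seed=1),
            )
        assert np.abs(s).max() < 0.5

    def test_deterministic_given_seed(self, tiny_lognorm):
        params = ModuleScoreParams(n_bins=4, n_ctrl=2, seed=5)
        s1 = module_score(tiny_lognorm, ["g1", "g2"], params)
        s2 = module_score(tiny_lognorm, ["g1", "g2"], params)
        pd.testing.assert_series_equal(s1, s2)

    def test_missing_genes_dropped_with_warning(self, tiny_lognorm):
        with pytest.warns(UserWarning, match="absent"):
            module_score(tiny_lognorm, ["g0", "NOPE"], ModuleScoreParams(n_bins=2, n_ctrl=2))

    def test_all_genes_absent_raises(self, tiny_lognorm):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                module_score(tiny_lognorm, ["NOPE"], ModuleScoreParams())

    def test_expectation_over_seeds(self):
        """Mean over many control draws approaches mean(sig) - mean(bin mean)
        when every signature gene sits in its own bin (3 SE band)."""
        rng = np.random.default_rng(0)
        base = np.sort(rng.gamma(2, 1, size=40))
        mat = pd.DataFrame(
            base[:, None] + rng.normal(0, 0.01, size=(40, 30)),
            index=[f"g{i:02d}" for i in range(40)],
        )
        sig = ["g05", "g25"]
        params = [ModuleScoreParams(n_bins=4, n_ctrl=3, seed=s) for s in range(100)]
        draws = np.array([module_score(mat, sig, p).mean() for p in params])

        avg = mat.mean(axis=1)
        bins = pd.cut(avg.rank(method="first"), bins=4, labels=False, include_lowest=True)
        expected = np.mean(
            [avg[sig].mean() - avg[(bins == bins[g]) & (bins.index != g)].mean() for g in sig]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * max(se, 1e-6) + 0.02


class TestTDSBulk:
    def test_sample_at_cohort_median_scores_zero(self, toy):
        tds = tds_bulk(toy["bulk_tpm"])
        assert tds["S0"] == pytest.approx(0.0, abs=1e-10)

    def test_one_log2_unit_above_median_scores_thirteen(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 100, size=13)
        cols = {f"s{i}": base * (1 + 0.01 * i) for i in range(5)}
        tpm = pd.DataFrame(cols, index=list(TDS_PANEL))
        # add one sample exactly one log2 unit above the per-gene median
        log2 = np.log2(tpm + 1.0)
        tpm["hi"] = 2.0 ** (log2.median(axis=1) + 1.0) - 1.0
        med_before = log2.median(axis=1)
        tds = tds_bulk(tpm)
        # medians over 6 samples shift; recompute expectation directly
        log2_all = np.log2(tpm + 1.0)
        expected = (log2_all["hi"] - log2_all.median(axis=1)).sum()
        assert tds["hi"] == pytest.approx(expected, abs=1e-10)
        assert tds["hi"] > 6.0  # clearly elevated

    def test_two_identical_samples_score_zero(self):
        tpm = pd.DataFrame(
            {"a": np.arange(13) + 1.0, "b": np.arange(13) + 1.0}, index=list(TDS_PANEL)
        )
        np.testing.assert_allclose(tds_bulk(tpm).to_numpy(), 0.0, atol=1e-12)

    def test_delta_shift_moves_only_that_sample_by_delta(self, toy):
        """Adding d to one gene's log2 value in one sample (above the median,
        median untouched) changes only that sample's TDS by exactly d."""
        tpm = toy["bulk_tpm"].copy()
        before = tds_bulk(tpm)
        d = 0.75
        g = "TG"
        # S4 is the top sample for every panel gene; a positive shift leaves
        # the per-gene median unchanged
        log2val = np.log2(tpm.loc[g, "S4"] + 1.0) + d
        tpm.loc[g, "S4"] = 2.0 ** log2val - 1.0
        after = tds_bulk(tpm)
        assert after["S4"] - before["S4"] == pytest.approx(d, abs=1e-10)
        for s in ["S0", "S1", "S2", "S3"]:
            assert after[s] == pytest.approx(before[s], abs=1e-10)

    def test_missing_panel_genes_warn_all_missing_raise(self, toy):
        tpm = toy["bulk_tpm"].drop(index=["TG"])
        with pytest.warns(UserWarning, match="absent"):
            tds_bulk(tpm)
        with pytest.raises(ValueError):
            tds_bulk(toy["bulk_tpm"].loc[["GENEX1", "GENEX2"]])

    def test_mean_reduction_flag(self, toy):
        s = tds_bulk(toy["bulk_tpm"], reduce="sum")
        m = tds_bulk(toy["bulk_tpm"], reduce="mean")
        np.testing.assert_allclose(s.to_numpy() / 13.0, m.to_numpy(), atol=1e-12)


class TestBRS:
    def test_two_gene_hand_arithmetic(self):
        """c(B)=(1,0), c(R)=(0,1), v=(1,0) -> BRS = 0 - 2 = -2, BRAF-like."""
        expr = pd.DataFrame(
            {"b1": [1.0, 0.0], "r1": [0.0, 1.0], "v": [1.0, 0.0]}, index=["gx", "gy"]
        )
        out = brs(expr, ["b1"], ["r1"], normalize=False)
        assert out.loc["v", "brs"] == pytest.approx(-2.0, abs=1e-12)
        assert out.loc["v", "call"] == "BRAF-like"

    def test_sample_at_braf_centroid_is_braf_like(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)])
        expr.columns = [f"s{i}" for i in range(8)]
        out = brs(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # a sample equal to c(B): append the mean of the BRAF set pre-z-score
        expr["at_cb"] = expr[["s0", "s1", "s2"]].mean(axis=1)
        out = brs(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out.loc["at_cb", "brs"] < 0
        assert out.loc["at_cb", "call"] == "BRAF-like"

    def test_equidistant_sample_is_ras_like_by_convention(self):
        expr = pd.DataFrame(
            {"b1": [2.0, 0.0], "r1": [0.0, 2.0], "mid": [1.0, 1.0]}, index=["gx", "gy"]
        )
        out = brs(expr, ["b1"], ["r1"], normalize=False)
        assert out.loc["mid", "brs"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["mid", "call"] == "RAS-like"

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(12, 10)), columns=[f"s{i}" for i in range(10)])
        a = brs(expr, ["s0", "s1"], ["s2", "s3"])
        b = brs(expr, ["s2", "s3"], ["s0", "s1"])
        np.testing.assert_allclose(a.brs.to_numpy(), -b.brs.to_numpy(), atol=1e-10)

    def test_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(
            rng.normal(size=(12, 10)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(10)],
        )
        a = brs(expr, ["s0", "s1"], ["s2", "s3"])
        perm = expr.iloc[rng.permutation(12), rng.permutation(10)]
        b = brs(perm, ["s0", "s1"], ["s2", "s3"])
        np.testing.assert_allclose(
            a.brs.sort_index().to_numpy(), b.brs.sort_index().to_numpy(), atol=1e-10
        )

    def test_zero_variance_gene_excluded_with_warning(self):
        expr = pd.DataFrame(
            {"s0": [1.0, 5.0], "s1": [2.0, 5.0], "s2": [3.0, 5.0], "s3": [4.0, 5.0]},
            index=["ok", "flat"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = brs(expr, ["s0", "s1"], ["s2", "s3"])
        assert len(out) == 4

    def test_empty_mutant_set_raises(self):
        expr = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            brs(expr, [], [0, 1])


class TestSingleCellScores:
    def test_tds_panel_separates_states(self, small_lognorm):
        ln, ann, truth = small_lognorm
        s = tds_single_cell(ln, params=ModuleScoreParams(seed=3))
        assert s[ann.state == "normal"].mean() > s[ann.state == "dediff_like"].mean()

    def test_braf_score_tracks_dedifferentiation(self, small_lognorm):
        ln, ann, truth = small_lognorm
        g = truth.genes
        out = braf_ras_cell_scores(
            ln,
            g.index[g.braf_sig].tolist(),
            g.index[g.ras_sig].tolist(),
            ModuleScoreParams(seed=4),
        )
        assert (
            out.braf_score[ann.state == "dediff_like"].mean()
            > out.braf_score[ann.state == "follicular_like"].mean()
        )

    def test_disjoint_signatures_uncorrelated_on_null(self):
        cfg = SimConfig(seed=21, effect_size=0.0)
        counts, _, truth = generate_single_cell_dataset(cfg)
        ln = log_normalize(counts)
        g = truth.genes
        out = braf_ras_cell_scores(
            ln,
            g.index[g.braf_sig].tolist(),
            g.index[g.ras_sig].tolist(),
            ModuleScoreParams(seed=6),
        )
        r = np.corrcoef(out.braf_score, out.ras_score)[0, 1]
        assert abs(r) < 0.25

    def test_same_seed_identical_scores(self, small_lognorm):
        ln, _, _ = small_lognorm
        a = tds_single_cell(ln, params=ModuleScoreParams(seed=7))
        b = tds_single_cell(ln, params=ModuleScoreParams(seed=7))
        pd.testing.assert_series_equal(a, b)
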