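import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import megrsn as m
from megrsn.stats import PairedTestResult


def brute_force_wilcoxon_p(diffs):
    """Independent oracle: enumerate all 2**n sign assignments explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


def brute_force_bh(ps, q=0.05):
    """Independent step-up oracle."""
    ps = np.asarray(ps)
    order = np.argsort(ps)
    msk = np.zeros(len(ps), dtype=bool)
    k_max = 0
    for k, idx in enumerate(order, start=1):
        if ps[idx] <= k * q / len(ps):
            k_max = k
    msk[order[:k_max]] = True
    return msk


def brute_force_tau(x, y):
    """Concordant/discordant pair counting with tie correction (tau-b)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


class TestWilcoxon:
    def test_uniform_shift_n10_matches_exact_two_in_1024(self):
        t1 = np.arange(10.0)
        r = m.wilcoxon_signed_rank(t1, t1 + 3.0)
        assert r.p_value == pytest.approx(2 / 1024)
        assert r.n == 10

    def test_sign_convention_increase_is_negative_z(self):
        # ten distinct increases (untied ranks): z = -(55 - 27.5)/sqrt(96.25)
        t1 = np.arange(10.0)
        t2 = t1 + np.linspace(1.0, 2.0, 10)
        r = m.wilcoxon_signed_rank(t1, t2)
        assert r.z_statistic == pytest.approx(-2.803, abs=0.001)
        r_dec = m.wilcoxon_signed_rank(t2, t1)
        assert r_dec.z_statistic == pytest.approx(2.803, abs=0.001)

    def test_fully_tied_differences_use_tie_corrected_variance(self):
        # a constant shift ties every |difference|: sigma^2 = sum(r^2)/4
        t1 = np.arange(10.0)
        r = m.wilcoxon_signed_rank(t1, t1 + 3.0)
        assert r.z_statistic == pytest.approx(-27.5 / np.sqrt(302.5 / 4), abs=1e-9)

    def test_zero_difference_dropped_matches_enumeration(self):
        rng = np.random.default_rng(0)
        t1 = rng.normal(size=8)
        t2 = t1 + rng.normal(size=8)
        t2[3] = t1[3]  # one exact zero difference -> effective n = 7
        r = m.wilcoxon_signed_rank(t1, t2, method="exact")
        assert r.n == 7
        assert r.p_value == pytest.approx(brute_force_wilcoxon_p(t2 - t1))

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_exact_p_equals_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            t1 = rng.normal(size=n)
            t2 = t1 + rng.normal(0.3, 1.0, size=n)
            r = m.wilcoxon_signed_rank(t1, t2, method="exact")
            assert r.p_value == pytest.approx(brute_force_wilcoxon_p(t2 - t1))

    def test_exact_handles_tied_ranks(self):
        t1 = np.zeros(6)
        t2 = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 2.0])  # heavy ties in |d|
        r = m.wilcoxon_signed_rank(t1, t2, method="exact")
        assert r.p_value == pytest.approx(brute_force_wilcoxon_p(t2 - t1))

    def test_agrees_with_scipy_approx(self):
        rng = np.random.default_rng(1)
        t1 = rng.normal(size=20)
        t2 = t1 + rng.normal(0.5, 1.0, size=20)
        r = m.wilcoxon_signed_rank(t1, t2, method="approx")
        ref = sps.wilcoxon(t2 - t1, correction=False, mode="approx")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_approx_close_to_exact_in_decision_region(self):
        # the normal approximation tracks the exact sign-flip p to within
        # 0.01 wherever the exact p is at decision scale (<= 0.05)
        for n in range(5, 13):
            maxs = n * (n + 1) // 2
            for w in range(maxs + 1):
                d = np.ones(n)
                ranks = np.arange(1, n + 1)
                # build a tie-free difference vector with W+ = w
                signs = np.ones(n)
                remaining = w
                for r in ranks[::-1]:
                    if remaining >= r:
                        remaining -= r
                    else:
                        signs[r - 1] = -1
                if remaining != 0:
                    continue
                diffs = signs * ranks
                exact = m.wilcoxon_signed_rank(np.zeros(n), diffs, method="exact")
                approx = m.wilcoxon_signed_rank(np.zeros(n), diffs, method="approx")
                if exact.p_value <= 0.05:
                    assert abs(exact.p_value - approx.p_value) < 0.01

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            m.wilcoxon_signed_rank(
                np.zeros(10), rng.normal(size=10), method="exact"
            ).p_value < 0.05
            for _ in range(200)
        )
        lo, hi = sps.binom.interval(0.95, 200, 0.05)
        assert lo <= rejections <= hi

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            r = m.wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert r.p_value == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            m.wilcoxon_signed_rank([1, 2, 3], [2, 3, 4])


class TestFdrPerBand:
    @staticmethod
    def _results(band_ps):
        out = []
        for band, ps in band_ps.items():
            for i, p in enumerate(ps):
                out.append(PairedTestResult(band, f"net{i}", 10, 0.0, p))
        return out

    def test_single_test_band_significant(self):
        res = m.fdr_per_band(self._results({"delta": [0.003]}))
        assert res[0].fdr_significant

    def test_families_are_per_band_never_pooled(self):
        # the same p = 0.027 survives in no 4-test family where it is the
        # smallest value, yet 0.003 survives in its own band
        res = m.fdr_per_band(self._results({
            "theta": [0.027, 0.4, 0.6, 0.8],
            "lower_alpha": [0.027, 0.3, 0.5, 0.9],
            "upper_alpha": [0.003, 0.2, 0.5, 0.9],
        }))
        flags = {(r.band, r.network): r.fdr_significant for r in res}
        assert not flags[("theta", "net0")]
        assert not flags[("lower_alpha", "net0")]
        assert flags[("upper_alpha", "net0")]
        assert sum(flags.values()) == 1

    def test_step_up_rejects_all_below_largest_passing_rank(self):
        # standard BH arithmetic: in one family of four, threshold for rank 3
        # is 0.0375 >= 0.027, so the two 0.027 values are rejected as well
        res = m.fdr_per_band(self._results({"b": [0.003, 0.027, 0.027, 0.8]}))
        assert [r.fdr_significant for r in res] == [True, True, True, False]

    def test_flags_match_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            ps = rng.uniform(0, 1, rng.integers(1, 12))
            res = m.fdr_per_band(self._results({"x": list(ps)}))
            np.testing.assert_array_equal(
                [r.fdr_significant for r in res], brute_force_bh(ps)
            )

    def test_null_uniform_p_controls_fdr(self):
        rng = np.random.default_rng(4)
        false_hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            ps = rng.uniform(0, 1, 6)
            res = m.fdr_per_band(self._results({"x": list(ps)}))
            false_hits += any(r.fdr_significant for r in res)
        # under the global null, P(any rejection) <= q = 0.05
        lo, hi = sps.binom.interval(0.95, n_seeds, 0.05)
        assert false_hits <= hi


class TestKendallTau:
    def test_perfectly_concordant_eight_pairs(self):
        x = np.arange(8.0)
        r = m.kendall_tau(x, 2 * x + 1)
        assert r.tau == pytest.approx(1.0)

    def test_one_discordant_pair_value(self):
        x = np.arange(1, 9.0)
        y = x.copy()
        y[[6, 7]] = y[[7, 6]]  # swap one adjacent pair -> 27 concordant, 1 discordant
        r = m.kendall_tau(x, y)
        assert r.tau == pytest.approx((27 - 1) / 28)

    def test_matches_pair_count_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 5, 9).astype(float)
            y = rng.integers(0, 5, 9).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r = m.kendall_tau(x, y)
            assert r.tau == pytest.approx(brute_force_tau(x, y), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        assert m.kendall_tau(x, -y).tau == pytest.approx(-m.kendall_tau(x, y).tau)

    def test_missing_pairs_dropped_pairwise(self):
        x = np.array([1, 2, 3, 4, 5, 6, np.nan, 8.0])
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        r = m.kendall_tau(x, y)
        assert r.n == 7
        assert r.tau == pytest.approx(1.0)

    def test_constant_input_reported_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            r = m.kendall_tau(np.ones(6), np.arange(6.0))
        assert np.isnan(r.tau)


class TestFullInference:
    @staticmethod
    def _summaries(rng, effect_cell=None, n_subjects=10):
        """Tidy summary table with independent Gaussian PLI noise; one
        (band, network) cell optionally carries a strong T2 increase."""
        rows = []
        bands = ["theta", "lower_alpha"]
        networks = ["DMN", "FPN_right", "global"]
        for s in range(1, n_subjects + 1):
            for band in bands:
                for net in networks:
                    for tp in ("T1", "T2"):
                        v = 0.25 + 0.01 * rng.standard_normal()
                        if (
                            effect_cell
                            and tp == "T2"
                            and (band, net) == effect_cell
                        ):
                            v += 0.08
                        rows.append((s, tp, band, net, np.clip(v, 0, 1)))
        return pd.DataFrame(
            rows, columns=["subject", "timepoint", "band", "network", "mean_pli"]
        )

    @staticmethod
    def _deltas(rng, summary, linked_cell=None, slope=0.0, n_subjects=10,
                missing=()):
        domains = ["executive_functioning", "verbal_memory", "working_memory",
                   "information_processing", "attention", "psychomotor_speed"]
        rows = []
        for s in range(1, n_subjects + 1):
            if s in missing:
                continue
            row = {"subject": s}
            for d in domains:
                row[d] = rng.normal(0, 0.5)
            if linked_cell:
                band, net = linked_cell
                cell = summary[(summary.band == band) & (summary.network == net)
                               & (summary.subject == s)]
                piv = cell.pivot(index="subject", columns="timepoint",
                                 values="mean_pli")
                row["verbal_memory"] += slope * float(
                    piv["T2"].iloc[0] - piv["T1"].iloc[0]
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def test_stage3_gated_on_fdr_survivors(self):
        rng = np.random.default_rng(7)
        summary = self._summaries(rng, effect_cell=("lower_alpha", "DMN"))
        deltas = self._deltas(rng, summary, ("lower_alpha", "DMN"), slope=10.0)
        report = m.run_full_inference(summary, deltas)
        surviving = {(r.band, r.network) for r in report.network_tests
                     if r.fdr_significant}
        assert ("lower_alpha", "DMN") in surviving
        stage3_cells = {(c.band, c.network) for c in report.correlations}
        assert stage3_cells == surviving
        # all six domains correlated for each surviving cell
        dmn_rows = [c for c in report.correlations
                    if (c.band, c.network) == ("lower_alpha", "DMN")]
        assert len(dmn_rows) == 6
        vm = [c for c in dmn_rows if c.domain == "verbal_memory"][0]
        assert vm.tau > 0

    def test_global_rows_feed_stage1_only(self):
        rng = np.random.default_rng(8)
        summary = self._summaries(rng)
        report = m.run_full_inference(summary, None)
        assert {r.band for r in report.global_tests} == {"theta", "lower_alpha"}
        assert all(r.network != "global" for r in report.network_tests)

    def test_incomplete_cognition_shrinks_stage3_only(self):
        rng = np.random.default_rng(9)
        summary = self._summaries(rng, effect_cell=("theta", "FPN_right"))
        deltas = self._deltas(rng, summary, ("theta", "FPN_right"), slope=10.0,
                              missing=(5, 7))
        report = m.run_full_inference(summary, deltas)
        assert all(r.n == 10 for r in report.network_tests)
        assert all(c.n == 8 for c in report.correlations)

    def test_null_cohort_usually_has_empty_stage3(self):
        rng = np.random.default_rng(10)
        empty = 0
        for _ in range(40):
            summary = self._summaries(rng)
            deltas = self._deltas(rng, summary)
            report = m.run_full_inference(summary, deltas)
            empty += not report.correlations
        assert empty >= 30  # family-wise hit rate is controlled near q
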