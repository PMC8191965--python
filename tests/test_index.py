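"""The dual-cutoff counting core: thresholds, scoring, AF aggregates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wellcount as wc
from conftest import profiles_from_z, random_sufficiency


class TestDomainThreshold:
    @pytest.mark.parametrize(
        "m,expected",
        [(9, 6), (6, 4), (1, 1), (7, 5), (2, 2), (3, 2), (4, 3), (5, 4), (12, 8)],
    )
    def test_two_thirds_ceiling(self, m, expected):
        assert wc.domain_threshold(m) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            wc.domain_threshold(0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(1, 500))
    def test_is_smallest_integer_at_least_two_thirds(self, m):
        t = wc.domain_threshold(m)
        assert t >= 2 * m / 3 and t - 1 < 2 * m / 3


class TestScoreDomain:
    def test_extremes_of_nine_variable_domain(self):
        assert wc.score_domain([1] * 9) == (9, 1)
        assert wc.score_domain([0] * 9) == (0, 0)

    def test_five_of_nine_is_insufficient(self):
        assert wc.score_domain([1, 1, 1, 1, 1, 0, 0, 0, 0]) == (5, 0)

    def test_six_of_nine_is_sufficient(self):
        assert wc.score_domain([1] * 6 + [0] * 3) == (6, 1)

    def test_matrix_form(self):
        raw, suff = wc.score_domain(np.array([[1, 1, 1], [1, 0, 0]]))
        assert raw.tolist() == [3, 1] and suff.tolist() == [1, 0]

    def test_nonbinary_rejected(self):
        with pytest.raises(TypeError):
            wc.score_domain([1, 2, 0])


class TestClassifyOverall:
    def test_boundary_of_four_of_six(self):
        out = wc.classify_overall([1, 1, 1, 1, 0, 0], k=4)
        assert out == {"W": 4, "maintained": 1, "c": 2}

    def test_one_below_cutoff(self):
        out = wc.classify_overall([1, 1, 1, 0, 0, 0], k=4)
        assert out == {"W": 3, "maintained": 0, "c": 3}

    def test_maximal_case(self):
        out = wc.classify_overall([1] * 6, k=4)
        assert out == {"W": 6, "maintained": 1, "c": 0}

    def test_default_cutoff_is_two_thirds_of_domains(self):
        assert wc.classify_overall([1, 1, 1, 1, 0, 0])["maintained"] == 1
        assert wc.classify_overall([1, 1, 0])["maintained"] == 1  # k = ceil(4/3) = 2

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            wc.classify_overall([1, 0], k=3)

    def test_equal_weights_reduce_to_counting(self):
        rng = np.random.default_rng(7)
        z = random_sufficiency(rng, 40, 6)
        plain = wc.classify_overall(z, k=4)
        weighted = wc.classify_overall(z, k=4, weights=[2.0] * 6)
        assert (plain["maintained"].to_numpy() == weighted["maintained"].to_numpy()).all()
        assert np.allclose(plain["W"], weighted["W"])

    def test_weights_are_normalised_to_domain_units(self):
        # doubled weight on an achieved domain counts for more
        out = wc.classify_overall([1, 0, 0], k=2, weights=[4.0, 1.0, 1.0])
        assert out["W"] == pytest.approx(4.0 / 6.0 * 3)
        assert out["maintained"] == 1


class TestSummarize:
    def test_intensity_on_printed_breakdown(self, fixture_z):
        s = wc.summarize(fixture_z)
        assert s.intensity_domains == pytest.approx(606 / 167)
        assert wc.round_half_up(s.intensity_domains, 1) == 3.6

    def test_adjusted_headcount_is_product(self, fixture_z):
        s = wc.summarize(fixture_z)
        assert s.adjusted_headcount == pytest.approx(
            s.headcount_deprived * s.intensity_share
        )
        assert s.adjusted_headcount == pytest.approx(0.173, abs=0.002)
        assert s.adjusted_headcount <= s.headcount_deprived

    def test_degenerate_fully_deprived_population(self):
        z = pd.DataFrame([[0] * 6], columns=list(wc.DOMAINS))
        s = wc.summarize(z)
        assert s.headcount_deprived == 1.0
        assert s.intensity_domains == 6.0
        assert s.intensity_share == 1.0
        assert s.adjusted_headcount == 1.0

    def test_nobody_deprived_reports_absent_intensity(self):
        z = pd.DataFrame(np.ones((5, 6), dtype=int), columns=list(wc.DOMAINS))
        s = wc.summarize(z)
        assert s.n_deprived == 0
        assert s.intensity_domains is None and s.adjusted_headcount is None

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            wc.summarize(pd.DataFrame(columns=list(wc.DOMAINS)))

    def test_conservation(self, fixture_z):
        s = wc.summarize(fixture_z)
        assert s.n_maintained + s.n_deprived == s.n_total

    def test_deprived_count_bound_with_default_cutoffs(self, fixture_z):
        # with k=4 of D=6 every deprived person misses >= 3 domains
        cls = wc.classify_overall(fixture_z, k=4)
        c = cls.loc[cls["maintained"] == 0, "c"]
        assert set(c.unique()) <= {3, 4, 5, 6}
        s = wc.summarize(fixture_z)
        assert 3.0 <= s.intensity_domains <= 6.0


class TestDriverTable:
    def test_hand_counted_shares(self):
        z = pd.DataFrame(
            {"P": [0, 0, 0, 0], "Q": [0, 0, 1, 1], "R": [1, 1, 1, 1]},
        )
        out = wc.driver_table(z, group="deprived", k=3)
        assert out.loc["P", "share_pct"] == 100.0
        assert out.loc["Q", "share_pct"] == 50.0
        assert out.loc["R", "share_pct"] == 0.0
        assert list(out.index) == ["P", "Q", "R"]  # descending dissatisfaction

    def test_single_respondent_three_domains(self):
        z = pd.DataFrame([[0, 0, 0, 1, 1, 1]], columns=list(wc.DOMAINS))
        out = wc.driver_table(z, group="deprived")
        assert (out["share_pct"].iloc[:3] == 100.0).all()
        assert (out["share_pct"].iloc[3:] == 0.0).all()

    def test_all_sufficient_group_has_zero_shares(self):
        z = pd.DataFrame(np.ones((4, 6), dtype=int), columns=list(wc.DOMAINS))
        out = wc.driver_table(z, group="maintained")
        assert (out["share_pct"] == 0.0).all()

    def test_empty_group_rejected(self):
        z = pd.DataFrame(np.ones((4, 6), dtype=int), columns=list(wc.DOMAINS))
        with pytest.raises(ValueError, match="deprived"):
            wc.driver_table(z, group="deprived")

    def test_shares_may_total_more_than_hundred(self, fixture_z):
        out = wc.driver_table(fixture_z, group="deprived")
        assert out["share_pct"].sum() > 100.0  # multiple-response semantics


def brute_force_reference(z: np.ndarray, k: int) -> dict:
    """First-principles re-computation of every aggregate, by loops."""
    n, d = z.shape
    W = [sum(int(v) for v in row) for row in z]
    maintained = [1 if w >= k else 0 for w in W]
    c = [d - w for w in W]
    deprived = [i for i in range(n) if not maintained[i]]
    h = len(deprived) / n
    a_raw = sum(c[i] for i in deprived) / len(deprived) if deprived else None
    m0 = h * a_raw / d if deprived else None
    censored = [
        sum(1 for i in deprived if z[i, j] == 0) / len(deprived) if deprived else 0.0
        for j in range(d)
    ]
    return {"W": W, "maintained": maintained, "c": c, "H": h,
            "A_raw": a_raw, "M0": m0, "censored": censored}


class TestOracleEquivalence:
    def test_counting_core_matches_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(1, 13))
            d = int(rng.integers(2, 5))
            k = int(rng.integers(1, d + 1))
            z = rng.integers(0, 2, size=(n, d))
            zdf = pd.DataFrame(z, columns=[f"D{j}" for j in range(d)])
            ref = brute_force_reference(z, k)
            cls = wc.classify_overall(zdf, k=k)
            assert cls["W"].tolist() == ref["W"]
            assert cls["maintained"].tolist() == ref["maintained"]
            assert cls["c"].tolist() == ref["c"]
            s = wc.summarize(zdf, k=k)
            assert s.headcount_deprived == pytest.approx(ref["H"])
            if ref["A_raw"] is None:
                assert s.intensity_domains is None
            else:
                assert s.intensity_domains == pytest.approx(ref["A_raw"])
                assert s.adjusted_headcount == pytest.approx(ref["M0"])
            for j, name in enumerate(zdf.columns):
                assert s.censored_domain_deprivation[name] == pytest.approx(
                    ref["censored"][j]
                )

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.data())
    def test_monotone_under_indicator_flips(self, data):
        d = data.draw(st.integers(2, 5))
        n = data.draw(st.integers(1, 8))
        rows = data.draw(
            st.lists(
                st.lists(st.integers(0, 1), min_size=d, max_size=d),
                min_size=n, max_size=n,
            )
        )
        z = pd.DataFrame(rows, columns=[f"D{j}" for j in range(d)])
        i = data.draw(st.integers(0, n - 1))
        j = data.draw(st.integers(0, d - 1))
        z2 = z.copy()
        z2.iloc[i, j] = 1  # flip (or keep) one indicator up
        k = data.draw(st.integers(1, d))
        before, after = wc.classify_overall(z, k=k), wc.classify_overall(z2, k=k)
        assert (after["W"] >= before["W"]).all()
        assert (after["maintained"] >= before["maintained"]).all()
        assert (after["c"] <= before["c"]).all()
        sb, sa = wc.summarize(z, k=k), wc.summarize(z2, k=k)
        assert sa.headcount_deprived <= sb.headcount_deprived
        if sa.adjusted_headcount is not None and sb.adjusted_headcount is not None:
            assert sa.adjusted_headcount <= sb.adjusted_headcount + 1e-12
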