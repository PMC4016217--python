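"""Transition scoring, turnover rates, eta-squared, and the binomial GLMM."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from habvalue.occupancy_dynamics import (
    anova_partition,
    correlate_occupancy_cessation,
    eta_squared,
    fit_binary_glmm,
    score_transitions,
    substrate_turnover_rates,
)
from habvalue.survey_data import OccupancySeries, Status

from conftest import series

OCC, UNOCC, UNK = Status.OCCUPIED, Status.UNOCCUPIED, Status.UNKNOWN


class TestScoreTransitions:
    def test_single_cessation(self):
        t = score_transitions([series("A", "thistle", {2005: OCC, 2006: UNOCC})])
        c = t.counts()
        assert c["cessations"] == 1 and c["possible_cessations"] == 1
        assert c["possible_colonizations"] == 0

    def test_unknown_prior_year_blocks_colonization(self):
        t = score_transitions([series("A", "thistle", {2006: UNK, 2007: OCC})])
        assert t.counts()["possible_colonizations"] == 0

    def test_hand_enumerated_five_year_series(self):
        # occ, unocc, unknown, occ, occ: possible cessations at 2006 (event)
        # and 2009 (persistence); no possible colonization (2007 unknown,
        # and 2008's year t-1 is unknown)
        t = score_transitions(
            [series("A", "thistle", {2005: OCC, 2006: UNOCC, 2007: UNK, 2008: OCC, 2009: OCC})]
        )
        c = t.counts()
        assert c["possible_cessations"] == 2
        assert c["cessations"] == 1
        assert c["possible_colonizations"] == 0
        by_year = {(r.year, r.transition) for r in t.rows}
        assert by_year == {(2006, "cessation"), (2009, "persistence")}

    def test_colonization_start_year_gate(self):
        s = [series("A", "thistle", {2005: UNOCC, 2006: OCC})]
        assert score_transitions(s, 2006).counts()["colonizations"] == 1
        assert score_transitions(s, 2007).counts()["possible_colonizations"] == 0

    def test_empty_and_singleton_series(self):
        assert score_transitions([]).rows == []
        assert score_transitions([series("A", "thistle", {2005: OCC})]).rows == []

    @given(
        st.lists(
            st.lists(st.sampled_from([OCC, UNOCC, UNK]), min_size=2, max_size=9),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation_identity(self, runs):
        """events + non-events = possible events, overall and per substrate."""
        subs = ["cattail-marsh", "grain-field", "nettle"]
        sset = [
            series(f"S{i}", subs[i % 3], {2004 + j: v for j, v in enumerate(r)})
            for i, r in enumerate(runs)
        ]
        t = score_transitions(sset, colonization_start_year=2005)
        for sub in [None] + subs:
            rows = t.rows if sub is None else [r for r in t.rows if r.substrate == sub]
            ces = sum(r.transition == "cessation" for r in rows)
            per = sum(r.transition == "persistence" for r in rows)
            col = sum(r.transition == "colonization" for r in rows)
            non = sum(r.transition == "non-colonization" for r in rows)
            assert ces + per == sum(r.possible_cessation for r in rows)
            assert col + non == sum(r.possible_colonization for r in rows)
            # never both kinds of denominator for one row
            assert not any(r.possible_cessation and r.possible_colonization for r in rows)

    @given(
        st.lists(st.sampled_from([OCC, UNOCC]), min_size=3, max_size=9),
        st.integers(min_value=1, max_value=7),
    )
    @settings(max_examples=40, deadline=None)
    def test_unknowns_never_increase_denominators(self, run, pos):
        pos = min(pos, len(run) - 2)
        statuses = {2004 + j: v for j, v in enumerate(run)}
        degraded = dict(statuses)
        degraded[2004 + pos] = UNK
        base = score_transitions([series("A", "thistle", statuses)], 2005).counts()
        less = score_transitions([series("A", "thistle", degraded)], 2005).counts()
        assert less["possible_cessations"] <= base["possible_cessations"]
        assert less["possible_colonizations"] <= base["possible_colonizations"]


class TestTurnoverRates:
    def _ten_site_years(self):
        # 7 occupied of 10 surveyed site-years in one substrate
        return [
            series(f"S{i}", "thistle", {2005: OCC if i < 7 else UNOCC, 2006: UNK})
            for i in range(10)
        ]

    def test_occupancy_point_and_exact_ci(self):
        sset = self._ten_site_years()
        out = substrate_turnover_rates(score_transitions(sset), sset)
        r = out[0]
        assert r.occupancy_mean == pytest.approx(0.7)
        # independent oracle: Clopper-Pearson from the exact binomial test
        lo, hi = stats.binomtest(7, 10).proportion_ci(confidence_level=0.95, method="exact")
        assert r.occupancy_ci == pytest.approx((lo, hi), abs=1e-12)

    def test_zero_events_boundary(self):
        sset = [
            series(f"S{i}", "nettle", {2005: OCC, 2006: OCC}) for i in range(5)
        ]
        out = substrate_turnover_rates(score_transitions(sset), sset)
        r = out[0]
        assert r.cessation_rate == 0.0
        assert r.cessation_ci[0] == 0.0

    def test_min_records_filter_omits_rate_not_substrate(self):
        sset = [series("S0", "willow", {2005: OCC, 2006: UNOCC})]
        out = substrate_turnover_rates(score_transitions(sset), sset, min_records=5)
        r = out[0]
        assert r.substrate == "willow"
        assert r.cessation_rate is None  # only 1 possible event
        assert r.occupancy_mean is None  # only 2 surveyed site-years


class TestEtaSquared:
    @pytest.mark.parametrize(
        "ss_e,ss_err,expected",
        [(8.52, 109.55, 0.07), (2.93, 23.07, 0.11)],
    )
    def test_published_table_values(self, ss_e, ss_err, expected):
        assert round(eta_squared(ss_e, ss_err), 2) == expected

    def test_boundaries(self):
        assert eta_squared(0, 5) == 0.0
        assert eta_squared(5, 0) == 1.0
        with pytest.raises(ValueError):
            eta_squared(0, 0)

    @given(st.floats(min_value=0.01, max_value=100), st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_effect_ss(self, ss_e, ss_err):
        assert eta_squared(ss_e + 1.0, ss_err) > eta_squared(ss_e, ss_err)


class TestAnovaPartition:
    def test_zero_residual_gives_eta_one(self):
        df = pd.DataFrame(
            {"y": [0.0] * 10 + [1.0] * 10, "g": ["a"] * 10 + ["b"] * 10}
        )
        aov = anova_partition(df, "y", ["g"]).table
        assert aov.loc["g", "eta_sq"] == pytest.approx(1.0)
        assert aov.loc["Error", "SS"] == pytest.approx(0.0, abs=1e-20)

    def test_partition_matches_formula(self, sim_small):
        _, survey, _ = sim_small
        df = pd.DataFrame(
            {
                "occ": [1.0 if r.status is OCC else 0.0 for r in survey],
                "substrate": [r.substrate for r in survey],
                "year": [r.year for r in survey],
            }
        )
        aov = anova_partition(df, "occ", ["substrate", "year"]).table
        ss_err = aov.loc["Error", "SS"]
        for effect in ("substrate", "year"):
            ss = aov.loc[effect, "SS"]
            assert aov.loc[effect, "eta_sq"] == pytest.approx(ss / (ss + ss_err))
        # total SS is conserved by the sequential partition
        total = ((df["occ"] - df["occ"].mean()) ** 2).sum()
        assert aov["SS"].sum() == pytest.approx(total, rel=1e-10)


class TestBinaryMixedLogit:
    def test_recovers_group_logits_on_balanced_data(self):
        rng = np.random.default_rng(4)
        n = 500
        rows = []
        for sub, p in (("cattail-marsh", 0.5), ("nettle", 0.8)):
            y = rng.random(n) < p
            for i, v in enumerate(y):
                rows.append({"occ": float(v), "substrate": sub, "year": 2005 + i % 5})
        res = fit_binary_glmm(
            pd.DataFrame(rows), "occ", ["substrate"], group="year",
            reference={"substrate": "cattail-marsh"},
        )
        tab = res.fe_table().set_index("term")
        icept = tab.loc["Intercept"]
        diff = tab.loc["substrate[nettle]"]
        assert abs(icept["estimate"] - 0.0) < 2 * icept["se"]
        assert abs(diff["estimate"] - (np.log(4) - 0.0)) < 2 * diff["se"]

    def test_single_substrate_reduces_to_pooled_logit(self):
        rng = np.random.default_rng(5)
        y = (rng.random(400) < 0.3).astype(float)
        df = pd.DataFrame({"occ": y, "substrate": "thistle", "year": 2005})
        res = fit_binary_glmm(df, "occ", ["substrate", "year"], group="year")
        pooled = y.mean()
        assert res.params[0] == pytest.approx(np.log(pooled / (1 - pooled)), abs=0.05)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame(
            {
                "occ": [1.0] * 20 + [0.0] * 10 + [1.0] * 10,
                "substrate": ["mustard"] * 20 + ["cattail-marsh"] * 20,
                "year": ([2005, 2006] * 20),
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            res = fit_binary_glmm(
                df, "occ", ["substrate"], group="year",
                reference={"substrate": "cattail-marsh"},
            )
        assert "substrate[mustard]" in res.separation_flags

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: adaptive-quadrature glmer on the same data."""
        rng = np.random.default_rng(42)
        rows = []
        for g in range(8):
            u = rng.normal(0, 0.7)
            for _ in range(40):
                sub = rng.choice(["a", "b"])
                eta = 0.3 + (0.9 if sub == "b" else 0.0) + u
                rows.append(
                    {"y": float(rng.random() < 1 / (1 + np.exp(-eta))), "sub": sub, "g": g}
                )
        df = pd.DataFrame(rows)
        res = fit_binary_glmm(df, "y", ["sub"], group="g", reference={"sub": "a"})
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ sub + (1|g), data=d, family=binomial, nAGQ=30)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        icept_r, slope_r, sd_r, ll_r = map(float, proc.stdout.split())
        assert res.params[0] == pytest.approx(icept_r, abs=0.01)
        assert res.params[1] == pytest.approx(slope_r, abs=0.01)
        assert res.random_sd == pytest.approx(sd_r, abs=0.02)
        assert res.llf == pytest.approx(ll_r, abs=0.02)


class TestCorrelation:
    @staticmethod
    def _summaries(points):
        from habvalue.occupancy_dynamics import SubstrateTurnover

        return [
            SubstrateTurnover(substrate=f"s{i}", occupancy_mean=o, cessation_rate=c)
            for i, (o, c) in enumerate(points)
        ]

    def test_perfect_negative_line(self):
        r, p = correlate_occupancy_cessation(
            self._summaries([(0.1, 0.9), (0.5, 0.5), (0.9, 0.1)])
        )
        assert r == pytest.approx(-1.0)
        assert p < 0.05

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(8)
        occ = rng.uniform(0.1, 0.9, 6)
        cess = rng.uniform(0.1, 0.9, 6)
        r, _ = correlate_occupancy_cessation(self._summaries(zip(occ, cess)))
        num = np.sum((occ - occ.mean()) * (cess - cess.mean()))
        den = np.sqrt(np.sum((occ - occ.mean()) ** 2) * np.sum((cess - cess.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            correlate_occupancy_cessation(self._summaries([(0.1, 0.9), (0.5, 0.5)]))


class TestParameterRecovery:
    def test_turnover_rates_unbiased_with_ci_coverage(self):
        """Estimated cessation/colonization rates recover the generating
        Markov-chain probabilities, and the exact binomial CIs cover the
        truth, on fully monitored 200-site x 7-year simulations."""
        from habvalue.survey_data import build_occupancy_series
        from habvalue.synthetic_data import (
            SimulationConfig,
            SubstrateParams,
            simulate_metapopulation,
            stationary_occupancy,
        )

        e_true, c_true = 0.66, 0.21
        params = SubstrateParams(
            cessation=e_true, colonization=c_true,
            initial_occupancy=stationary_occupancy(c_true, e_true),
            size_log_mean=5.0, size_log_sd=1.0,
            nest_failure=0.4, rss_mean=2.2, rss_sd=0.5,
        )
        e_hats, c_hats, e_cover, c_cover = [], [], 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                substrates={"thistle": params}, n_sites=200, years=(2005, 2011),
                monitoring_prob=1.0, n_nests_sampled=1, seed=seed,
            )
            _, survey, _ = simulate_metapopulation(cfg)
            sset = build_occupancy_series(survey)
            rates = substrate_turnover_rates(
                score_transitions(sset, colonization_start_year=2006), sset
            )[0]
            e_hats.append(rates.cessation_rate)
            c_hats.append(rates.colonization_rate)
            e_cover += rates.cessation_ci[0] <= e_true <= rates.cessation_ci[1]
            c_cover += rates.colonization_ci[0] <= c_true <= rates.colonization_ci[1]
        assert np.mean(e_hats) == pytest.approx(e_true, abs=0.03)
        assert np.mean(c_hats) == pytest.approx(c_true, abs=0.03)
        assert e_cover / n_seeds >= 0.9
        assert c_cover / n_seeds >= 0.9
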