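import numpy as np
import pandas as pd
import pytest

from screenmine import ranking as rk


class TestInhibitionProbability:
    def test_worked_examples(self):
        """The published-coefficient probabilities for the three scenario
        variants (inactive/active, dG -6/-7) land within coefficient-
        rounding distance of the printed percentages."""
        assert 100 * rk.inhibition_probability(0, 7.0, -6.0) == pytest.approx(55.26, abs=0.15)
        assert 100 * rk.inhibition_probability(1, 7.0, -6.0) == pytest.approx(94.96, abs=0.15)
        assert 100 * rk.inhibition_probability(1, 7.0, -7.0) == pytest.approx(96.58, abs=0.15)

    # (class, pIC50pred, dG, printed P) for the ten ranked candidates
    TABLE_ROWS = [
        ("laropiprant", 1, 9.38, -7.3, 1.00000),
        ("tafamidis", 1, 9.01, -6.8, 0.99999),
        ("desvenlafaxine", 1, 8.17, -7.9, 0.99976),
        ("paliperidone", 1, 7.39, -9.0, 0.99661),
        ("febuxostat", 1, 7.28, -6.4, 0.98517),
        ("flufenamic_acid", 1, 7.13, -7.1, 0.98032),
        ("norgestimate", 0, 7.76, -6.9, 0.97359),
        ("flibanserin", 0, 7.59, -8.3, 0.96989),
        ("tiaprofenic_acid", 0, 7.65, -6.3, 0.94887),
        ("penbutolol", 1, 7.00, -5.7, 0.94310),
    ]

    @pytest.mark.parametrize("name,cls,pic50,dg,printed", TABLE_ROWS)
    def test_published_ranking_roundtrip(self, name, cls, pic50, dg, printed):
        # the printed pIC50 (2 dp) and dG (1 dp) inputs are themselves
        # rounded; that propagates up to ~1e-3 through the logistic
        assert rk.inhibition_probability(cls, pic50, dg) == pytest.approx(printed, abs=1e-3)

    def test_probability_ordering_matches_printed(self):
        probs = [rk.inhibition_probability(c, p, g) for _, c, p, g, _ in self.TABLE_ROWS]
        assert probs == sorted(probs, reverse=True)

    def test_near_zero_limit(self):
        assert rk.inhibition_probability(0, 0.0, 0.0) == pytest.approx(9.5e-14, rel=0.05)

    def test_monotonicity(self):
        base = rk.inhibition_probability(0, 7.0, -6.0)
        assert rk.inhibition_probability(1, 7.0, -6.0) > base
        assert rk.inhibition_probability(0, 7.1, -6.0) > base
        assert rk.inhibition_probability(0, 7.0, -6.1) > base  # more negative dG

    def test_packaged_model_file(self):
        m = rk.LogisticModel.load()
        assert (m.b_class, m.b_pic50, m.b_dg, m.intercept) == (2.725, 3.967, -0.404, -29.986)


class TestFitLogistic:
    def test_recovers_published_coefficients(self):
        """Draws from the published model are refit to within 10%."""
        rng = np.random.default_rng(2)
        n = 1000
        # D-optimal-style design: spread the covariates wide while
        # steering the linear predictor to +-1.543 (where a Bernoulli
        # observation is most informative about logistic coefficients);
        # a sample with all probabilities near 1 identifies nothing
        cls = rng.integers(0, 2, n)
        dg = rng.choice([-16.0, -1.0], n)
        target_z = rng.choice([-1.5434, 1.5434], n)
        m0 = rk.TRPA1_LOGIT
        pic50 = (target_z - m0.b_class * cls - m0.b_dg * dg - m0.intercept) / m0.b_pic50
        y = rng.random(n) < 1 / (1 + np.exp(-target_z))
        model = rk.fit_logistic(cls, pic50, dg, y.astype(int))
        for got, true in [
            (model.b_class, 2.725),
            (model.b_pic50, 3.967),
            (model.b_dg, -0.404),
            (model.intercept, -29.986),
        ]:
            assert abs(got - true) / abs(true) <= 0.10

    def test_independent_labels_give_null_model(self):
        rng = np.random.default_rng(5)
        n = 800
        cls = rng.integers(0, 2, n)
        pic50 = rng.normal(7, 1, n)
        dg = rng.normal(-7, 1, n)
        y = rng.integers(0, 2, n)
        model = rk.fit_logistic(cls, pic50, dg, y)
        assert abs(model.b_pic50) < 0.2 and abs(model.b_dg) < 0.2

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            rk.fit_logistic([0, 1], [7, 8], [-6, -7], [1, 1])

    def test_perfect_separation_flagged(self):
        cls = [0] * 20 + [1] * 20
        pic50 = [5.0] * 20 + [9.0] * 20
        dg = [-6.0] * 40
        y = [0] * 20 + [1] * 20
        model = rk.fit_logistic(cls, pic50, dg, y)
        assert model.separable
        assert abs(model.b_pic50) <= 50.0


class TestBBBFilter:
    def test_boundary_pass(self):
        ok, fails = rk.bbb_filter(499.9, 2.0, 89.9, 3, 7)
        assert ok and fails == []

    @pytest.mark.parametrize(
        "args,expected",
        [
            ((500.0, 3.0, 50, 1, 2), ["MW"]),
            ((400, 1.9, 50, 1, 2), ["AlogP"]),
            ((400, 5.1, 50, 1, 2), ["AlogP"]),
            ((400, 3.0, 90.0, 1, 2), ["PSA"]),
            ((400, 3.0, 50, 4, 2), ["HBD"]),
            ((400, 3.0, 50, 1, 8), ["HBA"]),
        ],
    )
    def test_single_rule_failures(self, args, expected):
        ok, fails = rk.bbb_filter(*args)
        assert not ok and fails == expected

    def test_monotone_per_rule(self):
        ok, _ = rk.bbb_filter(400, 3.0, 50, 1, 2)
        assert ok
        # worsening any one property can only fail, never the reverse
        assert not rk.bbb_filter(600, 3.0, 50, 1, 2)[0]
        assert not rk.bbb_filter(400, 3.0, 120, 1, 2)[0]


class TestRankCandidates:
    def frame(self):
        return pd.DataFrame(
            {
                "activity_class": [1, 0, 1],
                "pic50_pred": [8.0, 7.0, 6.0],
                "dg": [-8.0, -6.0, -7.0],
                "MW": [300.0, 600.0, 400.0],
                "ALogP": [3.0, 3.0, 1.0],
                "TPSA": [50.0, 50.0, 50.0],
                "nHBDon": [1, 1, 1],
                "nHBAcc": [3, 3, 3],
            },
            index=pd.Index(["a", "b", "c"], name="id"),
        )

    def test_sorted_and_reported(self):
        ranked, report = rk.rank_candidates(self.frame(), bbb_rules=rk.BBBRules())
        assert list(ranked.index) == ["a", "b", "c"]
        assert ranked["probability"].is_monotonic_decreasing
        assert report["n_ranked"] == 3
        brute = (ranked["probability"] > 0.5).sum()
        assert report["P>0.5"] == brute
        assert report["P>0.5_bbb"] == ((ranked["probability"] > 0.5) & ranked["bbb_pass"]).sum()

    def test_bbb_flags(self):
        ranked, _ = rk.rank_candidates(self.frame(), bbb_rules=rk.BBBRules())
        assert bool(ranked.loc["a", "bbb_pass"])
        assert ranked.loc["b", "bbb_failures"] == "MW"
        assert ranked.loc["c", "bbb_failures"] == "AlogP"

    def test_missing_dg_excluded(self, caplog):
        df = self.frame()
        df.loc["b", "dg"] = np.nan
        with caplog.at_level("WARNING"):
            ranked, report = rk.rank_candidates(df, bbb_rules=None)
        assert "b" not in ranked.index and report["n_ranked"] == 2
        assert any("missing dg" in r.message for r in caplog.records)

    def test_tie_break_by_id(self):
        df = self.frame()
        df["activity_class"] = 1
        df["pic50_pred"] = 7.0
        df["dg"] = -7.0
        ranked, _ = rk.rank_candidates(df, bbb_rules=None)
        assert list(ranked.index) == ["a", "b", "c"]
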