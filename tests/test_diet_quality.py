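import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietprint import (
    ahei2010_score,
    assign_quintiles,
    hei2015_score,
    population_ratio_mean,
    score_component,
)
from dietprint.diet_quality import (
    ScoringStandard,
    amount_on_basis,
    weighted_quantile,
)
from dietprint.errors import ConfigurationError, EstimationError, ScoringError
from tests.conftest import floor_record, max_compliance_record

ADEQ = ScoringStandard(
    component="adeq", index="x", amount_column="a", direction="adequacy",
    max_points=10.0, zero_score=0.0, full_score=2.0, basis="per_day",
)
MODER = ScoringStandard(
    component="mod", index="x", amount_column="a", direction="moderation",
    max_points=10.0, zero_score=4.3, full_score=1.8, basis="per_day",
)


class TestScoreComponent:
    @pytest.mark.parametrize(
        "std,amount,expected",
        [
            (ADEQ, 2.0, 10.0),   # at the full-score threshold
            (ADEQ, 0.0, 0.0),    # at the zero-score threshold
            (ADEQ, 1.0, 5.0),    # midway -> half the points
            (ADEQ, 5.0, 10.0),   # clamped above
            (MODER, 1.8, 10.0),  # moderation: low intake earns full credit
            (MODER, 4.3, 0.0),
            (MODER, 3.05, 5.0),  # midway
            (MODER, 9.9, 0.0),
        ],
    )
    def test_piecewise_linear(self, std, amount, expected):
        assert score_component(amount, std) == pytest.approx(expected)

    def test_negative_amount_rejected(self):
        with pytest.raises(ScoringError):
            score_component(-1.0, ADEQ)

    def test_malformed_standard_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoringStandard(
                component="bad", index="x", amount_column="a", direction="adequacy",
                max_points=5.0, zero_score=2.0, full_score=1.0, basis="per_day",
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0, 20), b=st.floats(0, 20))
    def test_adequacy_monotone_moderation_antitone(self, a, b):
        lo, hi = sorted((a, b))
        assert score_component(lo, ADEQ) <= score_component(hi, ADEQ)
        assert score_component(lo, MODER) >= score_component(hi, MODER)


class TestHEI2015:
    def test_full_compliance_scores_100(self):
        assert hei2015_score(max_compliance_record())["total"] == pytest.approx(100.0)

    def test_floor_diet_scores_0(self):
        assert hei2015_score(floor_record())["total"] == pytest.approx(0.0)

    def test_mixed_record_matches_hand_evaluation(self):
        # densities chosen so each component is hand-evaluable:
        # fruits 0.4/0.8*5=2.5, whole fruit 1.25, veg 2.5, greens 0,
        # whole grains 5, dairy 10, protein 5, seafood/plant 2.5,
        # ratio 2.0 -> (2.0-1.2)/1.3*10, refined 5, sodium 5, sugar 5, satfat 5
        energy = 2000.0
        rec = pd.Series(
            {
                "energy_kcal": energy,
                "fruit_total_cup": 0.8, "fruit_whole_cup": 0.2,
                "veg_total_cup": 1.1, "greens_beans_cup": 0.0,
                "whole_grains_oz": 1.5, "dairy_cup": 2.6,
                "protein_total_oz": 5.0, "protein_seafood_plant_oz": 0.8,
                "sat_fat_g": 0.12 * energy / 9.0,
                "unsat_fat_g": 2.0 * 0.12 * energy / 9.0,
                "refined_grains_oz": 6.1, "sodium_g": 3.1,
                "added_sugar_g": 0.1625 * energy / 4.0,
            }
        )
        expected = (
            2.5 + 1.25 + 2.5 + 0.0 + 5.0 + 10.0 + 5.0 + 2.5
            + (2.0 - 1.2) / 1.3 * 10.0 + 5.0 + 5.0 + 5.0 + 5.0
        )
        got = hei2015_score(rec)
        assert got["total"] == pytest.approx(expected, abs=1e-9)
        assert got["total"] == pytest.approx(sum(
            v for k, v in got.items() if k != "total"
        ), abs=1e-9)

    def test_component_bounds(self, records):
        from dietprint import score_individuals

        sc = score_individuals(records.head(40), "hei2015")
        comp = sc.drop(columns=["total"])
        assert (comp.to_numpy() >= -1e-12).all()
        assert ((sc["total"] >= 0) & (sc["total"] <= 100)).all()

    def test_zero_energy_rejected(self):
        rec = max_compliance_record().copy()
        rec["energy_kcal"] = 0.0
        with pytest.raises(ScoringError):
            hei2015_score(rec)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(0.2, 5.0))
    def test_energy_scaling_invariance(self, k):
        """Scaling all intakes AND energy by k leaves the score unchanged."""
        rec = max_compliance_record().copy()
        rng = np.random.default_rng(3)
        for col in rec.index:
            if col in {"person_id", "age", "sex"}:
                continue
            rec[col] = float(rec[col]) * rng.uniform(0.3, 1.0)
        scaled = rec.copy()
        for col in rec.index:
            if col in {"person_id", "age", "sex"}:
                continue
            scaled[col] = float(rec[col]) * k
        assert hei2015_score(scaled)["total"] == pytest.approx(
            hei2015_score(rec)["total"], rel=1e-9
        )


class TestAHEI2010:
    def test_full_compliance_scores_100(self):
        assert ahei2010_score(max_compliance_record())["total"] == pytest.approx(100.0)

    def test_floor_diet_scores_0(self):
        assert ahei2010_score(floor_record())["total"] == pytest.approx(0.0)

    def test_child_zero_alcohol_gets_10(self):
        rec = max_compliance_record().copy()
        rec["age"], rec["alcohol_drinks"] = 10.0, 0.0
        assert ahei2010_score(rec, modified=True)["alcohol"] == pytest.approx(10.0)

    def test_child_any_alcohol_gets_0(self):
        rec = max_compliance_record().copy()
        rec["age"], rec["alcohol_drinks"] = 10.0, 0.2
        assert ahei2010_score(rec, modified=True)["alcohol"] == pytest.approx(0.0)

    def test_unmodified_applies_adult_band_to_children(self):
        rec = max_compliance_record().copy()
        rec["age"], rec["alcohol_drinks"] = 10.0, 1.0
        assert ahei2010_score(rec, modified=False)["alcohol"] == pytest.approx(10.0)

    def test_adult_abstainer_partial_credit(self):
        rec = max_compliance_record().copy()
        rec["alcohol_drinks"] = 0.0
        assert ahei2010_score(rec)["alcohol"] == pytest.approx(2.5)

    def test_heavy_drinking_scores_0(self):
        rec = max_compliance_record().copy()
        rec["energy_kcal"] = 1849.0
        rec["alcohol_drinks"] = 3.0
        assert ahei2010_score(rec)["alcohol"] == pytest.approx(0.0)

    def test_reference_energy_makes_modified_equal_unmodified(self):
        rec = max_compliance_record().copy()
        rec["energy_kcal"] = 1849.0
        mod = ahei2010_score(rec, modified=True)
        orig = ahei2010_score(rec, modified=False)
        for comp in mod:
            if comp not in {"alcohol", "total"}:
                assert mod[comp] == pytest.approx(orig[comp])

    def test_basis_rescaling_halves_at_double_energy(self):
        std = ScoringStandard(
            component="c", index="ahei2010", amount_column="a",
            direction="adequacy", max_points=10, zero_score=0, full_score=80,
            basis="per_day",
        )
        got = amount_on_basis({"a": 100.0}, std, energy=3698.0, rescale_to=1849.0)
        assert got == pytest.approx(50.0)


class TestPopulationRatio:
    def _two_records(self):
        base = floor_record()
        a, b = base.copy(), base.copy()
        a["person_id"], b["person_id"] = "A", "B"
        a["energy_kcal"] = b["energy_kcal"] = 1000.0
        a["fruit_total_cup"], b["fruit_total_cup"] = 2.0, 0.0
        return pd.DataFrame([a, b])

    def test_homogeneous_population_equals_individual(self, records):
        rec = records.iloc[[0]].copy()
        both = pd.concat([rec, rec.assign(person_id="P_copy")], ignore_index=True)
        pop = population_ratio_mean(both, np.ones(2), "hei2015")
        ind = hei2015_score(rec.iloc[0])
        assert pop["total"] == pytest.approx(ind["total"], abs=1e-9)

    def test_score_of_means_not_mean_of_scores(self):
        df = self._two_records()
        pop = population_ratio_mean(df, np.ones(2), "hei2015")
        # pooled fruit density (2.0+0)/2 = 1.0 >= 0.8 -> full 5 points,
        # while the mean of individual scores is (5 + 0)/2 = 2.5
        assert pop["total_fruits"] == pytest.approx(5.0)
        ind = [hei2015_score(r)["total_fruits"] for _, r in df.iterrows()]
        assert np.mean(ind) == pytest.approx(2.5)

    def test_weight_doubling_invariance(self):
        df = self._two_records()
        p1 = population_ratio_mean(df, np.array([1.0, 3.0]), "hei2015")
        p2 = population_ratio_mean(df, np.array([2.0, 6.0]), "hei2015")
        assert p1["total"] == pytest.approx(p2["total"], rel=1e-12)

    def test_nonpositive_weights_rejected(self):
        df = self._two_records()
        with pytest.raises(EstimationError):
            population_ratio_mean(df, np.array([1.0, 0.0]), "hei2015")


class TestQuintiles:
    def test_five_distinct_scores_in_order(self):
        q, _ = assign_quintiles(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
        assert list(q) == [1, 2, 3, 4, 5]

    def test_all_ties_collapse_to_q1_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            q, _ = assign_quintiles(np.full(6, 42.0))
        assert (q == 1).all()

    def test_too_few_individuals(self):
        with pytest.raises(EstimationError):
            assign_quintiles(np.array([1.0, 2.0]))

    def test_weighted_shares_near_20pct(self):
        rng = np.random.default_rng(11)
        s = rng.normal(50, 10, 400)
        w = rng.lognormal(0, 1, 400)
        q, cuts = assign_quintiles(s, w)
        shares = np.array([w[q == k].sum() for k in range(1, 6)]) / w.sum()
        assert np.abs(shares - 0.2).max() < 0.05
        # cutpoints agree with brute-force weighted ECDF inversion
        order = np.argsort(s)
        cdf = np.cumsum(w[order]) / w.sum()
        for p, c in zip([0.2, 0.4, 0.6, 0.8], cuts):
            brute = s[order][np.searchsorted(cdf, p, side="left")]
            assert c == pytest.approx(brute, abs=1e-12)

    def test_labels_nondecreasing_in_score(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 100, 60)
        q, _ = assign_quintiles(s, rng.lognormal(0, 0.8, 60))
        order = np.argsort(s)
        assert (np.diff(q[order]) >= 0).all()


def test_weighted_quantile_rejects_bad_weights():
    with pytest.raises(EstimationError):
        weighted_quantile([1.0, 2.0], [1.0, -1.0], [0.5])
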