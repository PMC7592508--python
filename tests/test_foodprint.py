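import numpy as np
import pandas as pd
import pytest

from dietprint import (
    AgronomicParameters,
    attribute_to_loss_categories,
    crops_to_land,
    demand_to_primary_crops,
    footprint_from_demand,
    land_to_resources,
    monte_carlo_footprint,
    reapportion_imports,
)
from dietprint.errors import ConfigurationError, EstimationError, ModelError
from dietprint.foodprint import check_land_availability


def _toy_params(
    conversions=None, allocations=None, yields=None, double_crop=None
) -> AgronomicParameters:
    """Three plant commodities (A,B share crop1; C on crop2) + one dairy."""
    conversions = conversions or {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}
    allocations = allocations or {"A": 0.7, "B": 0.3, "C": 1.0}
    yields = yields or {"crop1": 2000.0, "crop2": 4000.0, "hay": 8000.0}
    double_crop = double_crop or {"crop1": 1.0, "crop2": 1.0, "hay": 1.0}
    ct = pd.DataFrame(
        {
            "commodity_id": ["A", "B", "C", "D"],
            "food_group": ["fruits", "fruits", "vegetables", "dairy"],
            "kind": ["plant", "plant", "plant", "animal"],
            "target_id": ["crop1", "crop1", "crop2", "milk"],
            "conversion": [conversions[k] for k in "ABCD"],
            "allocation_fraction": [allocations["A"], allocations["B"], allocations["C"], 1.0],
            "domestic": [True, True, True, True],
        }
    )
    feed = pd.DataFrame(
        {
            "product_id": ["milk"],
            "crop_id": ["hay"],
            "kg_per_kg": [1.2],
            "allocation_fraction": [1.0],
        }
    )
    crops = pd.DataFrame(
        {
            "crop_id": ["crop1", "crop2", "hay"],
            "land_use_category": ["fruits", "vegetables", "hay"],
            "yield_kg_per_ha": [yields[c] for c in ("crop1", "crop2", "hay")],
            "double_crop_factor": [double_crop[c] for c in ("crop1", "crop2", "hay")],
            "utilization": [1.0, 1.0, 1.0],
        }
    )
    rates = pd.DataFrame(
        {
            "land_use_category": ["fruits", "vegetables", "hay"],
            "n_kg_ha": [100.0, 50.0, 10.0],
            "p2o5_kg_ha": [0.0, 25.0, 0.0],
            "k2o_kg_ha": [0.0, 25.0, 0.0],
            "pesticide_kg_ha": [10.0, 5.0, 0.5],
            "irrigation_m3_ha": [1000.0, 500.0, 0.0],
        }
    )
    return AgronomicParameters(ct, feed, crops, rates)


def _demand(**kg):
    return pd.DataFrame({"commodity_id": list(kg), "kg": list(kg.values())})


class TestReapportionImports:
    def _table(self, flags):
        return pd.DataFrame(
            {
                "commodity_id": list(flags),
                "food_group": ["g"] * len(flags),
                "kind": ["plant"] * len(flags),
                "target_id": ["crop"] * len(flags),
                "conversion": [1.0] * len(flags),
                "allocation_fraction": [1.0 / len(flags)] * len(flags),
                "domestic": list(flags.values()),
            }
        )

    def test_no_flags_identity(self):
        ct = self._table({"A": True, "B": True})
        out = reapportion_imports(_demand(A=10.0, B=5.0), ct)
        assert out.set_index("commodity_id")["kg"].to_dict() == {"A": 10.0, "B": 5.0}

    def test_proportional_split(self):
        # A flagged with 50 kg -> redistributed 30:20 to B and C
        ct = self._table({"A": False, "B": True, "C": True})
        out = reapportion_imports(_demand(A=50.0, B=30.0, C=20.0), ct)
        got = out.set_index("commodity_id")["kg"]
        assert got["A"] == 0.0
        assert got["B"] == pytest.approx(60.0)
        assert got["C"] == pytest.approx(40.0)
        assert got.sum() == pytest.approx(100.0)

    def test_zero_mass_flagged_item_no_change(self):
        ct = self._table({"A": False, "B": True})
        out = reapportion_imports(_demand(A=0.0, B=30.0), ct)
        assert out.set_index("commodity_id")["kg"]["B"] == pytest.approx(30.0)

    def test_fully_nondomestic_group_rejected(self):
        ct = self._table({"A": False, "B": False})
        with pytest.raises(ModelError):
            reapportion_imports(_demand(A=1.0, B=1.0), ct)


class TestDemandToPrimaryCrops:
    def test_identity_chain(self):
        params = _toy_params(allocations={"A": 1.0, "B": 1.0, "C": 1.0})
        params.commodity_table = params.commodity_table[
            params.commodity_table["commodity_id"].isin(["C"])
        ]
        req, _ = demand_to_primary_crops(_demand(C=100.0), params)
        assert req["crop2"] == pytest.approx(100.0)

    def test_livestock_feed_coefficient(self):
        params = _toy_params()
        req, _ = demand_to_primary_crops(_demand(D=100.0), params)
        assert req["hay"] == pytest.approx(120.0)  # 100 kg milk * 1.2 kg/kg

    def test_allocation_ledger_expansion(self):
        # oracle: explicit ledger sum; A and B share crop1 at 0.7/0.3
        params = _toy_params()
        req, ledger = demand_to_primary_crops(_demand(A=70.0, B=30.0), params)
        rows = ledger.set_index("user")
        assert rows.loc["A", "gross_draw_kg"] == pytest.approx(70.0 / 0.7)
        assert rows.loc["B", "gross_draw_kg"] == pytest.approx(30.0 / 0.3)
        brute = 70.0 / 0.7 * 0.7 + 30.0 / 0.3 * 0.3
        assert req["crop1"] == pytest.approx(brute, rel=1e-12)

    def test_allocation_conserves_demanded_mass(self):
        params = _toy_params()
        demand = _demand(A=12.0, B=34.0, C=56.0)
        req, ledger = demand_to_primary_crops(demand, params)
        assert ledger["allocated_kg"].sum() == pytest.approx(
            demand["kg"].sum(), rel=1e-9  # conversions are 1 here
        )

    def test_missing_conversion_rejected(self):
        with pytest.raises(ConfigurationError):
            demand_to_primary_crops(_demand(UNKNOWN=1.0), _toy_params())

    def test_bad_allocation_sums_rejected(self):
        params = _toy_params(allocations={"A": 0.7, "B": 0.7, "C": 1.0})
        with pytest.raises(ConfigurationError):
            demand_to_primary_crops(_demand(A=1.0), params)


class TestCropsToLand:
    def test_yield_division(self):
        land = crops_to_land(pd.Series({"crop1": 2000.0}), _toy_params())
        assert land["fruits"] == pytest.approx(1.0)

    def test_double_crop_halves_land(self):
        p1 = _toy_params()
        p2 = _toy_params(double_crop={"crop1": 2.0, "crop2": 1.0, "hay": 1.0})
        req = pd.Series({"crop1": 2000.0})
        assert crops_to_land(req, p2)["fruits"] == pytest.approx(
            crops_to_land(req, p1)["fruits"] / 2.0
        )

    def test_three_crop_hand_table(self):
        req = pd.Series({"crop1": 2000.0, "crop2": 8000.0, "hay": 4000.0})
        land = crops_to_land(req, _toy_params())
        # by hand: 2000/2000 = 1 ha; 8000/4000 = 2 ha; 4000/8000 = 0.5 ha
        assert land["fruits"] == pytest.approx(1.0)
        assert land["vegetables"] == pytest.approx(2.0)
        assert land["hay"] == pytest.approx(0.5)

    def test_unknown_crop_rejected(self):
        with pytest.raises(ConfigurationError):
            crops_to_land(pd.Series({"nope": 1.0}), _toy_params())


class TestLandToResources:
    def test_single_category_rate(self):
        land = pd.Series({"fruits": 1.0, "vegetables": 0.0, "hay": 0.0})
        fp = land_to_resources(land, _toy_params())
        assert fp.totals["fertilizer_kg"] == pytest.approx(100.0)
        assert fp.totals["pesticide_kg"] == pytest.approx(10.0)

    def test_zero_land_zero_resources(self):
        land = pd.Series({"fruits": 0.0, "vegetables": 0.0, "hay": 0.0})
        fp = land_to_resources(land, _toy_params())
        assert (fp.totals == 0).all()

    def test_two_category_hand_sum(self):
        land = pd.Series({"fruits": 2.0, "vegetables": 3.0, "hay": 0.0})
        fp = land_to_resources(land, _toy_params())
        # fertilizer: 2*100 + 3*(50+25+25) = 500; irrigation 2*1000+3*500
        assert fp.totals["fertilizer_kg"] == pytest.approx(500.0)
        assert fp.totals["irrigation_m3"] == pytest.approx(3500.0)

    def test_missing_rate_for_nonzero_land_rejected(self):
        params = _toy_params()
        params.rates = params.rates[params.rates["land_use_category"] != "fruits"]
        with pytest.raises(ConfigurationError):
            land_to_resources(pd.Series({"fruits": 1.0}), params)


class TestAttribution:
    def _fp(self, k):
        return land_to_resources(
            pd.Series({"fruits": k, "vegetables": 0.0, "hay": 0.0}), _toy_params()
        )

    def test_single_stream_share_one(self):
        shares = attribute_to_loss_categories({"consumed": self._fp(1.0)})
        assert (shares.loc["consumed"] == 1.0).all()

    def test_two_equal_streams(self):
        shares = attribute_to_loss_categories(
            {"a": self._fp(1.0), "b": self._fp(1.0)}
        )
        assert np.allclose(shares.to_numpy(), 0.5)

    def test_four_stream_brute_force(self):
        ks = {"retail_loss": 1.0, "inedible": 2.0, "consumer_waste": 3.0, "consumed": 4.0}
        shares = attribute_to_loss_categories({k: self._fp(v) for k, v in ks.items()})
        total = sum(ks.values())
        for k, v in ks.items():
            assert shares.loc[k, "land_ha"] == pytest.approx(v / total)
        assert shares.sum(axis=0)["fertilizer_kg"] == pytest.approx(1.0)

    def test_all_zero_resource_rejected(self):
        with pytest.raises(EstimationError):
            attribute_to_loss_categories({"a": self._fp(0.0)})


class TestFullChain:
    def test_linearity_in_demand(self):
        params = _toy_params()
        d = pd.Series({"A": 10.0, "B": 5.0, "C": 8.0, "D": 12.0})
        fp1 = footprint_from_demand(d, params, population=1e6)
        fp3 = footprint_from_demand(3.0 * d, params, population=1e6)
        pd.testing.assert_frame_equal(fp3.by_category, fp1.by_category * 3.0)

    def test_stream_additivity(self):
        params = _toy_params()
        streams = {
            "retail_loss": pd.Series({"A": 1.0, "B": 0.5, "C": 0.2, "D": 0.1}),
            "inedible": pd.Series({"A": 2.0, "B": 0.0, "C": 1.0, "D": 0.3}),
            "consumer_waste": pd.Series({"A": 3.0, "B": 1.0, "C": 0.5, "D": 0.6}),
            "consumed": pd.Series({"A": 10.0, "B": 4.0, "C": 6.0, "D": 5.0}),
        }
        fps = {k: footprint_from_demand(v, params, 1e6) for k, v in streams.items()}
        total = footprint_from_demand(sum(streams.values()), params, 1e6)
        summed = sum(list(fps.values())[1:], start=list(fps.values())[0])
        assert np.allclose(
            summed.by_category.to_numpy(), total.by_category.to_numpy(), rtol=1e-6
        )

    def test_land_availability_flag(self):
        params = _toy_params()
        fp = footprint_from_demand(
            pd.Series({"A": 10.0, "B": 5.0, "C": 8.0, "D": 12.0}), params, 1e6
        )
        avail = pd.Series(1e12, index=fp.by_category.index)
        avail["fruits"] = 0.0
        report = check_land_availability(fp, avail)
        assert bool(report.loc["fruits", "exceeds"])
        assert not bool(report.loc["hay", "exceeds"])


class TestMonteCarlo:
    def _person_demand(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            for c in ("A", "C", "D"):
                rows.append(
                    {
                        "person_id": f"P{i}",
                        "commodity_id": c,
                        "grams": float(rng.uniform(10, 300)),
                    }
                )
        demand = pd.DataFrame(rows)
        w = pd.Series(rng.lognormal(0, 0.5, n), index=[f"P{i}" for i in range(n)])
        return demand, w

    def test_deterministic_under_seed(self):
        demand, w = self._person_demand()
        kw = dict(draw_size=6, n_reps=20, seed=5)
        a = monte_carlo_footprint(demand, w, _toy_params(), 1e6, **kw)
        b = monte_carlo_footprint(demand, w, _toy_params(), 1e6, **kw)
        pd.testing.assert_frame_equal(a["replicates"], b["replicates"])

    def test_homogeneous_population_zero_width(self):
        n = 8
        rows = [
            {"person_id": f"P{i}", "commodity_id": "A", "grams": 100.0}
            for i in range(n)
        ]
        w = pd.Series(1.0, index=[f"P{i}" for i in range(n)])
        mc = monte_carlo_footprint(
            pd.DataFrame(rows), w, _toy_params(), 1e6, draw_size=4, n_reps=10, seed=1
        )
        assert np.allclose(mc["ci_low"], mc["ci_high"])

    def test_percentiles_match_stored_replicates(self):
        demand, w = self._person_demand()
        mc = monte_carlo_footprint(
            demand, w, _toy_params(), 1e6, draw_size=6, n_reps=40, seed=9
        )
        brute_lo = mc["replicates"].quantile(0.025, axis=0)
        brute_hi = mc["replicates"].quantile(0.975, axis=0)
        pd.testing.assert_series_equal(mc["ci_low"], brute_lo)
        pd.testing.assert_series_equal(mc["ci_high"], brute_hi)

    def test_draw_size_exceeding_n_rejected(self):
        demand, w = self._person_demand(n=5)
        with pytest.raises(EstimationError):
            monte_carlo_footprint(
                demand, w, _toy_params(), 1e6, draw_size=6, n_reps=5, seed=0
            )
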