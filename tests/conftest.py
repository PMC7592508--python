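import numpy as np
import pandas as pd
import pytest

from dietprint import (
    PopulationSpec,
    SurveyDesignSpec,
    generate_parameter_tables,
    generate_population,
)


@pytest.fixture(scope="session")
def small_design():
    return SurveyDesignSpec(n_strata=6, psus_per_stratum=2, individuals_per_psu=15, seed=7)


@pytest.fixture(scope="session")
def small_pop():
    return PopulationSpec(n_foods=20, n_commodities=16)


@pytest.fixture(scope="session")
def tables(small_pop, small_design):
    return generate_parameter_tables(
        small_pop.n_foods, small_pop.n_commodities, 12, seed=small_design.seed
    )


@pytest.fixture(scope="session")
def records(small_design, small_pop, tables):
    return generate_population(small_design, small_pop, tables)


@pytest.fixture()
def tiny_survey():
    """Six individuals in two strata x two PSUs, hand-enterable numbers."""
    return pd.DataFrame(
        {
            "y": [10.0, 20.0, 30.0, 15.0, 25.0, 35.0],
            "w": [1.0, 2.0, 3.0, 1.0, 1.0, 2.0],
            "stratum": [1, 1, 1, 2, 2, 2],
            "psu": [1, 1, 2, 1, 2, 2],
        }
    )


def max_compliance_record():
    """Record saturating every HEI-2015 and AHEI-2010 full-score standard."""
    energy = 2000.0
    e = energy / 1000.0
    return pd.Series(
        {
            "person_id": "MAX",
            "age": 40.0,
            "sex": "female",
            "energy_kcal": energy,
            # HEI adequacy at/above the full-score densities
            "fruit_total_cup": 0.8 * e,
            "fruit_whole_cup": 0.4 * e,
            "veg_total_cup": 1.1 * e,
            "greens_beans_cup": 0.2 * e,
            "whole_grains_oz": 1.5 * e,
            "dairy_cup": 1.3 * e,
            "protein_total_oz": 2.5 * e,
            "protein_seafood_plant_oz": 0.8 * e,
            # unsat:sat ratio 3 >= 2.5; sat fat 5 %energy <= 8
            "sat_fat_g": 0.05 * energy / 9.0,
            "unsat_fat_g": 3.0 * 0.05 * energy / 9.0,
            # moderation at/below the full-score thresholds (sodium must
            # satisfy both the HEI density and the AHEI 1849-basis standard)
            "refined_grains_oz": 1.0 * e,
            "sodium_g": 1.1 * energy / 1849.0,
            "added_sugar_g": 0.05 * energy / 4.0,  # 5 %energy <= 6.5
            # AHEI: amounts on the 1849 basis scaled to this record's energy
            "veg_servings": 5.0 * energy / 1849.0,
            "fruit_servings": 4.0 * energy / 1849.0,
            "whole_grains_g": 75.0 * energy / 1849.0,
            "nuts_legumes_servings": 1.0 * energy / 1849.0,
            "omega3_mg": 250.0 * energy / 1849.0,
            "pufa_g": 0.10 * energy / 9.0,  # 10 %energy
            "ssb_juice_servings": 0.0,
            "red_meat_servings": 0.0,
            "alcohol_drinks": 1.0 * energy / 1849.0,  # inside the moderate band
        }
    )


def floor_record():
    """Record at the floor of every component: zero adequacy intake and
    moderation intakes at/above every zero-score threshold."""
    energy = 2000.0
    e = energy / 1000.0
    return pd.Series(
        {
            "person_id": "FLOOR",
            "age": 40.0,
            "sex": "male",
            "energy_kcal": energy,
            "fruit_total_cup": 0.0,
            "fruit_whole_cup": 0.0,
            "veg_total_cup": 0.0,
            "greens_beans_cup": 0.0,
            "whole_grains_oz": 0.0,
            "dairy_cup": 0.0,
            "protein_total_oz": 0.0,
            "protein_seafood_plant_oz": 0.0,
            "sat_fat_g": 0.20 * energy / 9.0,  # 20 %energy >= 16
            "unsat_fat_g": 0.20 * energy / 9.0,  # ratio 1.0 <= 1.2
            "refined_grains_oz": 5.0 * e,  # >= 4.3 / 1000 kcal
            "sodium_g": 2.5 * e,  # >= 2.0 g / 1000 kcal
            "added_sugar_g": 0.30 * energy / 4.0,  # 30 %energy >= 26
            "veg_servings": 0.0,
            "fruit_servings": 0.0,
            "whole_grains_g": 0.0,
            "nuts_legumes_servings": 0.0,
            "omega3_mg": 0.0,
            "pufa_g": 0.01 * energy / 9.0,  # 1 %energy <= 2
            "ssb_juice_servings": 2.0 * energy / 1849.0,
            "red_meat_servings": 2.0 * energy / 1849.0,
            "sodium_mg": np.nan,  # unused; sodium_g drives both indices
            "alcohol_drinks": 3.0 * energy / 1849.0,  # >= 2.5 on basis
        }
    )
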