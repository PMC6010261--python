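"""Uncertainty propagation: variant classes, scenarios, agreement."""

import numpy as np
import pandas as pd
import pytest

from riverscape.core import ClassThresholds, LAYER_CODES, LAYERS
from riverscape.typology import assemble_typologies, rare_classes, summarize_classes
from riverscape.uncertainty import (
    agreement,
    run_scenarios,
    scenario_typologies,
    variant_class,
)

TEMP_BOUNDS = ClassThresholds().layer_bounds("temperature")
TEMP_CODES = LAYER_CODES["temperature"]


class TestVariantClass:
    def test_band_crossing_moves_to_adjacent_warmer_class(self):
        # 20.5 +/- 1.0 crosses the 21-degree boundary -> CL
        assert variant_class(20.5, 1.0, TEMP_BOUNDS, TEMP_CODES, "CC") == "CL"

    def test_band_within_class_unchanged(self):
        assert variant_class(20.0, 0.5, TEMP_BOUNDS, TEMP_CODES, "CC") == "CC"

    def test_zero_deviation_identity(self):
        for v, orig in [(20.5, "CC"), (18.0, "CD"), (26.0, "W")]:
            assert variant_class(v, 0.0, TEMP_BOUNDS, TEMP_CODES, orig) == orig

    def test_crossing_downward(self):
        # 19.3 +/- 0.5 crosses 19 -> CD
        assert variant_class(19.3, 0.5, TEMP_BOUNDS, TEMP_CODES, "CC") == "CD"

    def test_nearest_boundary_wins(self):
        # 20.8 +/- 2.0 crosses both 19 (dist 1.8) and 21 (dist 0.2) -> CL
        assert variant_class(20.8, 2.0, TEMP_BOUNDS, TEMP_CODES, "CC") == "CL"

    def test_equidistant_tie_takes_lower_class(self):
        # 20.0 +/- 1.5 crosses 19 and 21 at distance 1.0 each -> lower class CD
        assert variant_class(20.0, 1.5, TEMP_BOUNDS, TEMP_CODES, "CC") == "CD"

    def test_adjacency_invariant(self):
        rng = np.random.default_rng(3)
        order = {c: k for k, c in enumerate(TEMP_CODES)}
        from riverscape.classify import classify_temperature

        for _ in range(500):
            v = rng.uniform(10, 32)
            d = rng.uniform(0, 3)
            orig = classify_temperature([v])[0]
            var = variant_class(v, d, TEMP_BOUNDS, TEMP_CODES, orig)
            assert abs(order[var] - order[orig]) <= 1


def make_classified(n, rng):
    t = ClassThresholds()
    from riverscape.classify import (
        classify_gradient,
        classify_size,
        classify_substrate,
        classify_temperature,
    )

    df = pd.DataFrame(index=range(n))
    df["cum_area_km2"] = np.exp(rng.uniform(0, 10, n))
    df["slope"] = rng.uniform(0, 0.15, n)
    df["summer_temp_c"] = rng.uniform(14, 28, n)
    df["substrate_diameter_mm"] = rng.uniform(1, 1500, n)
    df["size"] = classify_size(df["cum_area_km2"], t)
    df["gradient"] = classify_gradient(df["slope"], t)
    df["temperature"] = classify_temperature(df["summer_temp_c"], t)
    df["substrate"] = classify_substrate(df["substrate_diameter_mm"], t)
    hydro = rng.choice(["PR1", "PR2", "SHBF"], n)
    df["hydrology"] = hydro
    proba = rng.dirichlet([2, 2, 2], n)
    for j, c in enumerate(["PR1", "PR2", "SHBF"]):
        df[f"p_{c}"] = proba[:, j]
    # make the argmax consistent with the assigned class
    top = np.array(["PR1", "PR2", "SHBF"])[np.argmax(proba, axis=1)]
    df["hydrology"] = top
    df["valley_width_m"] = rng.uniform(5, 400, n)
    df["bankfull_width_m"] = rng.uniform(2, 50, n)
    df["valley_coverage"] = rng.uniform(0, 1, n)
    from riverscape.classify import classify_confinement

    df["confinement"] = classify_confinement(
        df["valley_width_m"], df["bankfull_width_m"], df["valley_coverage"], t
    )
    return df


class TestScenarios:
    def test_zero_bands_identity(self):
        rng = np.random.default_rng(5)
        df = make_classified(150, rng)
        lengths = rng.uniform(0.5, 3.0, 150)
        bands = {l: 0.0 for l in ("size", "gradient", "temperature", "substrate")}
        subset = ("size", "gradient", "temperature", "substrate")
        _, codes, tab = scenario_typologies(df, bands, "all", subset, lengths)
        orig = assemble_typologies(df, subset)
        orig_tab = summarize_classes(orig, lengths)
        assert (codes == orig).all()
        pd.testing.assert_frame_equal(tab, orig_tab)
        ag = agreement(orig, codes, lengths, rare_classes(orig_tab), rare_classes(tab))
        assert ag["pct_same_typology"] == 100.0
        assert ag["pct_same_rarity"] == 100.0

    def test_varying_one_layer_only_touches_that_position(self):
        rng = np.random.default_rng(7)
        df = make_classified(100, rng)
        bands = {"temperature": 1.5}
        subset = ("size", "gradient", "temperature")
        var_cls, codes, _ = scenario_typologies(df, bands, "temperature", subset, np.ones(100))
        assert (var_cls["size"] == df["size"]).all()
        assert (var_cls["gradient"] == df["gradient"]).all()

    def test_hydrology_variant_is_second_most_probable(self):
        rng = np.random.default_rng(9)
        df = make_classified(80, rng)
        subset = ("size", "hydrology")
        var_cls, _, _ = scenario_typologies(df, {}, "hydrology", subset, np.ones(80))
        proba = df[["p_PR1", "p_PR2", "p_SHBF"]].to_numpy()
        second = np.array(["PR1", "PR2", "SHBF"])[np.argsort(-proba, axis=1)[:, 1]]
        assert (var_cls["hydrology"].to_numpy() == second).all()

    def test_all_changes_confined_to_varied_layers(self):
        rng = np.random.default_rng(11)
        df = make_classified(120, rng)
        bands = {"size": 0.0, "gradient": 0.01, "temperature": 1.0, "substrate": 0.0,
                 "confinement": {"ratio": 0.5, "coverage": 0.1}}
        var_cls, _, _ = scenario_typologies(df, bands, "all", LAYERS, np.ones(120))
        assert (var_cls["size"] == df["size"]).all()  # zero band -> unchanged


class TestAgreement:
    def test_identical_scenarios_full_agreement(self):
        codes = pd.Series(["a", "b", "c"])
        ag = agreement(codes, codes.copy(), [1.0, 1.0, 1.0], {"a"}, {"a"})
        assert ag == {"pct_same_typology": 100.0, "pct_same_rarity": 100.0}

    def test_all_changed_zero_agreement(self):
        orig = pd.Series(["a", "b"])
        scen = pd.Series(["b", "a"])
        ag = agreement(orig, scen, [1.0, 1.0])
        assert ag["pct_same_typology"] == 0.0

    def test_length_weighted_hand_computation(self):
        rng = np.random.default_rng(13)
        n = 20
        orig = pd.Series(rng.choice(["a", "b", "c"], n))
        scen = orig.copy()
        flip = rng.random(n) < 0.3
        scen[flip] = "z"
        lengths = rng.uniform(0.1, 5.0, n)
        expected = 100.0 * lengths[~flip].sum() / lengths.sum()
        ag = agreement(orig, scen, lengths)
        assert ag["pct_same_typology"] == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(15)
        a = pd.Series(rng.choice(["x", "y"], 30))
        b = pd.Series(rng.choice(["x", "y"], 30))
        lengths = rng.uniform(0.5, 2.0, 30)
        assert agreement(a, b, lengths)["pct_same_typology"] == pytest.approx(
            agreement(b, a, lengths)["pct_same_typology"]
        )

    def test_mismatched_indexes_rejected(self):
        with pytest.raises(ValueError):
            agreement(pd.Series(["a"]), pd.Series(["a"], index=[5]), [1.0])


def test_run_scenarios_table_shape():
    rng = np.random.default_rng(17)
    df = make_classified(200, rng)
    lengths = rng.uniform(0.5, 2.0, 200)
    bands = {"size": 0.0, "gradient": 0.005, "temperature": 1.0}
    tab = run_scenarios(df, bands, lengths)
    assert list(tab["scenario"]) == [
        "original",
        "variant_size",
        "variant_gradient",
        "variant_hydrology",
        "variant_temperature",
        "variant_confinement",
        "variant_all",
    ]
    assert (tab["pct_same_typology"] <= 100.0).all()
    assert tab.loc[tab["scenario"] == "variant_size", "pct_same_typology"].iloc[0] == 100.0
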