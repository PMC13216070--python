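"""Grid prediction operations: settlement classification, AME conversion,
categorical weighting, the protein chain, biomass and uncertainty maps."""

import numpy as np
import pandas as pd
import pytest

from wildmeat.model.diagnostics import PosteriorDraws
from wildmeat.predict import (
    CellDesign,
    GridGeometry,
    LinTerm,
    biomass_kg_per_year,
    classify_settlements,
    dissimilarity_index,
    grid_ame,
    predict_cells,
    protein_contribution,
    sim_cell_design,
    weight_categorical,
)
from wildmeat.synthetic import prediction_cells


class TestClassifySettlements:
    @pytest.mark.parametrize(
        "pop, label",
        [
            (0, "village"),
            (9_999, "village"),
            (10_000, "town"),
            (99_999, "town"),
            (100_000, "city"),
            (250_000, "city"),
        ],
    )
    def test_thresholds(self, pop, label):
        assert classify_settlements([pop])[0] == label

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            classify_settlements([-1])


class TestGridAME:
    @pytest.mark.parametrize(
        "pop, prop_child, expected",
        [(1000, 0.0, 930.0), (1000, 1.0, 780.0), (0, 0.5, 0.0)],
    )
    def test_values(self, pop, prop_child, expected):
        assert grid_ame(pop, prop_child) == pytest.approx(expected)

    def test_bounded_by_population(self):
        pops = np.linspace(0, 1e5, 7)
        assert np.all(grid_ame(pops, 0.4) <= pops)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            grid_ame(-5, 0.2)
        with pytest.raises(ValueError):
            grid_ame(100, 1.2)


class TestWeightCategorical:
    def test_degenerate_props_pick_one_level(self):
        assert weight_categorical([2.0, 5.0, 9.0], [1, 0, 0]) == 2.0

    def test_equal_thirds_is_mean(self):
        levels = np.array([2.0, 5.0, 9.0])
        assert weight_categorical(levels, np.ones(3) / 3) == pytest.approx(
            levels.mean()
        )

    def test_education_weighting_limit(self):
        # all-primary cell (ED tilde = 0) reproduces the primary parameter
        ed = 0.0
        assert weight_categorical([1.7, -0.4], [1 - ed, ed]) == 1.7

    def test_draw_matrix_weighting(self):
        draws = np.arange(12.0).reshape(4, 3)
        out = weight_categorical(draws, [0.2, 0.3, 0.5])
        assert out.shape == (4,)
        assert out[0] == pytest.approx(0.3 + 2 * 0.5)

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            weight_categorical([1.0, 2.0], [0.6, 0.6])


class TestProteinChain:
    def test_regional_median_rate(self):
        protein, pct = protein_contribution(50.0)
        assert round(float(protein)) == 10
        assert round(float(pct)) == 18

    def test_city_rate(self):
        _, pct = protein_contribution(16.0)
        assert round(float(pct)) == 6

    def test_zero_rate(self):
        protein, pct = protein_contribution(0.0)
        assert protein == 0.0 and pct == 0.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            protein_contribution(-1.0)


class TestGeometry:
    def test_cell_area_is_site_buffer_circle(self):
        geom = GridGeometry()
        assert round(geom.cell_area_km2) == 5027

    def test_forest_buffer_is_twice_the_side(self):
        geom = GridGeometry()
        assert geom.forest_buffer_radius_km == pytest.approx(140.18)


class TestBiomass:
    def test_annual_kg(self):
        assert biomass_kg_per_year(0.05, 100.0) == pytest.approx(1825.0)

    def test_zero_ame(self):
        assert biomass_kg_per_year(0.3, 0.0) == 0.0

    def test_additive_over_cells(self):
        rates = np.array([0.05, 0.05])
        ames = np.array([100.0, 100.0])
        total = biomass_kg_per_year(rates, ames).sum()
        assert total == pytest.approx(2 * biomass_kg_per_year(0.05, 100.0))


class TestDissimilarity:
    def _cells(self):
        return pd.DataFrame(
            {
                "hpd": [10.0, 50.0, 100.0],
                "rem": [1.0, 2.0, 3.0],
                "hdi": [0.4, 0.5, 0.6],
                "fci": [0.2, 0.5, 0.8],
            }
        )

    def _data(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "hpd": np.full(20, 50.0),
                "rem": np.full(20, 2.0),
                "hdi": np.full(20, 0.5),
                "fci": np.full(20, 0.5),
            }
        )

    def test_zero_at_data_means(self):
        maps = dissimilarity_index(self._cells(), self._data())
        assert maps.delta.iloc[1] == pytest.approx(0.0)

    def test_maximum_is_number_of_covariates(self):
        maps = dissimilarity_index(self._cells(), self._data())
        assert maps.delta.max() == pytest.approx(4.0)
        assert (maps.delta >= 0).all() and (maps.delta <= 4).all()

    def test_linear_in_the_gap(self):
        cells = self._cells()
        maps = dissimilarity_index(cells, self._data())
        halved = cells.copy()
        halved["hpd"] = 50.0 + (halved["hpd"] - 50.0) / 2
        # the extreme cell still defines the normalizing maximum
        halved.loc[3] = [100.0, 2.0, 0.5, 0.5]
        maps2 = dissimilarity_index(halved, self._data())
        assert maps2.delta_prime.loc[0, "hpd"] == pytest.approx(
            maps.delta_prime.loc[0, "hpd"] / 2
        )

    def test_constant_covariate_rejected(self):
        cells = self._cells()
        cells["rem"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            dissimilarity_index(cells, self._data())


def _fake_draws(n_draws=80, seed=0):
    """Posterior-draw stand-in with the simulation model's column names
    (synthetic values; used only for structural identities)."""
    rng = np.random.default_rng(seed)
    names = (
        [f"a0[{r}]" for r in (1, 2, 3)] + [f"a1[{r}]" for r in (1, 2, 3)]
        + ["a_v3", "a_days"]
        + [f"b0[{r}]" for r in (1, 2, 3)] + [f"b1[{r}]" for r in (1, 2, 3)]
        + ["b_v3"]
        + [f"c0[{r}]" for r in (1, 2, 3)] + [f"c1[{r}]" for r in (1, 2, 3)]
        + ["c_ame", "log_kappa", "log_theta"]
    )
    base = np.concatenate([
        [-2.2, -2.6, -2.4, 0.8, 0.5, 0.6, 0.4, 0.05],
        [-1.7, -2.1, -1.9, 0.5, 0.3, 0.4, 0.3],
        [-1.0, -1.3, -1.15, 0.35, 0.2, 0.3, -0.03, np.log(30), np.log(2)],
    ])
    draws = base + 0.1 * rng.standard_normal((1, n_draws, len(names)))
    return PosteriorDraws(draws=draws, names=names)


@pytest.fixture(scope="module")
def preds(tiny_world):
    cells = prediction_cells(tiny_world["landscape"])
    return predict_cells(_fake_draws(), cells, sim_cell_design(), seed=3)


class TestCellPredictions:

    def test_rate_is_the_triple_product_drawwise(self, preds):
        assert np.array_equal(
            preds.rate, preds.consumption * preds.frequency * preds.quantity
        )

    def test_annual_kg_identity_drawwise(self, preds):
        ame = preds.cells["ame"].to_numpy()
        assert np.allclose(preds.kg_year, preds.rate * ame[None, :] * 365.0)

    def test_nonconsumption_draw_zeroes_the_rate(self, preds):
        zero = preds.consumption == 0.0
        assert zero.any()
        assert np.all(preds.rate[zero] == 0.0)

    def test_gram_scale_is_thousandfold(self, preds):
        summ = preds.cell_summary()
        assert summ["rate_median_g"].to_numpy() == pytest.approx(
            np.percentile(preds.rate, 50, axis=0) * 1000.0
        )

    def test_subregion_never_exceeds_regional_total(self, preds):
        total = preds.tonnes_draws()
        sub = preds.kg_year[:, :40].sum(axis=1) / 1000.0
        assert np.all(sub <= total + 1e-12)

    def test_sd_maps_nonnegative(self, preds):
        summ = preds.cell_summary()
        assert (summ["rate_sd_g"] >= 0).all()
        assert (summ["kg_year_sd"] >= 0).all()

    def test_unknown_term_type_rejected(self, preds, tiny_world):
        cells = prediction_cells(tiny_world["landscape"])
        bad = CellDesign(consumption=("nonsense",), frequency=(), quantity=())
        with pytest.raises(TypeError):
            predict_cells(_fake_draws(), cells, bad, seed=0)
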