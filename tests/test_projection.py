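import numpy as np
import pandas as pd
import pytest

from occaban import (
    HABITAT_TYPES,
    HabitatMatrix,
    McmcSettings,
    RangeStack,
    compute_cl_cg,
    map_summary,
    red_list_subset,
    species_effects,
)
from occaban.inference import PosteriorDraws


def make_stack(presence, species=None, coords=None):
    species = species or [f"sp{i:03d}" for i in range(presence.shape[1])]
    cells = [f"c{i}" for i in range(presence.shape[0])]
    return RangeStack(
        presence=pd.DataFrame(presence, index=cells, columns=species),
        coords=coords,
    )


def effects_frame(values, species=None):
    values = np.atleast_2d(values)
    species = species or [f"sp{i:03d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=species)


class TestComputeClCg:
    def test_single_cell_single_draw(self):
        # effects (-0.5, +0.2, -0.1), all present: CL=0.6, CG=0.2
        stack = make_stack(np.ones((1, 3), dtype=int))
        maps = compute_cl_cg(stack, effects_frame([-0.5, 0.2, -0.1]))
        assert maps["cl_mean"].iloc[0] == pytest.approx(0.6)
        assert maps["cg_mean"].iloc[0] == pytest.approx(0.2)
        assert maps["cg_minus_cl_mean"].iloc[0] == pytest.approx(-0.4)
        assert maps["prop_cl_mean"].iloc[0] == pytest.approx(0.75)

    def test_empty_cell_flagged_undefined(self):
        stack = make_stack(np.array([[0, 0, 0], [1, 1, 1]]))
        maps = compute_cl_cg(stack, effects_frame([-0.5, 0.2, -0.1]))
        assert maps["cl_mean"].iloc[0] == 0.0
        assert maps["cg_mean"].iloc[0] == 0.0
        assert not maps["prop_defined"].iloc[0]
        assert maps["prop_defined"].iloc[1]

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(77)
        n_cells, n_sp, n_draws = 100, 20, 50
        pres = rng.integers(0, 2, size=(n_cells, n_sp))
        eff = rng.normal(size=(n_draws, n_sp))
        maps = compute_cl_cg(make_stack(pres), effects_frame(eff))
        cl = np.zeros((n_cells, n_draws))
        cg = np.zeros((n_cells, n_draws))
        for c in range(n_cells):
            for d in range(n_draws):
                for s in range(n_sp):
                    if pres[c, s]:
                        e = eff[d, s]
                        if e < 0:
                            cl[c, d] += -e
                        elif e > 0:
                            cg[c, d] += e
        np.testing.assert_allclose(maps["cl_mean"], cl.mean(axis=1), atol=1e-10)
        np.testing.assert_allclose(maps["cl_sd"], cl.std(axis=1), atol=1e-10)
        np.testing.assert_allclose(maps["cg_mean"], cg.mean(axis=1), atol=1e-10)
        np.testing.assert_allclose(maps["cg_sd"], cg.std(axis=1), atol=1e-10)

    def test_sign_flip_swaps_cl_and_cg(self):
        rng = np.random.default_rng(8)
        pres = rng.integers(0, 2, size=(30, 10))
        eff = rng.normal(size=(20, 10))
        a = compute_cl_cg(make_stack(pres), effects_frame(eff))
        b = compute_cl_cg(make_stack(pres), effects_frame(-eff))
        np.testing.assert_allclose(a["cl_mean"], b["cg_mean"], atol=1e-12)
        np.testing.assert_allclose(a["cg_sd"], b["cl_sd"], atol=1e-12)

    def test_additive_over_disjoint_species_subsets(self):
        rng = np.random.default_rng(9)
        pres = rng.integers(0, 2, size=(15, 8))
        eff = rng.normal(size=(10, 8))
        full = compute_cl_cg(make_stack(pres), effects_frame(eff))
        left = compute_cl_cg(make_stack(pres[:, :3]), effects_frame(eff[:, :3]))
        sp_right = [f"sp{i:03d}" for i in range(3, 8)]
        right = compute_cl_cg(
            make_stack(pres[:, 3:], species=sp_right),
            effects_frame(eff[:, 3:], species=sp_right),
        )
        np.testing.assert_allclose(
            full["cl_mean"], left["cl_mean"] + right["cl_mean"], atol=1e-12
        )

    def test_absent_species_changes_nothing(self):
        rng = np.random.default_rng(10)
        pres = rng.integers(0, 2, size=(12, 5))
        eff = rng.normal(size=(7, 6))
        pres6 = np.hstack([pres, np.zeros((12, 1), dtype=int)])
        a = compute_cl_cg(make_stack(pres), effects_frame(eff[:, :5]))
        b = compute_cl_cg(make_stack(pres6), effects_frame(eff))
        np.testing.assert_allclose(a["cl_mean"], b["cl_mean"], atol=1e-14)
        np.testing.assert_allclose(a["cg_mean"], b["cg_mean"], atol=1e-14)

    def test_missing_species_effect_raises(self):
        stack = make_stack(np.ones((2, 3), dtype=int))
        with pytest.raises(KeyError, match="sp002"):
            compute_cl_cg(
                stack, effects_frame(np.zeros((4, 2)), species=["sp000", "sp001"])
            )


class TestSpeciesEffects:
    def _draws(self, rng, n=40):
        return PosteriorDraws(
            draws={
                "alpha0": rng.normal(size=(1, n)),
                "alpha_vec": rng.normal(size=(1, n, 11)),
            },
            rhat={}, divergences=0,
            settings=McmcSettings(n_chains=2, n_warmup=4, n_samples=4),
            variant="M3", species=[],
        )

    def test_identical_habitat_rows_identical_effects(self, uniform_habitat):
        rng = np.random.default_rng(12)
        draws = self._draws(rng)
        H = uniform_habitat.H.copy()
        H.loc["sp001"] = H.loc["sp000"]
        hab = HabitatMatrix(H=H, red_list=uniform_habitat.red_list)
        eff = species_effects(hab, draws)
        np.testing.assert_array_equal(eff["sp000"], eff["sp001"])

    def test_matches_dot_product_oracle(self, uniform_habitat):
        rng = np.random.default_rng(13)
        draws = self._draws(rng)
        eff = species_effects(uniform_habitat, draws)
        a0 = draws.stacked("alpha0")
        av = draws.stacked("alpha_vec")
        for sp in uniform_habitat.species:
            h = uniform_habitat.H.loc[sp].to_numpy(dtype=float)
            np.testing.assert_allclose(
                eff[sp], a0 + av @ h, atol=1e-12
            )

    def test_species_without_habitat_row_raises(self, uniform_habitat):
        rng = np.random.default_rng(14)
        with pytest.raises(KeyError, match="spX"):
            species_effects(uniform_habitat, self._draws(rng),
                            species=["sp000", "spX"])


class TestMapSummary:
    def test_all_negative_effects(self):
        stack = make_stack(np.ones((5, 3), dtype=int))
        eff = effects_frame(-np.abs(np.random.default_rng(1).normal(
            size=(10, 3))))
        maps = compute_cl_cg(stack, eff)
        summary = map_summary(maps)
        assert summary["frac_cl_gt_cg"] == 1.0
        assert (maps["cg_mean"] == 0).all()

    def test_pearson_matches_hand_formula_on_three_cells(self):
        pres = np.array([[1, 0], [1, 1], [0, 1]])
        eff = effects_frame(np.array([[-1.0, 2.0], [-0.5, 1.0]]))
        maps = compute_cl_cg(make_stack(pres), eff)
        summary = map_summary(maps)
        cl = maps["cl_mean"].to_numpy()
        cg = maps["cg_mean"].to_numpy()
        hand = (
            np.mean((cl - cl.mean()) * (cg - cg.mean()))
            / (cl.std() * cg.std())
        )
        assert summary["corr_cl_cg"] == pytest.approx(hand, abs=1e-12)

    def test_duplicating_cells_preserves_summary(self):
        rng = np.random.default_rng(15)
        pres = rng.integers(0, 2, size=(10, 4))
        eff = effects_frame(rng.normal(size=(8, 4)))
        a = map_summary(compute_cl_cg(make_stack(pres), eff))
        b = map_summary(compute_cl_cg(make_stack(np.vstack([pres, pres])), eff))
        assert a["frac_cl_gt_cg"] == b["frac_cl_gt_cg"]
        assert a["corr_cl_cg"] == pytest.approx(b["corr_cl_cg"], abs=1e-12)

    def test_single_cell_correlation_flagged(self):
        maps = compute_cl_cg(
            make_stack(np.ones((1, 2), dtype=int)),
            effects_frame([[-1.0, 1.0]]),
        )
        assert np.isnan(map_summary(maps)["corr_cl_cg"])


def test_red_list_subset(uniform_habitat):
    stack = make_stack(np.ones((3, 6), dtype=int),
                       species=uniform_habitat.species)
    sub = red_list_subset(uniform_habitat, stack)
    assert sub.species == ["sp000", "sp003"]
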