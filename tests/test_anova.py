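import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wheatqg as w
from conftest import make_obs


class TestCombinedAnova:
    def test_noise_free_genotype_effects_recovered_exactly(self):
        design = w.TrialDesign(n_genotypes=20, trait_names=("X",))
        truth = w.TrueComponents.diagonal(1, mu=10.0, sigma2_g=5.0, sigma2_e=0.0)
        obs, effects = w.simulate_trial(design, truth, seed=3, return_effects=True)
        vc = w.combined_anova(obs, "X")
        assert vc.sigma2["e"] == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2["g"] == pytest.approx(
            float(effects["X"].var(ddof=1)), rel=1e-10
        )
        assert vc.h2 == pytest.approx(1.0)

    def test_sum_of_squares_decomposition_is_complete(self, single_trait_trial):
        _, _, obs = single_trait_trial
        vc = w.combined_anova(obs, "X")
        ss_model = sum(vc.ms[k] * vc.df[k] for k in vc.ms)
        values = obs["value"].to_numpy()
        ss_total = float(((values - values.mean()) ** 2).sum())
        assert ss_model == pytest.approx(ss_total, rel=1e-8)

    def test_component_estimates_near_truth_at_one_seed(self, single_trait_trial):
        _, _, obs = single_trait_trial
        vc = w.combined_anova(obs, "X")
        # single-seed sampling bands are wide; the multi-seed recovery is
        # checked in the acceptance suite
        assert vc.sigma2["g"] == pytest.approx(10.0, rel=0.35)
        assert vc.sigma2["e"] == pytest.approx(4.0, rel=0.2)
        assert vc.f["G"] > 1.0 and vc.p["G"] < 1e-6

    def test_pure_noise_heritability_near_zero(self):
        design = w.TrialDesign(n_genotypes=100, trait_names=("X",))
        truth = w.TrueComponents.diagonal(1, sigma2_g=0.0, sigma2_e=4.0)
        h2 = [
            w.combined_anova(w.simulate_trial(design, truth, seed=s), "X").h2
            for s in range(20)
        ]
        assert np.mean(h2) < 0.15

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(
        c=st.floats(min_value=0.1, max_value=50.0),
        d=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_heritability_invariant_under_affine_rescaling(self, c, d):
        design = w.TrialDesign(n_genotypes=30, trait_names=("X",))
        truth = w.TrueComponents.diagonal(
            1, mu=5.0, sigma2_g=6.0, sigma2_gy=1.0, sigma2_gt=1.0, sigma2_e=2.0
        )
        obs = w.simulate_trial(design, truth, seed=9)
        scaled = obs.copy()
        scaled["value"] = c * scaled["value"] + d
        assert w.combined_anova(scaled, "X").h2 == pytest.approx(
            w.combined_anova(obs, "X").h2, rel=1e-9
        )

    def test_too_few_factor_levels_rejected(self):
        obs = make_obs(
            [
                ("G1", "2020", "N", "R1", "X", 1.0),
                ("G1", "2020", "N", "R2", "X", 2.0),
                ("G2", "2020", "N", "R1", "X", 3.0),
                ("G2", "2020", "N", "R2", "X", 4.0),
            ]
        )
        with pytest.raises(ValueError, match="'year'"):
            w.combined_anova(obs, "X")

    def test_moderate_missingness_imputed_with_warning(self):
        design = w.TrialDesign(n_genotypes=40, trait_names=("X",))
        truth = w.TrueComponents.diagonal(1, mu=10.0, sigma2_g=4.0, sigma2_e=1.0)
        obs = w.simulate_trial(design, truth, seed=4, missing_rate=0.03)
        with pytest.warns(UserWarning, match="imputed"):
            vc = w.combined_anova(obs, "X")
        assert vc.n_imputed > 0
        assert 0.0 < vc.h2 <= 1.0

    def test_excessive_missingness_is_an_error(self):
        design = w.TrialDesign(n_genotypes=40, trait_names=("X",))
        truth = w.TrueComponents.diagonal(1, mu=10.0, sigma2_g=4.0, sigma2_e=1.0)
        obs = w.simulate_trial(design, truth, seed=4, missing_rate=0.3)
        with pytest.raises(ValueError, match="missing"):
            w.combined_anova(obs, "X")


class TestPerEnvAnova:
    def test_identical_replicates_give_zero_error_and_unit_heritability(self):
        recs = []
        for i, v in enumerate([1.0, 3.0, 7.0, 2.0]):
            for rep in ("R1", "R2"):
                recs.append((f"G{i}", "2020", "D", rep, "X", v))
        ec = w.per_env_anova(make_obs(recs), "X", "D2020")
        assert ec.sigma2_e == pytest.approx(0.0, abs=1e-12)
        assert ec.h2 == pytest.approx(1.0)

    def test_genotype_constant_data_gives_zero_heritability(self):
        rng = np.random.default_rng(0)
        recs = [
            (f"G{i}", "2020", "D", rep, "X", 5.0 + rng.normal())
            for i in range(10)
            for rep in ("R1", "R2")
        ]
        # genotype means differ only through replicate noise; sigma2_g is
        # clamped at zero when MS_G < MS_E
        ec = w.per_env_anova(make_obs(recs), "X", "D2020")
        assert ec.sigma2_g >= 0.0
        if ec.clamped:
            assert ec.sigma2_g == 0.0 and ec.h2 == 0.0

    def test_closed_form_heritability_recovery(self):
        design = w.TrialDesign(n_genotypes=200, n_years=1, n_treatments=1, trait_names=("X",))
        truth = w.TrueComponents.diagonal(1, sigma2_g=8.0, sigma2_e=2.0)
        h2 = [
            w.per_env_anova(w.simulate_trial(design, truth, seed=s), "X", "N2020").h2
            for s in range(10)
        ]
        assert np.mean(h2) == pytest.approx(8.0 / 9.0, abs=0.02)

    def test_single_replicate_is_an_error(self):
        obs = make_obs(
            [("G1", "2020", "D", "R1", "X", 1.0), ("G2", "2020", "D", "R1", "X", 2.0)]
        )
        with pytest.raises(ValueError, match="replicate"):
            w.per_env_anova(obs, "X", "D2020")


class TestGenotypeMeans:
    def test_mean_over_replicates(self):
        obs = make_obs(
            [
                ("G1", "2020", "D", "R1", "X", 4.0),
                ("G1", "2020", "D", "R2", "X", 6.0),
                ("G1", "2020", "N", "R1", "X", 9.0),
                ("G1", "2021", "D", "R1", "X", 1.0),
            ]
        )
        m = w.genotype_means(obs, "D2020")
        assert m.loc["G1", "X"] == 5.0  # N and 2021 rows excluded

    def test_partial_missing_uses_remaining_replicate(self):
        obs = make_obs(
            [
                ("G1", "2020", "D", "R1", "X", np.nan),
                ("G1", "2020", "D", "R2", "X", 6.0),
            ]
        )
        assert w.genotype_means(obs, "D2020").loc["G1", "X"] == 6.0

    def test_unknown_environment_is_an_error(self):
        obs = make_obs([("G1", "2020", "D", "R1", "X", 1.0)])
        with pytest.raises(ValueError, match="N2021"):
            w.genotype_means(obs, "N2021")
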