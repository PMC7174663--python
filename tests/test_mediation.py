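"""Mediation: path fits, indirect effects, Monte-Carlo and Sobel
inference, proportion mediated, mediator contrasts."""

import numpy as np
import pandas as pd
import pytest

from beliefmed import (
    LmmSpec,
    MediationConfig,
    Mediator,
    MultilevelMediation,
    SynthTruth,
    TrialTable,
    compare_mediators,
    compare_random_slope_b,
    fit_lmm,
    generate_mediation_dataset,
    group_mean_center,
    mediate,
    monte_carlo_ci,
    proportion_mediated,
    sobel_z,
)
from beliefmed.exceptions import BeliefmedError, RankDeficiencyError, UndefinedStatisticError
from beliefmed.mediation import fit_path_a, fit_outcome_model


class TestMonteCarloCI:
    def test_degenerate_normals_collapse_to_point(self):
        assert monte_carlo_ci(2.0, 0.0, 3.0, 0.0, draws=2000, seed=0) == (6.0, 6.0)

    def test_published_interval_reproduced(self):
        """a=7.60 (SE .19) x b=0.33 (SE .12) at 1e5 draws lands on the
        printed 95% interval [0.77, 4.30] within +-0.1."""
        lo, hi = monte_carlo_ci(7.60, 0.19, 0.33, 0.12, draws=100_000, seed=12345)
        assert abs(lo - 0.77) < 0.1
        assert abs(hi - 4.30) < 0.1

    def test_null_interval_symmetric(self):
        lo, hi = monte_carlo_ci(0.0, 1.0, 0.0, 1.0, draws=100_000, seed=7)
        assert abs(lo + hi) < 0.05

    def test_seeded_runs_identical(self):
        one = monte_carlo_ci(1.0, 0.5, 2.0, 0.5, seed=42)
        two = monte_carlo_ci(1.0, 0.5, 2.0, 0.5, seed=42)
        assert one == two

    def test_width_shrinks_with_draws(self):
        """Quantile-estimation noise scales ~ draws^-1/2: the spread of
        the lower bound over replicates shrinks accordingly."""
        los_small = [monte_carlo_ci(1.0, 0.3, 1.0, 0.3, draws=1000, seed=s)[0]
                     for s in range(30)]
        los_big = [monte_carlo_ci(1.0, 0.3, 1.0, 0.3, draws=100_000, seed=s)[0]
                   for s in range(30)]
        ratio = np.std(los_small) / np.std(los_big)
        assert 5 < ratio < 20  # sqrt(100) = 10 up to sampling noise


class TestSobel:
    def test_first_order_arithmetic(self):
        z, p = sobel_z(7.60, 0.19, 0.33, 0.12)
        np.testing.assert_allclose(z, 2.5080 / np.sqrt(0.8356), rtol=1e-3)
        assert 2.70 < z < 2.78  # first-order value; the printed 2.80 is close

    def test_zero_b_gives_z_zero(self):
        z, p = sobel_z(1.0, 0.5, 0.0, 1.0)
        assert z == 0.0
        assert p == 1.0

    def test_reduces_to_b_over_se(self):
        z, _ = sobel_z(1.0, 0.0, 1.0, 1.0)
        np.testing.assert_allclose(z, 1.0)

    def test_degenerate_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sobel_z(0.0, 0.0, 0.0, 0.0)


class TestProportionMediated:
    def test_printed_single_mediator(self):
        prop, flagged = proportion_mediated(16.0289, 16.0289 + 10.6429)
        np.testing.assert_allclose(prop, 0.601, atol=5e-4)
        assert not flagged

    def test_printed_two_mediator(self):
        total = 17.3497 + 1.3658 + 7.9273
        p1, _ = proportion_mediated(17.3497, total)
        p2, _ = proportion_mediated(1.3658, total)
        np.testing.assert_allclose(p1, 0.651, atol=5e-4)
        np.testing.assert_allclose(p2, 0.051, atol=5e-4)

    def test_full_mediation_is_one(self):
        prop, flagged = proportion_mediated(4.2, 4.2)
        assert prop == 1.0 and not flagged

    def test_suppression_flagged(self):
        prop, flagged = proportion_mediated(-2.0, 3.0)
        assert flagged
        zero, flagged0 = proportion_mediated(1.0, 0.0)
        assert np.isnan(zero) and flagged0


class TestPathA:
    def test_balanced_closed_form(self, small_table):
        """Beliefs 60/30, 50/40, 70/60: the fixed path-a slope equals
        mean(DiffBelief)/2 = 8.333 (balanced OLS oracle)."""
        centered = group_mean_center(small_table, ["cue", "belief"])
        fit, log = fit_path_a(centered, Mediator("belief", "global"))
        np.testing.assert_allclose(fit.params.loc["cue_c", "Estimate"],
                                   (30 + 10 + 10) / 3 / 2, atol=1e-10)
        assert log == []
        assert fit.spec.random_terms == ()

    def test_zero_mediator_gives_zero_slope(self, small_table):
        df = small_table.df.copy()
        df["belief"] = 0.0
        centered = group_mean_center(TrialTable(df), ["cue", "belief"])
        fit, _ = fit_path_a(centered, Mediator("belief", "global"))
        np.testing.assert_allclose(fit.params.loc["cue_c", "Estimate"], 0.0,
                                   atol=1e-12)

    def test_random_slope_refused_for_global(self, small_table):
        centered = group_mean_center(small_table, ["cue", "belief"])
        with pytest.raises(BeliefmedError, match="confounded"):
            fit_path_a(centered, Mediator("belief", "global"), random_slope=True)

    def test_item_varying_keeps_random_slope_when_supported(self):
        table, _ = generate_mediation_dataset(
            SynthTruth(include_fluency=True, sd_fluency_cue_slope=0.2),
            n_participants=40, trials_per_level=20, seed=5)
        from beliefmed import apply_exclusions
        clean, _ = apply_exclusions(table)
        centered = group_mean_center(clean, ["cue", "fluency"])
        fit, log = fit_path_a(centered, Mediator("fluency", "item_varying"))
        assert "cue_c" in fit.spec.random_terms


class TestOutcomeModel:
    def test_duplicate_mediator_collinear(self, small_table):
        df = small_table.df.copy()
        df["belief2"] = df["belief"]
        centered = group_mean_center(TrialTable(df), ["cue", "belief", "belief2"])
        with pytest.raises(RankDeficiencyError):
            fit_outcome_model(centered, (Mediator("belief", "global"),
                                         Mediator("belief2", "global")))

    def test_recovers_generating_fixed_effects(self, recovery_table):
        table, truth = recovery_table
        from beliefmed import apply_exclusions
        clean, _ = apply_exclusions(table)
        centered = group_mean_center(clean, ["cue", "belief"])
        fit, _ = fit_outcome_model(centered, (Mediator("belief", "global"),))
        b_hat = fit.params.loc["belief_c"]
        c_hat = fit.params.loc["cue_c"]
        assert abs(b_hat["Estimate"] - truth.b) < 3 * b_hat["SE"]
        assert abs(c_hat["Estimate"] - truth.c_prime) < 3 * c_hat["SE"]


class TestMediate:
    def test_indirect_effect_identity_and_decomposition(self, recovery_table):
        """On balanced data with all random slopes pruned the OLS
        mediation identity a*b + c' = total cue slope holds; with the
        engine, ind == a*b exactly whenever cov_ab = 0."""
        table, _ = recovery_table
        res = mediate(table, MediationConfig(seed=0))
        row = res.paths.loc["belief"]
        np.testing.assert_allclose(row["ind"], row["a"] * row["b"] + row["cov_ab"],
                                   rtol=0, atol=0)  # exact identity
        assert row["cov_ab"] == 0.0

    def test_ols_decomposition_oracle(self):
        """Fixed-only path: a*b + c' equals the total-effect slope from
        regressing JOL on cue alone (classic OLS identity), checked on
        random small balanced tables."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            J, T = 6, 4
            rows = []
            for j in range(J):
                b1, b2 = rng.normal(60, 10), rng.normal(50, 10)
                for cue, b in ((1.0, b1), (-1.0, b2)):
                    for _ in range(T):
                        rows.append((f"p{j}", cue, b,
                                     50 + 0.4 * b + 2 * cue + rng.normal(0, 5)))
            table = TrialTable(pd.DataFrame(
                rows, columns=["participant", "cue", "belief", "jol"]))
            centered = group_mean_center(table, ["cue", "belief"])
            a = fit_lmm(LmmSpec("belief_c", ("cue_c",)), centered) \
                .params.loc["cue_c", "Estimate"]
            out = fit_lmm(LmmSpec("jol", ("cue_c", "belief_c")), centered)
            b = out.params.loc["belief_c", "Estimate"]
            cp = out.params.loc["cue_c", "Estimate"]
            total = fit_lmm(LmmSpec("jol", ("cue_c",)), centered) \
                .params.loc["cue_c", "Estimate"]
            np.testing.assert_allclose(a * b + cp, total, atol=1e-6)

    def test_null_indirect_effect_covered_by_ci(self):
        """With b = 0 the indirect effect is null: over seeded
        replicates the MC interval covers 0 at least 90% of the time."""
        truth = SynthTruth(b=0.0, sd_b_slope=0.0)
        covered = 0
        reps = 20
        for seed in range(reps):
            table, _ = generate_mediation_dataset(truth, 25, 10, seed=seed)
            res = mediate(table, MediationConfig(mc_draws=1000, seed=seed))
            lo, hi = res.paths.loc["belief", ["mc_lower", "mc_upper"]]
            covered += lo <= 0.0 <= hi
        assert covered >= 0.9 * reps

    def test_two_mediator_contrast_recovers_truth(self):
        truth = SynthTruth(include_fluency=True)
        table, _ = generate_mediation_dataset(truth, 40, 20, seed=77)
        res = mediate(table, MediationConfig(
            mediators=(Mediator("belief", "global"),
                       Mediator("fluency", "item_varying")),
            seed=3))
        ind_b = res.paths.loc["belief", "ind"]
        ind_f = res.paths.loc["fluency", "ind"]
        np.testing.assert_allclose(res.diff_ind, ind_f - ind_b, rtol=1e-12)
        lo, hi = res.diff_ind_ci
        assert lo < res.diff_ind < hi
        # proportions and c' recompose the total effect
        np.testing.assert_allclose(ind_b + ind_f + res.c_prime, res.total,
                                   rtol=1e-12)

    def test_compare_mediators_requires_two(self, recovery_table):
        table, _ = recovery_table
        res = mediate(table, MediationConfig(seed=0))
        with pytest.raises(ValueError, match="two"):
            compare_mediators(res)

    def test_seeded_mc_reproducible(self, recovery_table):
        table, _ = recovery_table
        r1 = mediate(table, MediationConfig(seed=11))
        r2 = mediate(table, MediationConfig(seed=11))
        pd.testing.assert_frame_equal(r1.paths, r2.paths)

    def test_model_object_roundtrip(self, recovery_table):
        table, _ = recovery_table
        model = MultilevelMediation(table, mediators=("belief",))
        res = model.fit(seed=1, mc_draws=2000)
        assert "belief" in res.summary()
        d = res.to_dict()
        assert d["mediators"]["belief"]["a"] == pytest.approx(
            res.paths.loc["belief", "a"])


class TestRandomSlopeComparison:
    def test_true_slope_variance_favors_slope_model(self):
        truth = SynthTruth(sd_b_slope=0.8)
        wins = 0
        for seed in range(5):
            table, _ = generate_mediation_dataset(truth, 40, 20, seed=seed)
            comp = compare_random_slope_b(table)
            if comp.usable and comp.preferred == "random belief slope":
                wins += 1
        assert wins >= 3

    def test_no_slope_variance_favors_simpler_model(self):
        truth = SynthTruth(sd_b_slope=0.0)
        wins = 0
        for seed in range(5):
            table, _ = generate_mediation_dataset(truth, 40, 20, seed=100 + seed)
            comp = compare_random_slope_b(table)
            if comp.usable and comp.preferred == "no random belief slope":
                wins += 1
        assert wins >= 3
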