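"""Mixed-model fitting, the statsmodels cross-check, and BIC selection."""

import numpy as np
import pandas as pd
import pytest

from camobreak.lmm_selection import (
    ModelSpec,
    default_maximal_spec,
    fit,
    recovery_maximal_spec,
    recovery_study,
    report,
    simplify,
    term_parents,
)
from camobreak.session_pipeline import derive_covariates, filter_events
from camobreak.synthetic_data import BehaviorModel, simulate_study


@pytest.fixture(scope="module")
def small_table(scene_library, behavior):
    events = simulate_study(30, scene_library, behavior, seed=11)
    retained, _ = filter_events(events)
    return derive_covariates(retained, scene_library.metrics, "near")


@pytest.fixture(scope="module")
def big_table(scene_library, behavior):
    events = simulate_study(250, scene_library, behavior, seed=42)
    retained, _ = filter_events(events)
    return derive_covariates(retained, scene_library.metrics, "near")


SIMPLE_SPEC = ModelSpec(
    fixed_terms=(
        "log_edge_dist",
        "slide_number",
        "viewing_condition",
        "log_pattern_diff",
        "viewing_condition:log_pattern_diff",
    ),
    random_terms=("session_id", "photo_id"),
)


class TestFitAgainstStatsmodels:
    """The crossed random-intercept fit must agree with MixedLM exactly."""

    @pytest.mark.parametrize("reml", [False, True])
    def test_llf_and_coefficients_match(self, small_table, reml):
        import statsmodels.formula.api as smf

        spec = SIMPLE_SPEC if not reml else ModelSpec(
            fixed_terms=SIMPLE_SPEC.fixed_terms,
            random_terms=SIMPLE_SPEC.random_terms,
            estimation="REML",
        )
        ours = fit(small_table, spec)

        df = small_table.copy()
        df["g"] = 1
        sm_model = smf.mixedlm(
            "log_capture_time ~ log_edge_dist + slide_number"
            " + C(viewing_condition, Treatment('trichromat'))"
            " + log_pattern_diff"
            " + C(viewing_condition, Treatment('trichromat')):log_pattern_diff",
            df,
            groups="g",
            vc_formula={
                "session_id": "0 + C(session_id)",
                "photo_id": "0 + C(photo_id)",
            },
        )
        sm_res = sm_model.fit(reml=reml, method="lbfgs")
        assert ours.llf == pytest.approx(sm_res.llf, abs=1e-4)
        assert ours.params.to_numpy() == pytest.approx(
            sm_res.fe_params.to_numpy(), abs=1e-4
        )
        assert ours.bse.to_numpy() == pytest.approx(
            sm_res.bse_fe.to_numpy(), rel=1e-2
        )

    def test_bic_identity(self, small_table):
        r = fit(small_table, SIMPLE_SPEC)
        assert r.bic == pytest.approx(-2 * r.llf + r.k_params * np.log(r.n))

    def test_viewing_coefficient_recovered_within_3_se(self, big_table, behavior):
        r = fit(big_table, recovery_maximal_spec())
        name = [c for c in r.params.index if c.endswith("[T.dichromat]")][0]
        z = (r.params[name] - behavior.b_viewing) / r.bse[name]
        assert abs(z) < 3.0


class TestFitEdgeCases:
    def test_constant_response_degenerate_fit(self):
        n = 40
        table = pd.DataFrame(
            {
                "log_capture_time": np.full(n, 1.25),
                "session_id": np.repeat([f"s{i}" for i in range(8)], 5),
                "photo_id": np.tile([f"p{i}" for i in range(5)], 8),
            }
        )
        spec = ModelSpec(fixed_terms=(), random_terms=("session_id",),)
        r = fit(table, spec)
        assert r.params.iloc[0] == pytest.approx(1.25)
        assert r.sigma_resid == pytest.approx(0.0, abs=1e-5)

    def test_rank_deficient_design_lists_aliased(self, small_table):
        df = small_table.copy()
        df["dup"] = df["log_pattern_diff"]
        spec = ModelSpec(
            fixed_terms=("log_pattern_diff", "dup"),
            random_terms=("session_id",),
        )
        with pytest.raises(ValueError, match="aliased"):
            fit(df, spec)

    def test_single_level_random_factor_rejected(self, small_table):
        df = small_table.copy()
        df["one"] = "x"
        with pytest.raises(ValueError, match="levels"):
            fit(df, ModelSpec(fixed_terms=(), random_terms=("one",), base_random=("one",)))

    def test_marginality_enforced_in_spec(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(fixed_terms=("viewing_condition:log_pattern_diff",))

    def test_term_parents(self):
        assert term_parents("a:b") == ("a", "b")
        assert term_parents("I(slide_number ** 2)") == ("slide_number",)
        assert term_parents("slide_number") == ()


@pytest.fixture(scope="module")
def selection(big_table):
    return simplify(big_table, recovery_maximal_spec())


class TestSimplify:
    def test_true_interaction_kept_null_dropped(self, selection):
        final_spec, _ = selection
        assert "viewing_condition:log_pattern_diff" in final_spec.fixed_terms
        assert "viewing_condition:bg_contrast" not in final_spec.fixed_terms

    def test_both_random_intercepts_retained(self, selection):
        final_spec, _ = selection
        assert set(final_spec.random_terms) == {"session_id", "photo_id"}

    def test_accepted_steps_decrease_bic_within_phase(self, selection):
        _, trace = selection
        for phase in ("drop-fixed", "add-random", "re-drop-fixed"):
            steps = [s for s in trace.accepted() if s.phase == phase]
            for s in steps:
                assert s.bic_after < s.bic_before + 1e-6

    def test_marginality_preserved_throughout(self, selection):
        final_spec, _ = selection
        for t in final_spec.fixed_terms:
            for parent in term_parents(t):
                assert parent in final_spec.fixed_terms

    def test_final_bic_not_above_maximal_with_same_randoms(self, big_table, selection):
        final_spec, _ = selection
        maximal = recovery_maximal_spec()
        max_refit = fit(
            big_table,
            ModelSpec(
                fixed_terms=maximal.fixed_terms,
                random_terms=final_spec.random_terms,
                base_random=maximal.base_random,
            ),
        )
        final_fit = fit(big_table, final_spec)
        assert final_fit.bic <= max_refit.bic + 1e-6

    def test_selection_invariant_to_row_permutation(self, big_table):
        perm = np.random.default_rng(7).permutation(len(big_table))
        shuffled = big_table.iloc[perm].reset_index(drop=True)
        spec_a, _ = simplify(big_table, recovery_maximal_spec())
        spec_b, _ = simplify(shuffled, recovery_maximal_spec())
        assert set(spec_a.fixed_terms) == set(spec_b.fixed_terms)
        assert set(spec_a.random_terms) == set(spec_b.random_terms)

    def test_null_effects_reduce_toward_nuisance_model(self, scene_library):
        bm = BehaviorModel(
            b_pattern=0.0,
            b_lumdiff=0.0,
            b_area=0.0,
            b_bglum=0.0,
            b_viewing=0.0,
            i_view_pattern=0.0,
            i_view_lumdiff=0.0,
            i_view_area=0.0,
            i_view_bglum=0.0,
        )
        events = simulate_study(250, scene_library, bm, seed=77)
        retained, _ = filter_events(events)
        table = derive_covariates(retained, scene_library.metrics, "near")
        final_spec, _ = simplify(table, recovery_maximal_spec())
        camo_terms = {
            t
            for t in final_spec.fixed_terms
            if any(
                c in t
                for c in ("pattern", "lum_dist", "target_area", "bg_lum", "bg_contrast")
            )
        }
        # most camouflage terms vanish; the simulated nuisance terms survive
        assert len(camo_terms) <= 2
        assert "slide_number" in final_spec.fixed_terms
        assert "log_edge_dist" in final_spec.fixed_terms


class TestReport:
    def test_report_structure_and_determinism(self, big_table):
        final_spec, trace = simplify(big_table, recovery_maximal_spec())
        final = fit(big_table, final_spec)
        rep1 = report(final, trace, scope="near")
        rep2 = report(fit(big_table, final_spec), trace, scope="near")
        assert rep1["summary"] == rep2["summary"]
        assert len(rep1["terms"]) == len(final_spec.fixed_terms)
        # every interaction row appears after both of its parents
        labels = list(rep1["terms"]["term"])
        for t in labels:
            for parent in term_parents(t):
                assert labels.index(parent) < labels.index(t)
        assert "logNearPatternDiff" in set(rep1["terms"]["label"]) or (
            "viewingCondition:logNearPatternDiff" in set(rep1["terms"]["label"])
        )


class TestRecoveryStudy:
    def test_end_to_end_recovery(self, scene_library, behavior):
        res = recovery_study(200, scene_library, behavior, seed=5)
        assert "viewing_condition:log_pattern_diff" in res.final_spec.fixed_terms
        assert res.n_retained <= res.n_events
        assert res.final_fit.converged
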