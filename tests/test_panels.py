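"""UDR scoring and panel search, including exhaustive-oracle checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from udrpanel import (
    ExpressionMatrix,
    FeatureSpec,
    PanelAssignment,
    PanelEvaluation,
    SyntheticDesign,
    assign_directions,
    backward_search,
    delta_ct_to_linear,
    enumerate_panels,
    evaluate_panel,
    exhaustive_search,
    gen_qpcr_cohort,
    normalize_delta_ct,
    select_optimal,
    udr_score,
    udr_scores,
)
from udrpanel.stats import DifferentialResult, RocResult

from conftest import toy_cohort, toy_matrix


def linear_cohort(features, seed=0, n_benign=50, n_case=50, stage="I"):
    design = SyntheticDesign(
        features=features, n_benign=n_benign, n_stage={stage: n_case}, seed=seed
    )
    m, meta = gen_qpcr_cohort(design)
    return delta_ct_to_linear(normalize_delta_ct(m, design.spike_in_id)), meta


class TestUdrScore:
    def test_hand_worked_ratio(self):
        # up mean 8, down mean (2+6)/2 = 4 -> UDR 2
        expr = toy_matrix({"u": [8.0], "d1": [2.0], "d2": [6.0]}, ["S1"], "linear")
        panel = PanelAssignment(["u"], ["d1", "d2"])
        assert udr_score(expr, panel, "S1") == 2.0

    def test_equal_members_give_unity(self):
        expr = toy_matrix({"u": [5.0], "d": [5.0]}, ["S1"], "linear")
        assert udr_score(expr, PanelAssignment(["u"], ["d"]), "S1") == 1.0

    @given(st.floats(0.01, 1000.0))
    def test_scale_invariance(self, c):
        expr = toy_matrix(
            {"u": [8.0, 3.0], "d1": [2.0, 9.0], "d2": [6.0, 1.0]}, ["S1", "S2"], "linear"
        )
        scaled = ExpressionMatrix(expr.data * c, "linear")
        panel = PanelAssignment(["u"], ["d1", "d2"])
        s1, _ = udr_scores(expr, panel)
        s2, _ = udr_scores(scaled, panel)
        assert np.allclose(s1, s2, rtol=1e-9)

    def test_missing_member_sample_skipped(self):
        expr = toy_matrix(
            {"u": [8.0, np.nan], "d": [2.0, 3.0]}, ["S1", "S2"], "linear"
        )
        scores, skipped = udr_scores(expr, PanelAssignment(["u"], ["d"]))
        assert list(scores.index) == ["S1"] and skipped == ["S2"]
        with pytest.raises(ValueError, match="missing"):
            udr_score(expr, PanelAssignment(["u"], ["d"]), "S2")

    def test_non_linear_scale_rejected(self):
        expr = toy_matrix({"u": [1.0], "d": [-2.0]}, ["S1"], "delta_ct")
        with pytest.raises(ValueError, match="linear"):
            udr_scores(expr, PanelAssignment(["u"], ["d"]))


class TestPanelAssignment:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PanelAssignment(["a"], ["a", "b"])

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            PanelAssignment([], ["b"])


class TestAssignDirections:
    def test_from_differential_results(self):
        results = [
            DifferentialResult("miR-150-5p", 0.678, 0.001, "delta_ct_means"),
            DifferentialResult("miR-497-5p", -1.322, 0.001, "delta_ct_means"),
            DifferentialResult("miR-610", -1.766, 0.03, "delta_ct_means"),
        ]
        up, down = assign_directions(results)
        assert up == {"miR-150-5p"} and down == {"miR-497-5p", "miR-610"}

    def test_single_direction_rejected(self):
        with pytest.raises(ValueError, match="both directions"):
            assign_directions([DifferentialResult("a", 1.0, 0.01, "t")])

    def test_flat_feature_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            assign_directions(
                [
                    DifferentialResult("a", 1.0, 0.01, "t"),
                    DifferentialResult("b", 0.0, 0.9, "t"),
                ]
            )

    def test_from_dataframe(self):
        df = pd.DataFrame(
            {"feature_id": ["a", "b"], "direction": ["up", "down"]}
        )
        assert assign_directions(df) == ({"a"}, {"b"})


class TestEnumeratePanels:
    @pytest.mark.parametrize(
        "n_up, n_down, expected",
        [(1, 5, 31), (1, 1, 1), (2, 3, 21)],
    )
    def test_subset_product_count(self, n_up, n_down, expected):
        panels = enumerate_panels(
            [f"u{i}" for i in range(n_up)], [f"d{i}" for i in range(n_down)]
        )
        assert len(panels) == expected
        assert len(set(panels)) == expected  # all distinct

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            enumerate_panels([], ["d"])


class TestEvaluatePanel:
    def test_strong_opposite_effects_give_high_auc(self):
        expr, meta = linear_cohort(
            [
                FeatureSpec("u", effect_log2fc=2.0, sigma=0.3),
                FeatureSpec("d", effect_log2fc=-2.0, sigma=0.3),
            ],
            seed=4,
        )
        ev = evaluate_panel(expr, meta, PanelAssignment(["u"], ["d"]), ("I",))
        assert ev.auc >= 0.95

    def test_null_panel_near_half(self):
        expr, meta = linear_cohort(
            [FeatureSpec("u", sigma=1.0), FeatureSpec("d", sigma=1.0)],
            seed=6, n_benign=200, n_case=200,
        )
        ev = evaluate_panel(expr, meta, PanelAssignment(["u"], ["d"]), ("I",))
        assert ev.auc == pytest.approx(0.5, abs=0.05)

    def test_samples_with_missing_members_excluded_and_recorded(self):
        expr = toy_matrix(
            {
                "u": [4.0, 4.0, 8.0, np.nan, 8.0, 8.0],
                "d": [8.0, 8.0, 4.0, 4.0, 4.0, 4.0],
            },
            ["B0", "B1", "T0", "T1", "T2", "T3"],
            "linear",
        )
        meta = toy_cohort(2, 4)
        ev = evaluate_panel(expr, meta, PanelAssignment(["u"], ["d"]), ("I",))
        assert ev.skipped_samples == ["T1"]
        assert "T1" not in ev.udr_scores.index

    def test_too_few_evaluable_samples_rejected(self):
        expr = toy_matrix(
            {"u": [4.0, np.nan, 8.0, 8.0], "d": [8.0, 8.0, 4.0, 4.0]},
            ["B0", "B1", "T0", "T1"],
            "linear",
        )
        meta = toy_cohort(2, 2)
        with pytest.raises(ValueError, match="fewer than 2"):
            evaluate_panel(expr, meta, PanelAssignment(["u"], ["d"]), ("I",))


class TestBackwardSearch:
    def test_minimal_panel_has_unit_path(self):
        expr, meta = linear_cohort(
            [FeatureSpec("u", effect_log2fc=1.0), FeatureSpec("d", effect_log2fc=-1.0)]
        )
        path = backward_search(expr, meta, {"u"}, {"d"}, ("I",))
        assert len(path) == 1

    def test_tie_broken_by_lexicographic_member(self):
        # two identical pure-noise members: removing either changes the AUC
        # identically, so the lexicographically smaller one must go first
        rng = np.random.default_rng(2)
        n = 30
        up = 2.0 ** rng.normal(1.0, 0.4, 2 * n)
        up[:n] = 2.0 ** rng.normal(-1.0, 0.4, n)
        down = 2.0 ** rng.normal(-1.0, 0.4, 2 * n)
        down[:n] = 2.0 ** rng.normal(1.0, 0.4, n)
        noise = 2.0 ** rng.normal(0.0, 1.5, 2 * n)
        samples = [f"B{i}" for i in range(n)] + [f"T{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(
                {"u": up, "d": down, "na": noise, "nb": noise}, index=samples
            ).T,
            "linear",
        )
        meta = toy_cohort(n, n)
        path = backward_search(expr, meta, {"u"}, {"d", "na", "nb"}, ("I",))
        assert len(path) >= 2
        removed_first = set(path[0].panel.members) - set(path[1].panel.members)
        assert removed_first == {"na"}

    def test_noise_member_eliminated_first_in_designed_regime(self):
        # moderate real effects + one pure-noise member: non-saturated AUC,
        # so removing the noise member is identifiably the best single move
        hits = 0
        for seed in range(100):
            expr, meta = linear_cohort(
                [
                    FeatureSpec("u", effect_log2fc=1.5, sigma=1.0),
                    FeatureSpec("d1", effect_log2fc=-1.5, sigma=1.0),
                    FeatureSpec("d2", effect_log2fc=-1.5, sigma=1.0),
                    FeatureSpec("zz-noise", effect_log2fc=0.0, sigma=1.0),
                ],
                seed=seed, n_benign=200, n_case=200,
            )
            path = backward_search(expr, meta, {"u"}, {"d1", "d2", "zz-noise"}, ("I",))
            if len(path) >= 2 and "zz-noise" not in path[1].panel.members:
                hits += 1
        assert hits >= 90

    def test_exhaustive_oracle_dominates_backward_search(self):
        # greedy elimination can never beat the full enumeration
        rng = np.random.default_rng(42)
        for trial in range(15):
            n_up = int(rng.integers(1, 4))
            n_down = int(rng.integers(1, 8 - n_up - 2)) if n_up < 5 else 1
            n_down = max(n_down, 1)
            features = [
                FeatureSpec(f"u{i}", effect_log2fc=float(rng.uniform(0, 1.5)), sigma=1.0)
                for i in range(n_up)
            ] + [
                FeatureSpec(f"d{i}", effect_log2fc=float(-rng.uniform(0, 1.5)), sigma=1.0)
                for i in range(n_down)
            ]
            expr, meta = linear_cohort(features, seed=100 + trial, n_benign=30, n_case=30)
            ups = {f"u{i}" for i in range(n_up)}
            downs = {f"d{i}" for i in range(n_down)}
            exhaustive = exhaustive_search(expr, meta, ups, downs, ("I",))
            assert len(exhaustive) == (2 ** n_up - 1) * (2 ** n_down - 1)
            best = max(e.auc for e in exhaustive)
            final = backward_search(expr, meta, ups, downs, ("I",))[-1]
            assert best >= final.auc - 1e-12


class TestLogUdrClosedForm:
    def test_population_auc_matches_normal_theory(self):
        # log-UDR of independent log2-normal members is exactly normal:
        # AUC = Phi(Delta / sqrt(2 * (1/N + 1/M))) for unit member variance
        deltas_up = {"u1": 1.0, "u2": 0.6}
        deltas_down = {"d1": -0.8, "d2": -1.2, "d3": -0.5}
        features = [
            FeatureSpec(f, effect_log2fc=e, sigma=1.0)
            for f, e in {**deltas_up, **deltas_down}.items()
        ]
        expr, meta = linear_cohort(features, seed=77, n_benign=10_000, n_case=10_000)
        panel = PanelAssignment(deltas_up, deltas_down)
        ev = evaluate_panel(expr, meta, panel, ("I",), log_scale=True)
        delta = np.mean(list(deltas_up.values())) + np.mean(
            [abs(v) for v in deltas_down.values()]
        )
        v = 1 / len(deltas_up) + 1 / len(deltas_down)
        expected = norm.cdf(delta / np.sqrt(2 * v))
        assert ev.auc == pytest.approx(expected, abs=0.01)


def _fake_eval(members_up, members_down, auc):
    roc = RocResult(
        points=np.array([[0.0, 0.0], [1.0, 1.0]]),
        auc=auc, ci_low=auc, ci_high=auc, n_case=10, n_control=10,
    )
    panel = PanelAssignment(members_up, members_down)
    return PanelEvaluation(panel=panel, udr_scores=pd.Series(dtype=float), roc=roc)


class TestSelectOptimal:
    def test_parsimony_prefers_small_near_best_panels(self):
        evals = [
            _fake_eval(["u"], ["a", "b", "c", "d", "e"], 0.897),   # 6-panel
            _fake_eval(["u"], ["a", "b", "c"], 0.952),             # 4-panel
            _fake_eval(["u"], ["a", "b"], 0.940),                  # 3-panel
        ]
        ranked = select_optimal(evals, parsimony_epsilon=0.02)
        assert [e.panel.size for e in ranked] == [3, 4]
        assert ranked[0].auc == 0.940 and ranked[1].auc == 0.952

    def test_zero_epsilon_keeps_only_argmax(self):
        evals = [_fake_eval(["u"], ["a"], 0.8), _fake_eval(["u"], ["b"], 0.9)]
        ranked = select_optimal(evals, parsimony_epsilon=0.0)
        assert len(ranked) == 1 and ranked[0].auc == 0.9

    def test_single_evaluation_returned(self):
        evals = [_fake_eval(["u"], ["a"], 0.7)]
        assert select_optimal(evals) == evals

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            select_optimal([])
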