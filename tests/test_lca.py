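"""Latent-class engine tests: exhaustive-enumeration oracles, EM
monotonicity, closed-form degenerate cases, parameter recovery, and
label-switching invariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aedesid.lca import (
    LabelingError,
    LcaFit,
    LcaModel,
    align_classes,
    all_patterns,
    assign_classes,
    fit_em,
    goodness_of_fit,
    label_classes,
    pattern_probability,
    select_model,
)
from aedesid.qpcr_io import AEGYPTI, NO_DETECTION, PatternRow, SIERRENSIS
from aedesid.simulate import SimConfig, default_edna_params, generate_edna_panel
from aedesid.qpcr_io import to_patterns


def _patterns_from_model(model: LcaModel, n: int, seed: int) -> list[PatternRow]:
    """Independent sampler used as the generating oracle for EM tests."""
    rng = np.random.default_rng(seed)
    classes = rng.choice(model.n_classes, size=n, p=model.prevalence)
    rows = []
    for i, r in enumerate(classes):
        y = rng.random(model.n_indicators) < model.response[:, r]
        rows.append(PatternRow(f"s{i}", tuple(2 if v else 1 for v in y)))
    return rows


def _sep2_model() -> LcaModel:
    """Two well-separated classes: 0.95 on own block, 0.05 elsewhere."""
    response = np.array([[0.95] * 3 + [0.05] * 3, [0.05] * 3 + [0.95] * 3]).T
    return LcaModel(prevalence=np.array([0.5, 0.5]), response=response)


class TestPatternProbability:
    def test_uniform_single_class(self):
        model = LcaModel(prevalence=[1.0], response=np.full((6, 1), 0.5))
        assert pattern_probability(model, (2, 1, 2, 1, 1, 2)) == pytest.approx(1 / 64)

    def test_degenerate_mixture_reduces_to_first_class(self):
        response = np.column_stack([np.linspace(0.1, 0.9, 6), np.full(6, 0.5)])
        model = LcaModel(prevalence=[1.0, 0.0], response=response)
        single = LcaModel(prevalence=[1.0], response=response[:, :1])
        for pattern in [(1,) * 6, (2,) * 6, (2, 1, 2, 1, 2, 1)]:
            assert pattern_probability(model, pattern) == pytest.approx(
                pattern_probability(single, pattern)
            )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), r=st.integers(1, 4))
    def test_probabilities_sum_to_one_over_all_64_patterns(self, seed, r):
        rng = np.random.default_rng(seed)
        model = LcaModel(
            prevalence=rng.dirichlet(np.ones(r)),
            response=rng.uniform(0.01, 0.99, size=(6, r)),
        )
        total = sum(pattern_probability(model, p) for p in all_patterns())
        assert total == pytest.approx(1.0, abs=1e-10)


class TestFitEm:
    def test_single_class_closed_form(self):
        patterns = _patterns_from_model(_sep2_model(), n=200, seed=4)
        fit = fit_em(patterns, n_classes=1, n_starts=1, seed=0)
        y = np.array([[v - 1 for v in p.indicators] for p in patterns], dtype=float)
        freqs = y.mean(axis=0)
        assert fit.model.prevalence == pytest.approx([1.0])
        assert fit.model.response[:, 0] == pytest.approx(freqs, abs=1e-6)
        closed_form = float(
            np.sum(y * np.log(freqs) + (1 - y) * np.log(1 - freqs))
        )
        assert fit.loglik == pytest.approx(closed_form, abs=1e-6)

    def test_loglik_monotone_every_iteration(self):
        patterns = _patterns_from_model(_sep2_model(), n=150, seed=5)
        fit = fit_em(patterns, n_classes=3, n_starts=3, seed=1)
        history = np.array(fit.loglik_history)
        assert (np.diff(history) >= -1e-9).all()

    def test_two_class_parameter_recovery(self):
        truth = _sep2_model()
        patterns = _patterns_from_model(truth, n=600, seed=7)
        fit = fit_em(patterns, n_classes=2, n_starts=10, seed=2)
        perm = align_classes(fit.model, truth.response)
        assert np.abs(fit.model.response[:, perm] - truth.response).max() < 0.05
        assert np.abs(fit.model.prevalence[perm] - truth.prevalence).max() < 0.05

    def test_converged_beats_generating_parameters_on_tiny_data(self):
        truth = _sep2_model()
        patterns = _patterns_from_model(truth, n=8, seed=9)
        fit = fit_em(patterns, n_classes=2, n_starts=10, seed=3)
        truth_ll = float(
            sum(math.log(pattern_probability(truth, p)) for p in patterns)
        )
        assert fit.loglik >= truth_ll - 1e-9

    def test_posterior_rows_sum_to_one(self):
        patterns = _patterns_from_model(_sep2_model(), n=100, seed=11)
        fit = fit_em(patterns, n_classes=2, n_starts=3, seed=4)
        assert fit.posterior.sum(axis=1) == pytest.approx(np.ones(100))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_em([], n_classes=2)
        with pytest.raises(ValueError):
            fit_em([PatternRow("s", (1,) * 6)], n_classes=0)


class TestGoodnessOfFit:
    def test_perfect_fit_has_zero_statistics(self):
        # one copy of every pattern: empirical = uniform = 1-class 0.5 model
        patterns = [PatternRow(f"s{i}", p) for i, p in enumerate(all_patterns())]
        fit = fit_em(patterns, n_classes=1, n_starts=1, seed=0)
        g2, chi2, _ = goodness_of_fit(fit, patterns)
        assert g2 == pytest.approx(0.0, abs=1e-6)
        assert chi2 == pytest.approx(0.0, abs=1e-6)

    def test_three_class_parameter_count_and_df(self):
        patterns = _patterns_from_model(_sep2_model(), n=100, seed=13)
        fit = fit_em(patterns, n_classes=3, n_starts=2, seed=5)
        assert fit.model.n_params == 20
        assert fit.df_fit == 64 - 1 - 20 == 43

    def test_g_squared_identity_with_saturated_likelihood(self):
        patterns = _patterns_from_model(_sep2_model(), n=300, seed=15)
        fit = fit_em(patterns, n_classes=2, n_starts=5, seed=6)
        n = len(patterns)
        counts: dict[tuple, int] = {}
        for p in patterns:
            counts[p.indicators] = counts.get(p.indicators, 0) + 1
        loglik_saturated = sum(o * math.log(o / n) for o in counts.values())
        assert fit.g_squared == pytest.approx(
            2 * (loglik_saturated - fit.loglik), abs=1e-6
        )


class TestSelectModel:
    def test_recovers_three_classes_from_default_generator(self):
        ds = generate_edna_panel(default_edna_params(), SimConfig(seed=21, n_sites=500))
        fit, table = select_model(to_patterns(ds), (2, 3, 4), n_starts=8, seed=7)
        assert fit.model.n_classes == 3
        assert table.attrs["criterion_choices"]["bic"] == 3

    def test_single_class_data_prefers_one_class(self):
        model = LcaModel(prevalence=[1.0], response=np.full((6, 1), 0.4))
        patterns = _patterns_from_model(model, n=400, seed=23)
        fit, _ = select_model(patterns, (1, 2, 3), n_starts=5, seed=8)
        assert fit.model.n_classes == 1

    def test_comparison_table_shape(self):
        patterns = _patterns_from_model(_sep2_model(), n=120, seed=25)
        _, table = select_model(patterns, (2, 3), n_starts=2, seed=9)
        assert list(table.index) == [2, 3]
        for col in ("aic", "bic", "g_squared", "chi_squared"):
            assert col in table.columns


def _fit_for_model(model: LcaModel, patterns=None) -> LcaFit:
    """Wrap a known model in an LcaFit for labeling/assignment tests."""
    patterns = patterns or [PatternRow("p0", (1,) * 6)]
    from aedesid.lca import _loglik_and_posterior, _to_binary

    y = _to_binary(patterns)
    ll, post = _loglik_and_posterior(y, np.ones(len(patterns)), model)
    g2, chi2, df = goodness_of_fit(model, patterns)
    return LcaFit(
        model=model, loglik=ll, aic=0, bic=0, g_squared=g2, chi_squared=chi2,
        df_fit=df, converged=True, n_iterations=0, posterior=post,
        n_obs=len(patterns), sample_ids=[p.sample_id for p in patterns],
    )


def _three_class_model() -> LcaModel:
    response = np.array(
        [
            [0.95, 0.95, 0.95, 0.04, 0.04, 0.04],  # sierrensis-like
            [0.05, 0.05, 0.05, 0.93, 0.93, 0.93],  # aegypti-like
            [0.02, 0.02, 0.02, 0.03, 0.03, 0.03],  # silent
        ]
    ).T
    return LcaModel(prevalence=[1 / 3] * 3, response=response)


class TestLabeling:
    def test_profiles_force_the_mapping(self):
        labeling = label_classes(_fit_for_model(_three_class_model()))
        assert labeling.mapping == {0: SIERRENSIS, 1: AEGYPTI, 2: NO_DETECTION}
        assert labeling.separation_score > 0.5

    def test_permuting_classes_permutes_mapping(self):
        base = _three_class_model()
        perm = [2, 0, 1]
        permuted = LcaModel(
            prevalence=base.prevalence[perm], response=base.response[:, perm]
        )
        labeling = label_classes(_fit_for_model(permuted))
        assert labeling.mapping == {1: SIERRENSIS, 2: AEGYPTI, 0: NO_DETECTION}

    def test_indistinguishable_profiles_raise(self):
        flat = LcaModel(prevalence=[0.5, 0.5], response=np.full((6, 2), 0.5))
        with pytest.raises(LabelingError):
            label_classes(_fit_for_model(flat))

    def test_weak_separation_raises(self):
        response = np.array(
            [[0.52, 0.5, 0.5], [0.52, 0.5, 0.5], [0.52, 0.5, 0.5],
             [0.48, 0.5, 0.5], [0.48, 0.5, 0.5], [0.48, 0.5, 0.5]]
        )
        weak = LcaModel(prevalence=[1 / 3] * 3, response=response)
        with pytest.raises(LabelingError, match="separation"):
            label_classes(_fit_for_model(weak))

    def test_label_switching_leaves_criteria_unchanged(self):
        base = _three_class_model()
        patterns = _patterns_from_model(base, n=100, seed=31)
        perm = [1, 2, 0]
        permuted = LcaModel(
            prevalence=base.prevalence[perm], response=base.response[:, perm]
        )
        for pattern in all_patterns():
            assert pattern_probability(base, pattern) == pytest.approx(
                pattern_probability(permuted, pattern)
            )
        g_base = goodness_of_fit(base, patterns)
        g_perm = goodness_of_fit(permuted, patterns)
        assert g_base == pytest.approx(g_perm)


class TestAssignClasses:
    def test_bayes_oracle_for_clear_patterns(self):
        model = _three_class_model()
        patterns = [
            PatternRow("sierr", (2, 2, 2, 1, 1, 1)),
            PatternRow("silent", (1, 1, 1, 1, 1, 1)),
        ]
        fit = _fit_for_model(model, patterns)
        labeling = label_classes(fit)
        assigned = assign_classes(fit, labeling, patterns)
        by_id = assigned.set_index("sample_id")
        assert by_id.loc["sierr", "assigned_class"] == SIERRENSIS
        assert by_id.loc["sierr", "posterior"] > 0.99
        assert by_id.loc["silent", "assigned_class"] == NO_DETECTION
        # independent Bayes computation by enumeration
        joint = [
            model.prevalence[r]
            * np.prod(
                [
                    model.response[j, r] if v == 2 else 1 - model.response[j, r]
                    for j, v in enumerate(patterns[0].indicators)
                ]
            )
            for r in range(3)
        ]
        assert by_id.loc["sierr", "posterior"] == pytest.approx(
            joint[0] / sum(joint), abs=1e-9
        )
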