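"""Rate-constant fitting: exact recoveries, closed-form oracles, replicate
statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pcmkin
from pcmkin.exceptions import FitError, KineticsDomainError
from pcmkin.rates import (
    estimate_order,
    fit_pseudo_first_order,
    fit_second_order_mixed,
    replicate_agreement,
    second_order_from_pseudo,
    titre_to_concentration,
)
from pcmkin.units import concentration_to_titre


class TestTitreConversion:
    @pytest.mark.parametrize(
        "titre, normality, aliquot, expected",
        [
            (0.0, 0.01, 10.0, 0.0),
            (4.0, 0.01, 10.0, 2.0e-3),
            (2.5, 0.02, 5.0, 5.0e-3),
        ],
    )
    def test_direct_arithmetic(self, titre, normality, aliquot, expected):
        assert titre_to_concentration(titre, normality, aliquot) == pytest.approx(
            expected, rel=1e-15)

    def test_zero_aliquot_is_domain_error(self):
        with pytest.raises(KineticsDomainError):
            titre_to_concentration(4.0, 0.01, 0.0)

    @given(
        conc=st.floats(1e-6, 1e-1),
        normality=st.floats(1e-3, 1.0),
        aliquot=st.floats(1.0, 25.0),
    )
    def test_round_trip_identity(self, conc, normality, aliquot):
        titre = concentration_to_titre(conc, normality, aliquot)
        back = titre_to_concentration(titre, normality, aliquot)
        assert back == pytest.approx(conc, rel=1e-12)

    def test_simulated_run_round_trips_through_titres(self, ref):
        cond = ref.reference_conditions()
        grid = pcmkin.default_time_grid(cond, ref.mechanism_table())
        run_t = pcmkin.simulate_scheme(cond, ref.mechanism_table(), grid,
                                       value_unit="cm3_titre")
        run_c = pcmkin.simulate_scheme(cond, ref.mechanism_table(), grid,
                                       value_unit="mol_per_dm3")
        np.testing.assert_allclose(run_t.concentrations(), run_c.values, rtol=1e-14)


class TestPseudoFirstOrder:
    def test_recovers_published_anchor_exactly(self, exact_decay_run):
        fit = fit_pseudo_first_order(exact_decay_run(k=1.91e-4))
        assert fit.constant == pytest.approx(1.91e-4, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.unit == "s^-1"

    @given(
        k=st.floats(1e-6, 1e-2),
        cat0=st.floats(1e-4, 1e-2),
        n=st.integers(3, 25),
    )
    def test_noise_free_recovery_any_grid(self, exact_decay_run, k, cat0, n):
        fit = fit_pseudo_first_order(exact_decay_run(k=k, cat0=cat0, pcm0=1.0, n=n))
        assert fit.constant == pytest.approx(k, rel=1e-9)

    def test_invariant_to_oxidant_scaling(self, exact_decay_run):
        k1 = fit_pseudo_first_order(exact_decay_run(cat0=1e-3)).constant
        k2 = fit_pseudo_first_order(exact_decay_run(cat0=2e-3)).constant
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_constant_series_reported_as_zero_with_flag(self):
        cond = pcmkin.ReactionConditions(cat0=2e-3, pcm0=0.04, os_total=0.0, oh=0.05)
        run = pcmkin.TitrationTimeSeries("flat", 1, [0, 100, 200],
                                         [2e-3, 2e-3, 2e-3], "mol_per_dm3", cond)
        fit = fit_pseudo_first_order(run)
        assert fit.constant == 0.0
        assert any("degenerate" in f for f in fit.flags)

    def test_late_points_beyond_90pct_conversion_are_excluded(self, exact_decay_run):
        # 6 half-lives ~ 98% conversion: the last points must fall outside
        k = 1e-3
        run = exact_decay_run(k=k, n=20, t_end=6.0 * np.log(2) / k)
        with pytest.warns(UserWarning, match="outside the fit window"):
            fit = fit_pseudo_first_order(run)
        assert fit.n_points < 20
        assert fit.constant == pytest.approx(k, rel=1e-9)


def closed_form_mixed(t, k2, a0, b0):
    """Independent analytic solution of da/dt = -k2 a b, db/dt = -k2 a b / 2.

    With delta = b0 - a0/2 conserved, partial fractions give
    a(t) = delta / ((b0/a0) exp(delta k2 t) - 1/2).
    """
    delta = b0 - a0 / 2.0
    return delta / ((b0 / a0) * np.exp(delta * k2 * t) - 0.5)


class TestSecondOrderMixed:
    @given(
        k2=st.floats(1e-4, 1e-1),
        a0=st.floats(5e-4, 5e-3),
        scale=st.floats(0.6, 20.0),
    )
    def test_closed_form_log_ratio_is_linear_with_known_slope(self, k2, a0, scale):
        b0 = a0 * scale  # keep delta = b0 - a0/2 > 0
        delta = b0 - a0 / 2.0
        t = np.linspace(0.0, 0.5 / (k2 * delta), 12)
        a = closed_form_mixed(t, k2, a0, b0)
        cond = pcmkin.ReactionConditions(cat0=a0, pcm0=b0, os_total=5e-5, oh=0.05)
        run = pcmkin.TitrationTimeSeries("cf", 1, t, a, "mol_per_dm3", cond)
        fit = fit_second_order_mixed(run)
        assert fit.constant == pytest.approx(k2, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_simulated_comparable_concentration_run(self, ref):
        # second-order conditions of the printed table: [PCM]=1.0e-2, [CAT]=2.0e-3
        cond = ref.reference_conditions().replace(cat0=2.0e-3, pcm0=1.0e-2)
        mech = ref.mechanism_table()
        k2 = pcmkin.mechanism.effective_second_order_constant(cond, mech)
        delta = cond.pcm0 - cond.cat0 / 2.0
        t = np.linspace(0.0, 0.6 / (k2 * delta), 10)
        run = pcmkin.simulate_scheme(cond, mech, t, value_unit="mol_per_dm3")
        fit = fit_second_order_mixed(run)
        assert fit.constant == pytest.approx(4.775e-3, rel=1e-6)

    def test_substrate_exhaustion_is_domain_error(self):
        cond = pcmkin.ReactionConditions(cat0=4e-3, pcm0=1e-3, os_total=5e-5, oh=0.05)
        run = pcmkin.TitrationTimeSeries("x", 1, [0, 1, 2], [4e-3, 3e-3, 2e-3],
                                         "mol_per_dm3", cond)
        with pytest.raises(KineticsDomainError):
            fit_second_order_mixed(run)

    def test_no_reaction_run_flagged_zero(self):
        cond = pcmkin.ReactionConditions(cat0=0.0, pcm0=1e-2, os_total=5e-5, oh=0.05)
        run = pcmkin.TitrationTimeSeries("z", 1, [0, 1, 2], [0.0, 0.0, 0.0],
                                         "mol_per_dm3", cond)
        fit = fit_second_order_mixed(run)
        assert fit.constant == 0.0 and any("degenerate" in f for f in fit.flags)


class TestSecondOrderFromPseudo:
    @pytest.mark.parametrize(
        "k_psi, pcm0, expected",
        [
            (1.91e-4, 4.0e-2, 4.775e-3),
            (2.303e-4, 5.0e-2, 4.606e-3),
            (0.0, 3.0e-2, 0.0),
        ],
    )
    def test_arithmetic(self, k_psi, pcm0, expected):
        assert second_order_from_pseudo(k_psi, pcm0) == pytest.approx(expected, rel=1e-12)

    def test_zero_substrate_is_domain_error(self):
        with pytest.raises(KineticsDomainError):
            second_order_from_pseudo(1e-4, 0.0)

    def test_agrees_with_mixed_fit_under_substrate_excess(self, ref):
        """The two second-order routes agree on noise-free pseudo-first-order runs."""
        dataset = pcmkin.generate_design(pcmkin.scenario("pcm_grid", 2))
        for run in dataset:
            if not run.conditions.is_pseudo_first_order:
                continue
            k_psi = fit_pseudo_first_order(run).constant
            k2_a = second_order_from_pseudo(k_psi, run.conditions.pcm0)
            k2_b = fit_second_order_mixed(run).constant
            assert k2_b == pytest.approx(k2_a, rel=0.02)


def _exponential_runs(xs, ks, field="pcm0"):
    runs = []
    for i, (x, k) in enumerate(zip(xs, ks)):
        cond = pcmkin.ReactionConditions(
            cat0=1e-3, pcm0=0.04, os_total=5e-5, oh=0.05).replace(**{field: x})
        t = np.linspace(0.0, 0.63 / k, 10)
        runs.append(pcmkin.TitrationTimeSeries(
            f"r{i}", 1, t, cond.cat0 * np.exp(-k * t), "mol_per_dm3", cond))
    return pcmkin.KineticDataset(runs=runs, design_label="custom")


class TestOrderEstimation:
    def test_substrate_grid_gives_first_order_through_origin(self):
        dataset = pcmkin.generate_design(pcmkin.scenario("pcm_grid", 4))
        est = estimate_order(dataset, "pcm")
        assert est.order == pytest.approx(1.0, abs=0.01)
        assert est.through_origin
        assert est.method == "log-log"

    def test_oxidant_grid_declared_first_order_by_invariance(self):
        dataset = pcmkin.generate_design(pcmkin.scenario("cat_grid", 4))
        est = estimate_order(dataset, "cat")
        assert est.order == 1.0
        assert est.method == "invariance"

    def test_squared_dependence_recovered(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) * 1e-2
        dataset = _exponential_runs(xs, 0.2 * xs**2)
        est = estimate_order(dataset, "pcm")
        assert est.order == pytest.approx(2.0, abs=1e-6)

    def test_too_few_runs_rejected(self):
        xs = np.array([1.0, 2.0, 3.0]) * 1e-2
        dataset = _exponential_runs(xs, 4.775e-3 * xs)
        with pytest.raises(KineticsDomainError, match="4 runs"):
            estimate_order(dataset, "pcm")

    def test_confounded_grid_rejected_with_field_names(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0]) * 1e-2
        dataset = _exponential_runs(xs, 4.775e-3 * xs)
        runs = list(dataset.runs)
        runs[0] = pcmkin.TitrationTimeSeries(
            runs[0].run_id, 1, runs[0].times, runs[0].values, "mol_per_dm3",
            runs[0].conditions.replace(oh=0.10))
        bad = pcmkin.KineticDataset(runs=runs, design_label="custom")
        with pytest.raises(KineticsDomainError, match="oh"):
            estimate_order(bad, "pcm")


def brute_force_icc(groups):
    """Independent one-way ANOVA decomposition by explicit sums of squares."""
    data = np.asarray(groups, dtype=float)
    g, k = data.shape
    grand = data.mean()
    ss_between = sum(k * (data[i].mean() - grand) ** 2 for i in range(g))
    ss_within = sum((data[i, j] - data[i].mean()) ** 2 for i in range(g) for j in range(k))
    msb = ss_between / (g - 1)
    msw = ss_within / (g * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestReplicateAgreement:
    def test_identical_replicates_are_perfectly_reproducible(self):
        stats = replicate_agreement([[1.5, 1.5, 1.5], [0.7, 0.7, 0.7]])
        assert stats.cv_percent == (0.0, 0.0)
        assert stats.icc == 1.0

    def test_between_group_only_variation(self):
        stats = replicate_agreement([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        assert stats.cv_percent == (0.0, 0.0)
        assert stats.icc == 1.0

    def test_hand_computable_anova_case(self):
        groups = [[1.0, 1.1, 0.9], [2.0, 2.1, 1.9]]
        stats = replicate_agreement(groups)
        assert stats.cv_percent[0] == pytest.approx(10.0, rel=1e-9)
        assert stats.cv_percent[1] == pytest.approx(5.0, rel=1e-9)
        assert stats.icc == pytest.approx(brute_force_icc(groups), rel=1e-12)
        assert stats.icc == pytest.approx(1.49 / 1.52, rel=1e-9)

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        data = rng.normal([[1.0], [2.0], [3.0], [4.0]], 0.1, size=(4, 3))
        ours = replicate_agreement(data.tolist()).icc
        frame = pd.DataFrame(
            {
                "target": np.repeat(np.arange(4), 3),
                "rater": np.tile(np.arange(3), 4),
                "score": data.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            frame, targets="target", raters="rater", ratings="score")
        theirs = table[table["Type"].isin(["ICC1", "ICC(1,1)"])].iloc[0]["ICC"]
        assert ours == pytest.approx(theirs, rel=1e-9)

    @given(
        shift=st.floats(-5.0, 5.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_icc_affine_invariance_and_cv_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        data = rng.normal([[1.0], [2.0], [3.0]], 0.05, size=(3, 3))
        base = replicate_agreement(data.tolist())
        moved = replicate_agreement((shift + scale * data).tolist())
        assert moved.icc == pytest.approx(base.icc, rel=1e-9, abs=1e-12)
        scaled_only = replicate_agreement((scale * data).tolist())
        np.testing.assert_allclose(scaled_only.cv_percent, base.cv_percent, rtol=1e-9)

    def test_zero_mean_group_named_in_error(self):
        with pytest.raises(KineticsDomainError, match="group 1"):
            replicate_agreement([[1.0, 1.2], [0.5, -0.5]])

    def test_unequal_replicate_counts_rejected(self):
        with pytest.raises(KineticsDomainError):
            replicate_agreement([[1.0, 1.2], [0.5, 0.6, 0.7]])
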