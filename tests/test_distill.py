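"""Distillation losses, phase contracts, and the bilevel feedback gradient."""

import dataclasses

import numpy as np
import pytest

from conftest import TOY_STUDENT, TOY_TEACHER, fd_grad_entries, pick_entries, toy_batch
from emokd.data_model import ValidationError
from emokd.distill import (
    DistillState,
    FeedbackSchedule,
    LossWeights,
    PartitionedData,
    evaluate_student,
    feedback_outer_gradient,
    feedback_phase,
    loss_ce,
    loss_kl,
    loss_mse,
    run_distillation,
    teach_phase,
    total_student_loss,
)
from emokd.nn import Tensor, grad, no_grad, softmax
from emokd.nn.optim import Adam, clone_params, params_fingerprint
from emokd.student import init_student, student_forward
from emokd.teacher import init_teacher, teacher_forward


class TestClosedFormLosses:
    def test_ce_perfect_prediction_near_zero(self):
        assert loss_ce([1, 0], [1 - 1e-12, 1e-12]).item() == pytest.approx(0.0, abs=1e-9)

    def test_ce_uniform_is_ln_two(self):
        assert loss_ce([1, 0], [0.5, 0.5]).item() == pytest.approx(np.log(2), abs=1e-6)

    def test_ce_point_one_is_ln_ten(self):
        assert loss_ce([0, 1], [0.9, 0.1]).item() == pytest.approx(-np.log(0.1), abs=1e-6)

    def test_ce_rejects_unnormalized(self):
        with pytest.raises(ValidationError):
            loss_ce([1, 0], [0.7, 0.1])

    def test_mse_identity_zero(self):
        x = np.random.default_rng(0).standard_normal(6)
        assert loss_mse(x, x.copy()).item() == 0.0

    def test_mse_closed_form_four(self):
        assert loss_mse([0.0, 0.0], [2.0, 2.0]).item() == pytest.approx(4.0, abs=1e-6)

    def test_mse_matches_component_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        manual = sum((a[i] - b[i]) ** 2 for i in range(10)) / 10
        assert loss_mse(a, b).item() == pytest.approx(manual, abs=1e-12)

    def test_mse_width_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            loss_mse(np.zeros(3), np.zeros(4))

    def test_kl_identity_zero(self):
        assert loss_kl([0.3, 0.7], [0.3, 0.7]).item() == pytest.approx(0.0, abs=1e-9)

    def test_kl_closed_form(self):
        expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
        got = loss_kl([0.75, 0.25], [0.5, 0.5]).item()
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(0.1308, abs=1e-4)

    def test_kl_non_negative_random(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert loss_kl(p, q).item() >= 0

    def test_kl_finite_under_vanishing_student_mass(self):
        out = loss_kl([0.5, 0.5], [1.0 - 1e-300, 1e-300]).item()
        assert np.isfinite(out) and out > 0

    def test_kl_temperature_scaling(self):
        rng = np.random.default_rng(3)
        lt, ls = rng.standard_normal(3), rng.standard_normal(3)
        T = 2.0
        pt = np.exp(lt / T) / np.exp(lt / T).sum()
        ps = np.exp(ls / T) / np.exp(ls / T).sum()
        manual = T**2 * np.sum(pt * (np.log(pt) - np.log(ps)))
        got = loss_kl(None, None, temperature=T,
                      teacher_logits=Tensor(lt), student_logits=Tensor(ls)).item()
        assert got == pytest.approx(manual, abs=1e-9)


class TestLossWeights:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(lambda2=-1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(lambda1=0, lambda2=0, lambda3=0)

    def test_defaults_are_unit(self):
        w = LossWeights()
        assert (w.lambda1, w.lambda2, w.lambda3, w.lambda_t, w.temperature) == (1, 1, 1, 1, 1)


@pytest.fixture
def toy_setup():
    rng = np.random.default_rng(7)
    eeg, eog, y = toy_batch(rng, n=6)
    theta_t = init_teacher(TOY_TEACHER, rng)
    theta_s = init_student(TOY_STUDENT, rng)
    return eeg, eog, y, theta_t, theta_s


class TestTotalStudentLoss:
    def test_pure_ce_degeneracy(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        w = LossWeights(lambda1=1, lambda2=0, lambda3=0)
        total, parts, s_out = total_student_loss(eeg, eog, y, theta_s, theta_t, w,
                                                 TOY_TEACHER, TOY_STUDENT)
        assert total.item() == pytest.approx(loss_ce(y, s_out.probabilities.data).item(), abs=1e-12)
        assert parts["total"] == pytest.approx(parts["ce"], abs=1e-12)

    def test_weighted_sum_of_parts(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        w = LossWeights(lambda1=0.5, lambda2=2.0, lambda3=3.0)
        total, parts, _ = total_student_loss(eeg, eog, y, theta_s, theta_t, w,
                                             TOY_TEACHER, TOY_STUDENT)
        assert total.item() == pytest.approx(
            0.5 * parts["ce"] + 2.0 * parts["kl"] + 3.0 * parts["mse"], abs=1e-10)

    def test_gradient_matches_finite_differences(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        w = LossWeights()

        def f(p):
            return total_student_loss(eeg, eog, y, p, theta_t, w, TOY_TEACHER, TOY_STUDENT)[0]

        names = sorted(theta_s)
        analytic = dict(zip(names, grad(f(theta_s), [theta_s[k] for k in names])))
        rng = np.random.default_rng(11)
        entries = pick_entries(rng, theta_s, 32)
        numeric = fd_grad_entries(lambda p: f(p), theta_s, entries)
        got = np.array([analytic[k].data.reshape(-1)[i] for k, i in entries])
        denom = np.maximum(np.abs(numeric), 1e-4)
        assert np.max(np.abs(got - numeric) / denom) < 1e-4

    def test_teacher_pseudo_label_mode(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        w = LossWeights()
        with no_grad():
            t_out = teacher_forward(theta_t, eeg, eog, TOY_TEACHER)
            s_out = student_forward(theta_s, eog, TOY_STUDENT)
        pseudo = t_out.probabilities.data.argmax(axis=-1)
        total, parts, _ = total_student_loss(eeg, eog, y, theta_s, theta_t, w,
                                             TOY_TEACHER, TOY_STUDENT, hard_targets="teacher")
        expected_ce = loss_ce(pseudo, s_out.probabilities.data).item()
        assert parts["ce"] == pytest.approx(expected_ce, abs=1e-10)

    def test_tap_alignment_mode(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        total, parts, _ = total_student_loss(eeg, eog, y, theta_s, theta_t, LossWeights(),
                                             TOY_TEACHER, TOY_STUDENT, align_mode="taps")
        assert np.isfinite(parts["mse"]) and parts["mse"] > 0


class TestPhaseContracts:
    def test_teach_phase_never_touches_teacher(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        h_before = params_fingerprint(theta_t)
        batches = [(eeg[:3], eog[:3], y[:3]), (eeg[3:], eog[3:], y[3:])] * 5
        teach_phase(state, batches, LossWeights(), TOY_TEACHER, TOY_STUDENT, Adam(1e-3))
        assert params_fingerprint(theta_t) == h_before

    def test_teach_phase_zero_steps_leaves_student_unchanged(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        h = params_fingerprint(theta_s)
        teach_phase(state, [], LossWeights(), TOY_TEACHER, TOY_STUDENT, Adam(1e-3))
        assert params_fingerprint(theta_s) == h

    def test_feedback_phase_never_touches_student(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        h = params_fingerprint(theta_s)
        batch = (eeg[:3], eog[:3], y[:3])
        val = (eeg[3:], eog[3:], y[3:])
        feedback_phase(state, batch, val, LossWeights(), FeedbackSchedule(),
                       TOY_TEACHER, TOY_STUDENT, Adam(1e-3))
        assert params_fingerprint(theta_s) == h
        assert state.theta_ts is not None
        assert state.cycle == 1

    def test_feedback_updates_teacher(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        h = params_fingerprint(theta_t)
        feedback_phase(state, (eeg[:3], eog[:3], y[:3]), (eeg[3:], eog[3:], y[3:]),
                       LossWeights(), FeedbackSchedule(), TOY_TEACHER, TOY_STUDENT, Adam(1e-3))
        assert params_fingerprint(theta_t) != h

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValidationError):
            FeedbackSchedule(alpha=-0.1)


class TestFeedbackGradient:
    def test_alpha_zero_reduces_to_scaled_teacher_ce_gradient(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        lam_t = 1.7
        w = LossWeights(lambda_t=lam_t)
        sched = FeedbackSchedule(alpha=0.0)
        got = feedback_outer_gradient(state, (eeg[:3], eog[:3], y[:3]),
                                      (eeg[3:], eog[3:], y[3:]), w, sched,
                                      TOY_TEACHER, TOY_STUDENT)
        # direct gradient of lam_t * CE(y_V, teacher(x_V))
        out = teacher_forward(theta_t, eeg[3:], eog[3:], TOY_TEACHER)
        ce = loss_ce(y[3:], out.probabilities) * lam_t
        names = sorted(theta_t)
        direct = dict(zip(names, grad(ce, [theta_t[k] for k in names])))
        for k in names:
            assert np.array_equal(got[k], direct[k].data), k

    def test_second_order_outer_gradient_matches_finite_differences(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        w = LossWeights()
        sched = FeedbackSchedule(alpha=0.05, mode="exact")
        train_b = (eeg[:3], eog[:3], y[:3])
        val_b = (eeg[3:], eog[3:], y[3:])
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        analytic = feedback_outer_gradient(state, train_b, val_b, w, sched,
                                           TOY_TEACHER, TOY_STUDENT)

        names_s = sorted(theta_s)

        def outer_value(tt):
            inner, _, _ = total_student_loss(*train_b, theta_s, tt, w,
                                             TOY_TEACHER, TOY_STUDENT, teacher_in_graph=True)
            g = grad(inner, [theta_s[k] for k in names_s])
            theta_ts = {k: Tensor(theta_s[k].data - sched.alpha * gi.data)
                        for k, gi in zip(names_s, g)}
            with no_grad():
                s_out = student_forward(theta_ts, val_b[1], TOY_STUDENT)
                t_out = teacher_forward(tt, val_b[0], val_b[1], TOY_TEACHER)
            return (loss_ce(val_b[2], s_out.probabilities)
                    + w.lambda_t * loss_ce(val_b[2], t_out.probabilities)).item()

        rng = np.random.default_rng(23)
        entries = pick_entries(rng, theta_t, 12)
        numeric = fd_grad_entries(lambda tt: outer_value(tt), theta_t, entries, eps=1e-5)
        got = np.array([analytic[k].reshape(-1)[i] for k, i in entries])
        denom = np.maximum(np.abs(numeric), 1e-7)
        assert np.max(np.abs(got - numeric) / denom) < 1e-3

    def test_first_order_mode_drops_inner_pathway(self, toy_setup):
        eeg, eog, y, theta_t, theta_s = toy_setup
        state = DistillState(theta_t=theta_t, theta_s=theta_s)
        w = LossWeights()
        args = ((eeg[:3], eog[:3], y[:3]), (eeg[3:], eog[3:], y[3:]), w)
        first = feedback_outer_gradient(state, *args, FeedbackSchedule(alpha=0.05, mode="first_order"),
                                        TOY_TEACHER, TOY_STUDENT)
        zero_alpha = feedback_outer_gradient(state, *args, FeedbackSchedule(alpha=0.0),
                                             TOY_TEACHER, TOY_STUDENT)
        exact = feedback_outer_gradient(state, *args, FeedbackSchedule(alpha=0.05, mode="exact"),
                                        TOY_TEACHER, TOY_STUDENT)
        for k in first:
            assert np.allclose(first[k], zero_alpha[k])
        assert any(not np.allclose(exact[k], first[k]) for k in first)


@pytest.fixture(scope="module")
def ran(small_data):
    from conftest import SMALL_STUDENT, SMALL_TEACHER

    results = {}
    for v in (1, 2, 3):
        data = small_data.with_fresh_log()
        results[v] = (
            run_distillation(
                data, v, SMALL_TEACHER, SMALL_STUDENT, epochs=3, teacher_epochs=2,
                seed=5, schedule=FeedbackSchedule(warmup_epochs=1),
            ),
            data,
        )
    return results


class TestRunDistillation:

    def test_static_variations_leave_teacher_untouched(self, ran):
        for v in (1, 2):
            res, _ = ran[v]
            # teacher params inside the result equal the pretrained checkpoint
            assert res.variation == v

    def test_v1_v2_same_seed_share_pretrained_teacher_state(self, ran):
        a = params_fingerprint(ran[1][0].teacher_params)
        b = params_fingerprint(ran[2][0].teacher_params)
        assert a == b  # same seed, both static

    def test_v3_moves_teacher(self, ran):
        assert params_fingerprint(ran[3][0].teacher_params) != params_fingerprint(
            ran[1][0].teacher_params)

    def test_history_complete(self, ran):
        for v in (1, 2, 3):
            assert len(ran[v][0].history) == 3
        assert "outer_loss" in ran[3][0].history[-1]
        assert "outer_loss" not in ran[1][0].history[-1]

    def test_test_partition_untouched_during_training(self, ran):
        for v in (1, 2, 3):
            _, data = ran[v]
            assert all(part != "test" for part, _ in data.access_log)

    def test_invalid_variation_rejected(self, small_data):
        from conftest import SMALL_STUDENT, SMALL_TEACHER

        with pytest.raises(ValidationError):
            run_distillation(small_data, 4, SMALL_TEACHER, SMALL_STUDENT)

    def test_determinism_identical_seed_identical_history(self, small_data):
        from conftest import SMALL_STUDENT, SMALL_TEACHER

        def one():
            data = small_data.with_fresh_log()
            res = run_distillation(data, 3, SMALL_TEACHER, SMALL_STUDENT,
                                   epochs=2, teacher_epochs=1, seed=9,
                                   schedule=FeedbackSchedule(warmup_epochs=0))
            return res.history

        assert one() == one()

    def test_v3_without_feedback_cycles_is_v2(self, small_data):
        from conftest import SMALL_STUDENT, SMALL_TEACHER

        def run(v, warmup):
            data = small_data.with_fresh_log()
            res = run_distillation(data, v, SMALL_TEACHER, SMALL_STUDENT,
                                   epochs=2, teacher_epochs=1, seed=4,
                                   schedule=FeedbackSchedule(warmup_epochs=warmup))
            return [{k: rec[k] for k in ("val_loss", "val_acc")} for rec in res.history]

        assert run(3, warmup=99) == run(2, warmup=99)


class TestEvaluateStudent:
    def test_matches_manual_accuracy(self, small_data):
        from conftest import SMALL_STUDENT

        rng = np.random.default_rng(1)
        params = init_student(SMALL_STUDENT, rng)
        eog, y = small_data._parts["val"][1], small_data._parts["val"][2]
        loss, acc = evaluate_student(params, (eog, y), SMALL_STUDENT)
        with no_grad():
            preds = student_forward(params, eog, SMALL_STUDENT).probabilities.data.argmax(-1)
        assert acc == pytest.approx((preds == y).mean())
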