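"""Tests of the banded + low-rank LD representations and their
Woodbury-based solve / trace / log-determinant contracts."""

import warnings

import numpy as np
import pytest

import heels as H
from heels import ldapprox as LA


@pytest.fixture(scope="module")
def R60(ld60):
    return ld60


class TestSeqBandLR:
    def test_banded_input_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        p, b = 40, 4
        A = rng.standard_normal((p, p))
        Rb = np.where(LA.band_mask(p, b), (A + A.T) / 2, 0.0)
        ap = LA.approx_seq_band_lr(Rb, b, 3)
        rep = LA.accuracy(ap, Rb)
        assert rep.frob_error < 1e-12 and rep.frob_ratio == pytest.approx(1.0)

    def test_full_bandwidth_exact_for_any_rank(self, R60):
        ap = LA.approx_seq_band_lr(R60, 60, 0)
        assert LA.accuracy(ap, R60).frob_error == 0.0

    def test_eckart_young_on_residual(self, R60):
        # error^2 = (banding error^2) - (sum of top-r residual eigenvalues^2)
        b, r = 5, 8
        ap = LA.approx_seq_band_lr(R60, b, r)
        mask = LA.band_mask(60, b)
        resid = R60 - np.where(mask, R60, 0.0)
        w = np.linalg.eigvalsh(resid)
        top = np.sort(np.abs(w))[::-1][:r]
        predicted = np.sum((R60[~mask]) ** 2) - np.sum(top**2)
        assert LA.accuracy(ap, R60).frob_error ** 2 == pytest.approx(predicted, rel=1e-10)

    def test_error_non_increasing_in_bandwidth(self, R60):
        errs = [LA.accuracy(LA.approx_seq_band_lr(R60, b, 5), R60).frob_error
                for b in (1, 5, 10, 20, 40, 60)]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))

    def test_error_non_increasing_in_rank(self, R60):
        # each extra eigenpair of the residual can only tighten the fit
        errs = [LA.accuracy(LA.approx_seq_band_lr(R60, 5, r), R60).frob_error
                for r in (0, 2, 5, 10, 20)]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))


class TestPSDBandLR:
    def test_banded_psd_input_recovered(self):
        rng = np.random.default_rng(1)
        p, b = 30, 3
        L = np.where(LA.band_mask(p, b), rng.standard_normal((p, p)), 0.0)
        L = np.tril(L)
        np.fill_diagonal(L, np.abs(np.diag(L)) + 0.5)
        Rpsd = L @ L.T  # PSD, bandwidth 2b-1
        ap = LA.approx_psd_band_lr(Rpsd, 2 * b - 1, 0, maxiter=2000)
        assert LA.accuracy(ap, Rpsd).frob_error < 1e-6

    def test_rank_zero_error_at_least_unconstrained_band(self, R60):
        b = 5
        ap = LA.approx_psd_band_lr(R60, b, 0, maxiter=1000)
        mask = LA.band_mask(60, b)
        seq_band_err = np.linalg.norm(R60[~mask])  # Seq keeps the band exactly
        assert LA.accuracy(ap, R60).frob_error >= seq_band_err - 1e-8

    def test_objective_close_to_long_run_reference(self, R60):
        short = LA.approx_psd_band_lr(R60, 5, 0, maxiter=600)
        ref = LA.approx_psd_band_lr(R60, 5, 0, maxiter=20000)
        assert short.objective <= ref.objective * 1.01 + 1e-10


class TestJointBandLR:
    def test_identity_recovered_exactly(self):
        ap = LA.approx_joint_band_lr(np.eye(25), 3, 2)
        assert LA.accuracy(ap, np.eye(25)).frob_error < 1e-8

    def test_objective_trace_monotone_descent(self, R60):
        for seed_b in (2, 4, 7):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ap = LA.approx_joint_band_lr(R60, seed_b, 4, maxiter=300)
            t = ap.objective_trace
            assert t.size > 1 and np.all(np.diff(t) <= 1e-9 * max(1.0, t[0]))

    def test_beats_two_step_solution_when_feasible(self, R60):
        b, r = 5, 8
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            two_step = LA.approx_psd_band_lr(R60, b, r, maxiter=2000)
            joint = LA.approx_joint_band_lr(R60, b, r, maxiter=2000)
        if np.all(two_step.eigenvalues >= 0):  # Eq-10-feasible two-step solution
            obj_two_step = np.linalg.norm(R60 - two_step.reconstruct()) ** 2
            assert joint.objective <= obj_two_step + 1e-8
        assert np.linalg.eigvalsh(joint.reconstruct()).min() >= -1e-8


class TestSpike:
    def test_model_matched_input_recovered(self):
        rng = np.random.default_rng(3)
        p, r0 = 40, 4
        U, _ = np.linalg.qr(rng.standard_normal((p, r0)))
        lam = np.array([9.0, 6.0, 4.0, 2.5])
        sigma2 = 0.7
        Rspk = sigma2 * np.eye(p) + (U * lam) @ U.T
        ap = LA.approx_spike(Rspk, 6, "Spike_LR")
        assert ap.banded_dense[0, 0] == pytest.approx(sigma2, abs=1e-8)
        assert LA.accuracy(ap, Rspk).frob_error < 1e-6

    def test_spike_psd_on_identity(self):
        ap = LA.approx_spike(np.eye(20), 3, "Spike_PSD")
        assert ap.banded_dense[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.max(np.abs(ap.factors)) < 1e-4

    def test_hetero_objective_no_worse_than_homogeneous(self, R60):
        homo = LA.approx_spike(R60, 5, "Spike_PSD", maxiter=2000)
        het = LA.approx_spike(R60, 5, "Spike_PSD_hetero", maxiter=2000)
        assert het.objective <= homo.objective + 1e-6 * homo.objective

    def test_psd_guarantee_small_rank(self, R60):
        # guaranteed-PSD strategies, plus the signed-eigenvalue strategies
        # under their truncate-positive option
        for ap in (
            LA.approx_spike(R60, 4, "Spike_LR", positive_only=True),
            LA.approx_spike(R60, 4, "Spike_PSD"),
            LA.approx_spike(R60, 4, "Spike_PSD_hetero"),
            LA.approx_psd_band_lr(R60, 5, 4, positive_only=True),
        ):
            assert np.linalg.eigvalsh(ap.reconstruct()).min() >= -1e-8, ap.strategy


@pytest.fixture(scope="module")
def approxes(ld60):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            LA.approx_seq_band_lr(ld60, 5, 8),
            LA.approx_psd_band_lr(ld60, 5, 8),
            LA.approx_joint_band_lr(ld60, 5, 8),
            LA.approx_spike(ld60, 8, "Spike_LR"),
            LA.approx_spike(ld60, 8, "Spike_PSD"),
            LA.approx_spike(ld60, 8, "Spike_PSD_hetero"),
        ]


class TestWoodbury:
    def test_rank_zero_equals_banded_solve(self, ld60):
        ap = LA.approx_seq_band_lr(ld60, 5, 0)
        v = np.arange(60.0)
        x = LA.woodbury_solve(ap, 1.0, v)
        expected = np.linalg.solve(np.eye(60) + ap.banded_dense, v)
        assert np.allclose(x, expected, atol=1e-10)

    def test_solve_matches_dense(self, approxes, ld60):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(60)
        # shifts above |min eigenvalue| of the signed banded slice, so the
        # banded Cholesky route is defined for every strategy
        for ap in approxes:
            for lam in (0.7, 1.5, 5.0):
                M = lam * np.eye(60) + ap.reconstruct()
                x_dense = np.linalg.solve(M, v)
                x = LA.woodbury_solve(ap, lam, v)
                assert np.max(np.abs(x - x_dense)) <= 1e-8 * np.max(np.abs(x_dense))

    def test_traces_and_logdet_match_dense(self, approxes):
        for ap in approxes:
            M = 0.8 * np.eye(60) + ap.reconstruct()
            Minv = np.linalg.inv(M)
            t1, t2, ld = LA.woodbury_traces(ap, 0.8)
            assert t1 == pytest.approx(np.trace(Minv), rel=1e-6)
            assert t2 == pytest.approx(np.sum(Minv * Minv), rel=1e-6)
            assert ld == pytest.approx(np.linalg.slogdet(M)[1], rel=1e-6)

    def test_dominant_shift_limit(self, approxes):
        v = np.ones(60)
        for ap in approxes:
            x = LA.woodbury_solve(ap, 1e8, v)
            assert np.max(np.abs(x - v / 1e8)) <= 1e-6 * np.max(np.abs(v / 1e8))

    def test_scaled_identity_closed_forms(self):
        p, c, lam = 15, 2.0, 0.5
        ap = LA.approx_seq_band_lr(c * np.eye(p), 1, 0)
        t1, t2, ld = LA.woodbury_traces(ap, lam)
        assert t1 == pytest.approx(p / (lam + c))
        assert t2 == pytest.approx(p / (lam + c) ** 2)
        assert ld == pytest.approx(p * np.log(lam + c))

    def test_logdet_monotone_in_shift(self, approxes):
        for ap in approxes[:3]:
            op = ap.operator()
            vals = [op.logdet(lam) for lam in (0.8, 1.6, 3.2, 6.4)]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_indefinite_shifted_band_raises(self):
        # strongly negative off-band mass makes the banded slice indefinite
        p = 20
        R = np.eye(p)
        R[0, 1] = R[1, 0] = 3.0  # banded slice at b=2 has eigenvalue -2
        ap = LA.approx_seq_band_lr(R, 2, 2)
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            ap.operator().solve(0.5, np.ones(p))


class TestAccuracyReport:
    def test_zero_approximation(self, ld60):
        ap = LA.approx_seq_band_lr(np.zeros((60, 60)), 1, 0)
        rep = LA.accuracy(ap, ld60)
        assert rep.frob_ratio == 0.0
        assert rep.frob_error == pytest.approx(np.linalg.norm(ld60))

    def test_invalid_hyperparameters_rejected(self, ld60):
        with pytest.raises(ValueError):
            LA.approx_seq_band_lr(ld60, 0, 5)
        with pytest.raises(ValueError):
            LA.approx_seq_band_lr(ld60, 5, 60)


class TestFullParameterLimit:
    def test_every_strategy_reproduces_exact_fit(self, small_panel):
        # at (b, r) = (p, p-1) all six strategies agree with the exact-LD fit
        stats, R = small_panel["stats"], small_panel["R"]
        p = 30
        exact = H.heels_fit(stats, H.DenseLD(R), tol=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            approxes = [
                LA.approx_seq_band_lr(R, p, p - 1),
                LA.approx_psd_band_lr(R, p, p - 1, maxiter=3000),
                LA.approx_joint_band_lr(R, p, p - 1, maxiter=3000),
                LA.approx_spike(R, p - 1, "Spike_LR"),
                LA.approx_spike(R, p - 1, "Spike_PSD", maxiter=3000),
                LA.approx_spike(R, p - 1, "Spike_PSD_hetero", maxiter=3000),
            ]
        for ap in approxes:
            fit = H.heels_fit(stats, ap.operator(), tol=1e-9)
            assert abs(fit.h2 - exact.h2) < 1e-6, ap.strategy
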