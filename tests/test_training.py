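"""Loss terms (incl. MC-SURE), schedule, sampling and the training loop."""

import numpy as np
import pytest

from dstripe.network import DStripeNet
from dstripe.simulate import (
    DihedralElement,
    ModulationConfig,
    PhantomConfig,
    SliceModulation,
    make_phantom,
    normalize_gm,
)
from dstripe.training import (
    TrainConfig,
    TrainingSample,
    corrected,
    loss_sure,
    lr_schedule,
    make_training_sample,
    perturbation,
    rho_sure,
    select_loss,
    sure_sigma,
    train,
)


@pytest.fixture()
def masked_volume(rng):
    S = rng.random((6, 5, 4)) + 0.5
    mask = rng.random((6, 5, 4)) > 0.3
    mask[0, 0, 0] = True  # ensure non-empty
    return S, mask


class TestMaskedLosses:
    def test_zero_when_exact(self, masked_volume):
        from dstripe.training import _masked_mse

        S, mask = masked_volume
        assert _masked_mse(S, S.copy(), mask) == 0.0

    def test_constant_offset_inside_mask(self, masked_volume):
        from dstripe.training import _masked_mse

        S, mask = masked_volume
        assert _masked_mse(S, S + 0.25, mask) == pytest.approx(0.25**2)

    def test_matches_brute_force_sum(self, masked_volume, rng):
        from dstripe.training import _masked_mse

        S, mask = masked_volume
        other = rng.random(S.shape)
        acc = 0.0
        n = 0
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                for k in range(S.shape[2]):
                    if mask[i, j, k]:
                        acc += (S[i, j, k] - other[i, j, k]) ** 2
                        n += 1
        assert _masked_mse(S, other, mask) == pytest.approx(acc / n)

    def test_empty_mask_raises(self, rng):
        from dstripe.training import _masked_mse

        with pytest.raises(ValueError, match="empty"):
            _masked_mse(np.ones((2, 2, 2)), np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestSureSigma:
    def test_zero_without_modulation(self, masked_volume):
        S, mask = masked_volume
        assert sure_sigma(S, S.copy(), mask) == 0.0

    def test_plus_minus_one_gives_unit_sd(self):
        S_d = np.zeros((2, 2, 2))
        diff = np.array([1.0, -1.0] * 4).reshape(2, 2, 2)
        mask = np.ones((2, 2, 2), bool)
        assert sure_sigma(S_d + diff, S_d, mask) == pytest.approx(1.0)

    def test_matches_brute_force(self, masked_volume, rng):
        S, mask = masked_volume
        other = rng.random(S.shape)
        vals = (S - other)[mask]
        assert sure_sigma(S, other, mask) == pytest.approx(
            float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
        )


class TestPerturbation:
    def test_unit_masked_sd(self, rng):
        S = rng.random((8, 8, 6)) + 0.5
        mask = rng.random((8, 8, 6)) > 0.4
        m_hat = normalize_gm(rng.uniform(0.8, 1.2, 6))
        P = perturbation(S, m_hat, mask)
        assert P[mask].std() == pytest.approx(1.0, abs=1e-9)

    def test_stripe_structure(self, rng):
        S = rng.random((8, 8, 6)) + 0.5
        mask = np.ones(S.shape, bool)
        m_hat = normalize_gm(rng.uniform(0.8, 1.2, 6))
        P = perturbation(S, m_hat, mask)
        for s in range(6):
            expected = S[:, :, s] * (m_hat.m[s] - 1.0)
            if abs(m_hat.m[s] - 1.0) > 1e-9:
                ratio = P[:, :, s] / expected
                np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_scale_invariance(self, rng):
        S = rng.random((8, 8, 6)) + 0.5
        mask = np.ones(S.shape, bool)
        m_hat = normalize_gm(rng.uniform(0.8, 1.2, 6))
        P1 = perturbation(S, m_hat, mask)
        P2 = perturbation(2.0 * S, m_hat, mask)
        np.testing.assert_allclose(P1, P2, rtol=1e-9)

    def test_degenerate_modulation_rejected(self):
        S = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="degenerate"):
            perturbation(S, SliceModulation(m=np.ones(4)), np.ones(S.shape, bool))


class TestRhoSure:
    def test_linear_map_exact_for_any_eps(self, rng):
        # for f(v) = a·v the divergence contraction is a·‖P‖²_M exactly
        S = rng.random((16, 16, 16))
        mask = rng.random(S.shape) > 0.5
        P = rng.normal(size=S.shape)
        a = 1.7
        for eps in (1e-1, 1e-3, 1e-6):
            rho = rho_sure(lambda v: a * v, S, P, mask, epsilon=eps)
            assert rho == pytest.approx(a * float((P[mask] ** 2).sum()), rel=1e-9)

    def test_constant_map_gives_zero(self, rng):
        S = rng.random((8, 8, 8))
        mask = np.ones(S.shape, bool)
        P = rng.normal(size=S.shape)
        c = np.full(S.shape, 3.0)
        assert rho_sure(lambda v: c, S, P, mask) == 0.0

    def test_first_order_convergence_on_quadratic_map(self, rng):
        # f(v) = v² has Jacobian diag(2v): contraction = Σ P²·2v; the
        # finite-difference error is ε·Σ P³, i.e. first order in ε
        S = rng.random((6, 6, 6)) + 1.0
        mask = np.ones(S.shape, bool)
        P = rng.normal(size=S.shape)
        exact = float((P * P * 2 * S).sum())
        errs = []
        for eps in (1e-2, 5e-3, 2.5e-3):
            rho = rho_sure(lambda v: v**2, S, P, mask, epsilon=eps)
            errs.append(abs(rho - exact))
        # halving ε halves the error (within 5%)
        assert errs[1] / errs[0] == pytest.approx(0.5, rel=0.05)
        assert errs[2] / errs[1] == pytest.approx(0.5, rel=0.05)


class TestLossSure:
    def test_perfect_reconstruction_gives_minus_sigma_sq(self, rng):
        S = rng.random((4, 4, 4))
        mask = np.ones(S.shape, bool)
        assert loss_sure(S, S.copy(), sigma=0.3, rho=0.0, mask=mask) == pytest.approx(-0.09)

    def test_sigma_zero_reduces_to_mse(self, rng):
        from dstripe.training import _masked_mse

        S = rng.random((4, 4, 4))
        f = rng.random((4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.4
        assert loss_sure(S, f, 0.0, 123.4, mask) == pytest.approx(_masked_mse(S, f, mask))

    def test_brute_force_assembly(self, rng):
        S = rng.random((4, 4, 4))
        f = rng.random((4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.4
        nM = mask.sum()
        sigma, rho = 0.2, -3.0
        expected = ((S - f)[mask] ** 2).sum() / nM - sigma**2 + 2 * sigma**2 / nM * abs(rho)
        assert loss_sure(S, f, sigma, rho, mask) == pytest.approx(expected)


class TestSelectLoss:
    @pytest.mark.parametrize("origin,recipe", [("AP", "aug+const"), ("LR", "aug+const"), ("IS", "sure")])
    def test_axis_to_recipe(self, origin, recipe):
        sample = TrainingSample(
            S_o=np.ones((4, 4, 4)), d=DihedralElement((0, 1, 2), (False,) * 3),
            m=SliceModulation(np.ones(4)), S_d=np.ones((4, 4, 4)),
            S_dm=np.ones((4, 4, 4)), mask=np.ones((4, 4, 4), bool),
            slice_axis_origin=origin,
        )
        assert select_loss(sample) == recipe

    def test_sampler_covers_recipes_uniformly(self, rng):
        cfg = TrainConfig(epochs=1)
        vol = rng.random((12, 12, 12))
        mask = np.ones((12, 12, 12), bool)
        counts = {"aug+const": 0, "sure": 0}
        n = 600
        for _ in range(n):
            s = make_training_sample(vol, mask, cfg, rng)
            counts[select_loss(s)] += 1
        # IS is one of three axes: expect 1/3 sure, 2/3 aug+const
        assert counts["sure"] / n == pytest.approx(1 / 3, abs=0.06)


class TestLrSchedule:
    def test_triangle_keypoints(self):
        assert lr_schedule(0) == pytest.approx(1e-4)
        assert lr_schedule(80) == pytest.approx(5e-4)
        assert lr_schedule(160) == pytest.approx(1e-4)
        assert lr_schedule(40) == pytest.approx(3e-4)
        assert lr_schedule(240) == pytest.approx(5e-4)


class TestCorrected:
    def test_ratio_equals_field(self, tiny_net, rng):
        S = rng.random((32, 32, 12)).astype(np.float32) + 0.1
        F = tiny_net.forward(S, train=False)
        c = corrected(tiny_net, S, train=False)
        np.testing.assert_allclose(c / S, F, rtol=1e-5)

    def test_positive_input_positive_output(self, tiny_net, rng):
        S = rng.random((32, 32, 12)).astype(np.float32) + 0.1
        assert np.all(corrected(tiny_net, S, train=False) > 0)


@pytest.fixture(scope="module")
def tiny_train():
    # all extents ≥ 32: dihedral augmentation rotates z into the plane
    cfg = PhantomConfig(shape=(32, 32, 32), volumes_per_shell=(1, 2), shell_b=(0.0, 1000.0),
                        shell_attenuation=(1.0, 0.4))
    ph = make_phantom(cfg, np.random.default_rng(3))
    tc = TrainConfig(epochs=2, seed=99)
    net, log = train([(ph.dataset, ph.mask)], tc)
    return ph, tc, net, log


class TestTrainLoop:
    def test_deterministic_loss_log(self, tiny_train):
        ph, tc, net, log = tiny_train
        net2, log2 = train([(ph.dataset, ph.mask)], tc)
        assert len(log) == len(log2)
        for a, b in zip(log, log2):
            assert a == b

    def test_log_records_schedule_and_recipes(self, tiny_train):
        _, tc, _, log = tiny_train
        assert log[0]["lr"] == pytest.approx(1e-4)
        assert all(r["recipe"] in ("aug+const", "sure") for r in log)
        assert len(log) == 2 * 3  # 2 epochs × 3 volumes

    def test_sure_terms_logged_on_sure_steps(self, tiny_train):
        _, _, _, log = tiny_train
        for r in log:
            if r["recipe"] == "sure":
                assert np.isfinite(r["j_sure"]) and np.isfinite(r["sigma_sure"])
            else:
                assert np.isfinite(r["j_aug"]) and np.isfinite(r["j_const"])

    def test_no_datasets_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))
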