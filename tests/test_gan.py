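import numpy as np
import pytest

from progeval import AMINO_ACIDS, LabeledDataset
from progeval.generators.autodiff import Tensor
from progeval.generators.gan import (
    ConditionalGANConfig,
    GeneratorModel,
    _init_params,
    ac_loss,
    discriminator_score,
    encode_labels,
    encode_sequences,
    gradient_penalty,
    train_cgan,
)


def linear_config(hidden=(4,), branches=(1,), label_dim=3):
    # leaky slope 1 makes every layer affine: closed forms become exact
    return ConditionalGANConfig(
        seq_len=2,
        label_dim=label_dim,
        disc_hidden=hidden,
        projection_branches=branches,
        leaky_slope=1.0,
        seed=0,
    )


def make_params(config, seed=0):
    return _init_params(config, np.random.default_rng(seed))


class TestDiscriminatorScore:
    def test_matches_manual_matrix_arithmetic(self):
        config = linear_config()
        params = make_params(config)
        rng = np.random.default_rng(1)
        x = rng.random((5, config.x_dim))
        y = rng.random((5, 3))
        h = x @ params["d0_W"].data + params["d0_b"].data
        expected = (
            ((y @ params["v0_W"].data) * h).sum(axis=1)
            + (h @ params["psi0_W"].data).ravel()
            + params["psi0_b"].data[0]
        )
        got = discriminator_score(x, y, config, params)
        assert np.allclose(got, expected, atol=1e-12)

    def test_zero_projection_is_label_independent(self):
        config = linear_config()
        params = make_params(config)
        params["v0_W"].data[:] = 0.0
        rng = np.random.default_rng(2)
        x = rng.random((4, config.x_dim))
        a = discriminator_score(x, np.eye(3)[[0, 1, 2, 0]], config, params)
        b = discriminator_score(x, np.eye(3)[[2, 0, 1, 1]], config, params)
        assert np.allclose(a, b)

    def test_two_identical_branches_double_the_score(self):
        single = linear_config(hidden=(4,), branches=(1,))
        sp = make_params(single)
        double = linear_config(hidden=(4, 4), branches=(1, 2))
        dp = make_params(double)
        # second trunk layer = identity, both branches share all weights
        dp["d0_W"].data[:] = sp["d0_W"].data
        dp["d0_b"].data[:] = sp["d0_b"].data
        dp["d1_W"].data[:] = np.eye(4)
        dp["d1_b"].data[:] = 0.0
        for bi in (0, 1):
            dp[f"v{bi}_W"].data[:] = sp["v0_W"].data
            dp[f"psi{bi}_W"].data[:] = sp["psi0_W"].data
            dp[f"psi{bi}_b"].data[:] = sp["psi0_b"].data
        rng = np.random.default_rng(3)
        x = rng.random((4, single.x_dim))
        y = rng.random((4, 3))
        assert np.allclose(
            discriminator_score(x, y, double, dp),
            2 * discriminator_score(x, y, single, sp),
        )

    def test_accepts_unflattened_input(self):
        config = linear_config()
        params = make_params(config)
        rng = np.random.default_rng(4)
        x3 = rng.random((2, 2, 21))
        y = rng.random((2, 3))
        assert np.allclose(
            discriminator_score(x3, y, config, params),
            discriminator_score(x3.reshape(2, -1), y, config, params),
        )

    def test_invalid_branch_indices_rejected(self):
        with pytest.raises(ValueError):
            linear_config(hidden=(4,), branches=(2,))
        with pytest.raises(ValueError):
            linear_config(hidden=(4, 4), branches=(2, 1))


class TestACLoss:
    def test_confident_correct_predictions_vanish(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        probs = np.abs(y - 1e-9)
        assert ac_loss(probs, y, gamma=1.0) < 1e-7

    def test_uninformative_half_probs_closed_form(self):
        d = 5
        y = np.eye(d)[:3]
        probs = np.full((3, d), 0.5)
        assert ac_loss(probs, y, gamma=2.0) == pytest.approx(2.0 * d * np.log(2))

    def test_gamma_zero_disables(self):
        assert ac_loss(np.array([[0.9]]), np.array([[0.0]]), gamma=0.0) == 0.0

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            ac_loss(np.array([[1.2]]), np.array([[1.0]]))

    def test_monotone_in_per_label_error(self):
        y = np.array([[1.0, 0.0]])
        losses = [
            ac_loss(np.array([[p, 1 - p]]), y) for p in (0.9, 0.7, 0.5, 0.3)
        ]
        assert losses == sorted(losses)


class TestGradientPenalty:
    def test_matches_independent_finite_difference_recomputation(self):
        config = linear_config(hidden=(4, 4), branches=(1, 2))
        config = ConditionalGANConfig(
            **{**vars(config), "leaky_slope": 0.2}
        )
        params = make_params(config, seed=5)
        rng = np.random.default_rng(6)
        x_real = rng.random((3, config.x_dim))
        x_fake = rng.random((3, config.x_dim))
        y = rng.random((3, 3))
        eps_mix = rng.random(3)
        got = gradient_penalty(params, config, x_real, x_fake, y, eps_mix).data

        x_hat = eps_mix[:, None] * x_real + (1 - eps_mix[:, None]) * x_fake
        h = 1e-6
        norms = []
        for r in range(3):
            g = np.zeros(config.x_dim)
            for j in range(config.x_dim):
                xp, xm = x_hat.copy(), x_hat.copy()
                xp[r, j] += h
                xm[r, j] -= h
                g[j] = (
                    discriminator_score(xp, y, config, params)[r]
                    - discriminator_score(xm, y, config, params)[r]
                ) / (2 * h)
            norms.append(np.linalg.norm(g))
        expected = np.mean((np.array(norms) - 1) ** 2)
        assert got == pytest.approx(expected, abs=1e-5)


class TestEncoding:
    def test_one_hot_with_padding_channel(self):
        from progeval import ProteinSequence

        x = encode_sequences([ProteinSequence("s", "AC")], seq_len=4)
        x = x.reshape(4, 21)
        assert x[0, 0] == 1.0  # A
        assert x[1, AMINO_ACIDS.index("C")] == 1.0
        assert x[2, 20] == 1.0 and x[3, 20] == 1.0  # PAD
        assert np.allclose(x.sum(axis=1), 1.0)

    def test_multilabel_encoding_is_sum_of_one_hots(self):
        y = encode_labels([{"T1", "T3"}, {"T2"}], ["T1", "T2", "T3"])
        assert np.allclose(y, [[1, 0, 1], [0, 1, 0]])


class TestTraining:
    def test_untrained_sampler_shape_contract(self):
        config = ConditionalGANConfig(seq_len=20, label_dim=3, seed=0)
        params = _init_params(config, np.random.default_rng(0))
        model = GeneratorModel(config, params, ["T1", "T2", "T3"])
        seqs = model.sample({"T2"}, 7, seed=1)
        assert len(seqs) == 7
        for s in seqs:
            assert 1 <= len(s.residues) <= 20
            assert set(s.residues) <= set(AMINO_ACIDS)
            assert s.labels == {"T2"}

    def test_short_training_run_is_finite_and_reproducible(self, flat3):
        ds, _ = flat3
        small = LabeledDataset(ds.sequences[:120], vocabulary=ds.vocabulary)
        config = ConditionalGANConfig(
            seq_len=48, label_dim=3, steps=10, batch_size=16, seed=2
        )
        m1 = train_cgan(small, config)
        m2 = train_cgan(small, config)
        assert all(np.isfinite(h["d_loss"]) for h in m1.history)
        a = m1.sample({"T1"}, 3, seed=0)
        b = m2.sample({"T1"}, 3, seed=0)
        assert [s.residues for s in a] == [s.residues for s in b]

    def test_checkpoint_round_trip(self, tmp_path, flat3):
        ds, _ = flat3
        small = LabeledDataset(ds.sequences[:60], vocabulary=ds.vocabulary)
        config = ConditionalGANConfig(
            seq_len=48, label_dim=3, steps=3, batch_size=8, seed=3
        )
        model = train_cgan(small, config)
        p = tmp_path / "ckpt.json"
        model.save(p)
        back = GeneratorModel.load(p)
        a = model.sample({"T2"}, 4, seed=5)
        b = back.sample({"T2"}, 4, seed=5)
        assert [s.residues for s in a] == [s.residues for s in b]

    def test_label_dim_mismatch_raises(self, flat3):
        ds, _ = flat3
        config = ConditionalGANConfig(seq_len=48, label_dim=5, steps=1)
        with pytest.raises(ValueError, match="label_dim"):
            train_cgan(ds, config)
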