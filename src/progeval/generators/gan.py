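"""Miniature conditional Wasserstein GAN with gradient penalty (desk scale).

The critic (discriminator) combines two conditioning mechanisms:

* *Projection*: the score is a sum of an unconditional term and the inner
  product between a linear projection of the label encoding and an
  intermediate representation of the sequence,
  ``D(x, y) = A(v(y)^T phi(x) + psi(phi(x)))`` with ``A`` the identity.
  Several projections may tap the shared trunk at different depths
  (a tree-like branching structure); with one projection the formula
  reduces to the single-projection form.
* *Auxiliary classifier*: a label-prediction head sharing the trunk,
  whose per-label binary cross-entropy (weighted by ``ac_weight``)
  augments both players' losses.

The generator receives the label encoding concatenated to the latent
noise vector and emits per-position categorical distributions over the
20 amino acids plus a padding channel; sampling decodes by argmax and
truncates at the first padding position. Labels of a multilabel sequence
are encoded as the sum of the one-hot encodings of its terms.

Training follows the Wasserstein objective with a gradient penalty
``gp_weight * mean((||grad_x D(x_hat)|| - 1)^2)`` on random interpolates
between real and generated one-hot encodings; the second-order gradients
this requires are provided by the package's autodiff engine. This is an
intentionally small, CPU-friendly model for testing the evaluation
framework end to end, not a replica of any production architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..data_model import AMINO_ACIDS, LabeledDataset, ProteinSequence
from .autodiff import Adam, Tensor, grad

PAD = 20  # index of the padding channel
N_CHANNELS = 21


@dataclass
class ConditionalGANConfig:
    """Architecture and training parameters of the miniature cGAN.

    ``projection_branches`` lists the (1-based) trunk layer indices at
    which each projection taps the shared critic trunk; indices must be
    strictly increasing and at most the trunk depth.
    """

    seq_len: int = 48
    latent_dim: int = 32
    label_dim: int = 3
    gen_hidden: tuple[int, ...] = (128,)
    disc_hidden: tuple[int, ...] = (128, 128)
    projection_branches: tuple[int, ...] = (2,)
    ac_weight: float = 2.0
    gp_weight: float = 10.0
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    betas: tuple[float, float] = (0.5, 0.9)
    batch_size: int = 64
    steps: int = 1500
    critic_iters: int = 1
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        pb = tuple(self.projection_branches)
        if any(b < 1 or b > len(self.disc_hidden) for b in pb):
            raise ValueError(
                f"projection branch indices {pb} must lie in "
                f"[1, {len(self.disc_hidden)}]"
            )
        if list(pb) != sorted(set(pb)):
            raise ValueError("projection branch indices must be strictly increasing")
        if self.ac_weight < 0 or self.gp_weight < 0:
            raise ValueError("loss weights must be nonnegative")

    @property
    def x_dim(self) -> int:
        return self.seq_len * N_CHANNELS


def _init_params(config: ConditionalGANConfig, rng: np.random.Generator
                 ) -> dict[str, Tensor]:
    """He-style initialization of all generator and critic parameters."""

    def dense(name: str, n_in: int, n_out: int, params: dict) -> None:
        scale = np.sqrt(2.0 / n_in)
        params[f"{name}_W"] = Tensor(
            rng.normal(0, scale, size=(n_in, n_out)), requires_grad=True
        )
        params[f"{name}_b"] = Tensor(np.zeros(n_out), requires_grad=True)

    p: dict[str, Tensor] = {}
    # generator: [z ; y] -> hidden -> L * channels logits
    sizes = [config.latent_dim + config.label_dim, *config.gen_hidden]
    for i in range(len(sizes) - 1):
        dense(f"g{i}", sizes[i], sizes[i + 1], p)
    dense("g_out", sizes[-1], config.x_dim, p)
    # critic trunk
    sizes = [config.x_dim, *config.disc_hidden]
    for i in range(len(sizes) - 1):
        dense(f"d{i}", sizes[i], sizes[i + 1], p)
    # per-branch label projections (no bias) and unconditional heads
    for bi, layer in enumerate(config.projection_branches):
        width = config.disc_hidden[layer - 1]
        p[f"v{bi}_W"] = Tensor(
            rng.normal(0, np.sqrt(1.0 / config.label_dim),
                       size=(config.label_dim, width)),
            requires_grad=True,
        )
        dense(f"psi{bi}", config.disc_hidden[-1], 1, p)
    # auxiliary classifier head
    dense("ac", config.disc_hidden[-1], config.label_dim, p)
    return p


def generator_forward(
    z: Tensor, y: Tensor, config: ConditionalGANConfig, params: Mapping[str, Tensor]
) -> Tensor:
    """Map latent noise + label encoding to (batch, L, channels) probabilities."""
    h = Tensor(np.concatenate([z.data, y.data], axis=1))
    for i in range(len(config.gen_hidden)):
        h = (h @ params[f"g{i}_W"] + params[f"g{i}_b"]).leaky_relu(
            config.leaky_slope
        )
    logits = h @ params["g_out_W"] + params["g_out_b"]
    batch = logits.shape[0]
    return logits.reshape((batch, config.seq_len, N_CHANNELS)).softmax(axis=-1)


def _trunk_activations(
    x: Tensor, config: ConditionalGANConfig, params: Mapping[str, Tensor]
) -> list[Tensor]:
    acts = []
    h = x
    for i in range(len(config.disc_hidden)):
        h = (h @ params[f"d{i}_W"] + params[f"d{i}_b"]).leaky_relu(
            config.leaky_slope
        )
        acts.append(h)
    return acts


def critic_forward(
    x: Tensor, y: Tensor, config: ConditionalGANConfig, params: Mapping[str, Tensor]
) -> tuple[Tensor, Tensor]:
    """Critic score and auxiliary-classifier logits for a flat one-hot batch.

    The score is the sum over projection branches of
    ``v_i(y)^T h_{p_i}(x) + psi_i(h_last(x))`` with identity activation
    (the Wasserstein critic convention).
    """
    acts = _trunk_activations(x, config, params)
    score = None
    for bi, layer in enumerate(config.projection_branches):
        proj = y @ params[f"v{bi}_W"]  # (batch, width)
        term = (proj * acts[layer - 1]).sum(axis=1, keepdims=True)
        uncond = acts[-1] @ params[f"psi{bi}_W"] + params[f"psi{bi}_b"]
        branch = term + uncond
        score = branch if score is None else score + branch
    ac_logits = acts[-1] @ params["ac_W"] + params["ac_b"]
    return score, ac_logits


def discriminator_score(
    x: np.ndarray,
    y: np.ndarray,
    config: ConditionalGANConfig,
    params: Mapping[str, Tensor],
) -> np.ndarray:
    """Critic scores for one-hot sequences ``x`` and label encodings ``y``.

    ``x`` may be (batch, L, channels) or already flattened to
    (batch, L * channels); returns one scalar score per row.
    """
    xa = np.asarray(x, dtype=float)
    if xa.ndim == 3:
        xa = xa.reshape(xa.shape[0], -1)
    if xa.shape[1] != config.x_dim:
        raise ValueError(f"expected {config.x_dim} input features, got {xa.shape[1]}")
    score, _ = critic_forward(Tensor(xa), Tensor(y), config, params)
    return score.data.ravel()


def ac_loss(probs: np.ndarray, y_true: np.ndarray, gamma: float = 1.0) -> float:
    """Auxiliary-classifier loss: summed per-label binary cross-entropy.

    ``probs`` are per-label probabilities in [0, 1]; the loss is the BCE
    summed over the label dimension, averaged over the batch and scaled
    by ``gamma``. Zero exactly when ``gamma`` is 0, and minimized (to 0)
    only by confident correct predictions.
    """
    if gamma == 0.0:
        return 0.0
    p = np.asarray(probs, dtype=float)
    t = np.asarray(y_true, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).sum(axis=-1)
    return float(gamma * bce.mean())


def _ac_loss_t(logits: Tensor, y_true: Tensor) -> Tensor:
    """Stable per-label BCE from logits: softplus(l) - l * y, summed and averaged."""
    per = logits.softplus() - logits * y_true
    return per.sum(axis=1).mean()


def gradient_penalty(
    params: Mapping[str, Tensor],
    config: ConditionalGANConfig,
    x_real: np.ndarray,
    x_fake: np.ndarray,
    y: np.ndarray,
    eps: np.ndarray,
) -> Tensor:
    """``mean((||grad_x D(x_hat, y)|| - 1)^2)`` on interpolates x_hat.

    ``eps`` holds the per-sample interpolation coefficients in [0, 1].
    The returned tensor is differentiable with respect to the critic
    parameters (double backpropagation).
    """
    e = eps.reshape(-1, 1)
    x_hat = Tensor(e * x_real + (1 - e) * x_fake, requires_grad=True)
    score, _ = critic_forward(x_hat, Tensor(y), config, params)
    (gx,) = grad(score.sum(), [x_hat])
    norms = ((gx**2.0).sum(axis=1) + 1e-12).sqrt()
    return ((norms - 1.0) ** 2.0).mean()


# ---------------------------------------------------------------------------
# Data encoding


def encode_sequences(
    seqs: Sequence[ProteinSequence], seq_len: int
) -> np.ndarray:
    """One-hot encode to (n, L * channels); positions past the end are PAD."""
    aa_index = {c: i for i, c in enumerate(AMINO_ACIDS)}
    out = np.zeros((len(seqs), seq_len, N_CHANNELS))
    for i, seq in enumerate(seqs):
        for j in range(seq_len):
            if j < len(seq.residues):
                out[i, j, aa_index[seq.residues[j]]] = 1.0
            else:
                out[i, j, PAD] = 1.0
    return out.reshape(len(seqs), -1)


def encode_labels(
    label_sets: Sequence[set[str]], vocabulary: Sequence[str]
) -> np.ndarray:
    """Sum of one-hot term encodings per sequence (multilabel encoding)."""
    index = {t: i for i, t in enumerate(vocabulary)}
    out = np.zeros((len(label_sets), len(vocabulary)))
    for i, labels in enumerate(label_sets):
        for t in labels:
            out[i, index[t]] = 1.0
    return out


@dataclass
class GeneratorModel:
    """A trained conditional sampler: (label set, count, seed) -> sequences."""

    config: ConditionalGANConfig
    params: dict[str, Tensor]
    vocabulary: list[str]
    history: list[dict] = field(default_factory=list, repr=False)

    def sample(
        self, labels: set[str], count: int, seed: int = 0, id_prefix: str = "gan"
    ) -> list[ProteinSequence]:
        """Decode ``count`` sequences conditioned on a label set.

        Per-position argmax over the channel distribution; the sequence
        is truncated at the first padding-channel argmax. If truncation
        would leave fewer than 5 residues, the padding channel is ignored
        for that draw (guaranteeing embeddable output).
        """
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((count, self.config.latent_dim))
        y = np.repeat(
            encode_labels([labels], self.vocabulary), count, axis=0
        )
        probs = generator_forward(
            Tensor(z), Tensor(y), self.config, self.params
        ).data
        out = []
        for i in range(count):
            best = probs[i].argmax(axis=-1)
            stops = np.flatnonzero(best == PAD)
            end = int(stops[0]) if stops.size else self.config.seq_len
            if end < 5:
                best = probs[i][:, :PAD].argmax(axis=-1)
                end = self.config.seq_len
            residues = "".join(AMINO_ACIDS[c] for c in best[:end] if c != PAD)
            out.append(
                ProteinSequence(
                    id=f"{id_prefix}{i:06d}", residues=residues, labels=set(labels)
                )
            )
        return out

    def save(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "vocabulary": self.vocabulary,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        for k in ("gen_hidden", "disc_hidden", "projection_branches", "betas"):
            cfg[k] = tuple(cfg[k])
        config = ConditionalGANConfig(**cfg)
        params = {
            k: Tensor(np.array(v), requires_grad=True)
            for k, v in payload["params"].items()
        }
        return cls(config=config, params=params, vocabulary=payload["vocabulary"])


def train_cgan(
    train: LabeledDataset, config: ConditionalGANConfig
) -> GeneratorModel:
    """Adversarial training of the miniature conditional WGAN-GP.

    Critic loss: mean D(fake) - mean D(real) + gp_weight * GP
    + ac_weight * (BCE on real + BCE on fake); generator loss:
    -mean D(fake) + ac_weight * BCE on fake. Raises on non-finite loss,
    naming the training step.
    """
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    g_names = [k for k in params if k.startswith("g")]
    d_names = [k for k in params if not k.startswith("g")]
    opt_g = Adam([params[k] for k in g_names], lr=config.lr_g, betas=config.betas)
    opt_d = Adam([params[k] for k in d_names], lr=config.lr_d, betas=config.betas)

    X = encode_sequences(train.sequences, config.seq_len)
    Y = encode_labels([s.labels for s in train.sequences], train.vocabulary)
    if Y.shape[1] != config.label_dim:
        raise ValueError(
            f"config.label_dim={config.label_dim} but corpus has "
            f"{Y.shape[1]} vocabulary terms"
        )
    n = X.shape[0]
    model = GeneratorModel(config=config, params=params,
                           vocabulary=list(train.vocabulary))

    for step in range(config.steps):
        for _ in range(config.critic_iters):
            idx = rng.choice(n, size=config.batch_size, replace=False)
            x_real, y = X[idx], Y[idx]
            z = rng.standard_normal((config.batch_size, config.latent_dim))
            x_fake = generator_forward(
                Tensor(z), Tensor(y), config, params
            ).data.reshape(config.batch_size, -1)

            score_r, ac_r = critic_forward(Tensor(x_real), Tensor(y), config, params)
            score_f, ac_f = critic_forward(Tensor(x_fake), Tensor(y), config, params)
            gp = gradient_penalty(
                params, config, x_real, x_fake, y,
                rng.random(config.batch_size),
            )
            yt = Tensor(y)
            d_loss = (
                score_f.mean() - score_r.mean()
                + config.gp_weight * gp
                + config.ac_weight * (_ac_loss_t(ac_r, yt) + _ac_loss_t(ac_f, yt))
            )
            if not np.isfinite(d_loss.data):
                raise FloatingPointError(
                    f"critic loss diverged at step {step}"
                )
            opt_d.step(grad(d_loss, [params[k] for k in d_names]))

        idx = rng.choice(n, size=config.batch_size, replace=False)
        y = Y[idx]
        z = rng.standard_normal((config.batch_size, config.latent_dim))
        x_fake_t = generator_forward(Tensor(z), Tensor(y), config, params)
        flat = x_fake_t.reshape((config.batch_size, -1))
        score_f, ac_f = critic_forward(flat, Tensor(y), config, params)
        g_loss = -score_f.mean() + config.ac_weight * _ac_loss_t(ac_f, Tensor(y))
        if not np.isfinite(g_loss.data):
            raise FloatingPointError(f"generator loss diverged at step {step}")
        opt_g.step(grad(g_loss, [params[k] for k in g_names]))

        if step % 100 == 0 or step == config.steps - 1:
            model.history.append(
                {"step": step, "d_loss": float(d_loss.data),
                 "g_loss": float(g_loss.data), "gp": float(gp.data)}
            )
    return model
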