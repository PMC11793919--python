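"""Adversarial imputation: networks, losses, training loop, imputation.

The generator receives the composed input M.X + (1-M).Z (observed entries of
the standardized series, small Gaussian noise in the missing slots), runs it
through a bidirectional (or unidirectional) GRUI stack driven by the
forward/backward time-lag matrices, and projects each combined hidden state
back to feature space, producing a full imputation G-hat. The completed
matrix is

    X-hat = M . X + (1 - M) . G-hat,

so observed entries are preserved exactly by construction. The discriminator
is a second GRUI stack scoring X-hat per entry (one raw critic score per
feature per timestep); scores at observed positions play the "real"
expectation and scores at imputed positions the "fake" expectation of the
f-divergence variational objective. Training alternates discriminator ascent
on L_D^f with generator descent on L_GA^f + lambda * L_R, after a
reconstruction-only pretraining phase. After training, the noise filling the
missing slots can be refined per sequence by gradient descent so the
generator's output best matches the observed context.

Noise is shaped like the data matrix, as the compose formula requires; the
`noise_dim` configuration field is retained for completeness but the
alternative latent-vector reading is not implemented.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import autodiff as ad
from .autodiff import Adam, Tensor, clip_grad_norm
from .fdiv import discriminator_loss, generator_adv_loss, get_divergence
from .grui import GRUIParams, _run_direction_t
from .series import IncompleteSeries, SeriesScaler, as_series_list

__all__ = [
    "TrainConfig",
    "SequenceNet",
    "ImputerNets",
    "compose_input",
    "generator_forward",
    "assemble_imputed",
    "reconstruction_loss",
    "generator_loss",
    "train",
    "refine_noise",
    "impute",
    "save_checkpoint",
    "load_checkpoint",
    "FDivGANImputer",
]


@dataclass
class TrainConfig:
    """All training hyperparameters.

    Defaults follow the reference configuration: batch 128, 64 hidden units,
    lambda = 0.15, learning rate 1e-3, 5 pretraining + 30 adversarial epochs,
    400 noise-refinement iterations. `d_steps_per_g_step` defaults to 1, or 5
    when the Wasserstein critic is selected (left as None to auto-resolve).
    """

    batch_size: int = 128
    hidden_size: int = 64
    noise_dim: int = 64  # recorded; the implemented noise is X-shaped
    lambda_recon: float = 0.15
    learning_rate: float = 0.001
    pretrain_epochs: int = 5
    epochs: int = 30
    refine_iterations: int = 400
    divergence: str = "forward_kl"
    direction: str = "bi"
    seed: int = 0
    d_steps_per_g_step: int | None = None
    noise_scale: float = 0.01
    max_grad_norm: float = 5.0
    refine_lr: float = 0.5
    lambda_adv_refine: float = 0.1
    clip_radius: float = 0.01  # Wasserstein weight-clipping radius

    def __post_init__(self):
        for name in ("batch_size", "hidden_size", "pretrain_epochs", "epochs",
                     "refine_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.batch_size == 0:
            raise ValueError("batch_size must be positive")
        if self.lambda_recon < 0:
            raise ValueError("lambda_recon must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.direction not in ("uni", "bi"):
            raise ValueError("direction must be 'uni' or 'bi'")
        get_divergence(self.divergence)  # validate the name early

    def resolved_d_steps(self) -> int:
        if self.d_steps_per_g_step is not None:
            return self.d_steps_per_g_step
        return 5 if self.divergence == "wasserstein" else 1


@dataclass
class SequenceNet:
    """A (bi)directional GRUI stack with a per-timestep affine projection."""

    fwd: GRUIParams
    bwd: GRUIParams | None
    W_out: Tensor
    b_out: Tensor

    def tensors(self) -> list:
        out = self.fwd.tensors() + [self.W_out, self.b_out]
        if self.bwd is not None:
            out = self.bwd.tensors() + out
        return out

    def apply(self, xs_cols, df_cols, db_cols) -> list:
        """Per-timestep (B, D_out) projections of the combined hidden states."""
        hf = _run_direction_t(xs_cols, df_cols, self.fwd, reverse=False)
        if self.bwd is not None:
            hb = _run_direction_t(xs_cols, db_cols, self.bwd, reverse=True)
            hs = [(a + b) * 0.5 for a, b in zip(hf, hb)]
        else:
            hs = hf
        return [ad.linear(h, self.W_out, self.b_out) for h in hs]

    @classmethod
    def initialize(cls, input_size, hidden_size, output_size, direction,
                   rng: np.random.Generator):
        limit = np.sqrt(6.0 / (hidden_size + output_size))
        return cls(
            fwd=GRUIParams.initialize(input_size, hidden_size, rng),
            bwd=(GRUIParams.initialize(input_size, hidden_size, rng)
                 if direction == "bi" else None),
            W_out=ad.parameter(rng.uniform(-limit, limit,
                                           size=(output_size, hidden_size))),
            b_out=ad.parameter(np.zeros(output_size)),
        )


@dataclass
class ImputerNets:
    """Generator and discriminator networks plus their structural metadata."""

    generator: SequenceNet
    discriminator: SequenceNet
    n_features: int
    hidden_size: int
    direction: str

    @classmethod
    def initialize(cls, n_features: int, config: TrainConfig,
                   rng: np.random.Generator):
        return cls(
            generator=SequenceNet.initialize(
                n_features, config.hidden_size, n_features, config.direction, rng),
            discriminator=SequenceNet.initialize(
                n_features, config.hidden_size, n_features, config.direction, rng),
            n_features=n_features,
            hidden_size=config.hidden_size,
            direction=config.direction,
        )


# ---- elementwise building blocks ----------------------------------------


def _check_same_shape(*arrs):
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def compose_input(X, M, Z) -> np.ndarray:
    """M.X + (1-M).Z: observed entries kept, missing slots filled with noise."""
    X, M, Z = (np.asarray(a, dtype=float) for a in (X, M, Z))
    _check_same_shape(X, M, Z)
    return M * np.nan_to_num(X) + (1.0 - M) * Z


def assemble_imputed(X, M, G_hat) -> np.ndarray:
    """X-hat = M.X + (1-M).G-hat; agrees with X exactly wherever M = 1."""
    X, M, G_hat = (np.asarray(a, dtype=float) for a in (X, M, G_hat))
    _check_same_shape(X, M, G_hat)
    return M * np.nan_to_num(X) + (1.0 - M) * G_hat


def reconstruction_loss(X, M, G_hat) -> float:
    """Squared error between X and G-hat on observed entries, mean-normalized."""
    X, M, G_hat = (np.asarray(a, dtype=float) for a in (X, M, G_hat))
    _check_same_shape(X, M, G_hat)
    obs = M == 1
    n = int(obs.sum())
    if n == 0:
        warnings.warn("reconstruction loss over zero observed entries; defined as 0")
        return 0.0
    diff = (X[obs] - G_hat[obs])
    return float((diff**2).sum() / n)


def generator_loss(adv: float, recon: float, lambda_recon: float) -> float:
    """L_G^f = L_GA^f + lambda * L_R."""
    return adv + lambda_recon * recon


# ---- batched internals ---------------------------------------------------


def _prepare(series: IncompleteSeries) -> dict:
    lags = series.lags()
    return {
        "X": np.nan_to_num(series.values),
        "M": series.mask.astype(float),
        "DF": lags.delta_f,
        "DB": lags.delta_b,
        "T": series.n_timesteps,
    }


def _stack_batch(items: list) -> dict:
    return {k: np.stack([it[k] for it in items]) for k in ("X", "M", "DF", "DB")}


def _cols(arr3d: np.ndarray) -> list:
    """(B, D, T) -> list over t of constant (B, D) tensors."""
    return [Tensor(arr3d[:, :, t]) for t in range(arr3d.shape[2])]


def _generator_cols(batch: dict, z_cols: list, nets: ImputerNets) -> list:
    M, X = batch["M"], batch["X"]
    composed = [
        Tensor(M[:, :, t] * X[:, :, t]) + Tensor(1.0 - M[:, :, t]) * z_cols[t]
        for t in range(X.shape[2])
    ]
    return nets.generator.apply(composed, _cols(batch["DF"]), _cols(batch["DB"]))


def _discriminator_scores(batch: dict, g_cols: list, nets: ImputerNets):
    M, X = batch["M"], batch["X"]
    xhat = [
        Tensor(M[:, :, t] * X[:, :, t]) + Tensor(1.0 - M[:, :, t]) * g_cols[t]
        for t in range(X.shape[2])
    ]
    s_cols = nets.discriminator.apply(xhat, _cols(batch["DF"]), _cols(batch["DB"]))
    return ad.stack(s_cols, axis=0)  # (T, B, D)


def _recon_tensor(batch: dict, g_cols: list):
    obs = np.stack([batch["M"][:, :, t] == 1 for t in range(batch["X"].shape[2])])
    if not obs.any():
        return Tensor(0.0), obs
    gst = ad.stack(g_cols, axis=0)
    xobs = np.stack([batch["X"][:, :, t] for t in range(batch["X"].shape[2])])[obs]
    diff = ad.select(gst, obs) - Tensor(xobs)
    return ad.tmean(diff**2), obs


def _mask_stack(batch: dict) -> np.ndarray:
    return np.stack([batch["M"][:, :, t] for t in range(batch["X"].shape[2])])


def _clip_weights(net: SequenceNet, radius: float) -> None:
    for p in net.tensors():
        np.clip(p.value, -radius, radius, out=p.value)


def _noise_like(shape, rng: np.random.Generator, scale: float) -> np.ndarray:
    return rng.normal(size=shape) * scale


# ---- public network application -----------------------------------------


def generator_forward(series: IncompleteSeries, Z, nets: ImputerNets,
                      config: TrainConfig | None = None) -> np.ndarray:
    """Run the generator on one sequence; returns the full (D, T) imputation."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape != series.values.shape:
        raise ValueError("noise must be shaped like the series values")
    if nets.n_features != series.n_features:
        raise ValueError("feature count differs from the trained networks")
    batch = _stack_batch([_prepare(series)])
    z_cols = [Tensor(Z[None, :, t]) for t in range(series.n_timesteps)]
    g_cols = _generator_cols(batch, z_cols, nets)
    return np.stack([c.value[0] for c in g_cols], axis=1)


# ---- training ------------------------------------------------------------


def _batches(prepared: list, batch_size: int, rng: np.random.Generator):
    """Shuffle, bucket by sequence length, and yield stacked batches."""
    order = rng.permutation(len(prepared))
    buckets: dict = {}
    for idx in order:
        buckets.setdefault(prepared[idx]["T"], []).append(prepared[idx])
    for T in sorted(buckets):
        items = buckets[T]
        for i in range(0, len(items), batch_size):
            yield _stack_batch(items[i : i + batch_size])


def train(dataset, config: TrainConfig):
    """Pretrain the generator on reconstruction, then run adversarial epochs.

    Sequences are expected in standardized units (see `standardize` /
    `FDivGANImputer`). Returns (nets, history) where history holds per-epoch
    pretraining reconstruction and per-epoch adversarial L_D, L_GA, L_R.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("cannot train on an empty dataset")
    spec = get_divergence(config.divergence)
    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    nets = ImputerNets.initialize(dataset[0].n_features, config, init_rng)
    prepared = [_prepare(s) for s in dataset]
    opt_g = Adam(nets.generator.tensors(), lr=config.learning_rate, betas=(0.5, 0.9))
    opt_d = Adam(nets.discriminator.tensors(), lr=config.learning_rate, betas=(0.5, 0.9))
    history = {"pretrain_recon": [], "d_loss": [], "g_adv": [], "recon": []}

    def _zero_all():
        opt_g.zero_grad()
        opt_d.zero_grad()

    for _ in range(config.pretrain_epochs):
        vals = []
        for batch in _batches(prepared, config.batch_size, shuffle_rng):
            z = _noise_like(batch["X"].shape, noise_rng, config.noise_scale)
            g_cols = _generator_cols(batch, _cols(z), nets)
            recon, _ = _recon_tensor(batch, g_cols)
            ad.backward(recon)
            clip_grad_norm(opt_g.params, config.max_grad_norm)
            opt_g.step()
            _zero_all()
            vals.append(recon.item())
        history["pretrain_recon"].append(float(np.mean(vals)) if vals else 0.0)

    d_steps = config.resolved_d_steps()
    for _ in range(config.epochs):
        dl, gl, rl = [], [], []
        for batch in _batches(prepared, config.batch_size, shuffle_rng):
            mstack = _mask_stack(batch)
            obs, miss = mstack == 1, mstack == 0
            z = _noise_like(batch["X"].shape, noise_rng, config.noise_scale)

            if obs.any() and miss.any():
                for _step in range(d_steps):
                    g_cols = _generator_cols(batch, _cols(z), nets)
                    detached = [Tensor(c.value) for c in g_cols]
                    scores = _discriminator_scores(batch, detached, nets)
                    loss_d = discriminator_loss(
                        ad.select(scores, obs), ad.select(scores, miss), spec)
                    ad.backward(-loss_d)
                    clip_grad_norm(opt_d.params, config.max_grad_norm)
                    opt_d.step()
                    _zero_all()
                    if spec.critic_based:
                        _clip_weights(nets.discriminator, config.clip_radius)
                    dl.append(loss_d.item())

            g_cols = _generator_cols(batch, _cols(z), nets)
            recon, obs_sel = _recon_tensor(batch, g_cols)
            if miss.any():
                scores = _discriminator_scores(batch, g_cols, nets)
                adv = generator_adv_loss(ad.select(scores, miss), spec)
            else:
                adv = Tensor(0.0)
            # Eq.-(10) weighting uses the squared Frobenius norm (a sum over
            # observed entries), so lambda multiplies the un-normalized error
            loss_g = adv + config.lambda_recon * recon * float(obs_sel.sum())
            ad.backward(loss_g)
            clip_grad_norm(opt_g.params, config.max_grad_norm)
            opt_g.step()
            _zero_all()
            gl.append(adv.item())
            rl.append(recon.item())
        history["d_loss"].append(float(np.mean(dl)) if dl else 0.0)
        history["g_adv"].append(float(np.mean(gl)) if gl else 0.0)
        history["recon"].append(float(np.mean(rl)) if rl else 0.0)
    return nets, history


# ---- noise refinement and imputation ------------------------------------


def _refine_noise_batch(items: list, nets: ImputerNets, config: TrainConfig,
                        z0s: list) -> list:
    """Refine missing-slot noise for a bucket of equal-length sequences.

    Sequences are independent: each keeps its own step size, backtracking
    acceptance and best-so-far reconstruction, so the result equals refining
    them one at a time while sharing the batched forward passes.
    """
    batch = _stack_batch([_prepare(s) for s in items])
    B, D, T = batch["X"].shape
    mstack = _mask_stack(batch)  # (T, B, D)
    obs_b = [mstack[:, b, :] == 1 for b in range(B)]
    miss_b = [mstack[:, b, :] == 0 for b in range(B)]
    z = np.stack(z0s).transpose(2, 0, 1).copy()  # (T, B, D)
    backup = z.copy()
    lr = np.full(B, config.refine_lr)
    best = np.full(B, np.inf)
    consecutive_rejects = np.zeros(B, dtype=int)

    def per_seq_losses(g_cols):
        gst = ad.stack(g_cols, axis=0)  # (T, B, D)
        terms, recon_vals = [], np.zeros(B)
        need_scores = any(m.any() for m in miss_b)
        sst = None
        if need_scores and config.lambda_adv_refine != 0:
            sst = _discriminator_scores(batch, g_cols, nets)
        for b in range(B):
            if obs_b[b].any():
                xobs = batch["X"][b].T[obs_b[b]]
                full = np.zeros_like(mstack, dtype=bool)
                full[:, b, :] = obs_b[b]
                diff = ad.select(gst, full) - Tensor(xobs)
                recon = ad.tmean(diff**2)
            else:
                recon = Tensor(0.0)
            recon_vals[b] = recon.item()
            term = recon
            if sst is not None and miss_b[b].any():
                full = np.zeros_like(mstack, dtype=bool)
                full[:, b, :] = miss_b[b]
                term = term + config.lambda_adv_refine * (
                    -ad.tmean(ad.select(sst, full)))
            terms.append(term)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total, recon_vals

    # a step is accepted while its recon component stays within RECON_TOL of
    # the best seen; rejected sequences revert and retry, halving their step
    # only after several consecutive rejections (recon is nearly flat in z
    # once the generator reconstructs well, so hard monotonicity would freeze
    # the adversarial pull)
    RECON_TOL = 1e-6
    PATIENCE = 5
    for _ in range(config.refine_iterations):
        z_cols = [ad.parameter(z[t]) for t in range(T)]
        loss, recon_vals = per_seq_losses(_generator_cols(batch, z_cols, nets))
        rejected = recon_vals > best + RECON_TOL
        accepted = ~rejected
        z[:, rejected, :] = backup[:, rejected, :]
        consecutive_rejects[rejected] += 1
        consecutive_rejects[accepted] = 0
        slow = rejected & (consecutive_rejects >= PATIENCE)
        lr[slow] *= 0.5
        consecutive_rejects[slow] = 0
        if accepted.any():
            best[accepted] = np.minimum(best[accepted], recon_vals[accepted])
            backup[:, accepted, :] = z[:, accepted, :]
            ad.backward(loss)
            for t in range(T):
                if z_cols[t].grad is not None:
                    z[t, accepted, :] -= (lr[accepted, None]
                                          * z_cols[t].grad[accepted, :])
        if (lr < 1e-9).all():
            break
    return [backup[:, b, :].T.copy() for b in range(B)]


def refine_noise(series: IncompleteSeries, nets: ImputerNets, config: TrainConfig,
                 z0: np.ndarray | None = None) -> np.ndarray:
    """Optimize the missing-slot noise for one sequence, weights held fixed.

    Plain gradient descent on L_R + lambda' * (-mean critic score at imputed
    positions), with backtracking so the reconstruction component is
    nonincreasing across accepted iterations. Returns the refined (D, T)
    noise matrix (observed-slot entries are inert and left unchanged).
    """
    if z0 is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
        z0 = _noise_like(series.values.shape, rng, config.noise_scale)
    z0 = np.asarray(z0, dtype=float)
    if z0.shape != series.values.shape:
        raise ValueError("noise must be shaped like the series values")
    if config.refine_iterations == 0:
        return z0.copy()
    return _refine_noise_batch([series], nets, config, [z0])[0]


def impute(dataset, nets: ImputerNets, config: TrainConfig,
           scaler: SeriesScaler | None = None) -> list:
    """Complete every sequence; observed entries are preserved exactly.

    Sequences must be in the units the networks were trained on (standardized
    if a scaler is given; its inverse maps the output back to original units).
    """
    dataset = list(dataset)
    for series in dataset:
        if series.n_features != nets.n_features:
            raise ValueError("feature count differs from the trained networks")
    noise = []
    for i, series in enumerate(dataset):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77, i]))
        noise.append(_noise_like(series.values.shape, rng, config.noise_scale))
    if config.refine_iterations > 0:
        # bucket equal-length sequences so refinement shares forward passes;
        # sequences are refined independently, so this matches one-at-a-time
        buckets: dict = {}
        for i, series in enumerate(dataset):
            buckets.setdefault(series.n_timesteps, []).append(i)
        for idxs in buckets.values():
            refined = _refine_noise_batch([dataset[i] for i in idxs], nets,
                                          config, [noise[i] for i in idxs])
            for i, z in zip(idxs, refined):
                noise[i] = z
    out = []
    for series, z in zip(dataset, noise):
        g_hat = generator_forward(series, z, nets, config)
        xhat = assemble_imputed(series.values, series.mask, g_hat)
        if scaler is not None:
            xhat = scaler.inverse_transform_values(xhat)
        out.append(
            IncompleteSeries(xhat, timestamps=series.timestamps.copy(),
                             feature_names=series.feature_names)
        )
    return out


# ---- checkpointing -------------------------------------------------------


def _net_arrays(net: SequenceNet, prefix: str) -> dict:
    arrays = {f"{prefix}.fwd.{k}": v for k, v in net.fwd.arrays().items()}
    if net.bwd is not None:
        arrays.update({f"{prefix}.bwd.{k}": v for k, v in net.bwd.arrays().items()})
    arrays[f"{prefix}.W_out"] = net.W_out.value
    arrays[f"{prefix}.b_out"] = net.b_out.value
    return arrays


def save_checkpoint(nets: ImputerNets, path) -> None:
    """Flat named-array container (.npz) with a JSON metadata entry."""
    meta = json.dumps({
        "n_features": nets.n_features,
        "hidden_size": nets.hidden_size,
        "direction": nets.direction,
    })
    arrays = _net_arrays(nets.generator, "gen")
    arrays.update(_net_arrays(nets.discriminator, "disc"))
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> ImputerNets:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))

    def load_net(prefix):
        fwd = GRUIParams.from_arrays(
            {k.split(".")[-1]: data[f"{prefix}.fwd.{k.split('.')[-1]}"]
             for k in data.files if k.startswith(f"{prefix}.fwd.")})
        bwd = None
        if any(k.startswith(f"{prefix}.bwd.") for k in data.files):
            bwd = GRUIParams.from_arrays(
                {k.split(".")[-1]: data[f"{prefix}.bwd.{k.split('.')[-1]}"]
                 for k in data.files if k.startswith(f"{prefix}.bwd.")})
        return SequenceNet(fwd, bwd, ad.parameter(data[f"{prefix}.W_out"]),
                           ad.parameter(data[f"{prefix}.b_out"]))

    return ImputerNets(load_net("gen"), load_net("disc"), meta["n_features"],
                       meta["hidden_size"], meta["direction"])


# ---- estimator surface ---------------------------------------------------


class FDivGANImputer(TransformerMixin, BaseEstimator):
    """GAN-based time-series imputer with an f-divergence adversarial loss.

    fit() standardizes the training sequences per feature, trains the
    generator/discriminator pair, and stores the fitted networks; transform()
    fills the missing entries of (new or the same) sequences, returning
    values in original units with observed entries untouched.

    Parameters mirror :class:`TrainConfig`; `random_state` seeds every source
    of randomness so fit/transform are fully reproducible.
    """

    def __init__(self, divergence="forward_kl", direction="bi", hidden_size=64,
                 batch_size=128, lambda_recon=0.15, learning_rate=0.001,
                 pretrain_epochs=5, epochs=30, refine_iterations=400,
                 d_steps_per_g_step=None, noise_scale=0.01, max_grad_norm=5.0,
                 refine_lr=0.5, lambda_adv_refine=0.1, random_state=0):
        self.divergence = divergence
        self.direction = direction
        self.hidden_size = hidden_size
        self.batch_size = batch_size
        self.lambda_recon = lambda_recon
        self.learning_rate = learning_rate
        self.pretrain_epochs = pretrain_epochs
        self.epochs = epochs
        self.refine_iterations = refine_iterations
        self.d_steps_per_g_step = d_steps_per_g_step
        self.noise_scale = noise_scale
        self.max_grad_norm = max_grad_norm
        self.refine_lr = refine_lr
        self.lambda_adv_refine = lambda_adv_refine
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, hidden_size=self.hidden_size,
            lambda_recon=self.lambda_recon, learning_rate=self.learning_rate,
            pretrain_epochs=self.pretrain_epochs, epochs=self.epochs,
            refine_iterations=self.refine_iterations, divergence=self.divergence,
            direction=self.direction, seed=self.random_state,
            d_steps_per_g_step=self.d_steps_per_g_step,
            noise_scale=self.noise_scale, max_grad_norm=self.max_grad_norm,
            refine_lr=self.refine_lr, lambda_adv_refine=self.lambda_adv_refine,
        )

    def fit(self, X, y=None, timestamps=None):
        dataset = as_series_list(X, timestamps)
        self.scaler_ = SeriesScaler().fit(dataset)
        standardized = self.scaler_.transform_dataset(dataset)
        self.nets_, self.history_ = train(standardized, self._config())
        self.n_features_in_ = dataset[0].n_features
        return self

    def transform(self, X, timestamps=None):
        if not hasattr(self, "nets_"):
            raise ValueError("imputer is not fitted")
        dataset = as_series_list(X, timestamps)
        standardized = self.scaler_.transform_dataset(dataset)
        completed = impute(standardized, self.nets_, self._config(), self.scaler_)
        if isinstance(X, np.ndarray):
            return np.stack([s.values for s in completed])
        return completed
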