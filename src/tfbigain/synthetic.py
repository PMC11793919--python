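"""Synthetic irregular multivariate time series with known ground truth.

The generator emulates the structure the imputer targets: cross-correlated
multivariate sequences with temporal autocorrelation, irregular timestamps,
and configurable completely-at-random (MCAR) missingness, plus an optional
bursty mechanism producing geometric runs of consecutive missing values
(which is what makes the accumulated time-lag recursions interesting).

The latent process is a VAR(1) with a shared scalar autoregressive
coefficient a and exchangeable innovation correlation rho:

    x_t = a x_{t-1} + e_t,   e_t ~ N(0, Sigma),
    Sigma = noise_sd^2 [(1 - rho) I + rho J],

initialized from its stationary marginal; the last feature additionally
carries a deterministic sinusoidal seasonal component evaluated at the
(possibly irregular) timestamps. Binary sequence labels follow a logistic
rule on the per-feature time means, standing in for a downstream
classification task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import IncompleteSeries

__all__ = [
    "SimConfig",
    "generate_complete",
    "apply_missingness",
    "generate_labels",
    "simulate",
]

SEASONAL_PERIOD = 12.0  # time units per cycle of the seasonal feature
SEASONAL_AMPLITUDE = 1.0
MIN_GAP = 0.1  # shortest irregular sampling gap (keeps timestamps increasing)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_sequences: int = 20
    n_features: int = 5
    n_timesteps: int = 48
    ar_coefficient: float = 0.8
    cross_corr: float = 0.3
    noise_sd: float = 1.0
    irregular: bool = True
    missing_rate: float = 0.2
    label_rule: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        errors = []
        if self.n_sequences < 1:
            errors.append("n_sequences must be >= 1")
        if self.n_features < 1:
            errors.append("n_features must be >= 1")
        if self.n_timesteps < 1:
            errors.append("n_timesteps must be >= 1")
        if not -1 < self.ar_coefficient < 1:
            errors.append("ar_coefficient must lie in (-1, 1) for stationarity")
        if not 0 <= self.cross_corr <= 1:
            errors.append("cross_corr must lie in [0, 1]")
        if self.noise_sd <= 0:
            errors.append("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            errors.append("missing_rate must lie in [0, 1)")
        if self.label_rule is not None and len(self.label_rule) != self.n_features:
            errors.append("label_rule length must equal n_features")
        if errors:
            raise ValueError("; ".join(errors))


def _innovation_chol(config: SimConfig) -> np.ndarray:
    D, rho = config.n_features, config.cross_corr
    sigma = config.noise_sd**2 * ((1 - rho) * np.eye(D) + rho * np.ones((D, D)))
    # exchangeable correlation with rho in [0,1] is positive semidefinite;
    # nudge the diagonal so Cholesky succeeds at rho = 1
    return np.linalg.cholesky(sigma + 1e-12 * np.eye(D))


def generate_complete(config: SimConfig) -> list:
    """Fully observed dataset of IncompleteSeries (mask all ones)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    D, T, a = config.n_features, config.n_timesteps, config.ar_coefficient
    chol = _innovation_chol(config)
    marginal_scale = 1.0 / np.sqrt(1.0 - a**2)
    out = []
    for _ in range(config.n_sequences):
        if config.irregular:
            gaps = MIN_GAP + rng.exponential(1.0 - MIN_GAP, size=T - 1)
            t = np.concatenate([[0.0], np.cumsum(gaps)])
        else:
            t = np.arange(T, dtype=float)
        x = np.empty((D, T))
        x[:, 0] = marginal_scale * (chol @ rng.standard_normal(D))
        for i in range(1, T):
            x[:, i] = a * x[:, i - 1] + chol @ rng.standard_normal(D)
        x[-1] += SEASONAL_AMPLITUDE * np.sin(2 * np.pi * t / SEASONAL_PERIOD)
        out.append(IncompleteSeries(x, timestamps=t))
    return out


def _draw_removal(shape, rate, rng, burst_mean_run=None):
    if burst_mean_run is None:
        return rng.random(shape) < rate
    # two-state Markov chain per feature row: stationary missing probability
    # `rate`, geometric missing runs with the requested mean length
    p_leave = 1.0 / burst_mean_run                 # missing -> observed
    p_enter = rate * p_leave / max(1.0 - rate, 1e-12)  # observed -> missing
    p_enter = min(p_enter, 1.0)
    D, T = shape
    removed = np.zeros(shape, dtype=bool)
    state = rng.random(D) < rate
    removed[:, 0] = state
    for i in range(1, T):
        u = rng.random(D)
        state = np.where(state, u >= p_leave, u < p_enter)
        removed[:, i] = state
    return removed


def apply_missingness(dataset, rate: float, seed: int = 0,
                      burst_mean_run: float | None = None):
    """Hide entries at random; returns (incomplete, truth, evaluation masks).

    Each entry is removed independently with probability `rate` (MCAR), or in
    geometric bursts of mean length `burst_mean_run` with the same marginal
    rate. Sequences left with a feature that has no observation are redrawn;
    the evaluation mask marks exactly the removed positions.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    incomplete, truth, eval_masks = [], [], []
    for s in dataset:
        for attempt in range(1000):
            removed = _draw_removal(s.values.shape, rate, rng, burst_mean_run)
            if ((~removed).sum(axis=1) >= 1).all():
                break
        else:  # pragma: no cover - reachable only at extreme rates
            removed[:, 0] = False
        vals = s.values.copy()
        vals[removed] = np.nan
        incomplete.append(
            IncompleteSeries(vals, timestamps=s.timestamps.copy(),
                             feature_names=s.feature_names)
        )
        truth.append(s.values.copy())
        eval_masks.append(removed)
    return incomplete, truth, eval_masks


def generate_labels(dataset, label_rule, seed: int = 0) -> np.ndarray:
    """Binary labels: Bernoulli(sigmoid(w . per-feature time means + noise))."""
    rule = np.asarray(label_rule, dtype=float)
    D = dataset[0].n_features
    if rule.shape != (D,):
        raise ValueError(f"label_rule must have length {D}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 307]))
    labels = np.empty(len(dataset), dtype=int)
    for i, s in enumerate(dataset):
        obs = s.mask == 1
        with np.errstate(invalid="ignore"):
            means = np.where(obs.any(axis=1),
                             np.nansum(np.where(obs, s.values, 0.0), axis=1)
                             / np.maximum(obs.sum(axis=1), 1), 0.0)
        logit = rule @ means + rng.normal(0.0, 0.1)
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        labels[i] = int(rng.random() < p)
    return labels


def simulate(config: SimConfig):
    """Full simulation: (incomplete, truth, eval_masks, labels-or-None)."""
    complete = generate_complete(config)
    incomplete, truth, eval_masks = apply_missingness(
        complete, config.missing_rate, seed=config.seed)
    labels = None
    if config.label_rule is not None:
        labels = generate_labels(complete, config.label_rule, seed=config.seed)
    return incomplete, truth, eval_masks, labels
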